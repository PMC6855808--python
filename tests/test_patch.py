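"""Tests for patch-clamp kinetics, dose-response and group statistics."""

import numpy as np
import pytest
from scipy import stats

import lipidmod as lm
from lipidmod.exceptions import DegenerateDataError, DomainError, FitFailureError


def decay_trace(components, plateau_current=0.0, peak=500.0, duration=21.0,
                rate=1000.0, noise=0.0, seed=0):
    """Pure decay from t=0 (activation treated as instantaneous)."""
    t = np.arange(0.0, duration, 1.0 / rate)
    i = np.full_like(t, plateau_current)
    total = sum(a for a, _ in components)
    for a, tau in components:
        i = i + (peak - plateau_current) * (a / total) * np.exp(-t / tau)
    if noise > 0:
        i = i + np.random.default_rng(seed).normal(0, noise * peak, t.shape)
    # prepend a two-sample rise so the peak is at a positive index
    t = np.concatenate([[-2e-3, -1e-3], t + 1e-9])
    i = np.concatenate([[0.0, peak / 2], i])
    return lm.CurrentTrace(t - t[0], i)


class TestFitActivation:
    def test_noiseless_roundtrip(self):
        traces, _ = lm.gen_current_traces(
            activation_tau=0.134, plateau=1.0, sigma=0.0, seed=1
        )
        assert lm.fit_activation(traces[0]) == pytest.approx(0.134, rel=0.01)

    def test_sampling_rate_invariance(self):
        taus = []
        for rate in (1000.0, 2000.0):
            traces, _ = lm.gen_current_traces(
                activation_tau=0.1, plateau=1.0, sigma=0.0, sample_rate=rate, seed=1
            )
            taus.append(lm.fit_activation(traces[0]))
        assert taus[0] == pytest.approx(taus[1], rel=0.01)

    def test_instantaneous_step_bounded_by_dt(self):
        t = np.arange(0.0, 1.0, 1e-3)
        i = np.where(t > 0, 100.0, 0.0)
        i[0] = 0.0
        tau = lm.fit_activation(lm.CurrentTrace(t, i))
        assert tau <= 1e-3 + 1e-12

    def test_no_rise_fails(self):
        t = np.arange(0.0, 1.0, 1e-3)
        with pytest.raises(FitFailureError):
            lm.fit_activation(lm.CurrentTrace(t, np.exp(-t)))


class TestFitDesensitization:
    def test_single_exponential_selects_single(self):
        tr = decay_trace([(1.0, 2.0)], plateau_current=50.0)
        fit = lm.fit_desensitization(tr)
        assert fit.model == "single"
        assert fit.components[0][1] == pytest.approx(2.0, rel=0.02)

    def test_double_roundtrip(self):
        tr = decay_trace([(0.5, 0.5), (0.5, 5.0)])
        fit = lm.fit_desensitization(tr)
        assert fit.model == "double"
        taus = sorted(tau for _, tau in fit.components)
        assert taus[0] == pytest.approx(0.5, rel=0.05)
        assert taus[1] == pytest.approx(5.0, rel=0.05)

    def test_identical_taus_fall_back_to_single(self):
        tr = decay_trace([(0.5, 2.0), (0.5, 2.0)])
        assert lm.fit_desensitization(tr).model == "single"

    def test_non_decaying_trace_fails(self):
        t = np.arange(0.0, 21.0, 1e-3)
        with pytest.raises(FitFailureError):
            lm.fit_desensitization(lm.CurrentTrace(t, np.linspace(0, 100, t.size)))

    def test_single_preferred_under_noise(self):
        """With 2% peak noise on single-exponential decays the double model
        must be selected at most rarely (parsimony under the null)."""
        wrong = 0
        for seed in range(50):
            tr = decay_trace([(1.0, 1.9)], plateau_current=50.0,
                             duration=10.0, rate=200.0, noise=0.02, seed=seed)
            if lm.fit_desensitization(tr).model == "double":
                wrong += 1
        assert wrong <= 2  # >= 95% correct


class TestWeightedTau:
    def test_equal_weights(self):
        fit = lm.ExpFitResult([(1.0, 2.0), (1.0, 4.0)], "double", 0.0, 0, 0, 0.0)
        assert lm.weighted_tau(fit) == pytest.approx(3.0)

    def test_direct_evaluation(self):
        fit = lm.ExpFitResult([(3.0, 0.5), (1.0, 2.0)], "double", 0.0, 0, 0, 0.0)
        assert lm.weighted_tau(fit) == pytest.approx(0.875)

    def test_single_identity(self):
        fit = lm.ExpFitResult([(5.0, 1.9)], "single", 0.0, 0, 0, 0.0)
        assert lm.weighted_tau(fit) == pytest.approx(1.9)

    def test_zero_amplitude_sum_rejected(self):
        fit = lm.ExpFitResult([(1.0, 2.0), (-1.0, 4.0)], "double", 0.0, 0, 0, 0.0)
        with pytest.raises(DomainError):
            lm.weighted_tau(fit)

    def test_bounded_by_component_taus(self):
        fit = lm.ExpFitResult([(2.0, 0.5), (1.0, 5.0)], "double", 0.0, 0, 0, 0.0)
        wt = lm.weighted_tau(fit)
        assert 0.5 <= wt <= 5.0


class TestExtentAt20s:
    def test_non_desensitizing_trace(self):
        t = np.arange(0.0, 21.0, 1e-2)
        tr = lm.CurrentTrace(t, np.full_like(t, 200.0))
        assert lm.extent_at_20s(tr) == pytest.approx(1.0)

    def test_fully_decayed_trace(self):
        tr = decay_trace([(1.0, 0.2)], plateau_current=0.0)
        assert lm.extent_at_20s(tr) == pytest.approx(0.0, abs=1e-6)

    def test_matches_generating_model(self):
        """Noiseless WT-like trace: the extent equals the generating
        envelope at 20 s divided by the observed peak envelope."""
        traces, truth = lm.gen_current_traces(sigma=0.0, seed=2)
        tr = traces[0]
        expected = truth["envelope_at_20s"] * 500.0 / tr.peak
        assert lm.extent_at_20s(tr) == pytest.approx(expected, rel=1e-6)

    def test_scaling_invariance(self):
        traces, _ = lm.gen_current_traces(sigma=0.0, seed=3)
        tr = traces[0]
        scaled = lm.CurrentTrace(tr.time, tr.current * 7.5)
        assert lm.extent_at_20s(scaled) == pytest.approx(lm.extent_at_20s(tr))

    def test_short_trace_rejected(self):
        t = np.arange(0.0, 5.0, 1e-2)
        tr = lm.CurrentTrace(t, np.exp(-t))
        with pytest.raises(DomainError):
            lm.extent_at_20s(tr)


class TestDoseResponse:
    @staticmethod
    def hill_peaks(ec50, imax=1000.0, noise=0.0, seed=0,
                   concs=(0.5, 1.0, 2.0, 5.0, 10.0, 30.0)):
        rng = np.random.default_rng(seed)
        out = []
        for c in concs:
            i = imax * c**2 / (c**2 + ec50**2)
            if noise > 0:
                i += rng.normal(0, noise * imax)
            out.append((c, i))
        return out

    def test_half_maximal_at_ec50(self):
        res = lm.fit_dose_response(self.hill_peaks(5.1))
        assert res.predict(res.params["ec50"]) == pytest.approx(
            res.params["i_max"] / 2, rel=1e-6
        )

    def test_noiseless_roundtrip(self):
        res = lm.fit_dose_response(self.hill_peaks(5.1))
        assert res.params["ec50"] == pytest.approx(5.1, rel=0.01)

    def test_current_scaling_leaves_ec50(self):
        peaks = self.hill_peaks(5.1)
        scaled = [(c, 3.0 * i) for c, i in peaks]
        a = lm.fit_dose_response(peaks)
        b = lm.fit_dose_response(scaled)
        assert a.params["ec50"] == pytest.approx(b.params["ec50"], rel=1e-9)
        assert b.params["i_max"] == pytest.approx(3 * a.params["i_max"], rel=1e-9)

    def test_recovery_across_reported_range(self):
        """EC50 recovered within 10% at 5% peak noise across the measured
        WT/mutant range (2.4 - 6.5 mM)."""
        for ec50 in (2.4, 5.1, 6.5):
            errs = []
            for seed in range(20):
                res = lm.fit_dose_response(self.hill_peaks(ec50, noise=0.05, seed=seed))
                errs.append(abs(res.params["ec50"] - ec50) / ec50)
            assert np.median(errs) < 0.10

    def test_no_saturation_flagged(self):
        res = lm.fit_dose_response(self.hill_peaks(40.0, concs=(0.5, 1, 2, 5)))
        assert res.wide_confidence


class TestCombineWeightedTaus:
    def test_single_fit_n1(self):
        fit = lm.ExpFitResult([(5.0, 1.9)], "single", 0.0, 0, 0, 0.0)
        mean, sd, n = lm.combine_weighted_taus([fit])
        assert (mean, sd, n) == (pytest.approx(1.9), 0.0, 1)

    def test_pooled_mean(self):
        single = lm.ExpFitResult([(5.0, 2.0)], "single", 0.0, 0, 0, 0.0)
        double = lm.ExpFitResult([(1.0, 0.9), (1.0, 2.9)], "double", 0.0, 0, 0, 0.0)
        mean, sd, n = lm.combine_weighted_taus([single, double])
        assert mean == pytest.approx(1.95)
        assert n == 2

    def test_permutation_invariance(self):
        fits = [
            lm.ExpFitResult([(1.0, tau)], "single", 0.0, 0, 0, 0.0)
            for tau in (0.5, 1.9, 3.2)
        ]
        a = lm.combine_weighted_taus(fits)
        b = lm.combine_weighted_taus(fits[::-1])
        assert a == b


class TestGroupCompare:
    def test_identical_groups_nothing_significant(self):
        vals = [1.0, 1.1, 0.9, 1.05]
        table = lm.group_compare({"a": vals, "b": vals, "c": vals})
        assert not table["significant"].any()

    def test_anova_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
        table = lm.group_compare({"a": a, "b": b})
        t_stat, _ = stats.ttest_ind(a, b)
        assert table.attrs["anova_F"] == pytest.approx(t_stat**2, rel=1e-9)

    def test_bonferroni_design_against_reference(self):
        rng = np.random.default_rng(8)
        wt = rng.normal(1.95, 0.1, 6)
        groups = {
            "WT": wt,
            "mutA": wt - 1.5,  # strongly different
            "mutB": wt + rng.normal(0, 0.01, 6),  # indistinguishable from WT
        }
        table = lm.group_compare(groups, design="wt_vs_mutants", reference="WT")
        res = dict(zip(table["group_b"], table["significant"]))
        assert res["mutA"] and not res["mutB"]

    def test_degenerate_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            lm.group_compare({"a": [1.0, 1.0], "b": [1.0, 1.0]})

    def test_reference_required_for_wt_design(self):
        with pytest.raises(DomainError):
            lm.group_compare({"a": [1, 2], "b": [2, 3]}, design="wt_vs_mutants")
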
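"""Patch-clamp activation/desensitization kinetics and dose-response.

Agonist-evoked currents from excised patches rise to a peak (activation,
fitted with a single exponential over the 10-90% rise window) and then
decay during sustained agonist application (desensitization, fitted with
single and double exponentials; the better model is selected by a
small-sample-corrected information criterion with identifiability guards).
Double fits are summarised by the amplitude-weighted time constant

.. math:: \\tau_w = \\frac{A_1\\tau_1 + A_2\\tau_2}{A_1 + A_2}

The extent of desensitization is the current 20 s after agonist onset
normalised to the peak.  Peak dose-response curves are fitted to a Hill
equation with n fixed at 2.  Group comparisons follow the study's designs:
one-way ANOVA with Tukey HSD for many-group comparisons, and pairwise
tests against a reference with Bonferroni correction for WT-versus-mutant
panels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .base import FitResults, stderr_from_covariance
from .exceptions import DegenerateDataError, DomainError, FitFailureError

__all__ = [
    "CurrentTrace",
    "ExpFitResult",
    "DesensMetrics",
    "DoseResponseModel",
    "DoseResponseResults",
    "fit_activation",
    "fit_desensitization",
    "weighted_tau",
    "extent_at_20s",
    "fit_dose_response",
    "combine_weighted_taus",
    "group_compare",
]

logger = logging.getLogger(__name__)


@dataclass
class CurrentTrace:
    """One agonist-evoked current trace; agonist application at t = 0."""

    time: np.ndarray  # s
    current: np.ndarray  # pA
    concentration: float = np.nan  # agonist, mM
    condition: str = ""
    patch_id: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.current)):
            raise ValueError("current must be finite")

    @property
    def peak_index(self) -> int:
        return int(np.argmax(np.abs(self.current)))

    @property
    def peak(self) -> float:
        return float(self.current[self.peak_index])


@dataclass
class ExpFitResult:
    """Single/double exponential decay fit with model selection scores."""

    components: List[Tuple[float, float]]  # (amplitude, tau)
    model: Literal["single", "double"]
    plateau: float
    aicc_single: float
    aicc_double: float
    rmse: float

    def __post_init__(self):
        if any(tau <= 0 for _, tau in self.components):
            raise ValueError("time constants must be positive")
        if self.model == "double" and len(self.components) != 2:
            raise ValueError("double model needs two components")


@dataclass
class DesensMetrics:
    """Summary metrics of one desensitization trace."""

    weighted_tau: float  # s
    norm_current_20s: float  # fraction of peak


def _aicc(ssr: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return n * math.log(max(ssr, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_activation(trace: CurrentTrace) -> float:
    """Single-exponential activation time constant (s) of the 10-90% rise.

    Flags an instantaneous rise (window narrower than one sample interval)
    by returning the sample interval; raises on traces with no peak.
    """
    i_peak = trace.peak_index
    if i_peak == 0:
        raise FitFailureError("no rising phase before the peak", {})
    t = trace.time[: i_peak + 1]
    i = trace.current[: i_peak + 1]
    peak = i[-1]
    lo, hi = 0.10 * peak, 0.90 * peak
    mask = (np.abs(i) >= abs(lo)) & (np.abs(i) <= abs(hi))
    dt = float(np.median(np.diff(trace.time)))
    if mask.sum() < 3:
        logger.warning("activation rise faster than sampling; tau bounded by dt")
        return dt
    tw, iw = t[mask], i[mask]

    def rise(tt, a, tau):
        return a * (1.0 - np.exp(-tt / tau))

    tau0 = max(tw[-1] - tw[0], dt)
    try:
        popt, _ = optimize.curve_fit(
            rise, tw, iw, p0=(peak, tau0),
            bounds=([-np.inf, dt / 100], [np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError as err:
        raise FitFailureError("activation fit did not converge", {"tau0": tau0}) from err
    return float(popt[1])


def fit_desensitization(trace: CurrentTrace) -> ExpFitResult:
    """Fit the decay from the peak with single and double exponentials
    (free plateau) and select by AICc.

    Selection guards: the double model is only preferred when its time
    constants are separated by at least a factor of 2 and both amplitudes
    carry the same sign and at least 5% of the total amplitude; otherwise
    the two components are not identifiable and the single fit is kept.
    """
    i_peak = trace.peak_index
    t = trace.time[i_peak:] - trace.time[i_peak]
    i = trace.current[i_peak:]
    if len(t) < 10:
        raise FitFailureError("too few samples after the peak", {})
    peak = i[0]
    if abs(i[-1]) >= abs(peak) * 0.999:
        raise FitFailureError("trace does not decay after the peak", {})

    def single(tt, c, a, tau):
        return c + a * np.exp(-tt / tau)

    def double(tt, c, a1, tau1, a2, tau2):
        return c + a1 * np.exp(-tt / tau1) + a2 * np.exp(-tt / tau2)

    amp0 = peak - i[-1]
    # time to decay halfway as tau guess
    half = i[-1] + amp0 / 2
    crossed = np.nonzero(np.abs(i) <= abs(half))[0]
    tau0 = float(t[crossed[0]]) if crossed.size else float(t[-1] / 3)
    tau0 = max(tau0, float(t[1]))

    try:
        ps, _ = optimize.curve_fit(
            single, t, i, p0=(i[-1], amp0, tau0),
            bounds=([-np.inf, -np.inf, 1e-7], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        ssr_s = float(np.sum((i - single(t, *ps)) ** 2))
    except RuntimeError as err:
        raise FitFailureError("single-exponential decay fit failed", {}) from err
    aicc_s = _aicc(ssr_s, len(t), 4)  # 3 params + variance

    best_d = None
    for split in (3.0, 10.0):
        p0 = (i[-1], amp0 / 2, tau0 / split, amp0 / 2, tau0 * split)
        try:
            pd_, _ = optimize.curve_fit(
                double, t, i, p0=p0,
                bounds=([-np.inf, -np.inf, 1e-7, -np.inf, 1e-7],
                        [np.inf, np.inf, np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        ssr = float(np.sum((i - double(t, *pd_)) ** 2))
        if best_d is None or ssr < best_d[0]:
            best_d = (ssr, pd_)
    aicc_d = _aicc(best_d[0], len(t), 6) if best_d else np.inf

    use_double = False
    if best_d is not None and aicc_d < aicc_s:
        _, (c, a1, tau1, a2, tau2) = best_d
        total = a1 + a2
        ratio = max(tau1, tau2) / min(tau1, tau2)
        same_sign = a1 * a2 > 0
        big_enough = (
            total != 0
            and min(abs(a1), abs(a2)) >= 0.05 * abs(total)
        )
        use_double = ratio >= 2.0 and same_sign and big_enough

    if use_double:
        ssr, (c, a1, tau1, a2, tau2) = best_d
        comps = sorted([(float(a1), float(tau1)), (float(a2), float(tau2))],
                       key=lambda x: x[1])
        return ExpFitResult(
            comps, "double", float(c), aicc_s, aicc_d,
            rmse=math.sqrt(ssr / len(t)),
        )
    c, a, tau = ps
    return ExpFitResult(
        [(float(a), float(tau))], "single", float(c), aicc_s, aicc_d,
        rmse=math.sqrt(ssr_s / len(t)),
    )


def weighted_tau(fit: ExpFitResult) -> float:
    """Amplitude-weighted time constant (s): (A1*tau1 + A2*tau2)/(A1 + A2)
    for double fits, the single tau otherwise."""
    if fit.model == "single":
        return fit.components[0][1]
    (a1, t1), (a2, t2) = fit.components
    if a1 + a2 == 0:
        raise DomainError("amplitudes sum to zero; weighted tau undefined")
    return (a1 * t1 + a2 * t2) / (a1 + a2)


def extent_at_20s(trace: CurrentTrace, at: float = 20.0) -> float:
    """Current ``at`` seconds after agonist onset, normalised to peak."""
    if trace.time[-1] < at:
        raise DomainError(f"trace shorter than {at} s after onset")
    i_at = float(np.interp(at, trace.time, trace.current))
    peak = trace.peak
    if peak == 0:
        raise DegenerateDataError("zero peak current")
    return i_at / peak


class DoseResponseResults(FitResults):
    """Hill (n = 2) dose-response fit of peak currents."""

    _title = "Peak dose-response (Hill n = 2)"

    def __init__(self, ec50, i_max, hill_n, bse, nobs, rmse, wide_confidence=False):
        super().__init__({"ec50": ec50, "i_max": i_max, "hill_n": hill_n}, bse, nobs, rmse)
        self.wide_confidence = bool(wide_confidence)

    def predict(self, c):
        c = np.asarray(c, dtype=float)
        p = self.params
        return p["i_max"] * c ** p["hill_n"] / (c ** p["hill_n"] + p["ec50"] ** p["hill_n"])

    def _summary_extra(self):
        return "[no saturation: wide confidence]" if self.wide_confidence else ""


class DoseResponseModel:
    """Hill dose-response model of peak current versus agonist concentration
    with the Hill coefficient fixed (default n = 2)."""

    def __init__(self, concentrations: Sequence[float], peaks: Sequence[float],
                 hill_n: float = 2.0):
        c = np.asarray(concentrations, dtype=float)
        i = np.asarray(peaks, dtype=float)
        if len(np.unique(c)) < 4:
            raise FitFailureError("need >= 4 distinct concentrations", {})
        self.c, self.i, self.hill_n = c, i, float(hill_n)

    def fit(self) -> DoseResponseResults:
        n = self.hill_n

        def hill(c, ec50, imax):
            return imax * c**n / (c**n + ec50**n)

        p0 = (float(np.median(self.c)), float(self.i.max()))
        try:
            popt, pcov = optimize.curve_fit(
                hill, self.c, self.i, p0=p0,
                bounds=([1e-9, -np.inf], [1e9, np.inf]), maxfev=20000,
            )
        except RuntimeError as err:
            raise FitFailureError("dose-response fit failed", {"p0": p0}) from err
        ec50, imax = popt
        wide = self.c.max() < 2 * ec50  # no saturation information
        resid = self.i - hill(self.c, *popt)
        se = stderr_from_covariance(pcov)
        return DoseResponseResults(
            float(ec50), float(imax), n,
            {"ec50": se[0], "i_max": se[1], "hill_n": np.nan},
            len(self.c), float(np.sqrt(np.mean(resid**2))),
            wide_confidence=wide,
        )


def fit_dose_response(
    peaks: Sequence[Tuple[float, float]], hill_n: float = 2.0
) -> DoseResponseResults:
    """Functional wrapper: ``peaks`` is a list of (concentration mM, peak)."""
    c, i = zip(*peaks)
    return DoseResponseModel(c, i, hill_n).fit()


def combine_weighted_taus(fits: Sequence[ExpFitResult]) -> Tuple[float, float, int]:
    """Pool weighted taus of double fits with taus of single fits.

    Returns (mean, sd, n); sd is 0 when n = 1 (single-observation flag via n).
    """
    if not fits:
        raise DomainError("need at least one fit")
    taus = np.asarray([weighted_tau(f) for f in fits])
    sd = float(taus.std(ddof=1)) if taus.size > 1 else 0.0
    return float(taus.mean()), sd, int(taus.size)


def group_compare(
    groups: Dict[str, Sequence[float]],
    design: Literal["many_vs_many", "wt_vs_mutants"] = "many_vs_many",
    reference: Optional[str] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group comparisons with the study's two designs.

    ``many_vs_many``: one-way ANOVA (F, p) followed by Tukey HSD adjusted
    pairwise p-values.  ``wt_vs_mutants``: two-sample t-tests of each group
    against ``reference`` with Bonferroni-adjusted p-values.

    Returns a tidy frame with columns group_a, group_b, statistic, p_adj,
    significant; the ANOVA F and p are attached as frame attrs.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise DomainError("need >= 2 groups")
    samples = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(len(v) < 2 for v in samples.values()):
        raise DomainError("each group needs n >= 2")
    if all(np.ptp(v) == 0 for v in samples.values()):
        raise DegenerateDataError("zero within-group variance everywhere")

    rows = []
    attrs = {}
    if design == "many_vs_many":
        f_stat, f_p = stats.f_oneway(*samples.values())
        attrs = {"anova_F": float(f_stat), "anova_p": float(f_p)}
        res = stats.tukey_hsd(*samples.values())
        for ia in range(len(labels)):
            for ib in range(ia + 1, len(labels)):
                p = float(res.pvalue[ia, ib])
                rows.append(
                    (labels[ia], labels[ib], float(res.statistic[ia, ib]), p, p < alpha)
                )
    elif design == "wt_vs_mutants":
        if reference is None or reference not in samples:
            raise DomainError("wt_vs_mutants design requires a valid reference group")
        others = [k for k in labels if k != reference]
        raw = []
        for k in others:
            t_stat, p = stats.ttest_ind(samples[reference], samples[k])
            raw.append((k, float(t_stat), float(p)))
        padj = multipletests([p for _, _, p in raw], alpha=alpha, method="bonferroni")[1]
        for (k, t_stat, _), p in zip(raw, padj):
            rows.append((reference, k, t_stat, float(p), p < alpha))
    else:
        raise DomainError(f"unknown design {design!r}")

    out = pd.DataFrame(
        rows, columns=["group_a", "group_b", "statistic", "p_adj", "significant"]
    )
    out.attrs.update(attrs)
    return out
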
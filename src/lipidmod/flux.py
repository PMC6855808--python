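"""Sequential-mixing stopped-flow flux kinetics.

Proteoliposomes loaded with the Tl+-quenchable fluorophore ANTS are exposed
to agonist for a controlled delay, then mixed with Tl+; the fluorescence
quench over the following second reports the open-channel fraction at that
delay.  Each quench trace is fitted to a stretched exponential

.. math:: F(t) = F_\\infty + (F_0 - F_\\infty) e^{-(t/\\tau)^\\beta}

whose instantaneous rate evaluated at 2 ms,
:math:`k = (\\beta/\\tau)(t/\\tau)^{\\beta-1}`, is the flux-rate readout.
Repeats are screened with a robust outlier rule (a deterministic surrogate
for visual inspection), averaged per delay, and the rate-versus-delay
course is decomposed into two exponentials

.. math:: K(t) = A_1 e^{-t/\\tau_1} + A_2 e^{-t/\\tau_2}

with the shorter time constant describing activation and the longer one
desensitization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .base import FitResults, stderr_from_covariance
from .exceptions import DegenerateDataError, DomainError, FitFailureError

__all__ = [
    "QuenchTrace",
    "StretchedFit",
    "RatePoint",
    "RateCourseModel",
    "RateCourseResults",
    "fit_stretched",
    "initial_rate",
    "screen_repeats",
    "aggregate_rates",
    "fit_rate_course",
    "T_EVAL",
]

logger = logging.getLogger(__name__)

#: time at which the influx rate is evaluated (s)
T_EVAL = 0.002


@dataclass
class QuenchTrace:
    """One stopped-flow fluorescence trace at one agonist delay."""

    time: np.ndarray  # s, strictly increasing, > 0
    fluorescence: np.ndarray
    delay: float  # agonist pre-incubation time, s
    condition: str = ""
    repeat: int = 0

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.size < 20:
            raise ValueError("quench trace needs >= 20 samples")
        if self.time[0] <= 0 or np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing from > 0")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("fluorescence must be finite")


@dataclass
class StretchedFit:
    """Stretched-exponential fit of one quench trace."""

    f0: float
    f_inf: float
    tau: float  # s
    beta: float  # (0, 1]
    rmse: float
    no_flux: bool = False
    delay: float = np.nan
    condition: str = ""
    repeat: int = 0

    def __post_init__(self):
        if not self.no_flux:
            if not self.tau > 0:
                raise ValueError("tau must be positive")
            if not (0 < self.beta <= 1):
                raise ValueError("beta must be in (0, 1]")


@dataclass
class RatePoint:
    """Mean influx rate at one delay after repeat screening."""

    delay: float  # s
    k_mean: float  # 1/s
    k_sd: float  # 1/s
    n_repeats_used: int
    n_repeats_rejected: int = 0


def _stretched(t, f0, f_inf, tau, beta):
    return f_inf + (f0 - f_inf) * np.exp(-((t / tau) ** beta))


def fit_stretched(trace: QuenchTrace, noise_floor_mult: float = 3.0) -> StretchedFit:
    """Least-squares stretched-exponential fit with tau > 0, beta in (0, 1].

    A trace whose amplitude is below ``noise_floor_mult`` times the local
    noise is flagged ``no_flux`` instead of being fitted.
    """
    t = trace.time
    f = trace.fluorescence
    # noise estimated from first differences (robust to the slow trend)
    noise = np.std(np.diff(f)) / math.sqrt(2) if f.size > 1 else 0.0

    def _no_flux():
        return StretchedFit(
            f0=float(f.mean()), f_inf=float(f.mean()), tau=np.inf, beta=1.0,
            rmse=float(np.std(f)), no_flux=True,
            delay=trace.delay, condition=trace.condition, repeat=trace.repeat,
        )

    # flux must produce a downward trend distinguishable from noise: compare
    # the head and tail means against their sampling error
    m = max(f.size // 10, 5)
    trend = float(np.mean(f[:m]) - np.mean(f[-m:]))
    trend_se = noise * math.sqrt(2.0 / m)
    if trend <= max(noise_floor_mult * trend_se, 1e-12):
        return _no_flux()
    f0_0 = float(f[0])
    finf_0 = float(f[-1])
    # tau guess: first crossing of 1/e of the amplitude
    target = finf_0 + (f0_0 - finf_0) / math.e
    below = np.nonzero(f <= target)[0] if f0_0 > finf_0 else np.nonzero(f >= target)[0]
    tau_0 = float(t[below[0]]) if below.size else float(t[-1])
    p0 = (f0_0, finf_0, max(tau_0, t[0]), 0.8)
    lo = [-np.inf, -np.inf, 1e-7, 1e-3]
    hi = [np.inf, np.inf, 1e7, 1.0]
    try:
        popt, _ = optimize.curve_fit(
            _stretched, t, f, p0=p0, bounds=(lo, hi), maxfev=10000
        )
    except RuntimeError as err:
        raise FitFailureError(
            "stretched-exponential fit did not converge",
            {"p0": p0, "error": str(err)},
        ) from err
    # if the fitted curve explains less quench over the recorded window
    # than the noise floor, the 2 ms extrapolation is meaningless
    explained = abs(_stretched(t[0], *popt) - _stretched(t[-1], *popt))
    if explained <= noise_floor_mult * noise:
        return _no_flux()
    resid = f - _stretched(t, *popt)
    return StretchedFit(
        f0=float(popt[0]), f_inf=float(popt[1]),
        tau=float(popt[2]), beta=float(popt[3]),
        rmse=float(np.sqrt(np.mean(resid**2))),
        delay=trace.delay, condition=trace.condition, repeat=trace.repeat,
    )


def initial_rate(fit: StretchedFit, t_eval: float = T_EVAL) -> float:
    """Instantaneous influx rate k = (beta/tau)*(t_eval/tau)^(beta-1) (1/s).

    A no-flux fit propagates as rate 0.
    """
    if fit.no_flux:
        return 0.0
    if not t_eval > 0:
        raise DomainError("t_eval must be positive")
    return (fit.beta / fit.tau) * (t_eval / fit.tau) ** (fit.beta - 1.0)


def screen_repeats(
    traces: Sequence[QuenchTrace],
    mad_threshold: float = 3.0,
    rmse_mult: float = 3.0,
    t_eval: float = T_EVAL,
) -> Tuple[List[StretchedFit], List[StretchedFit]]:
    """Partition the repeats at one delay into (kept, rejected).

    A repeat is rejected when its fitted rate deviates from the per-delay
    median by more than ``mad_threshold`` scaled median absolute deviations
    or its fit rmse exceeds ``rmse_mult`` times the median rmse.  With
    fewer than 3 repeats no rejection is attempted.
    """
    fits = [fit_stretched(tr) for tr in traces]
    if len(fits) < 3:
        if len(fits) > 1:
            logger.warning(
                "screen_repeats: only %d repeats; keeping all", len(fits)
            )
        return fits, []
    rates = np.asarray([initial_rate(f, t_eval) for f in fits])
    rmses = np.asarray([f.rmse for f in fits])
    med = np.median(rates)
    mad = 1.4826 * np.median(np.abs(rates - med))
    med_rmse = np.median(rmses)
    bad = np.zeros(len(fits), dtype=bool)
    if mad > 0:
        bad |= np.abs(rates - med) > mad_threshold * mad
    if med_rmse > 0:
        bad |= rmses > rmse_mult * med_rmse
    if bad.all():
        raise DegenerateDataError("all repeats rejected by the outlier screen")
    kept = [f for f, b in zip(fits, bad) if not b]
    rejected = [f for f, b in zip(fits, bad) if b]
    if rejected:
        logger.info(
            "screen_repeats: rejected %d/%d repeats at delay %.4g s",
            len(rejected), len(fits), traces[0].delay,
        )
    return kept, rejected


def aggregate_rates(
    traces_by_delay: Sequence[Sequence[QuenchTrace]],
    t_eval: float = T_EVAL,
    mad_threshold: float = 3.0,
) -> List[RatePoint]:
    """Screen and average the repeats of each delay into RatePoints."""
    points = []
    for group in traces_by_delay:
        kept, rejected = screen_repeats(group, mad_threshold=mad_threshold, t_eval=t_eval)
        rates = np.asarray([initial_rate(f, t_eval) for f in kept])
        sd = float(rates.std(ddof=1)) if rates.size > 1 else 0.0
        points.append(
            RatePoint(
                delay=group[0].delay,
                k_mean=float(rates.mean()),
                k_sd=sd,
                n_repeats_used=len(kept),
                n_repeats_rejected=len(rejected),
            )
        )
    points.sort(key=lambda p: p.delay)
    return points


def _double_exp(t, a1, tau1, a2, tau2):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


class RateCourseResults(FitResults):
    """Two-exponential decomposition of the rate-versus-delay course.

    Components are canonically ordered tau1 < tau2: tau1 is the activation
    time constant, tau2 the desensitization time constant.
    ``single_fallback`` marks courses with no resolvable second component.
    """

    _title = "Rate-course decomposition (activation / desensitization)"

    def __init__(self, a1, tau1, a2, tau2, bse, nobs, rmse, single_fallback=False):
        super().__init__(
            {"a1": a1, "tau1": tau1, "a2": a2, "tau2": tau2}, bse, nobs, rmse
        )
        self.single_fallback = bool(single_fallback)

    @property
    def activation_tau(self) -> float:
        return self.params["tau1"]

    @property
    def desensitization_tau(self) -> float:
        return self.params["tau2"]

    def predict(self, t):
        p = self.params
        return _double_exp(np.asarray(t, dtype=float), p["a1"], p["tau1"], p["a2"], p["tau2"])

    def _summary_extra(self):
        note = "  [single-component fallback]" if self.single_fallback else ""
        return (
            f"activation tau: {self.activation_tau:.4g} s    "
            f"desensitization tau: {self.desensitization_tau:.4g} s{note}"
        )


class RateCourseModel:
    """Model of the influx rate versus agonist-exposure delay.

    Parameters
    ----------
    points : list of :class:`RatePoint` (>= 5 delays spanning rise and decay)
    weighted : weight residuals by 1/sd where sds are available (default
        False, matching an unweighted least-squares fit)
    """

    def __init__(self, points: Sequence[RatePoint], weighted: bool = False):
        points = sorted(points, key=lambda p: p.delay)
        if len(points) < 5:
            raise FitFailureError(
                "need >= 5 delay points", {"n_points": len(points)}
            )
        self.points = points
        self.t = np.asarray([p.delay for p in points])
        self.k = np.asarray([p.k_mean for p in points])
        self.sd = np.asarray([p.k_sd for p in points])
        self.weighted = weighted

    @classmethod
    def from_traces(
        cls, traces_by_delay: Sequence[Sequence[QuenchTrace]], t_eval: float = T_EVAL
    ) -> "RateCourseModel":
        return cls(aggregate_rates(traces_by_delay, t_eval=t_eval))

    def fit(self) -> RateCourseResults:
        t, k = self.t, self.k
        sigma = None
        if self.weighted and np.all(self.sd > 0):
            sigma = self.sd
        kmax = k.max()
        i_peak = int(np.argmax(k))
        t_peak = t[i_peak] if t[i_peak] > 0 else t[1]
        # tail estimate of the slow time constant
        tail = (t > t_peak) & (k > 1e-12 * max(kmax, 1))
        if tail.sum() >= 2:
            slope = np.polyfit(t[tail], np.log(np.maximum(k[tail], 1e-300)), 1)[0]
            tau2_tail = -1.0 / slope if slope < 0 else 10 * t_peak
        else:
            tau2_tail = 10 * t_peak
        rising = i_peak > 0 and k[0] < 0.9 * kmax

        best = None
        if rising:
            for tau1_0 in (t_peak / 3, t_peak / 10, t_peak):
                for tau2_0 in (max(tau2_tail, 2 * tau1_0), 5 * t_peak, 20 * t_peak):
                    p0 = (-kmax, tau1_0, kmax, tau2_0)
                    try:
                        popt, pcov = optimize.curve_fit(
                            _double_exp, t, k, p0=p0, sigma=sigma,
                            bounds=([-np.inf, 1e-7, -np.inf, 1e-7],
                                    [np.inf, 1e7, np.inf, 1e7]),
                            maxfev=20000,
                        )
                    except RuntimeError:
                        continue
                    ssr = float(np.sum((k - _double_exp(t, *popt)) ** 2))
                    if best is None or ssr < best[0]:
                        best = (ssr, popt, pcov)
        # degenerate double fits (indistinct taus) also fall back
        resolvable = best is not None and (
            max(best[1][1], best[1][3]) / min(best[1][1], best[1][3]) > 1.05
        )
        if not resolvable:
            return self._fit_single(sigma)
        ssr, popt, pcov = best
        a1, tau1, a2, tau2 = popt
        se = stderr_from_covariance(pcov)
        if tau1 > tau2:  # canonical ordering
            a1, tau1, a2, tau2 = a2, tau2, a1, tau1
            se = se[[2, 3, 0, 1]]
        bse = dict(zip(("a1", "tau1", "a2", "tau2"), se))
        rmse = math.sqrt(ssr / len(t))
        return RateCourseResults(a1, tau1, a2, tau2, bse, len(t), rmse)

    def _fit_single(self, sigma) -> RateCourseResults:
        t, k = self.t, self.k

        def single(tt, a, tau):
            return a * np.exp(-tt / tau)

        tau0 = t[len(t) // 2]
        try:
            popt, pcov = optimize.curve_fit(
                single, t, k, p0=(k.max(), tau0), sigma=sigma,
                bounds=([-np.inf, 1e-7], [np.inf, 1e7]), maxfev=20000,
            )
        except RuntimeError as err:
            raise FitFailureError(
                "rate-course fit failed in both double and single form",
                {"error": str(err)},
            ) from err
        a, tau = popt
        se = stderr_from_covariance(pcov)
        resid = k - single(t, *popt)
        rmse = float(np.sqrt(np.mean(resid**2)))
        logger.warning("rate course: no resolvable second component; single fit")
        return RateCourseResults(
            0.0, tau, a, tau,
            {"a1": np.nan, "tau1": se[1], "a2": se[0], "tau2": se[1]},
            len(t), rmse, single_fallback=True,
        )


def fit_rate_course(points: Sequence[RatePoint], weighted: bool = False) -> RateCourseResults:
    """Functional wrapper around :class:`RateCourseModel`."""
    return RateCourseModel(points, weighted=weighted).fit()
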
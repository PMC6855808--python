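"""Thermal-stability Hill fit and the binding-to-stability coupling.

The thermal stabilizing effect of a lipid is the ratio of the pentamer peak
height after heating with lipid to the heated no-lipid control, so the
baseline (no lipid) is 1 by construction.  The effect versus lipid
concentration follows a Hill curve

.. math:: E(c) = 1 + (E_{max} - 1)\\,\\frac{c^n}{c^n + EC_{50}^n}

Because the binding experiment (native MS) and the stability assay were run
under the same conditions, concentration can be eliminated between the
binding curve (average bound lipids versus c) and the Hill curve, giving
the fractional stabilizing effect as a function of the number of bound
lipids.  Binding does not approach saturation over the measurable range, so
the binding curve is extrapolated — by default linearly through the origin
and the last measured point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .base import FitResults, stderr_from_covariance
from .exceptions import DomainError, FitFailureError
from .ms_binding import BindingCurve

__all__ = [
    "StabilityMeasurement",
    "HillCurve",
    "CouplingCurve",
    "HillStabilityModel",
    "HillStabilityResults",
    "fit_hill_stability",
    "fractional_effect",
    "couple_binding_to_stability",
]


@dataclass(frozen=True)
class StabilityMeasurement:
    """One (concentration, effect-ratio) observation."""

    concentration: float  # uM
    effect: float  # pentamer peak height with lipid / heated control
    replicate: int = 0

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if not np.isfinite(self.effect):
            raise ValueError("effect must be finite")


@dataclass(frozen=True)
class HillCurve:
    """Hill parameters of the stabilizing effect."""

    ec50: float  # uM
    hill_n: float
    e_max: float
    baseline: float = 1.0

    def __post_init__(self):
        if not self.ec50 > 0:
            raise ValueError("ec50 must be positive")
        if not self.hill_n > 0:
            raise ValueError("hill_n must be positive")
        if self.e_max < self.baseline:
            raise ValueError("e_max must be >= baseline")


@dataclass
class CouplingCurve:
    """Fractional stabilizing effect versus bound-lipid count."""

    points: List[Tuple[float, float]]  # (n_bound, fractional_effect in [0,1])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["n_bound", "fractional_effect"])


def fractional_effect(curve: HillCurve, concentration: float) -> float:
    """Fraction of the maximal stabilizing effect, c^n/(c^n + EC50^n)."""
    if concentration < 0:
        raise DomainError("concentration must be >= 0")
    if concentration == 0:
        return 0.0
    cn = concentration**curve.hill_n
    return cn / (cn + curve.ec50**curve.hill_n)


def _hill(c, ec50, n, e_max, baseline=1.0):
    c = np.asarray(c, dtype=float)
    frac = np.where(c > 0, c**n / (c**n + ec50**n), 0.0)
    return baseline + (e_max - baseline) * frac


class HillStabilityResults(FitResults):
    """Fitted Hill curve with standard errors from the fit covariance."""

    _title = "Hill fit of thermal stabilizing effect"

    def __init__(self, curve: HillCurve, bse, nobs, rmse):
        super().__init__(
            {"ec50": curve.ec50, "hill_n": curve.hill_n, "e_max": curve.e_max},
            bse,
            nobs=nobs,
            rmse=rmse,
        )
        self.curve = curve

    def predict(self, concentration):
        return _hill(
            concentration,
            self.curve.ec50,
            self.curve.hill_n,
            self.curve.e_max,
            self.curve.baseline,
        )

    def fractional_effect(self, concentration: float) -> float:
        return fractional_effect(self.curve, concentration)


class HillStabilityModel:
    """Least-squares Hill model of stabilizing effect versus concentration.

    The baseline is fixed at 1 (no lipid equals the heated control by the
    definition of the effect ratio); EC50, Hill n and E_max are free.
    """

    def __init__(self, data: Sequence[StabilityMeasurement]):
        data = list(data)
        concs = {m.concentration for m in data}
        if len(concs) < 4:
            raise FitFailureError(
                "need >= 4 distinct concentrations for a Hill fit",
                {"n_concentrations": len(concs)},
            )
        self.data = data
        self.c = np.asarray([m.concentration for m in data], dtype=float)
        self.e = np.asarray([m.effect for m in data], dtype=float)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "HillStabilityModel":
        """Build from a frame with columns concentration_uM, effect
        (optional replicate)."""
        reps = df["replicate"] if "replicate" in df.columns else np.zeros(len(df))
        data = [
            StabilityMeasurement(c, e, int(r))
            for c, e, r in zip(df["concentration_uM"], df["effect"], reps)
        ]
        return cls(data)

    def fit(self, baseline: float = 1.0) -> HillStabilityResults:
        span = self.e.max() - baseline
        noise = max(np.std(self.e[self.c == self.c.min()]), 1e-12)
        if span <= max(3 * noise, 1e-9):
            raise FitFailureError(
                "no stabilizing signal above baseline",
                {"max_effect": float(self.e.max()), "baseline": baseline},
            )
        # initial guesses: EC50 at the half-rise concentration, n ~ 1.5
        half = baseline + span / 2
        above = self.c[self.e >= half]
        ec50_0 = float(above.min()) if above.size else float(np.median(self.c[self.c > 0]))
        p0 = (max(ec50_0, 1e-6), 1.5, self.e.max())
        try:
            popt, pcov = optimize.curve_fit(
                lambda c, ec50, n, emax: _hill(c, ec50, n, emax, baseline),
                self.c,
                self.e,
                p0=p0,
                bounds=([1e-9, 0.05, baseline], [1e9, 20.0, np.inf]),
                maxfev=20000,
            )
        except RuntimeError as err:
            raise FitFailureError(
                "Hill fit did not converge", {"p0": p0, "error": str(err)}
            ) from err
        curve = HillCurve(popt[0], popt[1], popt[2], baseline)
        resid = self.e - _hill(self.c, *popt, baseline)
        rmse = float(np.sqrt(np.mean(resid**2)))
        se = stderr_from_covariance(pcov)
        bse = {"ec50": se[0], "hill_n": se[1], "e_max": se[2]}
        return HillStabilityResults(curve, bse, len(self.c), rmse)


def fit_hill_stability(data: Sequence[StabilityMeasurement]) -> HillCurve:
    """Functional wrapper: fit and return the HillCurve only."""
    return HillStabilityModel(data).fit().curve


def _invert_binding(
    binding: BindingCurve, n_bound: float, extrapolation: str
) -> float:
    """Concentration at which the (extrapolated) binding curve reaches
    ``n_bound`` average bound lipids."""
    c = binding.concentrations
    a = binding.avg_bound
    if np.any(np.diff(a) <= 0):
        raise DomainError("binding curve must be strictly increasing to invert")
    if n_bound < 0:
        raise DomainError("n_bound must be >= 0")
    if n_bound <= a[-1]:
        # piecewise-linear inversion within the measured range, anchored
        # at the origin below the first point
        aa = np.concatenate([[0.0], a])
        cc = np.concatenate([[0.0], c])
        return float(np.interp(n_bound, aa, cc))
    if extrapolation == "linear":
        # line through the origin and the last measured point
        return float(n_bound * c[-1] / a[-1])
    if extrapolation == "model":
        raise DomainError(
            "model extrapolation cannot reach bound counts beyond the "
            "measured range without a saturating model; supply one via "
            "the binding curve or use extrapolation='linear'"
        )
    raise DomainError(f"unknown extrapolation {extrapolation!r}")


def couple_binding_to_stability(
    binding: BindingCurve,
    curve: HillCurve,
    n_bound: Sequence[float] | float,
    extrapolation: str = "linear",
) -> CouplingCurve:
    """Fractional stabilizing effect as a function of bound-lipid count.

    For each queried ``n_bound``, the binding curve is inverted for the
    concentration giving that average bound count (linearly extrapolated
    beyond the measured range through the origin and the last point), and
    the fractional Hill effect is evaluated at that concentration.
    """
    if len(binding.points) < 1:
        raise DomainError("binding curve needs at least one point")
    queries = np.atleast_1d(np.asarray(n_bound, dtype=float))
    points = []
    for n in queries:
        if n == 0:
            points.append((0.0, 0.0))
            continue
        c = _invert_binding(binding, float(n), extrapolation)
        points.append((float(n), fractional_effect(curve, c)))
    return CouplingCurve(points)
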
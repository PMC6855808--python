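"""Native-MS lipid-binding quantification and the binomial equal-site model.

Native mass spectrometry of an intact pentameric channel resolves peaks for
the apo protein and for the protein with 1, 2, ... n bound phospholipids.
From the deconvoluted peak heights :math:`I_n` at one lipid concentration we
compute the average number of bound lipids

.. math:: \\bar{n} = \\frac{\\sum_n n I_n}{\\sum_n I_n}

and, across a concentration series, fit a binomial binding model: N
equivalent, independent sites each with dissociation constant K, so that at
free lipid concentration [A] the per-site occupancy is
:math:`p = [A]/([A]+K)` and the mole fraction of the q-bound species is
:math:`\\binom{N}{q} p^q (1-p)^{N-q}`.  Either K is fitted with N fixed
(e.g. N = 32, the annular site count from coarse-grained simulations) or N
is selected over an integer grid with K fixed — the latter quantifies site
loss in binding-deficient mutants.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .base import FitResults
from .exceptions import (
    ComparabilityError,
    DegenerateDataError,
    DomainError,
    FitFailureError,
)

__all__ = [
    "LipidSpecies",
    "PeakSet",
    "BindingCurve",
    "BinomialBindingModel",
    "average_bound",
    "occupancy",
    "bound_distribution",
    "expected_bound",
    "filter_charge_states",
    "affinity_ratio",
    "BinomialSiteModel",
    "BinomialSiteResults",
]

FitMode = Literal["fit_K", "fit_N"]

#: default upper charge state retained for deconvolution-derived peak tables
DEFAULT_MAX_CHARGE = 26

#: integer grid searched in fit_N mode; N is a site count, not a continuous
#: parameter, so the search is exhaustive and reproducible
N_GRID = range(1, 65)


@dataclass(frozen=True)
class LipidSpecies:
    """A phospholipid species.

    ``charge_class`` distinguishes anionic (e.g. PG) from zwitterionic
    (PE, PC) headgroups; ``average_mass`` is the ~750 Da average mass that
    separates adjacent bound states in the deconvoluted spectrum.
    """

    name: str
    charge_class: str = "zwitterionic"
    average_mass: Optional[float] = None

    def __post_init__(self):
        if not self.name:
            raise ValueError("species name must be nonempty")
        if self.charge_class not in ("anionic", "zwitterionic"):
            raise ValueError(f"unknown charge_class {self.charge_class!r}")
        if self.average_mass is not None and not self.average_mass > 0:
            raise ValueError("average_mass must be positive")


POPG = LipidSpecies("POPG", "anionic", 748.5)
POPE = LipidSpecies("POPE", "zwitterionic", 717.5)
POPC = LipidSpecies("POPC", "zwitterionic", 759.6)


@dataclass
class PeakSet:
    """Deconvoluted peak heights by bound-lipid count at one concentration.

    ``entries`` is a list of ``(n_bound, intensity)`` pairs with strictly
    increasing ``n_bound``; intensities are arbitrary-unit peak heights.
    """

    species: LipidSpecies
    concentration: float  # uM
    entries: List[Tuple[int, float]]
    charge_state_max: Optional[int] = None

    def __post_init__(self):
        ns = [n for n, _ in self.entries]
        if any(n < 0 or n != int(n) for n in ns):
            raise ValueError("n_bound values must be nonnegative integers")
        if any(b <= a for a, b in zip(ns, ns[1:])):
            raise ValueError("n_bound values must be strictly increasing")
        ivals = np.asarray([i for _, i in self.entries], dtype=float)
        if ivals.size == 0:
            raise ValueError("PeakSet needs at least one entry")
        if not np.all(np.isfinite(ivals)) or np.any(ivals < 0):
            raise ValueError("intensities must be finite and >= 0")

    @property
    def n_bound(self) -> np.ndarray:
        return np.asarray([n for n, _ in self.entries], dtype=int)

    @property
    def intensities(self) -> np.ndarray:
        return np.asarray([i for _, i in self.entries], dtype=float)

    def mole_fractions(self) -> np.ndarray:
        """Intensities normalised to unit sum."""
        ivals = self.intensities
        total = ivals.sum()
        if total <= 0:
            raise DegenerateDataError("all intensities are zero")
        return ivals / total


@dataclass
class BindingCurve:
    """Average bound lipids versus concentration for one species."""

    species: LipidSpecies
    # (concentration uM, avg_bound, sd, n_replicates)
    points: List[Tuple[float, float, float, int]]

    def __post_init__(self):
        cs = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(cs, cs[1:])):
            raise ValueError("concentrations must be strictly increasing")

    @property
    def concentrations(self) -> np.ndarray:
        return np.asarray([p[0] for p in self.points], dtype=float)

    @property
    def avg_bound(self) -> np.ndarray:
        return np.asarray([p[1] for p in self.points], dtype=float)


@dataclass(frozen=True)
class BinomialBindingModel:
    """N equivalent sites with dissociation constant ``k_d`` (uM)."""

    n_sites: int
    k_d: float

    def __post_init__(self):
        if self.n_sites < 1 or self.n_sites != int(self.n_sites):
            raise ValueError("n_sites must be a positive integer")
        if not (np.isfinite(self.k_d) and self.k_d > 0):
            raise ValueError("k_d must be finite and positive")


def average_bound(peaks: PeakSet) -> float:
    """Average number of bound lipids, sum(n*I_n)/sum(I_n).

    Raises :class:`DegenerateDataError` if all intensities are zero.
    """
    fracs = peaks.mole_fractions()
    return float(np.dot(peaks.n_bound, fracs))


def occupancy(model: BinomialBindingModel, concentration: float) -> float:
    """Per-site occupancy p = [A]/([A]+K) at lipid concentration [A] (uM)."""
    if concentration < 0:
        raise DomainError("concentration must be >= 0")
    return concentration / (concentration + model.k_d)


def bound_distribution(model: BinomialBindingModel, concentration: float) -> np.ndarray:
    """Mole fractions of the q-bound species for q = 0..N (binomial pmf)."""
    p = occupancy(model, concentration)
    q = np.arange(model.n_sites + 1)
    return stats.binom.pmf(q, model.n_sites, p)


def expected_bound(model: BinomialBindingModel, concentration: float) -> float:
    """Mean bound-lipid count N*p; the model's prediction for average_bound."""
    return model.n_sites * occupancy(model, concentration)


def filter_charge_states(
    raw_peaks: pd.DataFrame,
    max_charge: int = DEFAULT_MAX_CHARGE,
    species: LipidSpecies = POPG,
    concentration: float = 0.0,
) -> PeakSet:
    """Restrict a per-charge-state peak table to charges <= ``max_charge``
    and sum intensities per bound count.

    High charge states systematically under-report binding (electrostatic
    stripping of bound lipid), so deconvolution of lipid-bound spectra is
    restricted to the low charge states.
    """
    required = {"charge", "n_bound", "intensity"}
    missing = required - set(raw_peaks.columns)
    if missing:
        raise DomainError(f"peak table missing columns: {sorted(missing)}")
    kept = raw_peaks[raw_peaks["charge"] <= max_charge]
    if kept.empty:
        raise DegenerateDataError(
            f"no peaks remain with charge <= {max_charge}"
        )
    summed = kept.groupby("n_bound", sort=True)["intensity"].sum()
    entries = [(int(n), float(i)) for n, i in summed.items()]
    return PeakSet(species, concentration, entries, charge_state_max=max_charge)


class BinomialSiteResults(FitResults):
    """Fitted binomial site model.

    Attributes
    ----------
    model : BinomialBindingModel with the fitted (N, K)
    mode : "fit_K" or "fit_N"
    objective : minimised summed squared residual
    fitted_on : "mole_fractions" or "avg_bound"
    """

    _title = "Binomial equal-site binding fit"

    def __init__(self, model, mode, objective, fitted_on, bse, nobs, rmse):
        super().__init__(
            {"n_sites": model.n_sites, "k_d": model.k_d},
            bse,
            nobs=nobs,
            rmse=rmse,
        )
        self.model = model
        self.mode = mode
        self.objective = float(objective)
        self.fitted_on = fitted_on

    def _summary_extra(self):
        return f"mode: {self.mode}    objective (SSR): {self.objective:.5g}"

    def predict(self, concentration: float) -> np.ndarray:
        return bound_distribution(self.model, concentration)

    def expected_bound(self, concentration: float) -> float:
        return expected_bound(self.model, concentration)

    def to_json(self, seed: Optional[int] = None) -> str:
        rec = {
            "n_sites": self.model.n_sites,
            "k_d_uM": self.model.k_d,
            "mode": self.mode,
            "objective": self.objective,
            "fitted_on": self.fitted_on,
            "k_d_stderr_uM": self.bse.get("k_d"),
        }
        if seed is not None:
            rec["seed"] = seed
        return json.dumps(rec, indent=2)


class BinomialSiteModel:
    """Joint binomial-site fit over a native-MS concentration series.

    Parameters
    ----------
    data : list of :class:`PeakSet`
        Peak tables for one lipid species at >= 2 concentrations.
    fitted_on : "mole_fractions" (default; residuals on per-concentration
        mole-fraction histograms) or "avg_bound" (residuals on the
        average-bound curve).

    All concentrations are weighted equally in the joint objective.
    """

    def __init__(self, data: Sequence[PeakSet], fitted_on: str = "mole_fractions"):
        if fitted_on not in ("mole_fractions", "avg_bound"):
            raise ValueError("fitted_on must be 'mole_fractions' or 'avg_bound'")
        data = list(data)
        if len({ps.concentration for ps in data}) < 2:
            raise FitFailureError(
                "need peak sets at >= 2 distinct concentrations",
                {"n_concentrations": len({ps.concentration for ps in data})},
            )
        if all(np.all(ps.n_bound == 0) for ps in data):
            raise FitFailureError(
                "all peak sets are apo-only; K and N are unidentifiable",
                {"reason": "no bound species observed"},
            )
        self.data = data
        self.fitted_on = fitted_on
        self.species = data[0].species

    # -- objective ---------------------------------------------------------
    def _residuals(self, n_sites: int, k_d: float) -> np.ndarray:
        model = BinomialBindingModel(n_sites, k_d)
        res = []
        for ps in self.data:
            if self.fitted_on == "mole_fractions":
                obs = ps.mole_fractions()
                p = occupancy(model, ps.concentration)
                pred = stats.binom.pmf(np.minimum(ps.n_bound, n_sites), n_sites, p)
                pred = np.where(ps.n_bound > n_sites, 0.0, pred)
                res.append(obs - pred)
            else:
                res.append(
                    np.atleast_1d(
                        average_bound(ps) - expected_bound(model, ps.concentration)
                    )
                )
        return np.concatenate(res)

    def objective(self, n_sites: int, k_d: float) -> float:
        """Summed squared residual at (N, K)."""
        r = self._residuals(n_sites, k_d)
        return float(np.dot(r, r))

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        mode: FitMode = "fit_K",
        n_sites: Optional[int] = None,
        k_d: Optional[float] = None,
    ) -> BinomialSiteResults:
        """Fit with one free parameter.

        ``fit_K``: K is optimised (in log space) with N fixed at ``n_sites``.
        ``fit_N``: N is selected over the integer grid 1..64 with K fixed at
        ``k_d``.
        """
        if mode == "fit_K":
            if n_sites is None:
                raise DomainError("fit_K mode requires n_sites")
            # the SSR is flat for K far below the concentration range, so a
            # bounded 1-D minimiser alone can stall; bracket on a coarse
            # log grid first, then refine between the bracketing neighbours
            grid = np.logspace(-3, 6, 91)
            grid_obj = [self.objective(n_sites, k) for k in grid]
            i0 = int(np.argmin(grid_obj))
            lo = grid[max(i0 - 1, 0)]
            hi = grid[min(i0 + 1, len(grid) - 1)]
            result = optimize.minimize_scalar(
                lambda logk: self.objective(n_sites, math.exp(logk)),
                bounds=(math.log(lo), math.log(hi)),
                method="bounded",
                options={"xatol": 1e-12},
            )
            if not result.success:
                raise FitFailureError(
                    "K optimisation failed", {"message": result.message}
                )
            k_best = math.exp(result.x)
            obj = float(result.fun)
            n_best = int(n_sites)
            k_se = self._k_stderr(n_best, k_best, obj)
            bse = {"n_sites": np.nan, "k_d": k_se}
        elif mode == "fit_N":
            if k_d is None:
                raise DomainError("fit_N mode requires k_d")
            objs = {n: self.objective(n, k_d) for n in N_GRID}
            n_best = min(objs, key=lambda n: (objs[n], n))
            obj = objs[n_best]
            k_best = float(k_d)
            bse = {"n_sites": np.nan, "k_d": np.nan}
        else:
            raise DomainError(f"unknown fit mode {mode!r}")

        nobs = sum(len(ps.entries) for ps in self.data)
        rmse = math.sqrt(obj / nobs)
        model = BinomialBindingModel(n_best, k_best)
        return BinomialSiteResults(
            model, mode, obj, self.fitted_on, bse, nobs, rmse
        )

    def _k_stderr(self, n_sites: int, k_best: float, obj: float) -> float:
        """Approximate SE of K from the curvature of the SSR profile."""
        nobs = sum(len(ps.entries) for ps in self.data)
        dof = max(nobs - 1, 1)
        sigma2 = obj / dof
        h = max(1e-4 * k_best, 1e-8)
        d2 = (
            self.objective(n_sites, k_best + h)
            - 2 * obj
            + self.objective(n_sites, k_best - h)
        ) / h**2
        if d2 <= 0 or not np.isfinite(d2):
            return np.nan
        return math.sqrt(2 * sigma2 / d2)


def affinity_ratio(fit_a: BinomialSiteResults, fit_b: BinomialSiteResults) -> float:
    """K_b / K_a for two fit_K results with equal site counts.

    A ratio > 1 means species ``a`` binds tighter (lower K).
    """
    if fit_a.mode != "fit_K" or fit_b.mode != "fit_K":
        raise ComparabilityError("affinity_ratio requires two fit_K results")
    if fit_a.model.n_sites != fit_b.model.n_sites:
        raise ComparabilityError(
            "site counts differ "
            f"({fit_a.model.n_sites} vs {fit_b.model.n_sites})"
        )
    return fit_b.model.k_d / fit_a.model.k_d
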
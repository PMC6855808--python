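"""Synthetic-data generators with known ground truth.

Each generator emulates one input class of the analysis pipeline with the
statistical structure the corresponding analysis assumes, and returns the
generating parameters alongside the data so recovery can be scored:

* native-MS peak sets — binomial site occupancy with multiplicative
  log-normal intensity noise;
* thermal-stability curves — Hill-shaped effect with additive Gaussian
  noise, floored at 0;
* coarse-grained membrane frames — a ring of TMD beads at the box centre
  with lipids placed uniformly per leaflet, species drawn with a
  configurable bias inside the boundary shell (expected enrichment has the
  closed form :math:`B_i = w_i/\\sum_j w_j x_j - 1`);
* stopped-flow quench traces — an irreversible resting->open->desensitized
  scheme whose open probability sets the target influx rate, converted to
  a stretched-exponential trace by inverting the rate equation, so pipeline
  recovery is a true inverse problem;
* patch-clamp current traces — exponential activation multiplying a
  double-exponential desensitization envelope with a free plateau.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .boundary import MembraneFrame
from .exceptions import DomainError
from .flux import QuenchTrace, T_EVAL
from .ms_binding import (
    BinomialBindingModel,
    LipidSpecies,
    PeakSet,
    POPG,
    bound_distribution,
)
from .patch import CurrentTrace
from .stability import HillCurve, StabilityMeasurement

__all__ = [
    "GeneratorConfig",
    "KineticScheme",
    "TABLE2_SCHEMES",
    "DEFAULT_DELAYS",
    "gen_peaksets",
    "gen_stability_curve",
    "gen_membrane_frames",
    "gen_flux_experiment",
    "gen_current_traces",
]

#: log-spaced agonist-exposure delays, 10 ms to 25 s; dense enough at the
#: short end to resolve activation constants down to ~10 ms
DEFAULT_DELAYS = tuple(np.geomspace(0.01, 25.0, 24))


@dataclass(frozen=True)
class KineticScheme:
    """Irreversible resting -> open -> desensitized gating scheme.

    ``a`` and ``d`` (1/s) are the activation and desensitization rates;
    ``k_max`` is the influx rate at full open probability, ``k_leak`` the
    agonist-independent background rate, ``beta`` the stretching exponent
    of the quench traces.
    """

    a: float
    d: float
    k_max: float = 30.0
    k_leak: float = 0.0
    beta: float = 0.7

    def __post_init__(self):
        if not (self.a > self.d > 0):
            raise ValueError("need a > d > 0 for resolvable components")
        if not (self.k_max > self.k_leak >= 0):
            raise ValueError("need k_max > k_leak >= 0")
        if not (0 < self.beta <= 1):
            raise ValueError("beta must be in (0, 1]")

    def open_probability(self, t: float) -> float:
        """O(t) = a/(a-d) * (exp(-d t) - exp(-a t))."""
        a, d = self.a, self.d
        if math.isclose(a, d, rel_tol=1e-9):
            return a * t * math.exp(-a * t)  # confluent limit
        return a / (a - d) * (math.exp(-d * t) - math.exp(-a * t))

    def rate(self, t: float) -> float:
        return self.k_leak + self.k_max * self.open_probability(t)


#: kinetic parameter sets of the two liposome conditions of the
#: stopped-flow experiment (activation tau 39 ms / desensitization tau
#: 0.42 s in POPC; 13 ms / 9.2 s in 2:1:1 POPC:POPE:POPG)
TABLE2_SCHEMES: Dict[str, KineticScheme] = {
    "POPC": KineticScheme(a=1 / 0.039, d=1 / 0.42),
    "POPC:POPE:POPG": KineticScheme(a=1 / 0.013, d=1 / 9.2),
}


@dataclass
class GeneratorConfig:
    """Seed plus per-generator keyword blocks, as read from a YAML config."""

    seed: int
    peaksets: Dict = field(default_factory=dict)
    stability: Dict = field(default_factory=dict)
    membrane: Dict = field(default_factory=dict)
    flux: Dict = field(default_factory=dict)
    currents: Dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# native MS
# ---------------------------------------------------------------------------

def gen_peaksets(
    model: BinomialBindingModel,
    concentrations: Sequence[float] = (2.0, 6.0, 12.0, 18.0, 24.0, 36.0),
    sigma: float = 0.05,
    seed: int = 0,
    species: LipidSpecies = POPG,
    scale: float = 1000.0,
    truncate_below: float = 1e-4,
) -> Tuple[List[PeakSet], Dict]:
    """Peak sets across a concentration series from a binomial site model.

    Intensities are the exact binomial mole fractions times ``scale`` with
    multiplicative log-normal noise of parameter ``sigma``, truncated at
    the largest bound count whose exact fraction exceeds
    ``truncate_below``.
    """
    rng = np.random.default_rng(seed)
    out = []
    for c in concentrations:
        fracs = bound_distribution(model, c)
        keep = np.nonzero(fracs > truncate_below)[0]
        n_max = int(keep.max()) if keep.size else 0
        ns = np.arange(n_max + 1)
        noise = rng.lognormal(0.0, sigma, size=ns.size) if sigma > 0 else 1.0
        intens = fracs[ns] * scale * noise
        out.append(PeakSet(species, float(c), [(int(n), float(i)) for n, i in zip(ns, intens)]))
    truth = {
        "n_sites": model.n_sites,
        "k_d": model.k_d,
        "sigma": sigma,
        "seed": seed,
    }
    return out, truth


# ---------------------------------------------------------------------------
# thermal stability
# ---------------------------------------------------------------------------

def gen_stability_curve(
    hill: HillCurve = HillCurve(ec50=52.0, hill_n=1.7, e_max=6.0),
    concentrations: Sequence[float] = (0.0, 10.0, 25.0, 50.0, 100.0, 200.0, 400.0),
    sigma: float = 0.3,
    seed: int = 0,
    n_replicates: int = 3,
) -> Tuple[List[StabilityMeasurement], Dict]:
    """Stabilizing-effect measurements from a Hill curve plus Gaussian
    noise, floored at 0 (an effect ratio cannot be negative)."""
    rng = np.random.default_rng(seed)
    data = []
    for rep in range(n_replicates):
        for c in concentrations:
            frac = 0.0 if c == 0 else c**hill.hill_n / (c**hill.hill_n + hill.ec50**hill.hill_n)
            e = hill.baseline + (hill.e_max - hill.baseline) * frac
            if sigma > 0:
                e += rng.normal(0.0, sigma)
            data.append(StabilityMeasurement(float(c), max(e, 0.0), rep))
    truth = {"ec50": hill.ec50, "hill_n": hill.hill_n, "e_max": hill.e_max,
             "sigma": sigma, "seed": seed}
    return data, truth


# ---------------------------------------------------------------------------
# membrane frames
# ---------------------------------------------------------------------------

def gen_membrane_frames(
    composition: Dict[str, float],
    n_lipids: int = 3000,
    protein_radius: float = 22.0,
    boundary_bias: Optional[Dict[str, float]] = None,
    n_frames: int = 10,
    box: Tuple[float, float, float] = (300.0, 300.0, 100.0),
    seed: int = 0,
    cutoff: float = 6.0,
    leaflet_z: float = 17.0,
    n_ring_beads: int = 120,
) -> Tuple[List[MembraneFrame], Dict]:
    """Synthetic membrane frames around a pentameric TMD footprint.

    The protein is a ring of TMD beads of radius ``protein_radius`` at the
    box centre, repeated at the two leaflet planes and the midplane so that
    in-plane proximity equals 3-D proximity.  Lipids (one phosphate bead
    each, at their leaflet plane) are placed uniformly outside the protein
    footprint; inside the boundary shell (within ``cutoff`` of the ring)
    species are drawn with probability proportional to ``w_i * x_i``,
    elsewhere proportional to ``x_i``.  The closed-form expected enrichment
    ``B_i = w_i / sum_j(w_j x_j) - 1`` is returned as ground truth.
    """
    names = list(composition)
    x = np.asarray([composition[n] for n in names], dtype=float)
    if not math.isclose(x.sum(), 1.0, abs_tol=1e-9):
        raise DomainError("composition fractions must sum to 1")
    w = np.asarray(
        [(boundary_bias or {}).get(n, 1.0) for n in names], dtype=float
    )
    if np.any(w <= 0):
        raise DomainError("boundary bias weights must be positive")
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    center = box / 2.0

    # protein: ring beads at three z-levels spanning the TMD
    angles = np.linspace(0.0, 2 * math.pi, n_ring_beads, endpoint=False)
    ring_xy = np.stack(
        [center[0] + protein_radius * np.cos(angles),
         center[1] + protein_radius * np.sin(angles)], axis=1
    )
    levels = (center[2] - leaflet_z, center[2], center[2] + leaflet_z)
    protein_xyz = np.concatenate(
        [np.column_stack([ring_xy, np.full(n_ring_beads, z)]) for z in levels]
    )

    p_bulk = x / x.sum()
    p_shell = w * x / (w * x).sum()
    per_leaflet = n_lipids // 2
    counts = (per_leaflet, n_lipids - per_leaflet)

    frames = []
    for fi in range(n_frames):
        coords = []
        species = []
        for leaf, n_leaf in zip((+1, -1), counts):
            placed = 0
            tries = 0
            while placed < n_leaf:
                m = (n_leaf - placed) * 2 + 16
                xy = rng.uniform(0.0, 1.0, size=(m, 2)) * box[:2]
                r = np.hypot(xy[:, 0] - center[0], xy[:, 1] - center[1])
                xy = xy[r >= protein_radius][: n_leaf - placed]
                r = np.hypot(xy[:, 0] - center[0], xy[:, 1] - center[1])
                z = np.full(len(xy), center[2] + leaf * leaflet_z)
                coords.append(np.column_stack([xy, z]))
                in_shell = r <= protein_radius + cutoff
                sp = np.where(
                    in_shell,
                    rng.choice(names, size=len(xy), p=p_shell),
                    rng.choice(names, size=len(xy), p=p_bulk),
                )
                species.append(sp)
                placed += len(xy)
                tries += 1
                if tries > 1000:
                    raise DomainError("infeasible lipid density; placement failed")
        bead_xyz = np.concatenate(coords)
        lipid_species = np.concatenate(species)
        n = len(lipid_species)
        frames.append(
            MembraneFrame(
                protein_xyz=protein_xyz,
                protein_is_tmd=np.ones(len(protein_xyz), dtype=bool),
                lipid_species=lipid_species,
                bead_xyz=bead_xyz,
                bead_lipid=np.arange(n),
                phosphate_bead=np.arange(n),
                box=box,
                time=float(fi),
            )
        )
    expected_B = {n: float(wi / (w * x).sum() - 1.0) for n, wi in zip(names, w)}
    truth = {
        "composition": dict(composition),
        "boundary_bias": {n: float(wi) for n, wi in zip(names, w)},
        "expected_B": expected_B,
        "seed": seed,
    }
    return frames, truth


# ---------------------------------------------------------------------------
# stopped-flow flux
# ---------------------------------------------------------------------------

def _tau_from_rate(k: float, beta: float, t_eval: float = T_EVAL) -> float:
    """Invert k = (beta/tau)(t_eval/tau)^(beta-1) for tau."""
    return (beta * t_eval ** (beta - 1.0) / k) ** (1.0 / beta)


def gen_flux_experiment(
    scheme: KineticScheme,
    delays: Sequence[float] = DEFAULT_DELAYS,
    n_repeats: int = 8,
    sigma: float = 0.05,
    seed: int = 0,
    condition: str = "",
    f0: float = 1.0,
    f_inf: float = 0.2,
    trace_time: Optional[np.ndarray] = None,
) -> Tuple[List[List[QuenchTrace]], Dict]:
    """Quench traces for a delay series under one kinetic scheme.

    For each delay the scheme's open probability sets the target influx
    rate; the stretched-exponential time constant is obtained by inverting
    the 2 ms rate equation, and each repeat is the stretched exponential
    sampled over 1 s with additive Gaussian noise ``sigma * (f0 - f_inf)``.
    Rates below machine resolution yield flat (no-flux) traces.
    """
    if any(not (0.01 <= d <= 25.0) for d in delays):
        raise DomainError("delays must lie in [0.01, 25] s")
    rng = np.random.default_rng(seed)
    if trace_time is None:
        # logarithmic timebase over 2 ms - 1 s, as stopped-flow instruments
        # record multi-decade kinetics
        trace_time = np.geomspace(0.002, 1.0, 400)
    amp = f0 - f_inf
    traces_by_delay = []
    truth_rates = {}
    for delay in delays:
        k = scheme.rate(float(delay))
        truth_rates[float(delay)] = k
        group = []
        for rep in range(n_repeats):
            if k > 1e-9:
                tau = _tau_from_rate(k, scheme.beta)
                f = f_inf + amp * np.exp(-((trace_time / tau) ** scheme.beta))
            else:
                f = np.full_like(trace_time, f0)
            if sigma > 0:
                f = f + rng.normal(0.0, sigma * amp, size=f.shape)
            group.append(
                QuenchTrace(trace_time.copy(), f, delay=float(delay),
                            condition=condition, repeat=rep)
            )
        traces_by_delay.append(group)
    truth = {
        "activation_tau": 1.0 / scheme.a,
        "desensitization_tau": 1.0 / scheme.d,
        "k_max": scheme.k_max,
        "k_leak": scheme.k_leak,
        "beta": scheme.beta,
        "rates": truth_rates,
        "sigma": sigma,
        "seed": seed,
    }
    return traces_by_delay, truth


# ---------------------------------------------------------------------------
# patch-clamp currents
# ---------------------------------------------------------------------------

def gen_current_traces(
    activation_tau: float = 0.134,
    desens_components: Tuple[float, float, float, float] = (0.5, 0.5, 0.5, 3.4),
    plateau: float = 0.10,
    peak: float = 500.0,
    duration: float = 21.0,
    sample_rate: float = 1000.0,
    sigma: float = 0.01,
    seed: int = 0,
    n_traces: int = 1,
    concentration: float = 30.0,
    condition: str = "WT",
) -> Tuple[List[CurrentTrace], Dict]:
    """Agonist-evoked current traces with known kinetics.

    ``desens_components`` is (A1, tau1, A2, tau2) of the normalised
    desensitization envelope; the current is

    I(t) = peak * (1 - exp(-t/tau_a))
         * [plateau + (1-plateau) * (A1 e^{-t/tau1} + A2 e^{-t/tau2})/(A1+A2)]

    plus additive Gaussian noise of SD ``sigma * peak``.  The weighted
    desensitization tau and the envelope value at 20 s are returned as
    ground truth.
    """
    a1, tau1, a2, tau2 = desens_components
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, 1.0 / sample_rate)
    envelope = plateau + (1 - plateau) * (
        a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)
    ) / (a1 + a2)
    clean = peak * (1.0 - np.exp(-t / activation_tau)) * envelope
    traces = []
    for i in range(n_traces):
        cur = clean + (rng.normal(0.0, sigma * peak, size=t.shape) if sigma > 0 else 0.0)
        traces.append(
            CurrentTrace(t.copy(), cur, concentration=concentration,
                         condition=condition, patch_id=f"p{i}")
        )
    env20 = plateau + (1 - plateau) * (
        a1 * math.exp(-20.0 / tau1) + a2 * math.exp(-20.0 / tau2)
    ) / (a1 + a2)
    truth = {
        "activation_tau": activation_tau,
        "weighted_tau": (a1 * tau1 + a2 * tau2) / (a1 + a2),
        "components": desens_components,
        "plateau": plateau,
        "envelope_at_20s": env20,
        "sigma": sigma,
        "seed": seed,
    }
    return traces, truth
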
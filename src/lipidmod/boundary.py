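"""Boundary (annular) lipid classification, enrichment and density maps.

A lipid is a boundary lipid in a frame if any of its beads lies within a
cutoff (default 6 Å) of any transmembrane-domain (TMD) protein bead, under
periodic boundary conditions.  Per-species enrichment among boundary lipids
is quantified by

.. math:: B_i = \\left\\langle \\frac{b_i}{b_{tot}} \\frac{1}{x_i} \\right\\rangle - 1

where :math:`b_i` is the instantaneous boundary count of species *i*,
:math:`b_{tot}` the total boundary count, :math:`x_i` the bulk mole
fraction from the full lipid census, and the brackets average over frames
(and replicas).  B > 0 means enrichment, B = 0 random mixing, B < 0
depletion.

Leaflet-resolved lipid organisation is summarised as a polar density map of
phosphate beads around the protein pore axis: 4 Å radial bins out to 40 Å
and angular bins of width pi/15.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import ConfigError, DegenerateDataError, DomainError

__all__ = [
    "MembraneFrame",
    "BoundaryCount",
    "EnrichmentResult",
    "PolarDensityMap",
    "assign_leaflets",
    "find_boundary",
    "enrichment",
    "polar_density",
    "boundary_census",
]

logger = logging.getLogger(__name__)

BOUNDARY_CUTOFF = 6.0  # Å


@dataclass
class MembraneFrame:
    """One coarse-grained membrane snapshot, coordinates in Å.

    ``bead_xyz`` holds all lipid beads; ``bead_lipid`` maps each bead row to
    its lipid index; ``phosphate_bead`` gives, per lipid, the row of its
    phosphate (headgroup reference) bead.  Protein beads carry a TMD mask.
    """

    protein_xyz: np.ndarray  # (P, 3)
    protein_is_tmd: np.ndarray  # (P,) bool
    lipid_species: np.ndarray  # (L,) str
    bead_xyz: np.ndarray  # (B, 3)
    bead_lipid: np.ndarray  # (B,) int -> lipid index
    phosphate_bead: np.ndarray  # (L,) int -> row of bead_xyz
    box: np.ndarray  # (3,) periodic box lengths, Å
    time: float = 0.0  # us
    periodic_z: bool = False
    leaflet: Optional[np.ndarray] = None  # (L,) "outer"/"inner", lazily set

    def __post_init__(self):
        self.protein_xyz = np.asarray(self.protein_xyz, dtype=float)
        self.protein_is_tmd = np.asarray(self.protein_is_tmd, dtype=bool)
        self.bead_xyz = np.asarray(self.bead_xyz, dtype=float)
        self.bead_lipid = np.asarray(self.bead_lipid, dtype=int)
        self.phosphate_bead = np.asarray(self.phosphate_bead, dtype=int)
        self.lipid_species = np.asarray(self.lipid_species, dtype=object)
        self.box = np.asarray(self.box, dtype=float)
        if self.protein_is_tmd.size and not self.protein_is_tmd.any():
            raise ConfigError("frame has no TMD-flagged protein beads")
        if not self.protein_is_tmd.size:
            raise ConfigError("frame has no protein beads")
        if not (np.isfinite(self.bead_xyz).all() and np.isfinite(self.protein_xyz).all()):
            raise ValueError("coordinates must be finite")
        n_lip = self.lipid_species.size
        if n_lip == 0 or self.phosphate_bead.size != n_lip:
            raise ValueError("each lipid needs a phosphate bead index")

    @property
    def n_lipids(self) -> int:
        return int(self.lipid_species.size)

    @property
    def phosphate_xyz(self) -> np.ndarray:
        return self.bead_xyz[self.phosphate_bead]

    @property
    def species_names(self) -> List[str]:
        return sorted(set(self.lipid_species.tolist()))

    def bulk_fractions(self) -> Dict[str, float]:
        """Mole fraction of each species over the full lipid census."""
        names, counts = np.unique(self.lipid_species.astype(str), return_counts=True)
        return {n: c / self.n_lipids for n, c in zip(names, counts)}


@dataclass
class BoundaryCount:
    """Boundary-lipid counts in one frame."""

    per_species: Dict[str, int]
    time: float = 0.0
    boundary_lipids: Optional[np.ndarray] = None  # lipid indices

    @property
    def total(self) -> int:
        return int(sum(self.per_species.values()))


@dataclass
class EnrichmentResult:
    """Mean boundary enrichment of one species over frames."""

    species: str
    B: float
    sd: float
    n_frames: int
    bulk_fraction: float


@dataclass
class PolarDensityMap:
    """Mean area density of phosphate beads in (radius, angle) bins."""

    leaflet: str
    radial_edges: np.ndarray  # Å, length n_r + 1
    angular_edges: np.ndarray  # rad, length n_theta + 1
    values: np.ndarray  # (n_r, n_theta), beads per Å^2

    def bin_areas(self) -> np.ndarray:
        r = self.radial_edges
        areas = math.pi * (r[1:] ** 2 - r[:-1] ** 2) / (len(self.angular_edges) - 1)
        return np.repeat(areas[:, None], self.values.shape[1], axis=1)

    def integrated_count(self) -> float:
        """Mean number of in-range beads per frame implied by the map."""
        return float((self.values * self.bin_areas()).sum())


def _min_image(delta: np.ndarray, box: np.ndarray, periodic_z: bool) -> np.ndarray:
    """Minimum-image displacement vectors; PBC in x,y and optionally z."""
    delta = delta.copy()
    dims = (0, 1, 2) if periodic_z else (0, 1)
    for d in dims:
        delta[..., d] -= box[d] * np.round(delta[..., d] / box[d])
    return delta


def assign_leaflets(frame: MembraneFrame) -> np.ndarray:
    """Label each lipid outer/inner by its phosphate z versus the
    instantaneous median phosphate z.

    Raises :class:`DegenerateDataError` when all lipids are coplanar.
    """
    if frame.n_lipids < 2:
        raise DegenerateDataError("need >= 2 lipids to assign leaflets")
    z = frame.phosphate_xyz[:, 2]
    if np.ptp(z) < 1e-9:
        raise DegenerateDataError("all phosphate beads coplanar; no leaflets")
    median = np.median(z)
    labels = np.where(z > median, "outer", "inner").astype(object)
    # beads exactly at the median go to the side of the nearer extreme
    at = z == median
    if at.any():
        labels[at] = "outer" if (z.max() - median) < (median - z.min()) else "inner"
    frame.leaflet = labels
    return labels


def find_boundary(frame: MembraneFrame, cutoff: float = BOUNDARY_CUTOFF) -> BoundaryCount:
    """Count boundary lipids per species.

    A lipid is boundary iff the minimum distance between any of its beads
    and any TMD protein bead is <= ``cutoff`` (Å), minimum-image in the
    periodic directions.
    """
    if not cutoff > 0:
        raise DomainError("cutoff must be positive")
    tmd = frame.protein_xyz[frame.protein_is_tmd]
    if tmd.size == 0:
        raise ConfigError("frame has no TMD beads")
    beads = frame.bead_xyz
    # bead-level min distance to any TMD bead, chunked over TMD beads
    min_d2 = np.full(len(beads), np.inf)
    cutoff2 = cutoff * cutoff
    for t in tmd:
        delta = _min_image(beads - t, frame.box, frame.periodic_z)
        d2 = np.einsum("ij,ij->i", delta, delta)
        np.minimum(min_d2, d2, out=min_d2)
    bead_hit = min_d2 <= cutoff2
    lipid_hit = np.zeros(frame.n_lipids, dtype=bool)
    np.logical_or.at(lipid_hit, frame.bead_lipid, bead_hit)
    per_species: Dict[str, int] = {s: 0 for s in frame.species_names}
    for s in frame.lipid_species[lipid_hit]:
        per_species[str(s)] += 1
    return BoundaryCount(
        per_species, time=frame.time, boundary_lipids=np.flatnonzero(lipid_hit)
    )


def enrichment(
    frames: Sequence[MembraneFrame],
    species: str,
    cutoff: float = BOUNDARY_CUTOFF,
) -> EnrichmentResult:
    """Boundary enrichment B of ``species`` averaged over frames.

    Frames with no boundary lipids at all are skipped with a warning.
    Raises :class:`DomainError` if the species is absent from the census.
    """
    per_frame = []
    xs = []
    skipped = 0
    for frame in frames:
        x = frame.bulk_fractions().get(species, 0.0)
        if x == 0.0:
            raise DomainError(f"species {species!r} absent from frame census")
        counts = find_boundary(frame, cutoff)
        if counts.total == 0:
            skipped += 1
            continue
        b_i = counts.per_species.get(species, 0)
        per_frame.append((b_i / counts.total) / x - 1.0)
        xs.append(x)
    if skipped:
        logger.warning("enrichment: skipped %d frame(s) with no boundary lipids", skipped)
    if not per_frame:
        raise DegenerateDataError("no frames with boundary lipids")
    per_frame = np.asarray(per_frame)
    sd = float(per_frame.std(ddof=1)) if len(per_frame) > 1 else 0.0
    return EnrichmentResult(
        species=species,
        B=float(per_frame.mean()),
        sd=sd,
        n_frames=len(per_frame),
        bulk_fraction=float(np.mean(xs)),
    )


def boundary_census(
    frames: Sequence[MembraneFrame], cutoff: float = BOUNDARY_CUTOFF
) -> Tuple[float, float]:
    """Mean and SD of the total boundary-lipid count over frames."""
    frames = list(frames)
    if len(frames) < 2:
        raise DomainError("need >= 2 frames for a census")
    totals = np.asarray([find_boundary(f, cutoff).total for f in frames], dtype=float)
    return float(totals.mean()), float(totals.std(ddof=1))


def polar_density(
    frames: Sequence[MembraneFrame],
    species: str,
    leaflet: str,
    r_max: float = 40.0,
    dr: float = 4.0,
    dtheta: float = math.pi / 15,
    frame_window: str = "last_half",
) -> PolarDensityMap:
    """Leaflet-resolved polar density map of phosphate beads.

    The protein centre is the TMD centre of mass projected onto the
    membrane plane; each in-range phosphate bead of the requested species
    and leaflet is binned by (radius, angle) and the per-bin area density
    is averaged over the frame window (default: the last half of the
    frames supplied).
    """
    if leaflet not in ("outer", "inner"):
        raise DomainError("leaflet must be 'outer' or 'inner'")
    n_r = r_max / dr
    if abs(n_r - round(n_r)) > 1e-9:
        raise DomainError("r_max must be an integer multiple of dr")
    n_r = int(round(n_r))
    n_theta = int(round(2 * math.pi / dtheta))
    r_edges = np.linspace(0.0, r_max, n_r + 1)
    t_edges = np.linspace(0.0, n_theta * dtheta, n_theta + 1)

    frames = list(frames)
    if frame_window == "last_half":
        frames = frames[len(frames) // 2:]
    elif frame_window != "all":
        raise DomainError("frame_window must be 'last_half' or 'all'")
    if not frames:
        raise DegenerateDataError("no frames in the requested window")

    counts = np.zeros((n_r, n_theta))
    for frame in frames:
        labels = frame.leaflet if frame.leaflet is not None else assign_leaflets(frame)
        sel = (frame.lipid_species.astype(str) == species) & (labels == leaflet)
        phos = frame.phosphate_xyz[sel]
        tmd = frame.protein_xyz[frame.protein_is_tmd]
        center = tmd.mean(axis=0)
        delta = _min_image(phos - center, frame.box, frame.periodic_z)[:, :2]
        r = np.hypot(delta[:, 0], delta[:, 1])
        theta = np.mod(np.arctan2(delta[:, 1], delta[:, 0]), 2 * math.pi)
        # guard against theta == 2*pi after rounding
        theta[theta >= t_edges[-1]] = 0.0
        h, _, _ = np.histogram2d(r, theta, bins=[r_edges, t_edges])
        counts += h
    counts /= len(frames)
    areas = math.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2) / n_theta
    values = counts / areas[:, None]
    return PolarDensityMap(leaflet, r_edges, t_edges, values)
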
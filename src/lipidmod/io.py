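"""Readers and writers for the package's file formats.

CSV is the canonical tabular dialect (UTF-8, header row, '.' decimal);
fit results are written as JSON; configuration is YAML.  Coarse-grained
coordinate frames are read from GRO files (via MDAnalysis, nm converted to
Å on read) or from a flat CSV bead table.  All readers reject malformed
input rather than silently coercing it, and every filter step is logged so
exclusions are auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .boundary import MembraneFrame
from .exceptions import SchemaError
from .flux import QuenchTrace
from .ms_binding import LipidSpecies, PeakSet
from .patch import CurrentTrace

logger = logging.getLogger(__name__)

PEAKS_COLUMNS = ("species", "concentration_uM", "n_bound", "intensity")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


# ---------------------------------------------------------------------------
# native MS peak tables
# ---------------------------------------------------------------------------

def read_peaks_csv(
    path,
    max_charge: Optional[int] = None,
    charge_class: Dict[str, str] | None = None,
) -> List[PeakSet]:
    """Read a peak table grouped by (species, concentration).

    Columns: species, concentration_uM, n_bound, intensity, optional
    charge.  If a charge column is present and ``max_charge`` is given,
    higher charge states are dropped (and logged) before intensities are
    summed per bound count.  Duplicated (species, concentration, n_bound)
    rows are summed with a warning.
    """
    df = pd.read_csv(path)
    _require_columns(df, PEAKS_COLUMNS, path)
    bad = df.index[(df["intensity"] < 0) | ~np.isfinite(df["intensity"])]
    if len(bad):
        raise SchemaError(
            f"{path}: negative or non-finite intensity at data row {bad[0]}"
        )
    if (df["n_bound"] < 0).any() or (df["n_bound"] % 1 != 0).any():
        raise SchemaError(f"{path}: n_bound must be nonnegative integers")
    if "charge" in df.columns and max_charge is not None:
        n0 = len(df)
        df = df[df["charge"] <= max_charge]
        if len(df) < n0:
            logger.info(
                "read_peaks_csv: dropped %d rows with charge > %d",
                n0 - len(df), max_charge,
            )
    dup = df.duplicated(subset=["species", "concentration_uM", "n_bound"]).any()
    if dup and "charge" not in df.columns:
        logger.warning("read_peaks_csv: duplicated rows summed per n_bound")
    out = []
    for (name, conc), grp in df.groupby(["species", "concentration_uM"], sort=True):
        cls = (charge_class or {}).get(str(name), "anionic" if "PG" in str(name) else "zwitterionic")
        summed = grp.groupby("n_bound", sort=True)["intensity"].sum()
        entries = [(int(n), float(i)) for n, i in summed.items()]
        out.append(
            PeakSet(
                LipidSpecies(str(name), cls),
                float(conc),
                entries,
                charge_state_max=max_charge,
            )
        )
    return out


def write_peaks_csv(peaksets: Sequence[PeakSet], path) -> None:
    rows = [
        (ps.species.name, ps.concentration, int(n), float(i))
        for ps in peaksets
        for n, i in ps.entries
    ]
    pd.DataFrame(rows, columns=list(PEAKS_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------

def read_stability_csv(path) -> pd.DataFrame:
    """Columns: concentration_uM, effect, optional replicate."""
    df = pd.read_csv(path)
    _require_columns(df, ("concentration_uM", "effect"), path)
    if (df["concentration_uM"] < 0).any():
        raise SchemaError(f"{path}: negative concentration")
    if not np.isfinite(df["effect"]).all():
        raise SchemaError(f"{path}: non-finite effect value")
    return df


# ---------------------------------------------------------------------------
# quench traces / currents
# ---------------------------------------------------------------------------

def read_quench_csv(path) -> List[List[QuenchTrace]]:
    """Columns: condition, delay_s, repeat, time_s, fluorescence.

    Returns traces grouped by delay (one inner list per delay, sorted)."""
    df = pd.read_csv(path)
    _require_columns(df, ("condition", "delay_s", "repeat", "time_s", "fluorescence"), path)
    df["condition"] = df["condition"].fillna("")
    groups: Dict[float, List[QuenchTrace]] = {}
    for (cond, delay, rep), grp in df.groupby(["condition", "delay_s", "repeat"]):
        grp = grp.sort_values("time_s")
        tr = QuenchTrace(
            grp["time_s"].to_numpy(), grp["fluorescence"].to_numpy(),
            delay=float(delay), condition=str(cond), repeat=int(rep),
        )
        groups.setdefault(float(delay), []).append(tr)
    return [groups[d] for d in sorted(groups)]


def write_quench_csv(traces_by_delay: Sequence[Sequence[QuenchTrace]], path) -> None:
    frames = []
    for group in traces_by_delay:
        for tr in group:
            frames.append(
                pd.DataFrame(
                    {
                        "condition": tr.condition,
                        "delay_s": tr.delay,
                        "repeat": tr.repeat,
                        "time_s": tr.time,
                        "fluorescence": tr.fluorescence,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_currents_csv(path) -> List[CurrentTrace]:
    """Columns: condition, patch_id, concentration_mM, time_s, current_pA."""
    df = pd.read_csv(path)
    _require_columns(
        df, ("condition", "patch_id", "concentration_mM", "time_s", "current_pA"), path
    )
    df["condition"] = df["condition"].fillna("")
    df["patch_id"] = df["patch_id"].fillna("")
    out = []
    for (cond, pid, conc), grp in df.groupby(["condition", "patch_id", "concentration_mM"]):
        grp = grp.sort_values("time_s")
        out.append(
            CurrentTrace(
                grp["time_s"].to_numpy(), grp["current_pA"].to_numpy(),
                concentration=float(conc), condition=str(cond), patch_id=str(pid),
            )
        )
    return out


def write_currents_csv(traces: Sequence[CurrentTrace], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "condition": tr.condition,
                "patch_id": tr.patch_id,
                "concentration_mM": tr.concentration,
                "time_s": tr.time,
                "current_pA": tr.current,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# membrane frames: GRO and CSV bead tables
# ---------------------------------------------------------------------------

def read_gro_frame(
    path,
    species_map: Dict[str, str],
    phosphate_bead: str = "PO4",
    protein_resnames: Sequence[str] = ("PROT", "ELIC"),
    tmd_z_range: Optional[Tuple[float, float]] = None,
) -> MembraneFrame:
    """Read one coarse-grained GRO frame into a MembraneFrame.

    Residue names are mapped to lipid species via ``species_map``; residues
    in ``protein_resnames`` become protein beads (all flagged TMD unless a
    ``tmd_z_range`` in Å restricts the flag); unmapped residues are ignored
    with a count warning.  GRO coordinates (nm) are converted to Å.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    if u.dimensions is None or not np.any(u.dimensions[:3] > 0):
        raise SchemaError(f"{path}: GRO file has no box line")
    box = u.dimensions[:3].astype(float)  # MDAnalysis already reports Å
    pos = u.atoms.positions.astype(float)  # Å

    resnames = u.atoms.resnames
    names = u.atoms.names
    resids = u.atoms.resids

    prot_mask = np.isin(resnames, list(protein_resnames))
    protein_xyz = pos[prot_mask]
    if tmd_z_range is not None:
        z0, z1 = tmd_z_range
        protein_is_tmd = (protein_xyz[:, 2] >= z0) & (protein_xyz[:, 2] <= z1)
    else:
        protein_is_tmd = np.ones(len(protein_xyz), dtype=bool)

    lip_mask = np.isin(resnames, list(species_map))
    ignored = (~prot_mask & ~lip_mask).sum()
    if ignored:
        logger.warning("read_gro_frame: ignored %d beads with unmapped residues", ignored)

    lip_pos = pos[lip_mask]
    lip_resid = resids[lip_mask]
    lip_resname = resnames[lip_mask]
    lip_beadname = names[lip_mask]
    uniq, bead_lipid = np.unique(lip_resid, return_inverse=True)
    n_lip = len(uniq)
    lipid_species = np.empty(n_lip, dtype=object)
    phosphate = np.full(n_lip, -1, dtype=int)
    for row, (lid, rn, bn) in enumerate(zip(bead_lipid, lip_resname, lip_beadname)):
        lipid_species[lid] = species_map[rn]
        if bn == phosphate_bead:
            phosphate[lid] = row
    if (phosphate < 0).any():
        bad = uniq[phosphate < 0][:3]
        raise SchemaError(
            f"{path}: lipid residue(s) {bad.tolist()} lack a {phosphate_bead!r} bead"
        )
    return MembraneFrame(
        protein_xyz=protein_xyz,
        protein_is_tmd=protein_is_tmd,
        lipid_species=lipid_species,
        bead_xyz=lip_pos,
        bead_lipid=bead_lipid,
        phosphate_bead=phosphate,
        box=box,
    )


def write_gro_frame(frame: MembraneFrame, path, phosphate_bead: str = "PO4") -> None:
    """Write a MembraneFrame as a GRO file (Å converted to nm)."""
    lines = ["synthetic membrane frame"]
    n_atoms = len(frame.protein_xyz) + len(frame.bead_xyz)
    lines.append(f"{n_atoms:5d}")
    atom = 0
    for i, xyz in enumerate(frame.protein_xyz):
        atom += 1
        lines.append(
            f"{1:5d}{'PROT':<5s}{'BB':>5s}{atom % 100000:5d}"
            f"{xyz[0]/10:8.3f}{xyz[1]/10:8.3f}{xyz[2]/10:8.3f}"
        )
    phos_rows = set(frame.phosphate_bead.tolist())
    for row, xyz in enumerate(frame.bead_xyz):
        atom += 1
        lid = int(frame.bead_lipid[row])
        resid = (lid + 2) % 100000
        bead = phosphate_bead if row in phos_rows else "C1A"
        lines.append(
            f"{resid:5d}{str(frame.lipid_species[lid]):<5s}{bead:>5s}{atom % 100000:5d}"
            f"{xyz[0]/10:8.3f}{xyz[1]/10:8.3f}{xyz[2]/10:8.3f}"
        )
    lines.append(
        f"{frame.box[0]/10:10.5f}{frame.box[1]/10:10.5f}{frame.box[2]/10:10.5f}"
    )
    Path(path).write_text("\n".join(lines) + "\n")


def read_bead_csv(path) -> MembraneFrame:
    """Flat bead table: lipid_id, species, bead, x, y, z (Å) plus protein
    rows with species 'PROT'; box lengths in header comment or columns
    box_x, box_y, box_z on the first row."""
    df = pd.read_csv(path)
    _require_columns(df, ("lipid_id", "species", "bead", "x", "y", "z"), path)
    for c in ("box_x", "box_y", "box_z"):
        if c not in df.columns:
            raise SchemaError(f"{path}: missing box column {c}")
    box = df.iloc[0][["box_x", "box_y", "box_z"]].to_numpy(dtype=float)
    prot = df[df["species"] == "PROT"]
    lip = df[df["species"] != "PROT"]
    if lip.empty:
        raise SchemaError(f"{path}: no lipid rows")
    uniq, bead_lipid = np.unique(lip["lipid_id"].to_numpy(), return_inverse=True)
    lipid_species = np.empty(len(uniq), dtype=object)
    phosphate = np.full(len(uniq), -1, dtype=int)
    for row, (lid, sp, bead) in enumerate(
        zip(bead_lipid, lip["species"], lip["bead"])
    ):
        lipid_species[lid] = str(sp)
        if str(bead) == "PO4":
            phosphate[lid] = row
    if (phosphate < 0).any():
        raise SchemaError(f"{path}: lipid(s) without a PO4 bead")
    return MembraneFrame(
        protein_xyz=prot[["x", "y", "z"]].to_numpy(dtype=float),
        protein_is_tmd=np.ones(len(prot), dtype=bool),
        lipid_species=lipid_species,
        bead_xyz=lip[["x", "y", "z"]].to_numpy(dtype=float),
        bead_lipid=bead_lipid,
        phosphate_bead=phosphate,
        box=box,
    )


# ---------------------------------------------------------------------------
# run records
# ---------------------------------------------------------------------------

@dataclass
class RunRecord:
    """Provenance record of one CLI/pipeline run."""

    subcommand: str
    config: Dict
    seed: Optional[int] = None
    input_digests: Dict[str, str] = field(default_factory=dict)
    output_paths: List[str] = field(default_factory=list)
    log_level: str = "INFO"
    run_id: str = field(default_factory=lambda: uuid.uuid4().hex[:12])

    def add_input(self, path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
        self.input_digests[str(path)] = digest

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))
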
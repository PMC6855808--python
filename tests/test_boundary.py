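"""Tests for boundary-lipid classification, enrichment and density maps."""

import math

import numpy as np
import pytest
from scipy import stats

import lipidmod as lm
from lipidmod.boundary import _min_image
from lipidmod.exceptions import ConfigError, DegenerateDataError, DomainError


def frame_from_points(lipid_xyz, species, protein_xyz=((50.0, 50.0, 0.0),),
                      box=(100.0, 100.0, 60.0), periodic_z=False):
    """One-bead-per-lipid frame for hand-built geometries."""
    lipid_xyz = np.asarray(lipid_xyz, dtype=float)
    n = len(lipid_xyz)
    return lm.MembraneFrame(
        protein_xyz=np.asarray(protein_xyz, dtype=float),
        protein_is_tmd=np.ones(len(protein_xyz), dtype=bool),
        lipid_species=np.asarray(species, dtype=object),
        bead_xyz=lipid_xyz,
        bead_lipid=np.arange(n),
        phosphate_bead=np.arange(n),
        box=np.asarray(box, dtype=float),
        periodic_z=periodic_z,
    )


def brute_force_boundary(frame, cutoff=6.0):
    """Independent all-pairs minimum-image classification."""
    tmd = frame.protein_xyz[frame.protein_is_tmd]
    hits = set()
    for b, xyz in enumerate(frame.bead_xyz):
        for t in tmd:
            d = xyz - t
            for dim in (0, 1) + ((2,) if frame.periodic_z else ()):
                L = frame.box[dim]
                d[dim] -= L * round(d[dim] / L)
            if math.sqrt(float(np.dot(d, d))) <= cutoff:
                hits.add(int(frame.bead_lipid[b]))
                break
    counts = {s: 0 for s in frame.species_names}
    for lid in hits:
        counts[str(frame.lipid_species[lid])] += 1
    return counts


class TestAssignLeaflets:
    def test_two_lipids(self):
        f = frame_from_points([(10, 10, 20), (10, 10, -20)], ["POPG", "POPG"])
        labels = lm.assign_leaflets(f)
        assert list(labels) == ["outer", "inner"]

    def test_mirror_symmetry(self):
        xyz = [(10, 10, 17), (30, 10, 18), (10, 30, -17), (40, 40, -16)]
        f = frame_from_points(xyz, ["POPG"] * 4)
        labels = lm.assign_leaflets(f)
        mirrored = frame_from_points([(x, y, -z) for x, y, z in xyz], ["POPG"] * 4)
        labels_m = lm.assign_leaflets(mirrored)
        swap = {"outer": "inner", "inner": "outer"}
        assert [swap[l] for l in labels] == list(labels_m)

    def test_generator_roundtrip(self):
        frames, _ = lm.gen_membrane_frames(
            {"POPG": 0.5, "POPC": 0.5}, n_lipids=400, n_frames=1, seed=7
        )
        f = frames[0]
        labels = lm.assign_leaflets(f)
        truth = np.where(f.phosphate_xyz[:, 2] > f.box[2] / 2, "outer", "inner")
        assert (labels == truth).all()

    def test_coplanar_degenerate(self):
        f = frame_from_points([(1, 1, 5), (2, 2, 5), (3, 3, 5)], ["POPG"] * 3)
        with pytest.raises(DegenerateDataError):
            lm.assign_leaflets(f)


class TestFindBoundary:
    def test_inside_and_outside_cutoff(self):
        f = frame_from_points(
            [(55.9, 50, 0), (56.1, 50, 0)], ["POPG", "POPC"],
            protein_xyz=[(50, 50, 0)],
        )
        counts = lm.find_boundary(f, cutoff=6.0)
        assert counts.per_species == {"POPC": 0, "POPG": 1}

    def test_min_image_across_box_edge(self):
        # protein near the box edge; lipid wraps around in x
        f = frame_from_points(
            [(97.0, 50, 0)], ["POPG"], protein_xyz=[(1.0, 50.0, 0.0)],
        )
        counts = lm.find_boundary(f, cutoff=6.0)
        assert counts.total == 1  # 4 A via the periodic image

    def test_matches_brute_force_on_random_frame(self):
        rng = np.random.default_rng(42)
        n = 400
        xyz = np.column_stack([
            rng.uniform(0, 100, n), rng.uniform(0, 100, n),
            rng.choice([-17.0, 17.0], n),
        ])
        species = rng.choice(["POPG", "POPC", "POPE"], n)
        prot = np.column_stack([
            rng.uniform(40, 60, 30), rng.uniform(40, 60, 30),
            rng.uniform(-17, 17, 30),
        ])
        f = frame_from_points(xyz, species, protein_xyz=prot)
        counts = lm.find_boundary(f, cutoff=6.0)
        assert counts.per_species == brute_force_boundary(f, 6.0)

    def test_multibead_lipid_counts_once(self):
        # two beads of the same lipid both within the cutoff
        f = lm.MembraneFrame(
            protein_xyz=np.array([[50.0, 50.0, 0.0]]),
            protein_is_tmd=np.array([True]),
            lipid_species=np.array(["POPG"], dtype=object),
            bead_xyz=np.array([[54.0, 50.0, 0.0], [55.0, 50.0, 0.0]]),
            bead_lipid=np.array([0, 0]),
            phosphate_bead=np.array([0]),
            box=np.array([100.0, 100.0, 60.0]),
        )
        assert lm.find_boundary(f).total == 1

    def test_missing_tmd_flags_config_error(self):
        with pytest.raises(ConfigError):
            lm.MembraneFrame(
                protein_xyz=np.array([[0.0, 0.0, 0.0]]),
                protein_is_tmd=np.array([False]),
                lipid_species=np.array(["POPG"], dtype=object),
                bead_xyz=np.array([[1.0, 1.0, 0.0]]),
                bead_lipid=np.array([0]),
                phosphate_bead=np.array([0]),
                box=np.array([10.0, 10.0, 10.0]),
            )


def ring_frame(n_boundary_per_species, n_bulk_per_species, box=(200.0, 200.0, 60.0)):
    """Deterministic frame: lipids placed at fixed radii around a central bead."""
    center = np.asarray(box) / 2
    xyz, species = [], []
    for name, nb, nf in zip(("POPG", "POPC"), n_boundary_per_species, n_bulk_per_species):
        for i in range(nb):
            ang = 2 * math.pi * (i + (0.5 if name == "POPC" else 0)) / max(nb, 1)
            xyz.append(center + [5.0 * math.cos(ang), 5.0 * math.sin(ang), 17.0])
            species.append(name)
        for i in range(nf):
            ang = 2 * math.pi * i / max(nf, 1)
            xyz.append(center + [60.0 * math.cos(ang), 60.0 * math.sin(ang), -17.0])
            species.append(name)
    return frame_from_points(xyz, species, protein_xyz=[center + [0, 0, 17.0]], box=box)


class TestEnrichment:
    def test_single_species_zero_exactly(self):
        f = ring_frame((4, 0), (16, 0))
        res = lm.enrichment([f], "POPG")
        assert res.B == 0.0

    def test_direct_evaluation(self):
        # boundary fraction 0.2 at bulk fraction 0.1 -> B = 1.0
        f = ring_frame((2, 8), (8, 82))  # POPG: 2/10 boundary, 10/100 bulk
        res = lm.enrichment([f], "POPG")
        assert res.B == pytest.approx(1.0)
        assert res.bulk_fraction == pytest.approx(0.1)

    def test_mixing_conservation_identity(self):
        """sum_i x_i B_i = 0 exactly within each frame census."""
        frames, _ = lm.gen_membrane_frames(
            {"POPG": 0.3, "POPC": 0.7}, n_lipids=600, n_frames=1, seed=5,
            boundary_bias={"POPG": 2.0},
        )
        f = frames[0]
        total = 0.0
        for sp, x in f.bulk_fractions().items():
            total += x * lm.enrichment([f], sp).B
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_absent_species_domain_error(self):
        f = ring_frame((2, 8), (8, 82))
        with pytest.raises(DomainError):
            lm.enrichment([f], "POPE")

    def test_frames_without_boundary_skipped(self):
        lonely = frame_from_points(
            [(10.0, 10.0, 17.0), (90.0, 90.0, -17.0)], ["POPG", "POPC"],
            protein_xyz=[(50.0, 50.0, 0.0)],
        )
        informative = ring_frame((2, 8), (8, 82))
        res = lm.enrichment([lonely, informative], "POPG")
        assert res.n_frames == 1


class TestBoundaryCensus:
    def test_identical_frames_sd_zero(self):
        f = ring_frame((2, 8), (8, 82))
        mean, sd = lm.boundary_census([f, f, f])
        assert sd == 0.0

    def test_constructed_count(self):
        f = ring_frame((10, 20), (50, 50))
        mean, _ = lm.boundary_census([f, f])
        assert mean == 30.0

    def test_species_additivity(self):
        f = ring_frame((3, 7), (10, 20))
        counts = lm.find_boundary(f)
        assert sum(counts.per_species.values()) == counts.total == 10


class TestPolarDensity:
    def test_absent_species_all_zero(self):
        f = ring_frame((2, 8), (8, 82))
        lm.assign_leaflets(f)
        dmap = lm.polar_density([f, f], "POPG", "inner", frame_window="all")
        # POPG boundary ring is in the outer leaflet; inner holds only bulk at r=60
        assert dmap.values.sum() == 0.0

    def test_single_bead_lands_in_expected_bin(self):
        center = np.array([100.0, 100.0, 30.0])
        xyz = [center + [10 * math.cos(0.1), 10 * math.sin(0.1), 17.0],
               center + [50.0, 0.0, -17.0]]
        f = frame_from_points(xyz, ["POPG", "POPG"],
                              protein_xyz=[center], box=(200.0, 200.0, 60.0))
        dmap = lm.polar_density([f], "POPG", "outer", frame_window="all")
        nz = np.argwhere(dmap.values > 0)
        assert nz.tolist() == [[2, 0]]  # radial bin [8,12), angular bin [0, pi/15)

    def test_count_conservation(self):
        frames, _ = lm.gen_membrane_frames(
            {"POPG": 0.2, "POPC": 0.8}, n_lipids=800, n_frames=4, seed=9
        )
        dmaps = [lm.polar_density(frames, sp, leaf, frame_window="all")
                 for sp in ("POPG", "POPC") for leaf in ("outer", "inner")]
        integrated = sum(d.integrated_count() for d in dmaps)
        # mean number of phosphates within 40 A of the pore axis per frame
        direct = 0.0
        for f in frames:
            delta = _min_image(f.phosphate_xyz - f.protein_xyz.mean(axis=0), f.box, False)
            r = np.hypot(delta[:, 0], delta[:, 1])
            direct += (r < 40.0).sum()
        direct /= len(frames)
        assert integrated == pytest.approx(direct, rel=1e-9)

    def test_grid_shape_and_window(self):
        frames, _ = lm.gen_membrane_frames(
            {"POPG": 1.0}, n_lipids=200, n_frames=4, seed=3
        )
        dmap = lm.polar_density(frames, "POPG", "outer")
        assert dmap.values.shape == (10, 30)

    def test_non_integral_binning_rejected(self):
        frames, _ = lm.gen_membrane_frames({"POPG": 1.0}, n_lipids=100, n_frames=1, seed=3)
        with pytest.raises(DomainError):
            lm.polar_density(frames, "POPG", "outer", r_max=41.0, dr=4.0)

    def test_isotropic_angular_counts_poisson(self):
        """Under uniform placement the angular-bin counts at fixed radius
        are Poisson; a chi-square dispersion test should not reject."""
        frames, _ = lm.gen_membrane_frames(
            {"POPG": 1.0}, n_lipids=3000, n_frames=1, seed=13,
            protein_radius=4.0, box=(120.0, 120.0, 60.0),
        )
        dmap = lm.polar_density(frames, "POPG", "outer", frame_window="all")
        counts = (dmap.values * dmap.bin_areas())[5:, :].sum(axis=0)  # outer annuli
        expected = counts.mean()
        chi2 = ((counts - expected) ** 2 / expected).sum()
        p = 1 - stats.chi2.cdf(chi2, df=len(counts) - 1)
        assert p > 0.01
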
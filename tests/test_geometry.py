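import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from protolra.errors import BWLookupError, InputError, StructureError
from protolra.geometry import (
    A100Config,
    BWMap,
    StructureFrame,
    a100_index,
    ca_distance,
    chi2_torsion,
    classify_a100,
    dihedral,
    frame_count,
    heron_area,
    npxxy_rmsd,
    pocket_area,
    resolve_bw,
    sidechain_com,
)
from protolra.synthetic import generate_toy_structure


def rigid_transform(frame, seed=0):
    rot = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
    shift = np.random.default_rng(seed + 1).uniform(-20, 20, 3)
    return frame.transformed(rot, shift)


class TestHeron:
    def test_right_triangle(self):
        assert heron_area(3, 4, 5) == pytest.approx(6.0)

    def test_degenerate(self):
        assert heron_area(1, 2, 3) == pytest.approx(0.0)

    def test_inequality_violation(self):
        with pytest.raises(InputError):
            heron_area(1, 1, 3)

    def test_negative_side(self):
        with pytest.raises(InputError):
            heron_area(-1, 2, 2)

    def test_argument_order_invariance(self):
        for a, b, c in itertools.permutations((3.0, 4.0, 5.0)):
            assert heron_area(a, b, c) == pytest.approx(6.0)


class TestCaDistance:
    def test_three_four_five(self):
        toy = generate_toy_structure("ca_pair_5A")
        assert ca_distance(toy.frame, "3.50", "6.34", toy.bw_map) == pytest.approx(5.0)

    def test_symmetric(self):
        toy = generate_toy_structure("ca_pair_5A")
        d1 = ca_distance(toy.frame, "3.50", "6.34", toy.bw_map)
        d2 = ca_distance(toy.frame, "6.34", "3.50", toy.bw_map)
        assert d1 == d2

    def test_identical_positions_zero(self):
        frame = StructureFrame(
            names=["CA", "CA"], resnames=["ALA", "ALA"], resids=[1, 2],
            chains=["A", "A"], coords=[(1.0, 2.0, 3.0), (1.0, 2.0, 3.0)],
            masses=[12.0, 12.0],
        )
        bw = BWMap("t", {"3.50": ("A", 1), "6.34": ("A", 2)})
        assert ca_distance(frame, "3.50", "6.34", bw) == 0.0

    def test_rigid_invariance(self):
        toy = generate_toy_structure("toy_receptor")
        moved = rigid_transform(toy.frame, seed=4)
        d0 = ca_distance(toy.frame, "3.50", "6.34", toy.bw_map)
        d1 = ca_distance(moved, "3.50", "6.34", toy.bw_map)
        assert d1 == pytest.approx(d0, abs=1e-9)


class TestResolveBW:
    def test_found(self):
        toy = generate_toy_structure("ca_pair_5A")
        res = resolve_bw(toy.bw_map, toy.frame, "3.50")
        assert res.resid == 1 and res.chain == "A"

    def test_unknown_code(self):
        toy = generate_toy_structure("ca_pair_5A")
        with pytest.raises(BWLookupError):
            resolve_bw(toy.bw_map, toy.frame, "9.99")

    def test_missing_residue_names_location(self):
        toy = generate_toy_structure("ca_pair_5A")
        bad = BWMap("t", {"2.50": ("B", 77)})
        with pytest.raises(StructureError, match="B/77"):
            resolve_bw(bad, toy.frame, "2.50")


class TestSidechainCom:
    def test_alanine_single_cb(self):
        toy = generate_toy_structure("triangle345")
        res = resolve_bw(toy.bw_map, toy.frame, "2.50")
        np.testing.assert_allclose(sidechain_com(toy.frame, res), [0, 0, 0],
                                   atol=1e-12)

    def test_two_equal_mass_atoms_midpoint(self):
        frame = StructureFrame(
            names=["CA", "OD1", "OD2"], resnames=["ASP"] * 3, resids=[1] * 3,
            chains=["A"] * 3,
            coords=[(5.0, 5.0, 5.0), (0.0, 0.0, 0.0), (2.0, 0.0, 0.0)],
            masses=[12.011, 15.999, 15.999],
        )
        res = frame.residue("A", 1)
        np.testing.assert_allclose(sidechain_com(frame, res), [1.0, 0.0, 0.0])

    def test_glycine_error(self):
        frame = StructureFrame(
            names=["N", "CA", "C", "O"], resnames=["GLY"] * 4, resids=[1] * 4,
            chains=["A"] * 4,
            coords=[(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)],
            masses=[14.0, 12.0, 12.0, 16.0],
        )
        with pytest.raises(StructureError):
            sidechain_com(frame, frame.residue("A", 1))

    def test_hydrogens_excluded(self):
        frame = StructureFrame(
            names=["CA", "CB", "HB1", "1HB"], resnames=["ALA"] * 4,
            resids=[1] * 4, chains=["A"] * 4,
            coords=[(9, 9, 9), (1, 2, 3), (50, 0, 0), (-50, 0, 0)],
            masses=[12.011, 12.011, 1.008, 1.008],
        )
        res = frame.residue("A", 1)
        np.testing.assert_allclose(sidechain_com(frame, res), [1, 2, 3])


class TestPocketArea:
    def test_triangle345(self):
        toy = generate_toy_structure("triangle345")
        area = pocket_area(toy.frame, ("2.50", "3.39", "7.49"), toy.bw_map)
        assert area == pytest.approx(6.0)

    def test_permutation_invariance(self):
        toy = generate_toy_structure("triangle345")
        for codes in itertools.permutations(("2.50", "3.39", "7.49")):
            assert pocket_area(toy.frame, codes, toy.bw_map) == pytest.approx(6.0)

    def test_rigid_invariance(self):
        toy = generate_toy_structure("triangle345")
        moved = rigid_transform(toy.frame, seed=7)
        assert pocket_area(moved, ("2.50", "3.39", "7.49"), toy.bw_map) == \
            pytest.approx(6.0, abs=1e-9)

    def test_collinear_zero(self):
        frame = StructureFrame(
            names=["CB"] * 3, resnames=["ALA"] * 3, resids=[1, 2, 3],
            chains=["A"] * 3,
            coords=[(0, 0, 0), (1, 0, 0), (2, 0, 0)], masses=[12.0] * 3,
        )
        bw = BWMap("t", {"a": ("A", 1), "b": ("A", 2), "c": ("A", 3)})
        assert pocket_area(frame, ("a", "b", "c"), bw) == pytest.approx(0.0, abs=1e-9)

    def test_wrong_code_count(self):
        toy = generate_toy_structure("triangle345")
        with pytest.raises(InputError):
            pocket_area(toy.frame, ("2.50", "3.39"), toy.bw_map)


def independent_rmsd_after_kabsch(mov_fit, ref_fit, mov_eval, ref_eval):
    """Oracle: Kabsch via raw SVD, coded independently of the main path."""
    mc, rc = mov_fit.mean(axis=0), ref_fit.mean(axis=0)
    h = (mov_fit - mc).T @ (ref_fit - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = (mov_eval - mc) @ r.T + rc
    return float(np.sqrt(np.mean(np.sum((moved - ref_eval) ** 2, axis=1))))


class TestNpxxyRmsd:
    def test_identical_frames_zero(self):
        toy = generate_toy_structure("npxxy_shift_1A")
        assert npxxy_rmsd(toy.reference, toy.reference, toy.bw_map) == \
            pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_zero(self):
        toy = generate_toy_structure("npxxy_shift_1A")
        moved = rigid_transform(toy.reference, seed=2)
        assert npxxy_rmsd(moved, toy.reference, toy.bw_map) == \
            pytest.approx(0.0, abs=1e-7)

    def test_one_angstrom_shift(self):
        toy = generate_toy_structure("npxxy_shift_1A")
        rmsd = npxxy_rmsd(toy.frame, toy.reference, toy.bw_map,
                          fit_codes=toy.fit_codes)
        assert rmsd == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_kabsch(self):
        from protolra.geometry import _backbone_coords

        toy = generate_toy_structure("npxxy_shift_1A")
        moved = rigid_transform(toy.frame, seed=5)
        motif = ("7.49", "7.50", "7.51", "7.52", "7.53")
        expected = independent_rmsd_after_kabsch(
            _backbone_coords(moved, toy.bw_map, toy.fit_codes),
            _backbone_coords(toy.reference, toy.bw_map, toy.fit_codes),
            _backbone_coords(moved, toy.bw_map, motif),
            _backbone_coords(toy.reference, toy.bw_map, motif),
        )
        got = npxxy_rmsd(moved, toy.reference, toy.bw_map, fit_codes=toy.fit_codes)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_missing_backbone_atom(self):
        frame = StructureFrame(
            names=["N", "CA", "C"], resnames=["ALA"] * 3, resids=[1] * 3,
            chains=["A"] * 3,
            coords=[(0, 0, 0), (1.4, 0, 0), (2.2, 1.1, 0)], masses=[14, 12, 12],
        )
        bw = BWMap("t", {"7.49": ("A", 1)})
        with pytest.raises(StructureError, match="'O'"):
            npxxy_rmsd(frame, frame, bw, motif_codes=("7.49",),
                       fit_codes=("7.49",))

    def test_code_outside_map(self):
        toy = generate_toy_structure("triangle345")
        with pytest.raises(BWLookupError):
            npxxy_rmsd(toy.frame, toy.frame, toy.bw_map)  # no 7.49 in map


class TestA100:
    @staticmethod
    def _cfg(intercept):
        return A100Config(distance_pairs=[("3.50", "6.34")] * 5,
                          coefficients=[0.0] * 5, intercept=intercept)

    @pytest.mark.parametrize("intercept,state", [
        (60.0, "active"), (-1.0, "inactive"), (30.0, "intermediate"),
        (0.0, "intermediate"), (55.0, "intermediate"),
    ])
    def test_threshold_classification(self, intercept, state):
        toy = generate_toy_structure("ca_pair_5A")
        value, got = a100_index(toy.frame, self._cfg(intercept), toy.bw_map)
        assert value == pytest.approx(intercept)
        assert got == state

    def test_distances_enter_linearly(self):
        toy = generate_toy_structure("ca_pair_5A")
        cfg = A100Config(distance_pairs=[("3.50", "6.34")] * 5,
                         coefficients=[1.0, 2.0, 0.0, 0.0, 0.0], intercept=3.0)
        value, _ = a100_index(toy.frame, cfg, toy.bw_map)
        assert value == pytest.approx(3.0 + 3.0 * 5.0)

    def test_state_partition_no_gaps(self):
        for v in (-1e9, -1e-12, 0.0, 27.0, 55.0, 55.0 + 1e-12, 1e9):
            assert classify_a100(v) in ("inactive", "intermediate", "active")
        assert classify_a100(0.0) == "intermediate"
        assert classify_a100(55.0) == "intermediate"
        assert classify_a100(-1e-12) == "inactive"
        assert classify_a100(55.0 + 1e-9) == "active"

    def test_config_requires_five_pairs(self):
        with pytest.raises(InputError):
            A100Config(distance_pairs=[("a", "b")] * 4, coefficients=[0.0] * 4)


class TestChi2:
    @pytest.mark.parametrize("name,expected", [
        ("dihedral_cis", 0.0), ("dihedral_trans", 180.0), ("dihedral_90", 90.0),
    ])
    def test_constructed_angles(self, name, expected):
        toy = generate_toy_structure(name)
        res = toy.frame.residue("A", 1)
        assert chi2_torsion(toy.frame, res) == pytest.approx(expected, abs=1e-9)

    def test_matches_mdanalysis(self):
        mda_dihedrals = pytest.importorskip(
            "MDAnalysis.lib.distances"
        ).calc_dihedrals
        rng = np.random.default_rng(12)
        for _ in range(25):
            pts = rng.uniform(-5, 5, (4, 3))
            try:
                mine = dihedral(*pts)
            except InputError:
                continue
            theirs = np.degrees(float(mda_dihedrals(*[p[None] for p in pts])[0]))
            diff = (mine - theirs + 180.0) % 360.0 - 180.0
            assert abs(diff) < 1e-3  # MDAnalysis computes in float32

    def test_mirror_flips_sign(self):
        toy = generate_toy_structure("dihedral_90")
        mirrored = StructureFrame(
            names=toy.frame.names, resnames=toy.frame.resnames,
            resids=toy.frame.resids, chains=toy.frame.chains,
            coords=toy.frame.coords * np.array([1.0, 1.0, -1.0]),
            masses=toy.frame.masses,
        )
        a = chi2_torsion(toy.frame, toy.frame.residue("A", 1))
        b = chi2_torsion(mirrored, mirrored.residue("A", 1))
        assert b == pytest.approx(-a, abs=1e-9)

    def test_rotation_invariance(self):
        toy = generate_toy_structure("dihedral_90")
        moved = rigid_transform(toy.frame, seed=9)
        assert chi2_torsion(moved, moved.residue("A", 1)) == \
            pytest.approx(90.0, abs=1e-9)

    def test_missing_atoms(self):
        frame = StructureFrame(
            names=["CA", "CB"], resnames=["ASP"] * 2, resids=[1] * 2,
            chains=["A"] * 2, coords=[(0, 0, 0), (1, 0, 0)], masses=[12.0] * 2,
        )
        with pytest.raises(StructureError):
            chi2_torsion(frame, frame.residue("A", 1))

    def test_unknown_residue_type(self):
        frame = StructureFrame(
            names=["CA"], resnames=["XXX"], resids=[1], chains=["A"],
            coords=[(0, 0, 0)], masses=[12.0],
        )
        with pytest.raises(StructureError):
            chi2_torsion(frame, frame.residue("A", 1))


class TestFrameCount:
    def test_paper_counts(self):
        assert frame_count(100_000, 100, 1, include_t0=True) == 1001
        assert frame_count(100_000, 100, 3, include_t0=True) == 3003

    def test_zero_duration(self):
        assert frame_count(0, 100, 1, include_t0=True) == 1

    def test_without_t0(self):
        assert frame_count(100_000, 100, 1, include_t0=False) == 1000

    def test_non_divisible(self):
        with pytest.raises(InputError):
            frame_count(1000, 300, 1)
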
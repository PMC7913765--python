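"""Structure reading, selections, superposition and torsion metrics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from parpdyn import structmetrics as sm
from parpdyn.synthetic import (
    _rotation_about_axis,
    analytic_rms_displacement,
    fixed_selection,
    make_two_domain_pair,
    mobile_selection,
)

from conftest import write_backbone_pdb


def random_rigid(seed):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.normal(scale=5.0, size=3)
    return rot, trans


# ---------------------------------------------------------------------------
# Reading and selections


class TestReadStructure:
    def test_minimal_roundtrip(self, minimal_pdb):
        model = sm.read_structure(minimal_pdb)
        assert len(model.chains) == 1
        (chain,) = model.chains
        assert len(chain.residues) == 1
        assert [a.name for a in chain.residues[0].atoms] == ["N", "CA", "C"]
        np.testing.assert_allclose(chain.residues[0].atoms[1].pos, [1.458, 0, 0])

    def test_altlocs_retained_and_resolved(self, altloc_pdb):
        model = sm.read_structure(altloc_pdb)
        res = model.chains[0].residues[0]
        ca_atoms = [a for a in res.atoms if a.name == "CA"]
        assert sorted(a.altloc for a in ca_atoms) == ["A", "B"]
        # highest occupancy wins at lookup time
        assert res.get_atom("CA").altloc == "B"

    def test_unreadable_and_empty(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("this is not a coordinate file\n")
        with pytest.raises((ValueError, FileNotFoundError)):
            sm.read_structure(tmp_path / "nonexistent.pdb")
        with pytest.raises(ValueError):
            sm.read_structure(bad)


class TestSelections:
    def test_builtin_counts(self, tmp_path):
        # complete synthetic structure covering the catalytic-domain numbering
        numbers = list(range(660, 1012))
        path = write_backbone_pdb(tmp_path / "full.pdb", numbers)
        model = sm.read_structure(path)
        coords, mask, labels = sm.resolve_atoms(model, sm.BUILTIN_SELECTIONS["HD"], "A")
        n_hd_res = (721 - 666 + 1) + (743 - 730 + 1) + (779 - 750 + 1)
        assert mask.all()
        assert len(labels) == 3 * n_hd_res
        coords, mask, labels = sm.resolve_atoms(model, sm.BUILTIN_SELECTIONS["ART"], "A")
        assert mask.all()
        assert len(labels) == 3 * 218  # hand count: 147 + 71 residues

    def test_missing_residues_masked_not_skipped(self, tmp_path):
        numbers = [n for n in range(666, 780) if n not in (723, 724, 725)]
        path = write_backbone_pdb(tmp_path / "gap.pdb", numbers)
        model = sm.read_structure(path)
        sel = sm.parse_selection("A:720-728:N,CA,C")
        coords, mask, labels = sm.resolve_atoms(model, sel, "A")
        assert len(labels) == 3 * 9
        absent = {lab[1] for lab, ok in zip(labels, mask) if not ok}
        assert absent == {723, 724, 725}
        assert np.isnan(coords[~mask]).all()

    def test_zero_atoms_errors(self, tmp_path):
        path = write_backbone_pdb(tmp_path / "small.pdb", [1, 2, 3])
        model = sm.read_structure(path)
        with pytest.raises(ValueError, match="zero atoms"):
            sm.resolve_atoms(model, sm.parse_selection("A:100-110:N,CA,C"), "A")

    def test_selection_grammar_and_overlap(self):
        sel = sm.parse_selection("A:666-721:N,CA,C+A:730-743:N,CA")
        assert sel.items[0] == ("A", (666, 721), ("N", "CA", "C"))
        assert sel.items[1][2] == ("N", "CA")
        with pytest.raises(ValueError, match="overlap"):
            sm.AtomSelection("bad", (("A", (1, 10), ("CA",)), ("A", (5, 12), ("CA",))))


# ---------------------------------------------------------------------------
# Kabsch superposition


def grid_rmsd_oracle(moving, reference):
    """Brute-force minimum rmsd over proper rotations: coarse Euler grid then
    Nelder-Mead refinement.  Independent of the SVD implementation."""
    mov = moving - moving.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def rmsd_of(euler):
        rot = Rotation.from_euler("zyz", euler).as_matrix()
        d = mov @ rot.T - ref
        return np.sqrt(np.mean(np.sum(d * d, axis=1)))

    grid = np.deg2rad(np.arange(0, 360, 12.0))
    half = np.deg2rad(np.arange(0, 180.001, 12.0))
    best, best_val = None, np.inf
    for a in grid:
        for b in half:
            for c in grid:
                val = rmsd_of((a, b, c))
                if val < best_val:
                    best, best_val = (a, b, c), val
    res = minimize(rmsd_of, best, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
    return float(res.fun)


class TestKabsch:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_rigid_transform(self, seed):
        rng = np.random.default_rng(seed)
        cloud = rng.normal(scale=4.0, size=(8, 3))
        rot, trans = random_rigid(seed + 100)
        moved = cloud @ rot.T + trans
        fit = sm.kabsch_fit(moved, cloud)
        assert fit.rmsd_fit < 1e-9
        # recovered transform inverts the applied one
        np.testing.assert_allclose(fit.rotation @ rot, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(fit.apply(moved), cloud, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 7)
        a = rng.normal(scale=3.0, size=(n, 3))
        b = a + rng.normal(scale=0.8, size=(n, 3))
        fit = sm.kabsch_fit(a, b)
        assert abs(fit.rmsd_fit - grid_rmsd_oracle(a, b)) <= 1e-3

    def test_rotation_always_proper(self):
        # near-planar cloud where the unconstrained optimum is a reflection
        rng = np.random.default_rng(7)
        a = rng.normal(size=(5, 3))
        a[:, 2] *= 0.01
        mirrored = a * np.array([1.0, 1.0, -1.0])
        fit = sm.kabsch_fit(mirrored, a)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs_error(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            sm.kabsch_fit(line, line + 1.0)
        with pytest.raises(ValueError, match="at least 3"):
            sm.kabsch_fit(line[:2], line[:2])
        with pytest.raises(ValueError, match="shape"):
            sm.kabsch_fit(np.zeros((4, 3)), np.zeros((5, 3)))

    @given(st.integers(0, 1000))
    def test_rmsd_rigid_motion_invariant(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(scale=3.0, size=(6, 3))
        b = a + rng.normal(scale=0.5, size=(6, 3))
        base = sm.kabsch_fit(a, b).rmsd_fit
        rot, trans = random_rigid(seed + 1)
        assert sm.kabsch_fit(a @ rot.T + trans, b).rmsd_fit == pytest.approx(base, abs=1e-9)
        assert sm.kabsch_fit(a, b @ rot.T + trans).rmsd_fit == pytest.approx(base, abs=1e-9)


# ---------------------------------------------------------------------------
# Two-set rmsd


class TestTwoSetRmsd:
    def test_self_comparison_is_zero(self, tmp_path):
        path = write_backbone_pdb(tmp_path / "m.pdb", range(666, 1010))
        model = sm.read_structure(path)
        res = sm.two_set_rmsd(model, model,
                              sm.BUILTIN_SELECTIONS["ART"], sm.BUILTIN_SELECTIONS["HD"])
        assert res.rmsd_fit < 1e-12
        assert res.rmsd_measure < 1e-12

    def test_equal_sets_reduce_to_conventional(self):
        ref, disp, truth = make_two_domain_pair(hinge_angle=17.0, seed=3)
        sel = mobile_selection(truth)
        cross = sm.two_set_rmsd(ref, disp, sel, sel)
        ref_c, _, _ = sm.resolve_atoms(ref, sel, "A")
        disp_c, _, _ = sm.resolve_atoms(disp, sel, "A")
        conventional = sm.kabsch_fit(disp_c, ref_c).rmsd_fit
        assert cross.rmsd_measure == pytest.approx(conventional, abs=1e-9)
        assert cross.rmsd_measure == pytest.approx(cross.rmsd_fit, abs=1e-9)

    @pytest.mark.parametrize("angle", [5.0, 10.0, 25.0])
    def test_hinge_pair_matches_analytic_displacement(self, angle):
        ref, disp, truth = make_two_domain_pair(hinge_angle=angle, seed=11)
        res = sm.two_set_rmsd(ref, disp, fixed_selection(truth), mobile_selection(truth))
        coords, mask, _ = sm.resolve_atoms(ref, mobile_selection(truth), "A")
        assert res.rmsd_measure == pytest.approx(
            analytic_rms_displacement(truth, coords[mask]), abs=1e-9
        )
        assert res.rmsd_fit < 1e-9

    def test_intersection_pairing_reports_counts(self, tmp_path):
        rng = np.random.default_rng(5)
        a = write_backbone_pdb(tmp_path / "a.pdb", range(1, 31), rng)
        b = write_backbone_pdb(tmp_path / "b.pdb",
                               [n for n in range(1, 31) if n not in (10, 11)], rng)
        ma, mb = sm.read_structure(a), sm.read_structure(b)
        sel = sm.parse_selection("A:1-30:N,CA,C")
        res = sm.two_set_rmsd(ma, mb, sel, sel)
        assert res.n_fit == 3 * 28

    def test_empty_intersection_names_offending_set(self, tmp_path):
        a = write_backbone_pdb(tmp_path / "a.pdb", range(1, 15))
        b = write_backbone_pdb(tmp_path / "b.pdb", range(1, 15))
        ma, mb = sm.read_structure(a), sm.read_structure(b)
        fit = sm.parse_selection("A:1-14:N,CA,C", name="fitset")
        with pytest.raises(ValueError, match="zero atoms|measure"):
            sm.two_set_rmsd(ma, mb, fit, sm.parse_selection("A:100-120:N,CA,C"))


# ---------------------------------------------------------------------------
# Distances and torsions


class TestDistances:
    def test_ca_distance(self, tmp_path):
        path = tmp_path / "two.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A   2       3.000   4.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        model = sm.read_structure(path)
        assert sm.ca_distance(model, "A", 1, 2) == pytest.approx(5.0)
        assert sm.ca_distance(model, "A", 1, 1) == 0.0
        with pytest.raises(ValueError, match="3"):
            sm.ca_distance(model, "A", 1, 3)


class TestDihedral:
    def test_planar_limits(self):
        # cis: all four atoms coplanar with p1 and p4 on the same side
        cis = [(1.0, 1.0, 0.0), (0.0, 0.0, 0.0), (1.0, 0.0, 0.0), (2.0, 1.0, 0.0)]
        assert sm.dihedral(*[np.array(p) for p in [(1, 1, 0), (0, 0, 0), (1, 0, 0), (2, 1, 0)]]) == pytest.approx(0.0, abs=1e-12)
        trans = [np.array(p) for p in [(1, 1, 0), (0, 0, 0), (1, 0, 0), (2, -1, 0)]]
        assert abs(sm.dihedral(*trans)) == pytest.approx(180.0, abs=1e-12)

    @pytest.mark.parametrize("target", [60.0, -60.0, 100.0, -155.5])
    def test_constructed_torsion(self, target):
        # rotate the far atom about the central bond by the target angle
        p1 = np.array([1.0, 1.0, 0.0])
        p2 = np.array([0.0, 0.0, 0.0])
        p3 = np.array([1.0, 0.0, 0.0])
        arm = np.array([1.0, 1.0, 0.0])
        rot = _rotation_about_axis(np.array([1.0, 0.0, 0.0]), target)
        p4 = p3 + rot @ (arm - np.array([1.0, 0.0, 0.0]))
        assert sm.dihedral(p1, p2, p3, p4) == pytest.approx(target, abs=1e-9)

    @given(st.integers(0, 500))
    def test_rigid_invariance_reversal_and_mirror(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(scale=3.0, size=(4, 3))
        try:
            base = sm.dihedral(*pts)
        except ValueError:
            return  # degenerate draw
        rot, trans = random_rigid(seed + 2)
        moved = pts @ rot.T + trans
        assert sm.dihedral(*moved) == pytest.approx(base, abs=1e-8)
        # a torsion is unchanged by reversing the point order ...
        assert sm.dihedral(*pts[::-1]) == pytest.approx(base, abs=1e-8)
        # ... and negated by a mirror reflection
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert sm.dihedral(*mirrored) == pytest.approx(-base, abs=1e-8) or abs(
            base
        ) == pytest.approx(180.0, abs=1e-8)

    def test_degenerate_errors(self):
        p = np.zeros(3)
        with pytest.raises(ValueError, match="coincident"):
            sm.dihedral(p, p, np.array([1.0, 0, 0]), np.array([2.0, 1, 0]))
        with pytest.raises(ValueError, match="collinear"):
            sm.dihedral(np.array([-1.0, 0, 0]), p, np.array([1.0, 0, 0]),
                        np.array([2.0, 0, 0]))


def _nucleoside_pdb(tmp_path, chi_by_chain):
    """Build a fake purine-nucleoside ligand with controlled chi per chain."""
    lines = []
    serial = 1
    for chain, chi in chi_by_chain.items():
        o4 = np.array([1.0, 1.0, 0.0])
        c1 = np.array([0.0, 0.0, 0.0])
        n9 = np.array([1.4, 0.0, 0.0])
        rot = _rotation_about_axis(np.array([1.0, 0.0, 0.0]), chi)
        c4 = n9 + rot @ np.array([0.0, 1.3, 0.0])
        # random rigid placement per chain exercises rigid-motion invariance
        rng = np.random.default_rng(ord(chain[0]))
        frame = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(scale=8.0, size=3)
        for name, pos in (("O4'", o4), ("C1'", c1), ("N9", n9), ("C4", c4)):
            x, y, z = frame @ pos + shift
            lines.append(
                f"HETATM{serial:5d} {name:>4s} LIG {chain} 500    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           {name[0]:>2s}"
            )
            serial += 1
    lines.append("END")
    path = tmp_path / "lig.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


class TestGlycosidicChi:
    def test_constructed_value_and_rigid_invariance(self, tmp_path):
        path = _nucleoside_pdb(tmp_path, {"A": -60.0})
        model = sm.read_structure(path)
        assert sm.glycosidic_chi(model, residue_name="LIG") == pytest.approx(-60.0, abs=0.3)

    def test_circular_mean_across_chains(self, tmp_path):
        path = _nucleoside_pdb(tmp_path, {"A": -70.0, "B": -66.0})
        model = sm.read_structure(path)
        assert sm.glycosidic_chi(model, residue_name="LIG") == pytest.approx(-68.0, abs=0.3)
        per_chain = sm.glycosidic_chi(model, residue_name="LIG", average=False)
        assert set(per_chain) == {"A", "B"}

    def test_missing_atoms_listed(self, tmp_path):
        path = _nucleoside_pdb(tmp_path, {"A": -60.0})
        text = "\n".join(ln for ln in path.read_text().splitlines() if " C4 " not in ln)
        path.write_text(text + "\n")
        model = sm.read_structure(path)
        with pytest.raises(ValueError, match="C4"):
            sm.glycosidic_chi(model, residue_name="LIG")
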
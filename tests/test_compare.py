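"""Two-model comparison metrics: displacement, dihedral deltas,
peptide misorientation, Ramachandran transitions, census report."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lowres_audit import (
    AtomRecord,
    ChainModel,
    Residue,
    build_polypeptide,
    circular_diff,
    comparison_report,
    compare_peptides,
    compare_residues,
    helix_spec,
    inject_peptide_flip,
    max_heavy_displacement,
    pair_models,
    rama_region,
    wrong_minimum_transitions,
)
from lowres_audit.errors import ComparisonError
from conftest import translate


class TestCircularDiff:
    @pytest.mark.parametrize(
        "a,b,expected", [(170, -170, 20), (45, 45, 0), (-90, 90, 180), (0, 359, 1)]
    )
    def test_wraparound(self, a, b, expected):
        assert circular_diff(a, b) == pytest.approx(expected)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(3)
        for a, b in rng.uniform(-180, 180, size=(50, 2)):
            d = circular_diff(a, b)
            assert d == pytest.approx(circular_diff(b, a))
            assert 0.0 <= d <= 180.0

    def test_none_propagates(self):
        assert circular_diff(None, 10.0) is None


class TestPairModels:
    def test_identity_pairs_everything(self, helix10):
        pairs, realigned, ua, ub = pair_models(helix10, helix10.copy())
        assert len(pairs) == 10 and not realigned and not ua and not ub

    def test_renamed_residues_flagged_realigned_and_excluded(self, helix10):
        other = helix10.copy()
        for i in (2, 5, 7):
            other.residues[i].res_name = "GLY"
        pairs, realigned, _, _ = pair_models(helix10, other)
        assert len(realigned) == 3 and len(pairs) == 7
        comps = compare_residues(helix10, other)
        assert {c.res_id for c in comps} == {p[0].res_id for p in pairs}

    def test_disjoint_chains_raise(self, helix10):
        other = build_polypeptide(helix_spec(10, chain_id="B"))
        with pytest.raises(ComparisonError):
            pair_models(helix10, other)


class TestMaxHeavyDisplacement:
    def test_identical_residue_is_zero(self, helix10):
        r = helix10.residues[3]
        assert max_heavy_displacement(r, r) == 0.0

    def test_translation_recovered(self, helix10):
        moved = translate(helix10, (3, 0, 0))
        assert max_heavy_displacement(
            helix10.residues[2], moved.residues[2]
        ) == pytest.approx(3.0)

    def test_max_over_atoms(self):
        def make(ca, o):
            return Residue(
                chain_id="A", seq_num=1, res_name="ALA",
                atoms=[AtomRecord("CA", "C", ca), AtomRecord("O", "O", o),
                       AtomRecord("H", "H", [50, 50, 50])],
            )

        a = make([0, 0, 0], [1, 0, 0])
        b = make([1, 0, 0], [5, 0, 0])  # CA moved 1 A, O moved 4 A; H ignored
        assert max_heavy_displacement(a, b) == pytest.approx(4.0)

    def test_no_shared_heavy_atoms_warns(self):
        a = Residue(chain_id="A", seq_num=1, atoms=[AtomRecord("CA", "C", [0, 0, 0])])
        b = Residue(chain_id="A", seq_num=1, atoms=[AtomRecord("CB", "C", [0, 0, 0])])
        with pytest.warns(UserWarning):
            assert max_heavy_displacement(a, b) is None


class TestPeptideRotation:
    def test_identity_is_zero(self, helix20):
        for p in compare_peptides(helix20, helix20.copy()):
            assert p.rotation_angle == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("theta", [30.0, 90.0, 120.0, 180.0])
    def test_injected_flip_recovered_exactly(self, helix20, theta):
        flipped = inject_peptide_flip(helix20, 9, theta)
        rots = {p.res_id: p.rotation_angle for p in compare_peptides(helix20, flipped)}
        assert rots[("A", 10, "")] == pytest.approx(theta, abs=1e-6)
        others = [v for k, v in rots.items() if k != ("A", 10, "")]
        assert max(others) < 1e-6

    def test_global_rigid_motion_leaves_rotation_unchanged(self, helix20):
        flipped = inject_peptide_flip(helix20, 9, 100.0)
        rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True)
        moved = flipped.copy()
        for res in moved.residues:
            for atom in res.atoms:
                atom.position = rot.apply(atom.position) + np.array([10.0, -4.0, 2.5])
        base = {p.res_id: p.rotation_angle for p in compare_peptides(helix20, flipped)}
        after = {p.res_id: p.rotation_angle for p in compare_peptides(helix20, moved)}
        for k in base:
            assert after[k] == pytest.approx(base[k], abs=1e-6)

    def test_displacement_is_frame_dependent(self, helix20):
        moved = translate(helix20, (10, 0, 0))
        comps = compare_residues(helix20, moved)
        assert all(c.max_heavy_displacement == pytest.approx(10.0) for c in comps)


class TestRamaRegion:
    @pytest.mark.parametrize(
        "phi,psi,region",
        [(-63, -43, "alpha"), (-120, 130, "beta"), (60, 45, "left_alpha"),
         (-120, -170, "beta"), (170, 170, "other")],
    )
    def test_packaged_polygons(self, phi, psi, region):
        assert rama_region(phi, psi) == region


class TestWrongMinimum:
    def test_self_comparison_empty(self, helix20):
        comps = compare_residues(helix20, helix20.copy())
        assert wrong_minimum_transitions(comps) == []

    def test_large_flip_moves_both_neighbours_across_basins(self, helix20):
        flipped = inject_peptide_flip(helix20, 9, 150.0)
        comps = compare_residues(helix20, flipped)
        moved = {c.res_id[1] for c in wrong_minimum_transitions(comps)}
        assert {10, 11} <= moved

    def test_small_wiggle_within_basin_ignored(self, helix20):
        wiggled = build_polypeptide(helix_spec(20))
        # same basin, 10 deg away
        other = build_polypeptide(
            helix_spec(20).__class__(
                ["ALA"] * 20, [-73.0] * 20, [-33.0] * 20, [180.0] * 20
            )
        )
        comps = compare_residues(wiggled, other)
        assert wrong_minimum_transitions(comps) == []


class TestComparisonReport:
    def test_self_comparison_is_zero_everywhere(self, helix20):
        rep = comparison_report(helix20, helix20.copy())
        assert rep.n_changed == 0
        assert rep.fraction_changed == 0.0
        assert rep.n_misoriented == 0
        assert rep.n_wrong_minimum == 0

    def test_flip_census(self, helix20):
        flipped = inject_peptide_flip(helix20, 9, 150.0)
        rep = comparison_report(helix20, flipped)
        assert rep.n_misoriented == 1
        assert rep.n_changed >= 2  # both neighbours changed dihedrals
        assert rep.n_paired == 20

    def test_swap_symmetry(self, helix20):
        flipped = inject_peptide_flip(helix20, 9, 120.0)
        ab = comparison_report(helix20, flipped)
        ba = comparison_report(flipped, helix20)
        assert ab.n_changed == ba.n_changed
        assert ab.n_misoriented == ba.n_misoriented
        for pa, pb in zip(ab.peptides, ba.peptides):
            if pa.rotation_angle is not None:
                assert pa.rotation_angle == pytest.approx(pb.rotation_angle, abs=1e-6)

    def test_raising_thresholds_never_raises_counts(self, helix20):
        flipped = inject_peptide_flip(helix20, 9, 150.0)
        last_changed, last_mis = None, None
        for scale in (1.0, 1.5, 2.0, 3.0):
            rep = comparison_report(
                helix20, flipped,
                {"displacement": 2.0 * scale, "dihedral": 45.0 * scale,
                 "peptide": 60.0 * scale},
            )
            if last_changed is not None:
                assert rep.n_changed <= last_changed
                assert rep.n_misoriented <= last_mis
            last_changed, last_mis = rep.n_changed, rep.n_misoriented

    def test_strict_threshold_inequalities(self):
        def residue(x):
            return Residue(chain_id="A", seq_num=1, res_name="ALA",
                           atoms=[AtomRecord("CA", "C", [x, 0, 0])])

        a = ChainModel(residues=[residue(0.0)])
        b = ChainModel(residues=[residue(2.0)])  # exactly the 2 A threshold
        rep_eq = comparison_report(a, b)
        assert rep_eq.n_changed == 0
        c = ChainModel(residues=[residue(2.000001)])
        assert comparison_report(a, c).n_changed == 1
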
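"""Dihedral math, peptide classification, virtual dihedrals, contour lookup."""

import gemmi
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lowres_audit import (
    ContourTable,
    classify_peptide,
    compute_dihedrals,
    contour_lookup,
    count_cis_nonproline,
    dihedral,
    inject_cis_peptide,
    inject_peptide_flip,
    build_polypeptide,
    helix_spec,
)
from lowres_audit.errors import ConfigurationError, UndefinedDihedralError
from lowres_audit.geometry import wrap_angle
from lowres_audit.synthetic import BuildSpec
from conftest import single_residue_chain

finite_coord = st.floats(-50, 50, allow_nan=False)
point = st.tuples(finite_coord, finite_coord, finite_coord)


class TestDihedral:
    def test_perpendicular_quadruple_sign_fixed_by_oracle(self):
        # independent vector-algebra oracle: n1=(0,0,-1), n2=(1,0,0),
        # atan2(dot(cross(n1,n2),b2), dot(n1,n2)) = atan2(-1, 0) = -90 deg
        assert dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (0, 1, 1)) == pytest.approx(-90.0)

    def test_eclipsed_is_zero(self):
        assert dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (1, 1, 0)) == pytest.approx(0.0)

    def test_anti_eclipsed_is_180(self):
        assert dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (-1, 1, 0)) == pytest.approx(180.0)

    def test_collinear_points_raise(self):
        with pytest.raises(UndefinedDihedralError):
            dihedral((2, 0, 0), (1, 0, 0), (0, 0, 0), (0, 1, 0))
        with pytest.raises(UndefinedDihedralError):
            dihedral((1, 0, 0), (0, 0, 0), (0, 0, 0), (0, 1, 0))

    @settings(derandomize=True, max_examples=50)
    @given(p1=point, p2=point, p3=point, p4=point)
    def test_matches_gemmi_reversal_and_mirror_symmetry(self, p1, p2, p3, p4):
        try:
            mine = dihedral(p1, p2, p3, p4)
        except UndefinedDihedralError:
            return
        ref = np.degrees(
            gemmi.calculate_dihedral(*[gemmi.Position(*p) for p in (p1, p2, p3, p4)])
        )
        assert abs(wrap_angle(mine - ref)) < 1e-6
        # a torsion reads the same from either chain direction...
        rev = dihedral(p4, p3, p2, p1)
        assert abs(wrap_angle(mine - rev)) < 1e-6
        # ...and flips sign under mirror reflection
        mir = dihedral(*[(-p[0], p[1], p[2]) for p in (p1, p2, p3, p4)])
        assert abs(wrap_angle(mine + mir)) < 1e-6

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(4, 3)) * 3
        base = dihedral(*pts)
        from scipy.spatial.transform import Rotation

        for _ in range(5):
            rot = Rotation.random(rng=rng)
            shift = rng.normal(size=3) * 10
            moved = [rot.apply(p) + shift for p in pts]
            assert abs(dihedral(*moved) - base) < 1e-9


class TestComputeDihedrals:
    def test_ideal_helix_round_trip(self, helix20):
        for i, rec in enumerate(compute_dihedrals(helix20)):
            if i > 0:
                assert rec.phi == pytest.approx(-63.0, abs=1e-6)
                assert abs(rec.omega) == pytest.approx(180.0, abs=1e-6)
            if i < 19:
                assert rec.psi == pytest.approx(-43.0, abs=1e-6)

    def test_single_residue_all_null(self):
        recs = compute_dihedrals(single_residue_chain())
        assert len(recs) == 1
        r = recs[0]
        assert all(
            getattr(r, a) is None for a in ("phi", "psi", "omega", "mu_in", "mu_out", "nu")
        )

    def test_chain_break_nulls_spanning_dihedrals(self, helix20):
        broken = helix20.copy()
        shift = np.array([5.0, 0.0, 0.0])
        for res in broken.residues[10:]:
            for atom in res.atoms:
                atom.position = atom.position + shift
        recs = compute_dihedrals(broken)
        assert recs[10].omega is None and recs[10].phi is None
        assert recs[9].psi is None
        # residues away from the break are untouched
        assert recs[5].phi is not None and recs[15].phi is not None


class TestPeptideClassification:
    @pytest.mark.parametrize(
        "omega,label",
        [(2.0, "cis"), (-179.0, "trans"), (90.0, "twisted"),
         (30.0, "cis"), (150.0, "trans"), (-30.0, "cis"), (-150.0, "trans"),
         (30.0001, "twisted"), (149.9999, "twisted"), (180.0, "trans")],
    )
    def test_cutoffs_partition_deterministically(self, omega, label):
        assert classify_peptide(omega).label == label

    def test_every_angle_gets_exactly_one_label(self):
        for omega in np.linspace(-179.99, 180.0, 721):
            assert classify_peptide(float(omega)).label in {"cis", "twisted", "trans"}

    def test_proline_flagging(self):
        assert classify_peptide(1.0, "PRO").nonproline is False
        assert classify_peptide(1.0, "GLY").nonproline is True


class TestCisCensus:
    def test_counts_injected_cis_excluding_prolines(self):
        n = 20
        names = ["ALA"] * n
        names[8] = "PRO"  # cis-proline at peptide 7->8: excluded
        omega = [180.0] * n
        for pos in (5, 8, 12, 16):
            omega[pos] = 3.0
        model = build_polypeptide(BuildSpec(names, [-63.0] * n, [-43.0] * n, omega))
        count, table = count_cis_nonproline(model)
        assert count == 3
        assert set(table[table.cis_nonproline].seq) == {6, 13, 17}

    def test_all_trans_helix_has_none(self, helix20):
        count, _ = count_cis_nonproline(helix20)
        assert count == 0


class TestVirtualDihedrals:
    def test_helix_interior_is_regular(self, helix20):
        recs = compute_dihedrals(helix20)
        mu_in = [r.mu_in for r in recs if r.mu_in is not None]
        mu_out = [r.mu_out for r in recs if r.mu_out is not None]
        assert np.std(mu_in) < 0.1 and np.std(mu_out) < 0.1
        assert np.mean(mu_in) == pytest.approx(np.mean(mu_out), abs=0.1)

    def test_four_residue_chain_has_no_mu(self):
        model = build_polypeptide(helix_spec(4))
        recs = compute_dihedrals(model)
        assert all(r.mu_in is None and r.mu_out is None for r in recs)

    def test_flip_moves_nu_but_not_mu(self, helix20):
        flipped = inject_peptide_flip(helix20, 9, 180.0)
        before = compute_dihedrals(helix20)
        after = compute_dihedrals(flipped)
        i = 10  # nu(i) uses O(i-1), which the flip at peptide (9, 10) rotated
        dnu = abs(wrap_angle(after[i].nu - before[i].nu))
        assert dnu == pytest.approx(180.0, abs=1e-6)
        assert after[i].mu_in == pytest.approx(before[i].mu_in, abs=1e-9)


def _uniform_table(nbins=6):
    edges = np.linspace(-180, 180, nbins + 1)
    return ContourTable(
        ["mu_in", "mu_out"],
        {"mu_in": edges, "mu_out": edges},
        np.ones((nbins, nbins)),
    )


class TestContourLookup:
    def test_uniform_table_scores_one_everywhere(self, helix20):
        table = _uniform_table()
        for rec in compute_dihedrals(helix20):
            score, level = contour_lookup(rec, table)
            if score is None:
                continue
            assert score == pytest.approx(1.0)
            assert level == "none"

    def test_peaked_table_flags_flip_as_outlier(self, helix20):
        # nearly all mass in the bins containing the ideal-helix (mu_in, nu);
        # a peptide flip leaves the CA trace (mu) untouched but rotates the
        # carbonyl O, so it surfaces through the nu dimension
        edges = np.linspace(-180, 180, 24 + 1)
        probs = np.full((24, 24), 1e-6)
        recs = compute_dihedrals(helix20)
        interior = next(r for r in recs if r.mu_in is not None and r.nu is not None)
        bi = np.searchsorted(edges, interior.mu_in) - 1
        bj = np.searchsorted(edges, interior.nu) - 1
        probs[bi, bj] = 1.0
        table = ContourTable(["mu_in", "nu"], {"mu_in": edges, "nu": edges}, probs)
        score, level = contour_lookup(interior, table)
        assert score > 0.5 and level == "none"
        flipped = compute_dihedrals(inject_peptide_flip(helix20, 9, 180.0))
        changed = flipped[10]  # nu(10) uses the rotated O(9)
        assert abs(wrap_angle(changed.nu - recs[10].nu)) == pytest.approx(180.0, abs=1e-6)
        score_f, level_f = contour_lookup(changed, table)
        assert score_f < 0.01 and level_f == "1%"

    def test_empty_table_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            ContourTable(["mu_in"], {"mu_in": np.array([-180.0, 180.0])}, np.array([]))

    def test_angle_outside_domain_scores_zero_with_warning(self):
        edges = np.linspace(-90, 90, 7)
        table = ContourTable(["phi"], {"phi": edges}, np.ones(6))
        with pytest.warns(UserWarning, match="outside contour domain"):
            assert table.score({"phi": 170.0}) == 0.0

    def test_text_file_round_trip(self, tmp_path):
        table = _uniform_table(4)
        p = tmp_path / "table.txt"
        table.to_file(p)
        back = ContourTable.from_file(p)
        assert back.dimensions == table.dimensions
        assert back.convention == table.convention
        np.testing.assert_allclose(back.probabilities, table.probabilities)


def test_cis_injection_produces_cis_classification(helix20):
    cis = inject_cis_peptide(helix20, 8, 0.0)
    recs = compute_dihedrals(cis)
    assert classify_peptide(recs[8].omega).label == "cis"
    # neighbours keep their conformation
    assert recs[7].phi == pytest.approx(-63.0, abs=1e-6)
    assert recs[9].omega == pytest.approx(180.0, abs=1e-4) or abs(recs[9].omega) > 179.99
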
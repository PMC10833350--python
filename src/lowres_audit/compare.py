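"""Residue-by-residue comparison of two versions of the same model.

Implements the change metrics used to audit low-resolution rebuilds:

* maximum heavy-atom (non-H) displacement per residue, in the models'
  native frame (refined-into-the-same-map comparisons share a frame; an
  optional least-squares superposition handles models that do not);
* circular differences of phi/psi/omega;
* the peptide misorientation angle: the rotation of the carbonyl O about
  the CA(i)->CA(i+1) axis after local alignment of that axis, which is
  frame-independent by construction. The CO-CO virtual-dihedral difference
  is computed alongside as a second, independent misorientation measure;
* Ramachandran basin transitions ("wrong minimum" moves).

Default thresholds: a residue counts as changed when a non-H atom moved
by >2 A and/or phi, psi or omega changed by >45 deg (strict inequalities);
a peptide is misoriented when its rotation angle exceeds 60 deg.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy.spatial.transform import Rotation

from .errors import ComparisonError
from .geometry import DihedralRecord, compute_dihedrals, count_cis_nonproline, dihedral
from .model import ChainModel, Residue, as_chain_list

DEFAULT_THRESHOLDS = {
    "displacement": 2.0,  # A
    "dihedral": 45.0,  # deg, phi/psi/omega
    "peptide": 60.0,  # deg, misorientation
}


def _load_polygons():
    with resources.files("lowres_audit.data").joinpath("rama_polygons.json").open() as fh:
        data = json.load(fh)
    regions = {
        name: [MplPath(np.asarray(poly, dtype=float)) for poly in polys]
        for name, polys in data["regions"].items()
    }
    return data["version"], data["order"], regions


RAMA_VERSION, _RAMA_ORDER, _RAMA_REGIONS = _load_polygons()


def circular_diff(a: float | None, b: float | None) -> float | None:
    """Smallest angular separation of two angles in degrees, in [0, 180]."""
    if a is None or b is None:
        return None
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def rama_region(phi: float, psi: float) -> str:
    """Coarse Ramachandran basin label: alpha, beta, left_alpha or other.

    Basin polygons are versioned package data (see ``RAMA_VERSION``); they
    identify minima for wrong-minimum detection, they are not outlier
    contours.
    """
    pt = (phi, psi)
    for name in _RAMA_ORDER:
        for poly in _RAMA_REGIONS[name]:
            if poly.contains_point(pt, radius=1e-9):
                return name
    return "other"


@dataclass
class ResidueComparison:
    """Per-residue change metrics between model a and model b."""

    res_id: tuple[str, int, str]
    res_name: str
    max_heavy_displacement: float | None = None
    d_phi: float | None = None
    d_psi: float | None = None
    d_omega: float | None = None
    rama_before: str | None = None
    rama_after: str | None = None

    @property
    def changed(self) -> bool:
        if self.max_heavy_displacement is not None and self.max_heavy_displacement > 2.0:
            return True
        return any(d is not None and d > 45.0 for d in (self.d_phi, self.d_psi, self.d_omega))

    def changed_under(self, disp: float, dih: float) -> bool:
        if self.max_heavy_displacement is not None and self.max_heavy_displacement > disp:
            return True
        return any(d is not None and d > dih for d in (self.d_phi, self.d_psi, self.d_omega))

    @property
    def wrong_minimum(self) -> bool:
        if self.rama_before is None or self.rama_after is None:
            return False
        moved = any(d is not None and d > 45.0 for d in (self.d_phi, self.d_psi))
        return self.rama_before != self.rama_after and moved


@dataclass
class PeptideComparison:
    """Orientation change of the peptide unit between residues i and i+1."""

    res_id: tuple[str, int, str]  # residue i (first residue of the peptide)
    rotation_angle: float | None = None  # O rotation about the CA-CA axis, [0, 180]
    nu_difference: float | None = None  # independent measure: delta of the CO-CO virtual dihedral

    def misoriented(self, cutoff: float = 60.0) -> bool:
        return self.rotation_angle is not None and self.rotation_angle > cutoff


def pair_models(
    a: ChainModel | list[ChainModel], b: ChainModel | list[ChainModel]
) -> tuple[list[tuple[Residue, Residue]], list[tuple[Residue, Residue]], list[Residue], list[Residue]]:
    """Pair residues by (chain_id, seq_num, icode).

    Returns (pairs, realigned, unpaired_a, unpaired_b). Pairs whose residue
    names differ are flagged realigned (sequence register moved) and are
    excluded from dihedral/displacement statistics by default.
    """
    a_res = [r for c in as_chain_list(a) for r in c.residues]
    b_map = {r.res_id: r for c in as_chain_list(b) for r in c.residues}
    pairs, realigned, unpaired_a = [], [], []
    matched_b = set()
    for ra in a_res:
        rb = b_map.get(ra.res_id)
        if rb is None:
            unpaired_a.append(ra)
            continue
        matched_b.add(ra.res_id)
        if ra.res_name != rb.res_name:
            realigned.append((ra, rb))
        else:
            pairs.append((ra, rb))
    unpaired_b = [r for rid, r in b_map.items() if rid not in matched_b]
    if not pairs and not realigned:
        raise ComparisonError("models share no pairable residues")
    return pairs, realigned, unpaired_a, unpaired_b


def max_heavy_displacement(res_a: Residue, res_b: Residue) -> float | None:
    """Max Euclidean displacement over shared non-H atom names, in A."""
    b_atoms = {a.name: a for a in res_b.heavy_atoms}
    dists = [
        float(np.linalg.norm(a.position - b_atoms[a.name].position))
        for a in res_a.heavy_atoms
        if a.name in b_atoms
    ]
    if not dists:
        warnings.warn(f"{res_a.label()}: no shared non-H atoms")
        return None
    return max(dists)


def peptide_rotation(
    res_a_i: Residue,
    res_a_j: Residue,
    res_b_i: Residue,
    res_b_j: Residue,
    frame_a: np.ndarray | None = None,
    frame_b: np.ndarray | None = None,
) -> float | None:
    """Rotation of the carbonyl O about the CA(i)->CA(i+1) axis, degrees [0, 180].

    Model b's local frame is superposed onto model a's by a least-squares
    fit of the surrounding CA trace (CA of residues i-1..i+2 when supplied
    via frame_a/frame_b, else the two CA of the peptide); the returned
    value is |dihedral(O_b', CA_a(i), CA_a(i+1), O_a(i))| — the azimuth of
    the carbonyl O about the CA-CA axis. No peptide flip moves a CA atom,
    so the measure is exact for pure peptide rotations, and the local
    superposition makes it invariant under global rigid motions of either
    model. With only two framing CA, a minimal rotation aligning the
    CA->CA axes is used; the spin about the axis is then taken from the
    models as given.
    """
    ca_ai, ca_aj, o_a = res_a_i.pos("CA"), res_a_j.pos("CA"), res_a_i.pos("O")
    ca_bi, ca_bj, o_b = res_b_i.pos("CA"), res_b_j.pos("CA"), res_b_i.pos("O")
    if any(p is None for p in (ca_ai, ca_aj, o_a, ca_bi, ca_bj, o_b)):
        return None
    A = np.asarray(frame_a) if frame_a is not None else np.asarray([ca_ai, ca_aj])
    B = np.asarray(frame_b) if frame_b is not None else np.asarray([ca_bi, ca_bj])
    cen_a, cen_b = A.mean(axis=0), B.mean(axis=0)
    centered = A - cen_a
    collinear = np.linalg.matrix_rank(centered, tol=1e-6) < 2
    if len(A) >= 3 and not collinear:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # align_vectors warns on near-degenerate sets
            rot, _ = Rotation.align_vectors(centered, B - cen_b)
        o_b_aligned = cen_a + rot.apply(o_b - cen_b)
    else:
        rot, _ = Rotation.align_vectors((ca_aj - ca_ai)[None, :], (ca_bj - ca_bi)[None, :])
        o_b_aligned = ca_ai + rot.apply(o_b - ca_bi)
    # identical orientations give a degenerate quadruple -> 0 by definition
    if np.linalg.norm(o_b_aligned - o_a) < 1e-9:
        return 0.0
    try:
        return abs(dihedral(o_b_aligned, ca_ai, ca_aj, o_a))
    except Exception:
        return None


def compare_peptides(
    a: ChainModel | list[ChainModel], b: ChainModel | list[ChainModel]
) -> list[PeptideComparison]:
    """Peptide-orientation comparison for every peptide present in both models."""
    out = []
    b_chains = {c.chain_id: c for c in as_chain_list(b)}
    for chain_a in as_chain_list(a):
        chain_b = b_chains.get(chain_a.chain_id)
        if chain_b is None:
            continue
        b_idx = {r.res_id: i for i, r in enumerate(chain_b.residues)}
        nu_a = {r.res_id: r.nu for r in compute_dihedrals(chain_a)}
        nu_b = {r.res_id: r.nu for r in compute_dihedrals(chain_b)}
        for i in range(len(chain_a) - 1):
            ra_i, ra_j = chain_a.residues[i], chain_a.residues[i + 1]
            if ra_i.res_id not in b_idx or ra_j.res_id not in b_idx:
                continue
            rb_i = chain_b.residues[b_idx[ra_i.res_id]]
            rb_j = chain_b.residues[b_idx[ra_j.res_id]]
            # frame: CA trace of residues i-1..i+2, for the CAs paired in b
            fa, fb = [], []
            for k in range(i - 1, i + 3):
                if not 0 <= k < len(chain_a):
                    continue
                ra_k = chain_a.residues[k]
                if ra_k.res_id not in b_idx:
                    continue
                ca_a = ra_k.pos("CA")
                ca_b = chain_b.residues[b_idx[ra_k.res_id]].pos("CA")
                if ca_a is not None and ca_b is not None:
                    fa.append(ca_a)
                    fb.append(ca_b)
            out.append(
                PeptideComparison(
                    res_id=ra_i.res_id,
                    rotation_angle=peptide_rotation(
                        ra_i, ra_j, rb_i, rb_j,
                        frame_a=np.asarray(fa) if len(fa) >= 3 else None,
                        frame_b=np.asarray(fb) if len(fb) >= 3 else None,
                    ),
                    nu_difference=circular_diff(nu_a.get(ra_j.res_id), nu_b.get(ra_j.res_id)),
                )
            )
    return out


def compare_residues(
    a: ChainModel | list[ChainModel], b: ChainModel | list[ChainModel]
) -> list[ResidueComparison]:
    """Per-residue displacement, dihedral deltas and Ramachandran transitions."""
    pairs, _, _, _ = pair_models(a, b)
    paired_ids = {ra.res_id for ra, _ in pairs}
    rec_a: dict = {}
    rec_b: dict = {}
    for chain in as_chain_list(a):
        for r in compute_dihedrals(chain):
            rec_a[r.res_id] = r
    for chain in as_chain_list(b):
        for r in compute_dihedrals(chain):
            rec_b[r.res_id] = r
    out = []
    for ra, rb in pairs:
        da: DihedralRecord = rec_a.get(ra.res_id)
        db: DihedralRecord = rec_b.get(rb.res_id)
        cmp = ResidueComparison(res_id=ra.res_id, res_name=ra.res_name)
        cmp.max_heavy_displacement = max_heavy_displacement(ra, rb)
        if da is not None and db is not None:
            cmp.d_phi = circular_diff(da.phi, db.phi)
            cmp.d_psi = circular_diff(da.psi, db.psi)
            cmp.d_omega = circular_diff(da.omega, db.omega)
            if da.phi is not None and da.psi is not None:
                cmp.rama_before = rama_region(da.phi, da.psi)
            if db.phi is not None and db.psi is not None:
                cmp.rama_after = rama_region(db.phi, db.psi)
        out.append(cmp)
    assert all(c.res_id in paired_ids for c in out)
    return out


def wrong_minimum_transitions(comparisons: list[ResidueComparison]) -> list[ResidueComparison]:
    """Residues whose (phi, psi) moved to a different Ramachandran basin
    with a >45 deg change in phi or psi — refined into the wrong minimum."""
    return [c for c in comparisons if c.wrong_minimum]


@dataclass
class ComparisonReport:
    """Summary census of a two-model comparison."""

    n_paired: int
    n_excluded_realigned: int
    n_unpaired_a: int
    n_unpaired_b: int
    n_changed: int
    fraction_changed: float
    n_misoriented: int
    n_misoriented_by_nu: int
    n_cis_nonpro_a: int
    n_cis_nonpro_b: int
    n_wrong_minimum: int
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    conventions: dict = field(default_factory=dict)
    residues: list[ResidueComparison] = field(default_factory=list)
    peptides: list[PeptideComparison] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_paired": self.n_paired,
            "n_excluded_realigned": self.n_excluded_realigned,
            "n_unpaired": {"a": self.n_unpaired_a, "b": self.n_unpaired_b},
            "n_changed": self.n_changed,
            "fraction_changed": self.fraction_changed,
            "n_misoriented": self.n_misoriented,
            "n_misoriented_by_nu": self.n_misoriented_by_nu,
            "n_cis_nonpro": {"a": self.n_cis_nonpro_a, "b": self.n_cis_nonpro_b},
            "n_wrong_minimum": self.n_wrong_minimum,
            "thresholds": self.thresholds,
            "conventions": self.conventions,
        }

    def per_residue_frame(self) -> pd.DataFrame:
        rot = {p.res_id: p for p in self.peptides}
        rows = []
        for c in self.residues:
            p = rot.get(c.res_id)
            rows.append(
                {
                    "chain": c.res_id[0],
                    "seq": c.res_id[1],
                    "icode": c.res_id[2],
                    "resname": c.res_name,
                    "max_heavy_displacement": c.max_heavy_displacement,
                    "d_phi": c.d_phi,
                    "d_psi": c.d_psi,
                    "d_omega": c.d_omega,
                    "changed": c.changed_under(
                        self.thresholds["displacement"], self.thresholds["dihedral"]
                    ),
                    "rama_before": c.rama_before,
                    "rama_after": c.rama_after,
                    "wrong_minimum": c.wrong_minimum,
                    "peptide_rotation": None if p is None else p.rotation_angle,
                    "peptide_nu_difference": None if p is None else p.nu_difference,
                }
            )
        return pd.DataFrame(rows)


def comparison_report(
    a: ChainModel | list[ChainModel],
    b: ChainModel | list[ChainModel],
    thresholds: dict | None = None,
) -> ComparisonReport:
    """Full two-model census: changed residues, misoriented peptides,
    cis-nonprolines in each model, wrong-minimum transitions."""
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    pairs, realigned, unpaired_a, unpaired_b = pair_models(a, b)
    residues = compare_residues(a, b)
    peptides = compare_peptides(a, b)
    n_changed = sum(c.changed_under(th["displacement"], th["dihedral"]) for c in residues)
    n_mis = sum(p.misoriented(th["peptide"]) for p in peptides)
    n_mis_nu = sum(
        p.nu_difference is not None and p.nu_difference > th["peptide"] for p in peptides
    )
    cis_a, _ = count_cis_nonproline(a)
    cis_b, _ = count_cis_nonproline(b)
    return ComparisonReport(
        n_paired=len(pairs),
        n_excluded_realigned=len(realigned),
        n_unpaired_a=len(unpaired_a),
        n_unpaired_b=len(unpaired_b),
        n_changed=n_changed,
        fraction_changed=n_changed / len(residues) if residues else 0.0,
        n_misoriented=n_mis,
        n_misoriented_by_nu=n_mis_nu,
        n_cis_nonpro_a=cis_a,
        n_cis_nonpro_b=cis_b,
        n_wrong_minimum=len(wrong_minimum_transitions(residues)),
        thresholds=th,
        conventions={
            "rama_polygons": RAMA_VERSION,
            "nu": "dih(O(i-1),CA(i-1),CA(i),O(i))",
            "misorientation": "O rotation about the CA-CA axis after local "
                              "least-squares superposition of N(i), CA(i), CA(i+1), C(i+1)",
        },
        residues=residues,
        peptides=peptides,
    )
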
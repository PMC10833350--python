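"""Barbed-wire detection and pruning for low-confidence predicted models.

Low-pLDDT regions of AlphaFold-style predictions come in two very
different flavours: compact, protein-like "near-folded" parts that may
still be useful (e.g. as molecular-replacement search fragments), and
"barbed wire" — long, loopy strands that make essentially no contact with
the rest of the model and concentrate dire local backbone geometry. This
module scores five per-residue criteria (packing, psi, omega, CaBLAM-style
virtual-dihedral outliers, covalent geometry), segments each chain into
confident / near_folded / barbed_wire stretches, and prunes the barbed
wire.

Every numeric threshold lives in :class:`BarbedWireConfig` and is echoed
into reports; the defaults here are this package's own tuning, validated
against the synthetic generator's ground truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import EmptyModelError
from .geometry import ContourTable, compute_dihedrals, contour_lookup
from .io import extract_plddt
from .model import ChainModel, as_chain_list
from .synthetic import IDEALS, PSI_RARE_BAND

#: canonical CO-CO virtual-dihedral values of ideal secondary structure,
#: computed from the package's own chain builder (alpha-helix phi=-63,
#: psi=-43; beta-strand phi=-120, psi=130); used by the contour-free
#: CaBLAM fallback
NU_CANONICAL = {"helix": -34.16, "strand": -138.38}


def _circ_dist(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


@dataclass
class BarbedWireConfig:
    """All tunable thresholds of the barbed-wire classifier."""

    packing_radius: float = 8.0  # A, CB/CA neighbour search
    packing_min_neighbors: int = 3  # fewer -> packing flag
    packing_min_seq_sep: int = 4  # sequence separation for a countable contact
    geometry_sigma: float = 4.0  # z cutoff on bond lengths/angles
    psi_band: tuple[float, float] = PSI_RARE_BAND  # rarely populated psi range, deg
    cablam_outlier: float = 0.01  # contour score below -> cablam flag
    nu_fallback_deviation: float = 90.0  # deg, contour-free fallback
    window: int = 7  # sliding window length, residues
    window_flagged_min: int = 4  # multi-flag residues per window -> barbed window
    flags_per_residue_min: int = 2  # criterion flags that make a residue "multi-flagged"
    packing_density_min: float = 0.5  # min packing-flag fraction in a barbed window
    plddt_confident: float = 70.0  # at/above -> confident, never pruned
    plddt_near_folded: float = 65.0  # reporting band
    plddt_disorder: float = 50.0  # reporting band (IDR-like)
    min_segment_length: int = 3  # shorter segments merge into their neighbour
    plddt_is_confidence: bool = True  # False for plain B-factor models

    def to_dict(self) -> dict:
        d = asdict(self)
        d["psi_band"] = list(d["psi_band"])
        return d


@dataclass
class CriterionFlags:
    """The five barbed-wire criterion flags for one residue."""

    res_id: tuple[str, int, str]
    res_name: str
    packing_flag: bool = False
    psi_flag: bool = False
    omega_flag: bool = False
    cablam_flag: bool = False
    geometry_flag: bool = False
    packing_count: int = 0
    worst_geometry_z: float = 0.0
    plddt: float | None = None

    @property
    def n_flags(self) -> int:
        return sum(
            (self.packing_flag, self.psi_flag, self.omega_flag,
             self.cablam_flag, self.geometry_flag)
        )


@dataclass
class SegmentLabel:
    """A contiguous labelled residue range (author numbering, inclusive)."""

    chain_id: str
    start: int
    end: int
    label: str  # {barbed_wire, near_folded, confident}
    mean_plddt: float | None
    flag_density: float  # fraction of residues carrying >= 2 criterion flags
    n_res: int


# ---------------------------------------------------------------------------
# criteria
# ---------------------------------------------------------------------------

def _packing_atoms(chains: list[ChainModel]):
    """One reference atom per residue: CB, falling back to CA (GLY)."""
    pts, keys = [], []
    for ci, chain in enumerate(chains):
        for ri, res in enumerate(chain.residues):
            a = res.atom("CB") or res.atom("CA")
            if a is not None:
                pts.append(a.position)
                keys.append((ci, ri))
    return np.asarray(pts), keys


def packing_counts(
    model: ChainModel | list[ChainModel],
    radius: float = 8.0,
    min_seq_sep: int = 4,
) -> dict[tuple[str, int, str], int]:
    """Neighbour count per residue: CB/CA atoms within `radius` from
    residues at least `min_seq_sep` apart in sequence (any other chain
    always counts)."""
    chains = as_chain_list(model)
    pts, keys = _packing_atoms(chains)
    out: dict[tuple[str, int, str], int] = {}
    if len(pts) == 0:
        return out
    tree = cKDTree(pts)
    neighbor_lists = tree.query_ball_point(pts, radius)
    for k, (ci, ri) in enumerate(keys):
        count = 0
        for j in neighbor_lists[k]:
            cj, rj = keys[j]
            if cj != ci or abs(rj - ri) >= min_seq_sep:
                count += 1
        out[chains[ci].residues[ri].res_id] = count
    return out


def packing_score(
    model: ChainModel | list[ChainModel],
    i: int,
    radius: float = 8.0,
    min_neighbors: int = 3,
    chain_index: int = 0,
) -> tuple[int, bool]:
    """Neighbour count and packing flag for residue index i of one chain."""
    chains = as_chain_list(model)
    res = chains[chain_index].residues[i]
    counts = packing_counts(chains, radius=radius)
    n = counts.get(res.res_id, 0)
    return n, n < min_neighbors


def geometry_flag(
    model: ChainModel, i: int, sigma_cutoff: float = 4.0
) -> tuple[bool, float]:
    """Flag residue i when any backbone bond length or angle deviates by
    >= sigma_cutoff standard deviations from the packaged ideal values.
    Returns (flag, worst absolute z)."""
    from .geometry import PEPTIDE_BOND_MAX

    res = model.residues
    r = res[i]
    bonds = IDEALS["bonds"]
    angles = IDEALS["angles"]
    zs: list[float] = []

    def _bond(p, q, key):
        if p is not None and q is not None:
            d = float(np.linalg.norm(p - q))
            zs.append((d - bonds[key]["mean"]) / bonds[key]["sigma"])

    def _angle(p, q, s, key):
        if p is None or q is None or s is None:
            return
        v1, v2 = p - q, s - q
        cosa = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        ang = float(np.degrees(np.arccos(np.clip(cosa, -1.0, 1.0))))
        zs.append((ang - angles[key]["mean"]) / angles[key]["sigma"])

    N, CA, C, O = r.pos("N"), r.pos("CA"), r.pos("C"), r.pos("O")
    _bond(N, CA, "N-CA")
    _bond(CA, C, "CA-C")
    _bond(C, O, "C-O")
    _angle(N, CA, C, "N-CA-C")
    _angle(CA, C, O, "CA-C-O")
    if i + 1 < len(res):
        nn = res[i + 1].pos("N")
        if C is not None and nn is not None and float(np.linalg.norm(nn - C)) < PEPTIDE_BOND_MAX:
            _bond(C, nn, "C-N")
            _angle(CA, C, nn, "CA-C-N")
    if i > 0:
        pc = res[i - 1].pos("C")
        if pc is not None and N is not None and float(np.linalg.norm(N - pc)) < PEPTIDE_BOND_MAX:
            _angle(pc, N, CA, "C-N-CA")
    if not zs:
        import warnings

        warnings.warn(f"{r.label()}: no backbone geometry measurable")
        return False, 0.0
    worst = float(max(abs(z) for z in zs))
    return worst >= sigma_cutoff, worst


def compute_flags(
    model: ChainModel,
    contour: ContourTable | None = None,
    config: BarbedWireConfig | None = None,
    context: list[ChainModel] | None = None,
) -> list[CriterionFlags]:
    """All five criterion flags for every residue of one chain.

    `context` supplies additional chains for the packing neighbour search
    (defaults to the chain itself).
    """
    cfg = config or BarbedWireConfig()
    chains = context if context is not None else [model]
    counts = packing_counts(chains, radius=cfg.packing_radius,
                            min_seq_sep=cfg.packing_min_seq_sep)
    records = compute_dihedrals(model)
    plddt = extract_plddt(model) if cfg.plddt_is_confidence else [None] * len(model)
    flags = []
    for i, (res, rec) in enumerate(zip(model.residues, records)):
        f = CriterionFlags(res_id=res.res_id, res_name=res.res_name, plddt=plddt[i])
        f.packing_count = counts.get(res.res_id, 0)
        f.packing_flag = f.packing_count < cfg.packing_min_neighbors
        if rec.psi is not None:
            f.psi_flag = cfg.psi_band[0] <= rec.psi <= cfg.psi_band[1]
        if rec.omega is not None:
            cls = rec.peptide_class
            f.omega_flag = cls == "twisted" or (cls == "cis" and rec.nonproline)
        if contour is not None:
            score, _level = contour_lookup(rec, contour)
            f.cablam_flag = score is not None and score < cfg.cablam_outlier
        elif rec.nu is not None:
            f.cablam_flag = all(
                _circ_dist(rec.nu, v) > cfg.nu_fallback_deviation
                for v in NU_CANONICAL.values()
            )
        f.geometry_flag, f.worst_geometry_z = geometry_flag(
            model, i, sigma_cutoff=cfg.geometry_sigma
        )
        flags.append(f)
    return flags


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _smooth(labels: list[str], min_len: int) -> list[str]:
    """Merge runs shorter than min_len into the neighbouring label."""
    if not labels:
        return labels
    out = list(labels)
    changed = True
    while changed:
        changed = False
        runs = []
        s = 0
        for i in range(1, len(out) + 1):
            if i == len(out) or out[i] != out[s]:
                runs.append((s, i))
                s = i
        for s, e in runs:
            if e - s < min_len and len(runs) > 1:
                neighbour = out[s - 1] if s > 0 else out[e]
                if neighbour != out[s]:
                    for k in range(s, e):
                        out[k] = neighbour
                    changed = True
                    break
    return out


def segment_chain(
    flags: list[CriterionFlags], config: BarbedWireConfig | None = None
) -> list[SegmentLabel]:
    """Tile one chain into confident / near_folded / barbed_wire segments.

    Residues at or above the confident pLDDT cutoff are confident. The
    remaining runs are scored in sliding windows: a window is barbed wire
    when at least `window_flagged_min` of its residues carry at least
    `flags_per_residue_min` criterion flags AND the window's packing-flag
    density is at least `packing_density_min`. Residues covered by any
    barbed window are barbed wire; other low-confidence residues are
    near-folded. Runs shorter than `min_segment_length` merge into their
    neighbour. Fully deterministic.
    """
    cfg = config or BarbedWireConfig()
    n = len(flags)
    if n == 0:
        return []
    confident = [
        cfg.plddt_is_confidence and f.plddt is not None and f.plddt >= cfg.plddt_confident
        for f in flags
    ]
    multi = [f.n_flags >= cfg.flags_per_residue_min for f in flags]
    packed_bad = [f.packing_flag for f in flags]
    barbed = [False] * n

    i = 0
    while i < n:
        if confident[i]:
            i += 1
            continue
        j = i
        while j < n and not confident[j]:
            j += 1
        run = range(i, j)
        L = j - i
        w = cfg.window
        if L < w:
            frac_needed = cfg.window_flagged_min / cfg.window
            if (
                sum(multi[k] for k in run) >= frac_needed * L
                and np.mean([packed_bad[k] for k in run]) >= cfg.packing_density_min
            ):
                for k in run:
                    barbed[k] = True
        else:
            for s in range(i, j - w + 1):
                win = range(s, s + w)
                if (
                    sum(multi[k] for k in win) >= cfg.window_flagged_min
                    and np.mean([packed_bad[k] for k in win]) >= cfg.packing_density_min
                ):
                    for k in win:
                        barbed[k] = True
        i = j

    labels = [
        "confident" if confident[k] else ("barbed_wire" if barbed[k] else "near_folded")
        for k in range(n)
    ]
    labels = _smooth(labels, cfg.min_segment_length)

    segments = []
    s = 0
    chain_id = flags[0].res_id[0]
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[s]:
            seg_flags = flags[s:i]
            pl = [f.plddt for f in seg_flags if f.plddt is not None]
            segments.append(
                SegmentLabel(
                    chain_id=chain_id,
                    start=seg_flags[0].res_id[1],
                    end=seg_flags[-1].res_id[1],
                    label=labels[s],
                    mean_plddt=float(np.mean(pl)) if pl else None,
                    flag_density=float(np.mean([f.n_flags >= cfg.flags_per_residue_min
                                                for f in seg_flags])),
                    n_res=i - s,
                )
            )
            s = i
    return segments


def residue_labels(
    flags: list[CriterionFlags], segments: list[SegmentLabel]
) -> list[str]:
    """Per-residue label implied by the segmentation."""
    out = []
    for f in flags:
        seq = f.res_id[1]
        lab = "near_folded"
        for seg in segments:
            if seg.start <= seq <= seg.end:
                lab = seg.label
                break
        out.append(lab)
    return out


def prune_model(
    model: ChainModel, segments: list[SegmentLabel]
) -> tuple[ChainModel, list[str]]:
    """Remove barbed-wire residues; keep everything else.

    Returns the pruned chain and a removal log (one line per removed
    range). Raises EmptyModelError if nothing would remain.
    """
    barbed = [s for s in segments if s.label == "barbed_wire"]
    removed_log = [
        f"removed {model.chain_id}/{s.start}-{s.end} "
        f"({s.n_res} res, barbed_wire, mean pLDDT "
        f"{'n/a' if s.mean_plddt is None else f'{s.mean_plddt:.1f}'}, "
        f"multi-flag density {s.flag_density:.2f})"
        for s in barbed
    ]

    def _keep(res) -> bool:
        return not any(s.start <= res.seq_num <= s.end for s in barbed)

    kept = [r for r in model.residues if _keep(r)]
    if not kept:
        raise EmptyModelError(
            "pruning removed every residue: the whole chain is barbed wire"
        )
    return ChainModel(residues=kept, source_id=model.source_id + "-pruned"), removed_log


def flags_dataframe(flags: list[CriterionFlags]) -> pd.DataFrame:
    rows = [
        {
            "chain": f.res_id[0],
            "seq": f.res_id[1],
            "icode": f.res_id[2],
            "resname": f.res_name,
            "plddt": f.plddt,
            "packing_count": f.packing_count,
            "packing_flag": f.packing_flag,
            "psi_flag": f.psi_flag,
            "omega_flag": f.omega_flag,
            "cablam_flag": f.cablam_flag,
            "geometry_flag": f.geometry_flag,
            "worst_geometry_z": f.worst_geometry_z,
            "n_flags": f.n_flags,
        }
        for f in flags
    ]
    return pd.DataFrame(rows)
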
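"""Synthetic backbone fixtures: ideal-geometry chains, flip/cis injections,
and AlphaFold-like confidence-annotated test structures.

Chains are built by sequential internal-coordinate construction (NeRF):
each atom is placed from a bond length, bond angle and dihedral relative to
the three previously placed atoms, using the packaged ideal covalent
geometry. Only backbone atoms N, CA, C, O are built (plus CB on request,
for packing analysis); the carbonyl O is placed in the peptide plane,
trans to the next residue's N.

All randomness goes through :func:`numpy.random.default_rng` seeded from
the spec, so fixtures are bit-reproducible across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import BuildSpecError, InjectionError
from .geometry import dihedral, wrap_angle
from .model import AtomRecord, ChainModel, Residue


def _load_ideals() -> dict:
    with resources.files("lowres_audit.data").joinpath("backbone_ideals.json").open() as fh:
        return json.load(fh)


IDEALS = _load_ideals()
_B = {k: v["mean"] for k, v in IDEALS["bonds"].items()}
_A = {k: v["mean"] for k, v in IDEALS["angles"].items()}

#: psi band essentially unpopulated in folded proteins (between the helical
#: and extended basins); the barbed-wire generator draws from inside it and
#: the psi criterion flags it.
PSI_RARE_BAND = (60.0, 110.0)


def place_atom(a, b, c, bond: float, angle: float, dih: float) -> np.ndarray:
    """Place atom d with |c-d| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = dih (degrees). Standard NeRF construction."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(dih)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.column_stack([bc, np.cross(n, bc), n])
    d_local = np.array(
        [-bond * np.cos(ang), bond * np.sin(ang) * np.cos(tor), bond * np.sin(ang) * np.sin(tor)]
    )
    return c + m @ d_local


@dataclass
class BuildSpec:
    """Per-residue dihedral targets for the chain builder.

    omega[i] is the peptide bond preceding residue i (omega[0] unused);
    phi[0] and the final psi only orient terminal atoms. cn_lengths allows
    per-peptide C-N bond stretching (geometry-violation fixtures).
    """

    res_names: list[str]
    phi: list[float]
    psi: list[float]
    omega: list[float]
    cn_lengths: list[float] | None = None
    bfactors: list[float] | None = None
    with_cb: bool = False
    chain_id: str = "A"
    start_seq: int = 1
    source_id: str = "synthetic"

    def __post_init__(self) -> None:
        n = len(self.res_names)
        if n < 2:
            raise BuildSpecError("need at least 2 residues")
        for name, vals in (("phi", self.phi), ("psi", self.psi), ("omega", self.omega)):
            if len(vals) != n:
                raise BuildSpecError(f"{name} must have {n} entries, got {len(vals)}")
            for v in vals:
                if not -180.0 < v <= 180.0 or not np.isfinite(v):
                    raise BuildSpecError(f"{name} target {v} outside (-180, 180]")
        if self.cn_lengths is not None and len(self.cn_lengths) != n:
            raise BuildSpecError("cn_lengths must match residue count")
        if self.bfactors is not None and len(self.bfactors) != n:
            raise BuildSpecError("bfactors must match residue count")


def helix_spec(n: int, res_names: list[str] | None = None, **kw) -> BuildSpec:
    """Ideal right-handed alpha-helix targets (phi=-63, psi=-43, omega=180)."""
    names = res_names or ["ALA"] * n
    return BuildSpec(
        res_names=names, phi=[-63.0] * n, psi=[-43.0] * n, omega=[180.0] * n, **kw
    )


def build_polypeptide(spec: BuildSpec) -> ChainModel:
    """Construct a backbone chain realizing the spec's dihedral targets."""
    n = len(spec.res_names)
    cn = spec.cn_lengths or [_B["C-N"]] * n
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))

    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B["N-CA"], 0.0, 0.0)
    th = np.radians(180.0 - _A["N-CA-C"])
    C[0] = CA[0] + _B["CA-C"] * np.array([np.cos(th), np.sin(th), 0.0])
    for i in range(1, n):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], cn[i], _A["CA-C-N"], spec.psi[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], _B["N-CA"], _A["C-N-CA"], spec.omega[i])
        C[i] = place_atom(C[i - 1], N[i], CA[i], _B["CA-C"], _A["N-CA-C"], spec.phi[i])

    residues = []
    for i in range(n):
        b = spec.bfactors[i] if spec.bfactors is not None else 0.0
        atoms = [
            AtomRecord("N", "N", N[i], bfactor=b),
            AtomRecord("CA", "C", CA[i], bfactor=b),
            AtomRecord("C", "C", C[i], bfactor=b),
        ]
        # O in the peptide plane, trans to N(i+1): psi + 180 about the same axis
        o_dih = wrap_angle(spec.psi[i] + 180.0)
        atoms.append(
            AtomRecord("O", "O", place_atom(N[i], CA[i], C[i], _B["C-O"], _A["CA-C-O"], o_dih),
                       bfactor=b)
        )
        if spec.with_cb and spec.res_names[i] != "GLY":
            atoms.append(
                AtomRecord("CB", "C",
                           place_atom(C[i], N[i], CA[i], _B["CA-CB"], _A["N-CA-CB"], 122.6),
                           bfactor=b)
            )
        residues.append(
            Residue(
                chain_id=spec.chain_id,
                seq_num=spec.start_seq + i,
                res_name=spec.res_names[i],
                atoms=atoms,
            )
        )
    return ChainModel(residues=residues, source_id=spec.source_id)


@dataclass
class InjectionSpec:
    """A local perturbation: peptide flip (rigid rotation of one peptide
    unit about its CA-CA axis) or conversion of one peptide bond to cis."""

    kind: str  # {peptide_flip, cis_peptide}
    position: int  # 0-based residue index i (peptide between i and i+1 for flips)
    theta: float = 180.0  # degrees, flips only

    def __post_init__(self) -> None:
        if self.kind not in ("peptide_flip", "cis_peptide"):
            raise BuildSpecError(f"unknown injection kind {self.kind!r}")
        if self.kind == "peptide_flip" and not 0.0 < self.theta <= 180.0:
            raise BuildSpecError(f"flip theta {self.theta} outside (0, 180]")


def inject_peptide_flip(model: ChainModel, i: int, theta: float) -> ChainModel:
    """Rotate the peptide unit between residues i and i+1 by theta degrees.

    Atoms C(i), O(i) and N(i+1) rotate rigidly about the CA(i)->CA(i+1)
    axis; every other atom is untouched, so the recovered peptide-rotation
    angle between original and perturbed model is exactly theta.
    """
    out = model.copy()
    if not 0 <= i < len(out) - 1:
        raise InjectionError(f"flip position {i} not interior to a {len(out)}-residue chain")
    ri, rj = out.residues[i], out.residues[i + 1]
    ca_i, ca_j = ri.pos("CA"), rj.pos("CA")
    moving = [ri.atom("C"), ri.atom("O"), rj.atom("N")]
    if ca_i is None or ca_j is None or any(a is None for a in moving):
        raise InjectionError(f"peptide {ri.label()} lacks backbone atoms for a flip")
    axis = ca_j - ca_i
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.radians(theta) * axis)
    for atom in moving:
        atom.position = ca_i + rot.apply(atom.position - ca_i)
    return out


def inject_cis_peptide(model: ChainModel, i: int, target_omega: float = 0.0) -> ChainModel:
    """Set omega(i) (the peptide preceding residue i) to target_omega by
    rotating residues i..end about the C(i-1)->N(i) bond. Internal
    dihedrals elsewhere are unchanged."""
    out = model.copy()
    if not 1 <= i < len(out):
        raise InjectionError(f"cis position {i} needs a preceding residue")
    prev, curr = out.residues[i - 1], out.residues[i]
    for name, res in (("CA", prev), ("C", prev), ("N", curr), ("CA", curr)):
        if res.pos(name) is None:
            raise InjectionError(f"missing backbone atoms around {curr.label()}")
    c_prev = prev.pos("C").copy()
    axis = curr.pos("N") - c_prev
    axis = axis / np.linalg.norm(axis)

    def _measure() -> float:
        return dihedral(prev.pos("CA"), prev.pos("C"), curr.pos("N"), curr.pos("CA"))

    def _apply(delta: float) -> None:
        rot = Rotation.from_rotvec(np.radians(delta) * axis)
        for res in out.residues[i:]:
            for atom in res.atoms:
                atom.position = c_prev + rot.apply(atom.position - c_prev)

    # probe the rotation sense, then rotate the downstream chain in one go
    current = _measure()
    probe = 1.0
    _apply(probe)
    sense = 1.0 if abs(wrap_angle(_measure() - current - probe)) < 1e-6 else -1.0
    _apply(-probe)
    _apply(sense * wrap_angle(target_omega - current))
    return out


def apply_injections(model: ChainModel, specs: list[InjectionSpec]) -> ChainModel:
    for s in specs:
        if s.kind == "peptide_flip":
            model = inject_peptide_flip(model, s.position, s.theta)
        else:
            model = inject_cis_peptide(model, s.position, 0.0)
    return model


# ---------------------------------------------------------------------------
# AlphaFold-like fixtures with pLDDT in the B-factor column
# ---------------------------------------------------------------------------

#: frozen turn dihedrals used to fold helix-turn-helix fixtures back on
#: themselves into compact bundles
_TURN = [(-10.8, 31.9), (45.5, 69.4), (140.9, -93.1), (-124.9, -39.4)]


@dataclass
class AFFixture:
    """A generated model plus its residue-level ground-truth labels."""

    model: ChainModel
    truth: list[str] = field(default_factory=list)  # per residue: confident/near_folded/barbed_wire


def _set_bfactors(residues: list[Residue], values: np.ndarray) -> None:
    for res, v in zip(residues, values):
        for atom in res.atoms:
            atom.bfactor = float(v)


def _barbed_targets(n: int, rng: np.random.Generator):
    phi = rng.uniform(-160.0, -60.0, n)
    psi = rng.uniform(PSI_RARE_BAND[0] + 5.0, PSI_RARE_BAND[1] - 5.0, n)
    omega = np.where(
        rng.random(n) < 0.2,
        rng.choice([-1.0, 1.0], n) * rng.uniform(50.0, 130.0, n),
        rng.uniform(170.0, 180.0, n) * rng.choice([-1.0, 1.0], n),
    )
    cn = np.where(rng.random(n) < 0.1, 1.50, _B["C-N"])
    return phi, psi, omega, cn


def _bundle_targets(n: int) -> tuple[list[float], list[float]]:
    """Three helices joined by frozen turns, folding into a compact bundle."""
    phi: list[float] = []
    psi: list[float] = []
    seg = max(6, (n - 2 * len(_TURN)) // 3)
    layout: list[tuple[float, float]] = []
    layout += [(-63.0, -43.0)] * seg
    layout += _TURN
    layout += [(-63.0, -43.0)] * seg
    layout += _TURN
    while len(layout) < n:
        layout.append((-63.0, -43.0))
    layout = layout[:n]
    for p, s in layout:
        phi.append(p)
        psi.append(s)
    return phi, psi


def make_af_fixture(kind: str, n_res: int, seed: int, chain_id: str = "A") -> AFFixture:
    """Generate a confidence-annotated fixture.

    kind:
      * ``barbed_wire`` — extended, unpacked chain with psi in the rare
        band, 20% twisted peptides, 10% stretched C-N bonds; pLDDT 30-60.
      * ``near_folded`` — compact helix bundle with clean geometry;
        pLDDT 50-68 (low confidence but protein-like).
      * ``chimera`` — confident helix bundle (pLDDT 80-95) with a
        barbed-wire C-terminal tail (pLDDT 40-50).
    """
    if n_res < 10:
        raise BuildSpecError(f"n_res {n_res} too small (need >= 10)")
    rng = np.random.default_rng(seed)
    names = ["ALA"] * n_res

    if kind == "barbed_wire":
        phi, psi, omega, cn = _barbed_targets(n_res, rng)
        spec = BuildSpec(names, [wrap_angle(x) for x in phi], [wrap_angle(x) for x in psi],
                         [wrap_angle(x) for x in omega], cn_lengths=list(cn),
                         with_cb=True, chain_id=chain_id,
                         source_id=f"synthetic-barbed-seed{seed}")
        model = build_polypeptide(spec)
        _set_bfactors(model.residues, rng.uniform(30.0, 60.0, n_res))
        return AFFixture(model, ["barbed_wire"] * n_res)

    if kind == "near_folded":
        phi, psi = _bundle_targets(n_res)
        spec = BuildSpec(names, phi, psi, [180.0] * n_res, with_cb=True,
                         chain_id=chain_id, source_id=f"synthetic-nearfolded-seed{seed}")
        model = build_polypeptide(spec)
        _set_bfactors(model.residues, rng.uniform(50.0, 68.0, n_res))
        return AFFixture(model, ["near_folded"] * n_res)

    if kind == "chimera":
        tail = min(40, max(10, n_res // 3))
        core = n_res - tail
        if core < 20:
            raise BuildSpecError(f"chimera needs >= {20 + tail} residues")
        phi_c, psi_c = _bundle_targets(core)
        phi_t, psi_t, omega_t, cn_t = _barbed_targets(tail, rng)
        phi = phi_c + [wrap_angle(x) for x in phi_t]
        psi = psi_c + [wrap_angle(x) for x in psi_t]
        omega = [180.0] * core + [wrap_angle(x) for x in omega_t]
        cn = [_B["C-N"]] * core + list(cn_t)
        spec = BuildSpec(names, phi, psi, omega, cn_lengths=cn, with_cb=True,
                         chain_id=chain_id, source_id=f"synthetic-chimera-seed{seed}")
        model = build_polypeptide(spec)
        b = np.concatenate([rng.uniform(80.0, 95.0, core), rng.uniform(40.0, 50.0, tail)])
        _set_bfactors(model.residues, b)
        return AFFixture(model, ["confident"] * core + ["barbed_wire"] * tail)

    raise BuildSpecError(f"unknown fixture kind {kind!r}")
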
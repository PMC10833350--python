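"""Backbone dihedrals, peptide-bond classification and virtual dihedrals.

Conventions (each of these is load-bearing for the census counts, so they
are stated here once and used everywhere):

* Dihedrals follow the IUPAC sign convention and live in (-180, 180].
* omega(i) describes the peptide bond PRECEDING residue i, i.e. the bond
  between residues i-1 and i: omega(i) = dih(CA(i-1), C(i-1), N(i), CA(i)).
  A "cis-nonproline" is therefore a cis peptide whose residue i is not PRO.
* Residues i-1, i count as bonded only when the C(i-1)-N(i) distance is
  below 2.5 A; across a gap all spanning dihedrals are None.
* Cis: |omega| <= 30; trans: |omega| >= 150; twisted in between.
* The Calpha-trace virtual dihedrals are
  mu_in(i)  = dih(CA(i-2), CA(i-1), CA(i), CA(i+1)),
  mu_out(i) = dih(CA(i-1), CA(i), CA(i+1), CA(i+2)),
  and the CO-CO virtual dihedral is taken here as
  nu(i) = dih(O(i-1), CA(i-1), CA(i), O(i)); contour tables carry a
  convention tag so a differently defined table is never silently mixed in.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .errors import ConfigurationError, UndefinedDihedralError
from .model import ChainModel, as_chain_list

logger = logging.getLogger(__name__)

PEPTIDE_BOND_MAX = 2.5  # A, C(i-1)-N(i) continuity cutoff
CIS_CUTOFF = 30.0  # deg, |omega| <= cis
TRANS_CUTOFF = 150.0  # deg, |omega| >= trans

_COLLINEAR_TOL = 1e-9


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, IUPAC convention.

    Viewed along p2->p3, a clockwise rotation carrying the p1 projection
    onto the p4 projection is positive. Result in (-180, 180].

    Raises
    ------
    UndefinedDihedralError
        If consecutive points coincide or p1,p2,p3 / p2,p3,p4 are collinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b2) < _COLLINEAR_TOL:
        raise UndefinedDihedralError("central points p2, p3 coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise UndefinedDihedralError("collinear points leave the dihedral undefined")
    b2n = b2 / np.linalg.norm(b2)
    angle = np.degrees(np.arctan2(np.dot(np.cross(n1, n2), b2n), np.dot(n1, n2)))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def wrap_angle(a: float) -> float:
    """Map any angle in degrees onto (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclass
class PeptideClass:
    """Cis/twisted/trans label for one peptide bond."""

    label: str  # {cis, twisted, trans}
    nonproline: bool  # residue following the bond is not PRO


@dataclass
class DihedralRecord:
    """Backbone and virtual dihedrals of one residue (degrees, None at gaps)."""

    res_id: tuple[str, int, str]
    res_name: str
    phi: float | None = None
    psi: float | None = None
    omega: float | None = None  # peptide preceding this residue
    mu_in: float | None = None
    mu_out: float | None = None
    nu: float | None = None

    @property
    def peptide_class(self) -> str | None:
        return None if self.omega is None else classify_peptide(self.omega).label

    @property
    def nonproline(self) -> bool:
        return self.res_name != "PRO"

    @property
    def is_cis_nonproline(self) -> bool:
        return self.peptide_class == "cis" and self.nonproline


def classify_peptide(omega: float, following_res_name: str = "ALA") -> PeptideClass:
    """Classify a peptide bond from its omega dihedral.

    |omega| <= 30 -> cis; |omega| >= 150 -> trans; otherwise twisted.
    """
    if omega is None:
        raise ValueError("omega is None: peptide cannot be classified")
    a = abs(wrap_angle(omega))
    if a <= CIS_CUTOFF:
        label = "cis"
    elif a >= TRANS_CUTOFF:
        label = "trans"
    else:
        label = "twisted"
    return PeptideClass(label=label, nonproline=following_res_name.upper() != "PRO")


def _bonded(prev, curr) -> bool:
    c = prev.pos("C")
    n = curr.pos("N")
    return c is not None and n is not None and float(np.linalg.norm(n - c)) < PEPTIDE_BOND_MAX


def compute_dihedrals(model: ChainModel) -> list[DihedralRecord]:
    """phi/psi/omega plus virtual dihedrals for every residue of one chain.

    An angle is None exactly when a defining atom is missing or a chain
    break (C-N >= 2.5 A) interrupts the defining atoms.
    """
    res = model.residues
    n = len(res)
    bonded = [False] + [_bonded(res[i - 1], res[i]) for i in range(1, n)]

    def _try(ps) -> float | None:
        if any(p is None for p in ps):
            return None
        try:
            return dihedral(*ps)
        except UndefinedDihedralError:
            return None

    records = []
    for i, r in enumerate(res):
        rec = DihedralRecord(res_id=r.res_id, res_name=r.res_name)
        if i > 0 and bonded[i]:
            p = res[i - 1]
            rec.phi = _try([p.pos("C"), r.pos("N"), r.pos("CA"), r.pos("C")])
            rec.omega = _try([p.pos("CA"), p.pos("C"), r.pos("N"), r.pos("CA")])
            rec.nu = _try([p.pos("O"), p.pos("CA"), r.pos("CA"), r.pos("O")])
        elif i > 0 and not bonded[i]:
            logger.debug("chain break before %s", r.label())
        if i + 1 < n and bonded[i + 1]:
            nx = res[i + 1]
            rec.psi = _try([r.pos("N"), r.pos("CA"), r.pos("C"), nx.pos("N")])
        # mu_in/mu_out need the full five-CA window i-2..i+2, unbroken
        if 2 <= i < n - 2 and all(bonded[j] for j in range(i - 1, i + 3)):
            rec.mu_in = _try(
                [res[i - 2].pos("CA"), res[i - 1].pos("CA"), r.pos("CA"), res[i + 1].pos("CA")]
            )
            rec.mu_out = _try(
                [res[i - 1].pos("CA"), r.pos("CA"), res[i + 1].pos("CA"), res[i + 2].pos("CA")]
            )
        records.append(rec)
    return records


def virtual_dihedrals(model: ChainModel) -> list[tuple[float | None, float | None, float | None]]:
    """(mu_in, mu_out, nu) per residue; None where defining atoms are missing."""
    return [(r.mu_in, r.mu_out, r.nu) for r in compute_dihedrals(model)]


def count_cis_nonproline(
    models: ChainModel | list[ChainModel],
) -> tuple[int, pd.DataFrame]:
    """Census of cis peptide bonds preceding non-proline residues.

    Counts across all chains given (e.g. a whole PDB entry). Returns the
    count and a per-peptide table of every cis or twisted bond for
    diagnosis.
    """
    rows = []
    count = 0
    for chain in as_chain_list(models):
        for rec in compute_dihedrals(chain):
            if rec.omega is None:
                continue
            cls = rec.peptide_class
            if cls == "trans":
                continue
            is_cis_nonpro = cls == "cis" and rec.nonproline
            count += int(is_cis_nonpro)
            rows.append(
                {
                    "chain": rec.res_id[0],
                    "seq": rec.res_id[1],
                    "icode": rec.res_id[2],
                    "resname": rec.res_name,
                    "omega": rec.omega,
                    "class": cls,
                    "nonproline": rec.nonproline,
                    "cis_nonproline": is_cis_nonpro,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "chain", "seq", "icode", "resname", "omega", "class",
            "nonproline", "cis_nonproline",
        ],
    ).astype({"nonproline": bool, "cis_nonproline": bool})
    return count, table


def dihedrals_dataframe(models: ChainModel | list[ChainModel]) -> pd.DataFrame:
    """Per-residue dihedral table (the CSV the audit command writes)."""
    rows = []
    for chain in as_chain_list(models):
        for rec in compute_dihedrals(chain):
            rows.append(
                {
                    "chain": rec.res_id[0],
                    "seq": rec.res_id[1],
                    "icode": rec.res_id[2],
                    "resname": rec.res_name,
                    "phi": rec.phi,
                    "psi": rec.psi,
                    "omega": rec.omega,
                    "mu_in": rec.mu_in,
                    "mu_out": rec.mu_out,
                    "nu": rec.nu,
                    "peptide_class": rec.peptide_class,
                    "nonproline": rec.nonproline,
                }
            )
    return pd.DataFrame(rows)


class ContourTable:
    """Binned empirical probability surface over dihedral tuples.

    Loaded from a self-describing text file (header lines naming the
    dimensions, bin edges in degrees and a convention tag, then row-major
    bin probabilities). On load the bin masses are converted to coverage
    percentiles: a bin's score is the total probability mass of bins no
    more populated than it, so a uniform table scores 1.0 everywhere and a
    sharply peaked table scores ~0 off-peak. Lookups interpolate
    multilinearly between bin centres.
    """

    def __init__(
        self,
        dimensions: list[str],
        edges: dict[str, np.ndarray],
        probabilities: np.ndarray,
        convention: str = "artifact-nu-v1",
    ):
        self.dimensions = list(dimensions)
        self.edges = {k: np.asarray(v, dtype=float) for k, v in edges.items()}
        probabilities = np.asarray(probabilities, dtype=float)
        if probabilities.size == 0:
            raise ConfigurationError("contour table has no probability values")
        if probabilities.min() < 0:
            raise ConfigurationError("contour table probabilities must be non-negative")
        shape = tuple(len(self.edges[d]) - 1 for d in self.dimensions)
        try:
            probabilities = probabilities.reshape(shape)
        except ValueError as exc:
            raise ConfigurationError(
                f"expected {np.prod(shape)} values for bins {shape}, got {probabilities.size}"
            ) from exc
        total = probabilities.sum()
        if total <= 0:
            raise ConfigurationError("contour table probabilities sum to zero")
        self.probabilities = probabilities / total
        self.convention = convention
        # coverage percentile per bin; bins of equal mass share one score so
        # a uniform table scores exactly 1.0 everywhere
        flat = self.probabilities.ravel()
        uniq, inv = np.unique(np.round(flat, 15), return_inverse=True)
        mass_per_level = np.bincount(inv, weights=flat, minlength=len(uniq))
        tie_pct = np.cumsum(mass_per_level)
        pct = tie_pct[inv]
        self.percentiles = pct.reshape(self.probabilities.shape)
        centers = [
            0.5 * (self.edges[d][:-1] + self.edges[d][1:]) for d in self.dimensions
        ]
        self._centers = centers
        self._interp = RegularGridInterpolator(
            centers, self.percentiles, bounds_error=False, fill_value=None
        )

    # ---- file I/O -------------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "ContourTable":
        path = Path(path)
        dims: list[str] = []
        edges: dict[str, np.ndarray] = {}
        convention = "artifact-nu-v1"
        values: list[float] = []
        in_values = False
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if in_values:
                values.extend(float(x) for x in line.split())
                continue
            if line.startswith("dimensions:"):
                dims = line.split(":", 1)[1].split()
            elif line.startswith("convention:"):
                convention = line.split(":", 1)[1].strip()
            elif line.startswith("edges"):
                head, rest = line.split(":", 1)
                name = head.split()[1]
                edges[name] = np.array([float(x) for x in rest.split()])
            elif line.startswith("values:"):
                in_values = True
            else:
                raise ConfigurationError(f"unrecognized contour-table line: {line!r}")
        if not dims:
            raise ConfigurationError(f"{path}: no 'dimensions:' header")
        missing = [d for d in dims if d not in edges]
        if missing:
            raise ConfigurationError(f"{path}: missing bin edges for {missing}")
        return cls(dims, edges, np.array(values), convention=convention)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["# lowres-audit contour table"]
        lines.append("dimensions: " + " ".join(self.dimensions))
        lines.append(f"convention: {self.convention}")
        for d in self.dimensions:
            lines.append(f"edges {d}: " + " ".join(f"{e:g}" for e in self.edges[d]))
        lines.append("values:")
        for row in self.probabilities.reshape(-1, self.probabilities.shape[-1]):
            lines.append(" ".join(f"{v:.8g}" for v in row))
        path.write_text("\n".join(lines) + "\n")
        return path

    # ---- lookup ---------------------------------------------------------

    def score(self, values: dict[str, float]) -> float:
        """Coverage percentile at the given dihedral values (0..1)."""
        point = []
        for d in self.dimensions:
            v = values[d]
            lo, hi = self.edges[d][0], self.edges[d][-1]
            if not lo <= v <= hi:
                warnings.warn(
                    f"{d}={v:.1f} outside contour domain [{lo:g}, {hi:g}]; scoring 0"
                )
                return 0.0
            point.append(np.clip(v, self._centers[self.dimensions.index(d)][0],
                                 self._centers[self.dimensions.index(d)][-1]))
        return float(self._interp(np.array(point)[None, :])[0])


def contour_lookup(
    record: DihedralRecord, table: ContourTable
) -> tuple[float | None, str]:
    """Percentile score for one residue plus outlier level {none, 5%, 1%}.

    Scores below 0.01 are 1%-level outliers, below 0.05 5%-level.
    """
    values = {}
    for d in table.dimensions:
        v = getattr(record, d, None)
        if v is None:
            return None, "none"
        values[d] = v
    s = table.score(values)
    if s < 0.01:
        return s, "1%"
    if s < 0.05:
        return s, "5%"
    return s, "none"
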
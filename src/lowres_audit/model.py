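"""In-memory coordinate model: atoms, residues, single-chain models.

A parsed structure is a list of :class:`ChainModel`, one per chain, in file
order. Only amino-acid residues are kept (the 20 standard codes plus MSE,
which is renamed to MET on input); waters and other heteroatoms are dropped
at parse time. Coordinates are in Angstroms throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyModelError, ChainNotFoundError

#: Three-letter codes accepted into a ChainModel. MSE is mapped to MET on read.
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Elements excluded from heavy-atom ("non-H") metrics.
HYDROGEN_ELEMENTS = frozenset({"H", "D"})


@dataclass
class AtomRecord:
    """One atom: name, element, position (A), occupancy, B-factor-or-pLDDT."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.name!r}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r}: non-finite coordinates")
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in HYDROGEN_ELEMENTS


@dataclass
class Residue:
    """One residue identified by (chain_id, seq_num, icode)."""

    chain_id: str
    seq_num: int
    icode: str = ""
    res_name: str = "ALA"
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.res_name = self.res_name.upper()

    @property
    def res_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)

    def atom(self, name: str) -> AtomRecord | None:
        """First atom with this name, or None."""
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def pos(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.position

    @property
    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def label(self) -> str:
        """Human-readable residue tag, e.g. ``A/LEU 234``."""
        return f"{self.chain_id}/{self.res_name} {self.seq_num}{self.icode}".rstrip()


@dataclass
class ChainModel:
    """Ordered residues of one chain plus a free-text source identifier."""

    residues: list[Residue] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for r in self.residues:
            if r.res_id in seen:
                raise ValueError(f"duplicate residue identifier {r.res_id}")
            seen.add(r.res_id)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    @property
    def chain_id(self) -> str:
        if not self.residues:
            raise EmptyModelError("chain has no residues")
        return self.residues[0].chain_id

    def copy(self) -> "ChainModel":
        import copy as _copy

        return _copy.deepcopy(self)


def get_chain(chains: list[ChainModel], chain_id: str) -> ChainModel:
    """Look up one chain by ID in a parsed structure."""
    for c in chains:
        if c.residues and c.chain_id == chain_id:
            return c
    raise ChainNotFoundError(
        f"chain {chain_id!r} not found; available: "
        f"{[c.chain_id for c in chains if c.residues]}"
    )


def as_chain_list(model: "ChainModel | list[ChainModel]") -> list[ChainModel]:
    """Normalize a single chain or a structure to a list of chains."""
    if isinstance(model, ChainModel):
        return [model]
    return list(model)
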
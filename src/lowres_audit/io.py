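"""Reading and writing coordinate models (PDB and mmCIF, via gemmi).

Policy on input, mirroring single-conformer validation practice:

* only altloc ' ' (blank) or 'A' atoms are kept by default;
* waters and non-amino-acid heteroatoms are dropped; MSE is treated as MET;
* residue numbering is author numbering (``auth_seq_id``), so ranges quoted
  in the literature ("chain 2 residues 201-335") apply verbatim;
* numeric chain IDs such as "2" are accepted as-is.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import gemmi

from .errors import (
    ChainNotFoundError,
    ConfidenceRangeError,
    EmptyModelError,
    EncodingError,
    StructureParseError,
)
from .model import STANDARD_AA, AtomRecord, ChainModel, Residue, as_chain_list, get_chain

_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}

#: residue-name substitutions applied on read
_RENAME = {"MSE": "MET"}


def read_structure(
    path: str | Path,
    format: str = "auto",
    keep_altlocs: tuple[str, ...] = ("", "A"),
) -> list[ChainModel]:
    """Parse a PDB or mmCIF file into a list of single-chain models.

    Parameters
    ----------
    path : file path
    format : {"pdb", "mmcif", "auto"}
        "auto" detects from content/extension.
    keep_altlocs :
        Alternate-location indicators retained; default keeps the blank and
        'A' conformers only.

    Returns
    -------
    list of ChainModel, one per chain of the first model, file order.

    Raises
    ------
    StructureParseError
        If the file is missing or not parseable under the named standard.
    EmptyModelError
        If no protein residues survive filtering.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {sorted(_FORMATS)}, got {format!r}")
    if not path.exists():
        raise StructureParseError(f"file not found: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()

    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models in file")
    chains: list[ChainModel] = []
    source = st.name or path.stem
    for gchain in st[0]:
        residues: list[Residue] = []
        for gres in gchain:
            name = _RENAME.get(gres.name.upper(), gres.name.upper())
            if name not in STANDARD_AA:
                continue
            atoms: list[AtomRecord] = []
            seen_names: set[str] = set()
            for gatom in gres:
                altloc = gatom.altloc if gatom.altloc not in ("", "\x00") else ""
                if altloc not in keep_altlocs:
                    continue
                if gatom.name in seen_names:  # altloc-resolved uniqueness
                    continue
                seen_names.add(gatom.name)
                atoms.append(
                    AtomRecord(
                        name=gatom.name,
                        element=gatom.element.name,
                        position=[gatom.pos.x, gatom.pos.y, gatom.pos.z],
                        occupancy=min(max(gatom.occ, 0.0), 1.0),
                        bfactor=gatom.b_iso,
                        altloc=altloc,
                    )
                )
            if not atoms:
                continue
            residues.append(
                Residue(
                    chain_id=gchain.name,
                    seq_num=gres.seqid.num,
                    icode=(gres.seqid.icode or "").strip(),
                    res_name=name,
                    atoms=atoms,
                )
            )
        if residues:
            residues.sort(key=lambda r: (r.seq_num, r.icode))
            chains.append(ChainModel(residues=residues, source_id=source))
    if not chains:
        raise EmptyModelError(f"{path}: no protein residues found")
    return chains


def select_range(
    model: ChainModel | list[ChainModel], chain: str, start: int, end: int
) -> ChainModel:
    """Residues of `chain` with start <= seq_num <= end, inclusive on both ends."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    if isinstance(model, ChainModel):
        if model.chain_id != chain:
            raise ChainNotFoundError(f"model holds chain {model.chain_id!r}, not {chain!r}")
        src = model
    else:
        src = get_chain(as_chain_list(model), chain)
    picked = [r for r in src.residues if start <= r.seq_num <= end]
    if not picked:
        raise EmptyModelError(f"selection {chain}/{start}-{end} is empty")
    return ChainModel(residues=picked, source_id=src.source_id)


def extract_plddt(model: ChainModel) -> list[float | None]:
    """Per-residue confidence: the CA atom's B-factor column (AlphaFold pLDDT).

    Returns one value per residue; ``None`` (with a warning) where CA is
    missing. Values outside [0, 100] raise :class:`ConfidenceRangeError`
    naming the offending residue.
    """
    out: list[float | None] = []
    for res in model.residues:
        ca = res.atom("CA")
        if ca is None:
            warnings.warn(f"{res.label()}: no CA atom, confidence unavailable")
            out.append(None)
            continue
        if not 0.0 <= ca.bfactor <= 100.0:
            raise ConfidenceRangeError(
                f"{res.label()}: B-factor {ca.bfactor} outside the pLDDT range [0, 100]"
            )
        out.append(float(ca.bfactor))
    return out


def write_structure(
    model: ChainModel | list[ChainModel], path: str | Path, format: str = "pdb"
) -> Path:
    """Write chains to a coordinate file (PDB fixed columns, or mmCIF)."""
    chains = as_chain_list(model)
    if not chains or all(len(c) == 0 for c in chains):
        raise EmptyModelError("refusing to write an empty model")
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unsupported output format {format!r}")
    st = _to_gemmi(chains)
    path = Path(path)
    if format == "pdb":
        for c in chains:
            for r in c.residues:
                if r.seq_num > 9999 or r.seq_num < -999:
                    raise EncodingError(
                        f"{r.label()}: seq_num {r.seq_num} does not fit PDB columns"
                    )
        st.write_pdb(str(path))
    else:
        doc = st.make_mmcif_document()
        doc.write_file(str(path))
    return path


def _to_gemmi(chains: list[ChainModel]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = chains[0].source_id or "model"
    gmodel = gemmi.Model("1")
    for chain in chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.seq_num, res.icode or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                # canonical output precision is the PDB convention (0.001 A)
                # for every format, so PDB and mmCIF renderings of one model
                # parse back to identical coordinates
                ga.pos = gemmi.Position(*(round(float(x), 3) for x in atom.position))
                ga.occ = atom.occupancy
                ga.b_iso = atom.bfactor
                if atom.altloc:
                    ga.altloc = atom.altloc
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    return st
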
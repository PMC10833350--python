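import numpy as np
import pytest

from lowres_audit import ChainModel, Residue, AtomRecord, build_polypeptide, helix_spec


@pytest.fixture()
def helix20() -> ChainModel:
    """20-residue ideal poly-ALA alpha-helix (phi=-63, psi=-43, omega=180)."""
    return build_polypeptide(helix_spec(20))


@pytest.fixture()
def helix10() -> ChainModel:
    return build_polypeptide(helix_spec(10))


def single_residue_chain() -> ChainModel:
    res = Residue(
        chain_id="A",
        seq_num=1,
        res_name="ALA",
        atoms=[
            AtomRecord("N", "N", [0.0, 0.0, 0.0]),
            AtomRecord("CA", "C", [1.458, 0.0, 0.0]),
            AtomRecord("C", "C", [2.0, 1.4, 0.0]),
            AtomRecord("O", "O", [3.2, 1.5, 0.0]),
        ],
    )
    return ChainModel(residues=[res], source_id="single")


def translate(model: ChainModel, vec) -> ChainModel:
    out = model.copy()
    vec = np.asarray(vec, dtype=float)
    for res in out.residues:
        for atom in res.atoms:
            atom.position = atom.position + vec
    return out
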
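"""Fetch and cache coordinate files from the wwPDB (network required)."""

from __future__ import annotations

import urllib.request
from pathlib import Path

from .errors import StructureParseError
from .io import read_structure
from .model import ChainModel

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.cif"


def fetch_structure(
    pdb_id: str, cache_dir: str | Path = "scratch/pdb", timeout: float = 30.0
) -> list[ChainModel]:
    """Download (or reuse a cached copy of) a PDB entry as mmCIF and parse it.

    Raises StructureParseError if the entry cannot be retrieved — callers
    running offline should expect that and say so.
    """
    pdb_id = pdb_id.lower()
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / f"{pdb_id}.cif"
    if not path.exists():
        url = RCSB_URL.format(pdb_id=pdb_id.upper())
        try:
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                data = resp.read()
        except OSError as exc:
            raise StructureParseError(
                f"cannot retrieve {pdb_id} from {url} (offline?): {exc}"
            ) from exc
        path.write_bytes(data)
    return read_structure(path, format="mmcif")
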
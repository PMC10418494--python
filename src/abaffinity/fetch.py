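"""Obtain public crystal structures: local file first, RCSB second.

The antibody-antigen crystal complexes this package is exercised on
(HER2 ectodomain with a trastuzumab or pertuzumab Fab) are public PDB
entries.  ``get_entry`` looks for a local copy under ``data/pdb/`` (or an
explicit directory) and otherwise downloads the mmCIF from RCSB with a
short network timeout, caching it when a writable cache directory is given.
"""

from __future__ import annotations

import urllib.error
import urllib.request
from pathlib import Path

from .errors import DataError
from .structure import Structure, read_structure

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.cif"
LOCAL_CANDIDATES = ("data/pdb", "data", ".")


def get_entry(
    pdb_id: str,
    search_dirs: tuple[str, ...] = LOCAL_CANDIDATES,
    cache_dir: str | Path | None = None,
    timeout: float = 10.0,
) -> Structure:
    """Load a PDB entry from disk if available, else fetch it from RCSB.

    Raises :class:`DataError` when the entry is neither cached locally nor
    reachable over the network.
    """
    pdb_id = pdb_id.lower()
    for base in search_dirs:
        for suffix in (".cif", ".pdb"):
            for name in (pdb_id, pdb_id.upper()):
                p = Path(base) / f"{name}{suffix}"
                if p.exists():
                    return read_structure(p, label=pdb_id)
    url = RCSB_URL.format(pdb_id=pdb_id.upper())
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            text = resp.read().decode()
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise DataError(
            f"PDB entry {pdb_id!r} is not available locally "
            f"(searched {search_dirs}) and could not be fetched from RCSB: {exc}"
        ) from exc
    if cache_dir is not None:
        cache = Path(cache_dir)
        cache.mkdir(parents=True, exist_ok=True)
        (cache / f"{pdb_id}.cif").write_text(text)
    structure = read_structure(text, label=pdb_id)
    return structure
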
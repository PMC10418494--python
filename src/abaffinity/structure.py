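"""Macromolecular structure I/O and residue classification.

A :class:`Structure` wraps a heavy-atom :class:`biotite.structure.AtomArray`.
Loading resolves alternate locations to the highest-occupancy conformer,
drops hydrogens/deuteriums, waters and (by default) hetero ligands, and keeps
a single model.  Residue identity is the triple (chain id, residue number,
insertion code), so numbering gaps and inserts survive round trips.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile, get_structure as _cif_get_structure

from .errors import (
    ChainLookupError,
    ClassificationError,
    EmptyStructureError,
    FormatError,
    ValidationError,
)
from .tables import CLASS_TABLES, STANDARD_RESIDUES, ResidueClass, Scheme


class ResidueKey(NamedTuple):
    """Identity of a residue: (chain, number, insertion code, name)."""

    chain_id: str
    res_id: int
    ins_code: str
    res_name: str

    @property
    def ident(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_id, self.ins_code)


@dataclass
class Structure:
    """Heavy-atom protein structure (single model)."""

    atoms: struc.AtomArray
    label: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    @property
    def coords(self) -> np.ndarray:
        return self.atoms.coord

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for cid in self.atoms.chain_id:
            seen.setdefault(cid, None)
        return list(seen)

    def residue_starts(self) -> np.ndarray:
        return struc.get_residue_starts(self.atoms)

    def residue_keys(self) -> list[ResidueKey]:
        a = self.atoms
        return [
            ResidueKey(a.chain_id[i], int(a.res_id[i]), a.ins_code[i], a.res_name[i])
            for i in self.residue_starts()
        ]

    def atom_residue_index(self) -> np.ndarray:
        """Residue index (into :meth:`residue_keys`) for every atom."""
        starts = self.residue_starts()
        idx = np.zeros(self.n_atoms, dtype=int)
        idx[starts] = 1
        return np.cumsum(idx) - 1

    @property
    def n_residues(self) -> int:
        return len(self.residue_starts())

    def subset(self, chains: Iterable[str], label: str | None = None) -> "Structure":
        chains = list(chains)
        missing = [c for c in chains if c not in self.chain_ids]
        if missing:
            raise ChainLookupError(
                f"chain(s) {missing} not in structure (available: {self.chain_ids})"
            )
        mask = np.isin(self.atoms.chain_id, chains)
        return Structure(self.atoms[mask], label or self.label, dict(self.metadata))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        atoms = self.atoms.copy()
        atoms.coord = atoms.coord @ np.asarray(rotation).T + np.asarray(translation)
        return Structure(atoms, self.label, dict(self.metadata))

    def to_pdb_string(self) -> str:
        pdb = PDBFile()
        pdb.set_structure(self.atoms)
        return "\n".join(pdb.lines) + "\n"

    def write_pdb(self, path: str | Path) -> None:
        Path(path).write_text(self.to_pdb_string())


@dataclass
class ComplexPartition:
    """A structure split into two interacting sides (antigen vs antibody)."""

    structure: Structure
    side_a_chains: tuple[str, ...]
    side_b_chains: tuple[str, ...]

    @property
    def side_a(self) -> Structure:
        return self.structure.subset(self.side_a_chains)

    @property
    def side_b(self) -> Structure:
        return self.structure.subset(self.side_b_chains)


def _looks_like_cif(text: str) -> bool:
    head = text[:4000]
    return head.lstrip().startswith("data_") or "_atom_site." in head


def read_structure(
    path_or_text: str | Path,
    model_index: int = 1,
    keep_hetero: bool = False,
    label: str = "",
) -> Structure:
    """Read a PDB or mmCIF structure and return its heavy protein atoms.

    ``path_or_text`` may be a filesystem path or raw file content.  The
    requested model (1-based) is extracted, alternate locations are resolved
    to the highest-occupancy conformer, and hydrogens and waters are removed.
    Hetero ligands are removed unless ``keep_hetero`` is set.
    """
    text = None
    if isinstance(path_or_text, Path) or (
        len(str(path_or_text)) < 4096 and "\n" not in str(path_or_text)
    ):
        p = Path(path_or_text)
        if p.exists():
            text = p.read_text()
            label = label or p.stem
    if text is None:
        text = str(path_or_text)
    try:
        if _looks_like_cif(text):
            cif = CIFFile.read(io.StringIO(text))
            atoms = _cif_get_structure(cif, model=model_index, altloc="occupancy")
        else:
            pdb = PDBFile.read(io.StringIO(text))
            atoms = pdb.get_structure(model=model_index, altloc="occupancy")
    except Exception as exc:
        raise FormatError(f"could not parse structure content: {exc}") from exc
    if atoms.array_length() == 0:
        raise EmptyStructureError(f"model {model_index} contains no atoms")

    keep = ~np.isin(atoms.element, ["H", "D"])
    keep &= ~struc.filter_solvent(atoms)
    if not keep_hetero:
        keep &= struc.filter_amino_acids(atoms)
    atoms = atoms[keep]
    if atoms.array_length() == 0:
        raise EmptyStructureError("no heavy protein atoms after filtering")
    return Structure(atoms, label=label)


def partition_complex(
    structure: Structure,
    antigen_chains: Sequence[str],
    antibody_chains: Sequence[str],
) -> ComplexPartition:
    """Split a complex into antigen (side A) and antibody (side B) chains.

    Chains named on neither side are dropped.  The two sets must be disjoint
    and non-empty, and every named chain must exist.
    """
    side_a = tuple(dict.fromkeys(antigen_chains))
    side_b = tuple(dict.fromkeys(antibody_chains))
    if not side_a or not side_b:
        raise ValidationError("both antigen and antibody chain sets must be non-empty")
    overlap = set(side_a) & set(side_b)
    if overlap:
        raise ValidationError(f"chains {sorted(overlap)} assigned to both sides")
    available = structure.chain_ids
    missing = [c for c in (*side_a, *side_b) if c not in available]
    if missing:
        raise ChainLookupError(
            f"chain(s) {missing} not in structure (available: {available})"
        )
    retained = structure.subset((*side_a, *side_b))
    return ComplexPartition(retained, side_a, side_b)


def classify_residue(res_name: str, scheme: Scheme | str = Scheme.IC) -> ResidueClass:
    """Return the physicochemical class of a standard residue under a scheme."""
    scheme = Scheme(scheme)
    name = res_name.upper()
    if name not in STANDARD_RESIDUES:
        raise ClassificationError(
            f"residue {res_name!r} is not one of the 20 standard amino acids"
        )
    return CLASS_TABLES[scheme][name]


def classify_residues(
    keys: Iterable[ResidueKey],
    scheme: Scheme | str = Scheme.IC,
    on_unknown: str = "skip",
) -> dict[tuple[str, int, str], ResidueClass]:
    """Classify many residues; unknown names are skipped with a warning
    (``on_unknown='skip'``) or raise (``on_unknown='fail'``)."""
    out = {}
    skipped = []
    for key in keys:
        try:
            out[key.ident] = classify_residue(key.res_name, scheme)
        except ClassificationError:
            if on_unknown == "fail":
                raise
            skipped.append(key)
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} non-standard residue(s): "
            + ", ".join(f"{k.chain_id}{k.res_id}{k.res_name}" for k in skipped[:5]),
            stacklevel=2,
        )
    return out


def make_structure(
    chain_ids: Sequence[str],
    res_ids: Sequence[int],
    res_names: Sequence[str],
    atom_names: Sequence[str],
    elements: Sequence[str],
    coords: np.ndarray,
    ins_codes: Sequence[str] | None = None,
    label: str = "",
) -> Structure:
    """Assemble a :class:`Structure` from parallel per-atom arrays."""
    n = len(atom_names)
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(coords, dtype=np.float32).reshape(n, 3)
    atoms.chain_id = np.asarray(chain_ids, dtype="U4")
    atoms.res_id = np.asarray(res_ids, dtype=int)
    atoms.res_name = np.asarray(res_names, dtype="U5")
    atoms.atom_name = np.asarray(atom_names, dtype="U6")
    atoms.element = np.asarray(elements, dtype="U2")
    atoms.ins_code = (
        np.asarray(ins_codes, dtype="U1") if ins_codes is not None
        else np.full(n, "", dtype="U1")
    )
    atoms.hetero = np.full(n, False)
    return Structure(atoms, label=label)


def merge(structures: Sequence[Structure], label: str = "") -> Structure:
    """Concatenate structures into one (chains must not collide)."""
    seen: set[str] = set()
    for s in structures:
        dup = seen & set(s.chain_ids)
        if dup:
            raise ValidationError(f"duplicate chain id(s) on merge: {sorted(dup)}")
        seen |= set(s.chain_ids)
    arrays = [s.atoms for s in structures]
    merged = arrays[0]
    for arr in arrays[1:]:
        merged = merged + arr
    return Structure(merged, label=label)
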
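"""Interfacial residue-residue contacts and their class-pair tallies.

Two residues, one per binding partner, are in contact when any pair of their
heavy atoms lies within the cutoff (default 5.5 A, inclusive).  A contact is
counted once per residue pair regardless of how many atom pairs qualify.
Tallies are unordered in the class pair: a charged residue on the antigen
touching an apolar one on the antibody contributes to the same counter as
the reverse arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ValidationError
from .structure import ComplexPartition, ResidueKey, classify_residues
from .tables import Scheme

DEFAULT_CUTOFF = 5.5

#: canonical (sorted) class-pair keys -> ContactTally attribute
PAIR_FIELDS = {
    ("charged", "charged"): "ic_charged_charged",
    ("charged", "polar"): "ic_charged_polar",
    ("apolar", "charged"): "ic_charged_apolar",
    ("polar", "polar"): "ic_polar_polar",
    ("apolar", "polar"): "ic_polar_apolar",
    ("apolar", "apolar"): "ic_apolar_apolar",
}


@dataclass(frozen=True)
class ContactPair:
    residue_a: ResidueKey
    residue_b: ResidueKey
    min_distance: float


@dataclass
class ContactTally:
    """Counts of interfacial contacts by residue-class pair."""

    ic_charged_charged: int = 0
    ic_charged_polar: int = 0
    ic_charged_apolar: int = 0
    ic_polar_polar: int = 0
    ic_polar_apolar: int = 0
    ic_apolar_apolar: int = 0
    cutoff: float = DEFAULT_CUTOFF
    n_unclassified: int = 0
    scheme: Scheme = Scheme.IC

    @property
    def total(self) -> int:
        return sum(getattr(self, f) for f in PAIR_FIELDS.values())

    def as_dict(self) -> dict[str, int]:
        return {f: int(getattr(self, f)) for f in PAIR_FIELDS.values()}


def find_contacts(
    partition: ComplexPartition, cutoff: float = DEFAULT_CUTOFF
) -> list[ContactPair]:
    """All cross-partition residue pairs with any heavy-atom distance <= cutoff.

    Uses a k-d tree for the atom-pair search; equivalent to the all-pairs
    scan (property-tested) but O(n log n) in practice.
    """
    if cutoff <= 0:
        raise ValidationError(f"cutoff must be positive, got {cutoff}")
    side_a, side_b = partition.side_a, partition.side_b
    if side_a.n_atoms == 0 or side_b.n_atoms == 0:
        raise ValidationError("both sides of the partition must contain atoms")

    keys_a, keys_b = side_a.residue_keys(), side_b.residue_keys()
    res_a, res_b = side_a.atom_residue_index(), side_b.atom_residue_index()
    coords_a = side_a.coords.astype(np.float64)
    coords_b = side_b.coords.astype(np.float64)

    tree_a, tree_b = cKDTree(coords_a), cKDTree(coords_b)
    pairs = tree_a.query_ball_tree(tree_b, r=cutoff)

    best: dict[tuple[int, int], float] = {}
    for ia, neighbours in enumerate(pairs):
        if not neighbours:
            continue
        ra = res_a[ia]
        d = np.linalg.norm(coords_b[neighbours] - coords_a[ia], axis=1)
        for ib, dist in zip(neighbours, d):
            if dist > cutoff:  # guard the boundary exactly
                continue
            key = (ra, res_b[ib])
            if dist < best.get(key, np.inf):
                best[key] = float(dist)

    return [
        ContactPair(keys_a[ka], keys_b[kb], dist)
        for (ka, kb), dist in sorted(best.items())
    ]


def tally_contacts(
    pairs: list[ContactPair],
    scheme: Scheme | str = Scheme.IC,
    cutoff: float = DEFAULT_CUTOFF,
    on_unknown: str = "skip",
) -> ContactTally:
    """Tally contact pairs into the six unordered class-pair counters.

    Pairs involving a residue outside the 20 standard amino acids are skipped
    with a warning (or raise, per ``on_unknown``) and reported in
    ``n_unclassified``.
    """
    scheme = Scheme(scheme)
    keys = {p.residue_a for p in pairs} | {p.residue_b for p in pairs}
    classes = classify_residues(keys, scheme, on_unknown=on_unknown)
    tally = ContactTally(cutoff=cutoff, scheme=scheme)
    for pair in pairs:
        ca = classes.get(pair.residue_a.ident)
        cb = classes.get(pair.residue_b.ident)
        if ca is None or cb is None:
            tally.n_unclassified += 1
            continue
        f = PAIR_FIELDS[tuple(sorted([ca.value, cb.value]))]
        setattr(tally, f, getattr(tally, f) + 1)
    return tally


def interface_residues(
    pairs: list[ContactPair],
) -> tuple[set[tuple[str, int, str]], set[tuple[str, int, str]]]:
    """Residue identities participating in any contact, per side."""
    return (
        {p.residue_a.ident for p in pairs},
        {p.residue_b.ident for p in pairs},
    )


def contacts_to_frame(pairs: list[ContactPair], scheme: Scheme | str = Scheme.IC) -> pd.DataFrame:
    """Contact list as a data frame (CSV-exportable)."""
    classes = classify_residues(
        {p.residue_a for p in pairs} | {p.residue_b for p in pairs}, scheme
    )
    rows = []
    for p in pairs:
        rows.append(
            {
                "chain_a": p.residue_a.chain_id,
                "resnum_a": p.residue_a.res_id,
                "resname_a": p.residue_a.res_name,
                "chain_b": p.residue_b.chain_id,
                "resnum_b": p.residue_b.res_id,
                "resname_b": p.residue_b.res_name,
                "min_distance": p.min_distance,
                "class_a": getattr(classes.get(p.residue_a.ident), "value", "n/a"),
                "class_b": getattr(classes.get(p.residue_b.ident), "value", "n/a"),
            }
        )
    return pd.DataFrame(rows)
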
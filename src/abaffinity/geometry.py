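"""Rigid-body superposition, antigen grafting and steric-clash analysis.

The stoichiometry question — can an IgG carry one antigen per Fab arm? —
is probed with a purely rigid procedure: take the substructure formed by the
bound antigen and the Fab light chain it engages, superpose that light chain
onto the light chain of the free Fab (least-squares Kabsch fit on backbone
atoms of residues common to both), and inspect the resulting virtual 2:1
complex for interpenetration between the two antigen copies.  No
minimisation or repacking is applied afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import AlignmentError, ValidationError
from .structure import Structure, merge

BACKBONE_ATOMS = ("N", "CA", "C", "O")
DEFAULT_CLASH_CUTOFF = 2.5  # A, severe heavy-atom clash


@dataclass
class SuperpositionResult:
    rotation: np.ndarray        # 3x3 proper orthogonal
    translation: np.ndarray     # A
    rmsd: float                 # A, after transform
    n_atoms_matched: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class ClashReport:
    n_atom_pairs_below_cutoff: int
    min_interatomic_distance: float
    overlap_fraction: float      # share of side-A atoms within cutoff of side B
    cutoff: float


def superpose(
    mobile_coords: np.ndarray, reference_coords: np.ndarray
) -> SuperpositionResult:
    """Least-squares optimal rigid transform (Kabsch) mapping mobile onto
    reference paired coordinates.

    The rotation is always proper (determinant +1): a chirally inverted
    input is fitted as well as a rotation allows, never reflected.
    """
    mob = np.asarray(mobile_coords, dtype=float)
    ref = np.asarray(reference_coords, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValidationError("coordinate sets must be matching (n, 3) arrays")
    n = mob.shape[0]
    if n < 3:
        raise ValidationError("at least 3 paired atoms are required")
    mob_c, ref_c = mob.mean(axis=0), ref.mean(axis=0)
    p, q = mob - mob_c, ref - ref_c
    if np.linalg.matrix_rank(p, tol=1e-8) < 2:
        raise ValidationError("degenerate (collinear) coordinate set")
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ref_c - rot @ mob_c
    moved = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return SuperpositionResult(rot, trans, rmsd, n)


def _backbone_map(structure: Structure, chain: str) -> dict:
    """(res_id, ins_code, atom_name) -> coordinate for backbone atoms."""
    sub = structure.subset([chain])
    out = {}
    a = sub.atoms
    for i in range(sub.n_atoms):
        if a.atom_name[i] in BACKBONE_ATOMS:
            out[(int(a.res_id[i]), a.ins_code[i], a.atom_name[i])] = a.coord[i]
    return out


def superpose_chains(
    structure: Structure, mobile_chain: str, reference_chain: str
) -> SuperpositionResult:
    """Kabsch fit of one chain's backbone onto another's, paired by residue
    number and insertion code over their common residues."""
    mob_map = _backbone_map(structure, mobile_chain)
    ref_map = _backbone_map(structure, reference_chain)
    common = sorted(set(mob_map) & set(ref_map))
    if len(common) < 3:
        raise AlignmentError(
            f"chains {mobile_chain!r} and {reference_chain!r} share "
            f"{len(common)} backbone atom(s); need >= 3"
        )
    mob = np.array([mob_map[k] for k in common])
    ref = np.array([ref_map[k] for k in common])
    return superpose(mob, ref)


def graft_second_antigen(
    complex_1_1: Structure,
    bound_antigen_chain: str,
    bound_lightchain_chain: str,
    free_lightchain_chain: str,
    new_antigen_chain: str = "X",
) -> tuple[Structure, SuperpositionResult]:
    """Build a virtual 2:1 complex by rigid grafting.

    Copies the (bound antigen + engaged light chain) substructure, fits the
    light-chain backbone onto the free Fab's light chain, and merges the
    transformed antigen copy (renamed ``new_antigen_chain``) into the input.
    The input structure is left untouched.
    """
    for chain in (bound_antigen_chain, bound_lightchain_chain, free_lightchain_chain):
        if chain not in complex_1_1.chain_ids:
            raise AlignmentError(f"chain {chain!r} not present in structure")
    if new_antigen_chain in complex_1_1.chain_ids:
        raise ValidationError(f"chain id {new_antigen_chain!r} already in use")
    fit = superpose_chains(
        complex_1_1, bound_lightchain_chain, free_lightchain_chain
    )
    antigen = complex_1_1.subset([bound_antigen_chain])
    grafted_atoms = antigen.atoms.copy()
    grafted_atoms.coord = fit.apply(grafted_atoms.coord).astype(np.float32)
    grafted_atoms.chain_id = np.full(
        grafted_atoms.array_length(), new_antigen_chain, dtype="U4"
    )
    grafted = Structure(grafted_atoms, label=f"{complex_1_1.label}+graft")
    virtual = merge([complex_1_1, grafted], label=f"{complex_1_1.label}_2to1")
    return virtual, fit


def clash_report(
    structure: Structure,
    chains_a: list[str],
    chains_b: list[str],
    cutoff: float = DEFAULT_CLASH_CUTOFF,
) -> ClashReport:
    """Heavy-atom interpenetration between two chain sets.

    Counts cross-set atom pairs closer than ``cutoff``; reports the minimum
    interatomic distance and the fraction of side-A atoms with any side-B
    atom within the cutoff.
    """
    if not chains_a or not chains_b:
        raise ValidationError("both chain sets must be non-empty")
    side_a = structure.subset(chains_a)
    side_b = structure.subset(chains_b)
    ca = side_a.coords.astype(np.float64)
    cb = side_b.coords.astype(np.float64)
    tree_b = cKDTree(cb)
    neighbours = cKDTree(ca).query_ball_tree(tree_b, r=cutoff)
    n_pairs = sum(len(nb) for nb in neighbours)
    n_a_clashing = sum(1 for nb in neighbours if nb)
    min_dist, _ = tree_b.query(ca, k=1)
    return ClashReport(
        n_atom_pairs_below_cutoff=int(n_pairs),
        min_interatomic_distance=float(np.min(min_dist)),
        overlap_fraction=n_a_clashing / len(ca),
        cutoff=cutoff,
    )
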
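"""Solvent-accessible surface area, non-interacting surface, buried surface.

SASA is computed numerically (Shrake-Rupley-style sphere sampling with a
deterministic Fibonacci point set, via biotite) with a frozen element-wise
van der Waals radius table and a 1.4 A water probe.

The non-interacting surface (NIS) of a complex is the set of residues that
remain solvent exposed (relative SASA >= threshold, default 5%) and do not
participate in any interfacial contact.  Its composition by residue character
(%NIS charged / polar / apolar) feeds the affinity model.

Buried surface area (BSA) is the total SASA lost on complexation,
SASA(A) + SASA(B) - SASA(AB), summed over both sides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import biotite.structure as struc

from . import contacts as _contacts
from .errors import DegenerateSurfaceError, ParameterisationError
from .structure import ComplexPartition, ResidueKey, Structure, classify_residues
from .tables import MAX_ASA, VDW_RADII, ResidueClass, Scheme

DEFAULT_PROBE = 1.4
DEFAULT_POINTS = 960
DEFAULT_NIS_THRESHOLD = 5.0


@dataclass
class SASAResult:
    residues: list[ResidueKey]
    absolute: np.ndarray          # A^2 per residue
    relative: np.ndarray          # % of extended-reference maximum (NaN if no reference)
    atom_sasa: np.ndarray         # A^2 per atom
    probe: float
    n_points: int
    reference: str

    @property
    def total(self) -> float:
        return float(self.absolute.sum())


@dataclass
class NISResult:
    nis_charged_pct: float
    nis_polar_pct: float
    nis_apolar_pct: float
    counts: dict[str, int]
    n_nis_residues: int
    threshold_pct: float
    scheme: Scheme


@dataclass
class InterfaceSummary:
    bsa: float
    interface_residues_a: list[ResidueKey]
    interface_residues_b: list[ResidueKey]


def _radii_for(structure: Structure) -> np.ndarray:
    radii = np.empty(structure.n_atoms)
    for i, el in enumerate(structure.atoms.element):
        try:
            radii[i] = VDW_RADII[el.upper()]
        except KeyError:
            raise ParameterisationError(
                f"no van der Waals radius for element {el!r} "
                f"(atom {structure.atoms.atom_name[i]})"
            ) from None
    return radii


def compute_sasa(
    structure: Structure,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
    reference: str = "naccess",
) -> SASAResult:
    """Numerical SASA per atom, summed per residue, with relative values.

    Deterministic for fixed inputs: the sphere point set is a Fibonacci
    lattice, not a random sample.  Relative SASA is the per-residue absolute
    value over the extended-reference maximum for that residue type; residues
    without a reference entry get NaN and are excluded from NIS counting.
    """
    if structure.n_atoms == 0:
        raise DegenerateSurfaceError("cannot compute SASA of an empty structure")
    atom_sasa = struc.sasa(
        structure.atoms,
        probe_radius=probe,
        point_number=n_points,
        vdw_radii=_radii_for(structure),
    )
    atom_sasa = np.nan_to_num(atom_sasa, nan=0.0)
    keys = structure.residue_keys()
    res_index = structure.atom_residue_index()
    absolute = np.zeros(len(keys))
    np.add.at(absolute, res_index, atom_sasa)
    ref_table = MAX_ASA[reference]
    relative = np.full(len(keys), np.nan)
    for i, key in enumerate(keys):
        ref = ref_table.get(key.res_name)
        if ref:
            relative[i] = 100.0 * absolute[i] / ref
    return SASAResult(keys, absolute, relative, atom_sasa, probe, n_points, reference)


def nis_percentages(
    partition: ComplexPartition,
    sasa_complex: SASAResult,
    threshold_pct: float = DEFAULT_NIS_THRESHOLD,
    scheme: Scheme | str = Scheme.NIS,
    exclude_interface: bool = True,
    contact_cutoff: float = _contacts.DEFAULT_CUTOFF,
) -> NISResult:
    """Class composition (%) of the non-interacting surface of a complex.

    NIS residues are those with relative SASA (computed on the whole
    complex) at or above ``threshold_pct`` that are not interfacial;
    percentages are class shares of the NIS residue count and sum to 100.
    """
    scheme = Scheme(scheme)
    iface: set = set()
    if exclude_interface:
        pairs = _contacts.find_contacts(partition, cutoff=contact_cutoff)
        ia, ib = _contacts.interface_residues(pairs)
        iface = ia | ib
    classes = classify_residues(sasa_complex.residues, scheme)
    counts = {c.value: 0 for c in ResidueClass}
    n_surface = 0
    for key, rel in zip(sasa_complex.residues, sasa_complex.relative):
        if not np.isfinite(rel) or rel < threshold_pct:
            continue
        if key.ident in iface:
            continue
        cls = classes.get(key.ident)
        if cls is None:
            continue
        counts[cls.value] += 1
        n_surface += 1
    if n_surface == 0:
        raise DegenerateSurfaceError(
            "no non-interacting surface residues above the threshold"
        )
    pct = {c: 100.0 * n / n_surface for c, n in counts.items()}
    return NISResult(
        nis_charged_pct=pct["charged"],
        nis_polar_pct=pct["polar"],
        nis_apolar_pct=pct["apolar"],
        counts=counts,
        n_nis_residues=n_surface,
        threshold_pct=threshold_pct,
        scheme=scheme,
    )


def buried_surface_area(
    partition: ComplexPartition,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
    halved: bool = False,
    delta_threshold: float = 0.1,
) -> InterfaceSummary:
    """Buried surface area of a partition, plus per-side interface residues.

    ``halved=True`` divides the total dSASA by two (per-side convention);
    the default reports the total over both sides.  Interface residues are
    those losing more than ``delta_threshold`` A^2 of SASA on complexation.
    """
    sasa_ab = compute_sasa(partition.structure, probe, n_points)
    sasa_a = compute_sasa(partition.side_a, probe, n_points)
    sasa_b = compute_sasa(partition.side_b, probe, n_points)
    bsa = sasa_a.total + sasa_b.total - sasa_ab.total
    if bsa < 0:
        # numerical: point sampling can undershoot by a sliver
        warnings.warn(f"BSA slightly negative ({bsa:.3f} A^2); clamping to 0")
        bsa = 0.0
    if halved:
        bsa /= 2.0

    complex_abs = {k.ident: v for k, v in zip(sasa_ab.residues, sasa_ab.absolute)}

    def _iface(side: SASAResult) -> list[ResidueKey]:
        out = []
        for key, free_val in zip(side.residues, side.absolute):
            if free_val - complex_abs.get(key.ident, 0.0) > delta_threshold:
                out.append(key)
        return out

    return InterfaceSummary(float(bsa), _iface(sasa_a), _iface(sasa_b))
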
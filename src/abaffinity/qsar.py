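"""Contact-based binding-affinity model and its structure pipeline.

The predictor is a linear model over interfacial-contact counts and
non-interacting-surface percentages:

    dG = w_cc*IC_cc + w_ca*IC_ca + w_pp*IC_pp + w_pa*IC_pa
         + w_nis_apolar*%NIS_apolar + w_nis_charged*%NIS_charged + intercept

in kcal/mol.  Apolar-apolar and charged-polar contacts are deliberately not
part of the model.  The published charged-NIS coefficient appears in some
printings as +0.3810; that value is inconsistent with the model's own worked
predictions (it shifts a typical antibody-antigen complex by ~+5 kcal/mol),
so the default here is the consistent +0.13810, with the alternative
available via :meth:`QsarCoefficients.printed_variant`.

Dissociation constants follow Kd = exp(dG * 1000 / (R * T)) with
R = 1.987 cal/K/mol; temperature enters only this conversion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import contacts as _contacts
from . import sasa as _sasa
from .errors import ValidationError
from .structure import Structure, partition_complex, read_structure
from .tables import Scheme

R_CAL = 1.987  # cal / (K mol)
DEFAULT_TEMPERATURE = 309.0  # K


@dataclass(frozen=True)
class QsarCoefficients:
    """Weights (kcal/mol per unit descriptor) of the affinity model."""

    w_cc: float = -0.09459
    w_ca: float = -0.10007
    w_pp: float = +0.19577
    w_pa: float = -0.22671
    w_nis_apolar: float = +0.18681
    w_nis_charged: float = +0.13810
    intercept: float = -15.9433

    @classmethod
    def printed_variant(cls) -> "QsarCoefficients":
        """Coefficient set with the (inconsistent) +0.3810 charged-NIS weight."""
        return cls(w_nis_charged=+0.3810)


@dataclass
class AffinityPrediction:
    delta_g: float            # kcal/mol
    kd: float                 # molar
    temperature: float        # K
    tally: _contacts.ContactTally
    nis: _sasa.NISResult
    bsa: float
    label: str = ""
    metadata: dict = field(default_factory=dict)


@dataclass
class EnsemblePrediction:
    mean_delta_g: float
    sd_delta_g: float | None      # sample sd; None for n = 1
    n: int
    predictions: list[AffinityPrediction]
    failures: list[tuple[str, str]] = field(default_factory=list)


def select_antigen_fab_copy(
    structure: Structure, min_contact_residues: int = 5
) -> tuple[list[str], list[str]]:
    """Pick one antigen-Fab copy from a crystal asymmetric unit.

    The antigen is taken as the largest chain by residue count (a receptor
    ectodomain dwarfs a Fab chain); when the crystal holds several copies,
    the alphabetically first large chain is used and the choice is recorded
    in the returned metadata of downstream predictions.  Fab chains are the
    chains with at least ``min_contact_residues`` residues in interfacial
    contact with that antigen.
    """
    sizes = {}
    for key in structure.residue_keys():
        sizes[key.chain_id] = sizes.get(key.chain_id, 0) + 1
    biggest = max(sizes.values())
    large = sorted(c for c, n in sizes.items() if n > 0.8 * biggest)
    antigen = large[0]
    others = [c for c in structure.chain_ids if c != antigen]
    fab = []
    for chain in others:
        part = partition_complex(structure, [antigen], [chain])
        pairs = _contacts.find_contacts(part)
        touched = {p.residue_b.ident for p in pairs}
        if len(touched) >= min_contact_residues:
            fab.append(chain)
    if not fab:
        raise ValidationError(
            f"no chain makes an interface with putative antigen {antigen!r}"
        )
    return [antigen], sorted(fab)


def predict_delta_g(
    tally: _contacts.ContactTally,
    nis: _sasa.NISResult,
    coeffs: QsarCoefficients = QsarCoefficients(),
) -> float:
    """Evaluate the linear affinity model (kcal/mol)."""
    return (
        coeffs.w_cc * tally.ic_charged_charged
        + coeffs.w_ca * tally.ic_charged_apolar
        + coeffs.w_pp * tally.ic_polar_polar
        + coeffs.w_pa * tally.ic_polar_apolar
        + coeffs.w_nis_apolar * nis.nis_apolar_pct
        + coeffs.w_nis_charged * nis.nis_charged_pct
        + coeffs.intercept
    )


def dissociation_constant(
    delta_g: float, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """Kd (molar) from a binding free energy in kcal/mol."""
    if temperature <= 0:
        raise ValidationError(f"temperature must be positive, got {temperature}")
    return math.exp(delta_g * 1000.0 / (R_CAL * temperature))


def predict_structure_file(
    path_or_text: str | Path,
    antigen_chains: Sequence[str],
    antibody_chains: Sequence[str],
    coeffs: QsarCoefficients = QsarCoefficients(),
    temperature: float = DEFAULT_TEMPERATURE,
    cutoff: float = _contacts.DEFAULT_CUTOFF,
    nis_threshold: float = _sasa.DEFAULT_NIS_THRESHOLD,
    ic_scheme: Scheme | str = Scheme.IC,
    nis_scheme: Scheme | str = Scheme.NIS,
    sasa_points: int = _sasa.DEFAULT_POINTS,
    label: str = "",
) -> AffinityPrediction:
    """Full pipeline: read -> contacts -> SASA/NIS/BSA -> dG -> Kd."""
    structure = read_structure(path_or_text, label=label)
    return predict_structure(
        structure, antigen_chains, antibody_chains, coeffs, temperature,
        cutoff, nis_threshold, ic_scheme, nis_scheme, sasa_points,
        label=label or structure.label,
    )


def predict_structure(
    structure: Structure,
    antigen_chains: Sequence[str],
    antibody_chains: Sequence[str],
    coeffs: QsarCoefficients = QsarCoefficients(),
    temperature: float = DEFAULT_TEMPERATURE,
    cutoff: float = _contacts.DEFAULT_CUTOFF,
    nis_threshold: float = _sasa.DEFAULT_NIS_THRESHOLD,
    ic_scheme: Scheme | str = Scheme.IC,
    nis_scheme: Scheme | str = Scheme.NIS,
    sasa_points: int = _sasa.DEFAULT_POINTS,
    label: str = "",
) -> AffinityPrediction:
    partition = partition_complex(structure, antigen_chains, antibody_chains)
    pairs = _contacts.find_contacts(partition, cutoff=cutoff)
    tally = _contacts.tally_contacts(pairs, scheme=ic_scheme, cutoff=cutoff)
    sasa_complex = _sasa.compute_sasa(partition.structure, n_points=sasa_points)
    nis = _sasa.nis_percentages(
        partition, sasa_complex, threshold_pct=nis_threshold,
        scheme=nis_scheme, contact_cutoff=cutoff,
    )
    summary = _sasa.buried_surface_area(partition, n_points=sasa_points)
    dg = predict_delta_g(tally, nis, coeffs)
    return AffinityPrediction(
        delta_g=dg,
        kd=dissociation_constant(dg, temperature),
        temperature=temperature,
        tally=tally,
        nis=nis,
        bsa=summary.bsa,
        label=label or structure.label,
        metadata={
            "antigen_chains": list(antigen_chains),
            "antibody_chains": list(antibody_chains),
            "cutoff": cutoff,
            "nis_threshold": nis_threshold,
            "coefficients": coeffs.__dict__ if hasattr(coeffs, "__dict__") else vars(coeffs),
        },
    )


def predict_ensemble(
    snapshot_paths: Sequence[str | Path],
    antigen_chains: Sequence[str],
    antibody_chains: Sequence[str],
    **kwargs,
) -> EnsemblePrediction:
    """Per-snapshot predictions with ensemble mean and sample (n-1) sd.

    Snapshots that fail to process are recorded and excluded with a warning;
    if all fail, the last error is re-raised.
    """
    if not snapshot_paths:
        raise ValidationError("at least one snapshot is required")
    predictions: list[AffinityPrediction] = []
    failures: list[tuple[str, str]] = []
    last_exc: Exception | None = None
    for path in snapshot_paths:
        try:
            predictions.append(
                predict_structure_file(path, antigen_chains, antibody_chains, **kwargs)
            )
        except Exception as exc:
            failures.append((str(path), str(exc)))
            last_exc = exc
    if not predictions:
        raise last_exc  # type: ignore[misc]
    if failures:
        warnings.warn(f"{len(failures)} snapshot(s) failed and were excluded")
    dgs = np.array([p.delta_g for p in predictions])
    sd = float(np.std(dgs, ddof=1)) if len(dgs) > 1 else None
    return EnsemblePrediction(
        mean_delta_g=float(dgs.mean()),
        sd_delta_g=sd,
        n=len(dgs),
        predictions=predictions,
        failures=failures,
    )


def ensemble_from_predictions(
    predictions: Sequence[AffinityPrediction],
) -> EnsemblePrediction:
    """Summarise already-computed per-snapshot predictions."""
    if not predictions:
        raise ValidationError("no predictions to summarise")
    dgs = np.array([p.delta_g for p in predictions])
    sd = float(np.std(dgs, ddof=1)) if len(dgs) > 1 else None
    return EnsemblePrediction(float(dgs.mean()), sd, len(dgs), list(predictions))
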
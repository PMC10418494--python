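"""Synthetic fixtures with bundled ground truth.

Every generator here emits both the data and the truth it was built from, so
recovery tests can consume the data alone and compare against the bundle:

* toy protein complexes whose interfacial-contact list (and hence class-pair
  tally) is exact by construction;
* random two-chain complexes for oracle-equivalence testing, plus an
  independent O(n^2) brute-force contact scan to serve as that oracle;
* equilibrium mixtures simulated from a known association constant, and
  reference mixtures frozen to the study conditions of the
  HER2/trastuzumab and HER2/pertuzumab solution experiments;
* synthetic tetra-detector chromatograms of those mixtures;
* a minimal IgG-like fixture (two light-chain arms, one bound antigen) for
  the grafting/clash analysis.

Toy residues are minimal five-atom bodies (backbone N, CA, C, O plus a CB
side-chain carrier): contact and surface logic needs geometry, not
chemistry.  All randomness flows through integer-seeded NumPy generators,
so regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import sec as _sec
from .equilibrium import SpeciesConcentrations, simulate_equilibrium
from .errors import GenerationError, ValidationError
from .structure import Structure, make_structure
from .tables import ONE_TO_THREE

# local toy-residue template: CB is the contact carrier at the origin, the
# backbone sits strictly below it in y
_TEMPLATE = {
    "CB": np.array([0.0, 0.0, 0.0]),
    "CA": np.array([0.0, -1.5, 0.0]),
    "N": np.array([-1.2, -2.3, 0.0]),
    "C": np.array([1.2, -2.3, 0.0]),
    "O": np.array([2.2, -1.7, 0.0]),
}
_ELEMENTS = {"CB": "C", "CA": "C", "N": "N", "C": "C", "O": "O"}
_FLIP = np.diag([-1.0, -1.0, 1.0])  # proper 180-degree rotation about z

# study-condition optical properties (dA/dc in mL/g/cm)
DA_DC = {"mab_tzm": 1.38, "mab_pzm": 1.29, "antigen": 0.90}


@dataclass
class ToyComplexSpec:
    """Two-chain toy complex with an exactly realised contact list.

    ``contacts`` are (index into residues_a, index into residues_b,
    min heavy-atom distance).  Each residue may appear in at most one
    contact; contact pairs are isolated in space so nothing else touches.
    """

    residues_a: list[str]            # one-letter codes
    residues_b: list[str]
    contacts: list[tuple[int, int, float]] = field(default_factory=list)
    chain_a: str = "A"
    chain_b: str = "B"
    cluster_spacing: float = 25.0
    cutoff: float = 5.5


def _residue_atoms(center: np.ndarray, rotation: np.ndarray | None = None):
    rot = np.eye(3) if rotation is None else rotation
    names, elements, coords = [], [], []
    for name, local in _TEMPLATE.items():
        names.append(name)
        elements.append(_ELEMENTS[name])
        coords.append(rot @ local + center)
    return names, elements, coords


def _append_residue(buf, chain, res_id, res_name, center, rotation=None):
    names, elements, coords = _residue_atoms(np.asarray(center, float), rotation)
    for n, e, c in zip(names, elements, coords):
        buf["chain"].append(chain)
        buf["res_id"].append(res_id)
        buf["res_name"].append(res_name)
        buf["atom"].append(n)
        buf["element"].append(e)
        buf["coord"].append(c)


def brute_force_contact_pairs(
    structure: Structure, chains_a, chains_b, cutoff: float = 5.5
):
    """All-pairs O(n^2) residue contact scan (no spatial index).

    Returns {(residue_a_ident, residue_b_ident): min_distance}; serves as
    the independent oracle for the production contact finder.
    """
    side_a = structure.subset(list(chains_a))
    side_b = structure.subset(list(chains_b))
    keys_a = side_a.residue_keys()
    keys_b = side_b.residue_keys()
    idx_a = side_a.atom_residue_index()
    idx_b = side_b.atom_residue_index()
    out: dict = {}
    ca, cb = side_a.coords, side_b.coords
    for ia in range(side_a.n_atoms):
        d = np.sqrt(np.sum((cb.astype(float) - ca[ia].astype(float)) ** 2, axis=1))
        for ib in np.nonzero(d <= cutoff)[0]:
            key = (keys_a[idx_a[ia]].ident, keys_b[idx_b[ib]].ident)
            dist = float(d[ib])
            if dist < out.get(key, np.inf):
                out[key] = dist
    return out


def make_toy_complex(spec: ToyComplexSpec) -> tuple[Structure, dict]:
    """Realise a :class:`ToyComplexSpec`; returns (structure, ground truth).

    Ground truth maps (residue_a_ident, residue_b_ident) -> intended
    distance.  Generation self-checks the realised structure against the
    independent brute-force scan and refuses to emit a mismatch.
    """
    if not spec.residues_a and not spec.residues_b:
        raise GenerationError("empty specification: no residues on either side")
    seen_a, seen_b = set(), set()
    for ia, ib, dist in spec.contacts:
        if ia in seen_a or ib in seen_b:
            raise GenerationError(
                "unrealisable: a residue participates in more than one contact"
            )
        if not 0 < dist <= spec.cutoff:
            raise GenerationError(f"contact distance {dist} outside (0, cutoff]")
        seen_a.add(ia)
        seen_b.add(ib)

    buf = {k: [] for k in ("chain", "res_id", "res_name", "atom", "element", "coord")}
    truth = {}
    for k, (ia, ib, dist) in enumerate(spec.contacts):
        x0 = k * spec.cluster_spacing
        _append_residue(
            buf, spec.chain_a, ia + 1, ONE_TO_THREE[spec.residues_a[ia]], (x0, 0, 0)
        )
        _append_residue(
            buf, spec.chain_b, ib + 1, ONE_TO_THREE[spec.residues_b[ib]],
            (x0, dist, 0), rotation=_FLIP,
        )
        truth[((spec.chain_a, ia + 1, ""), (spec.chain_b, ib + 1, ""))] = dist
    far_a = [i for i in range(len(spec.residues_a)) if i not in seen_a]
    far_b = [i for i in range(len(spec.residues_b)) if i not in seen_b]
    for n, i in enumerate(far_a):
        _append_residue(
            buf, spec.chain_a, i + 1, ONE_TO_THREE[spec.residues_a[i]],
            (n * spec.cluster_spacing, -4 * spec.cluster_spacing, 0),
        )
    for n, i in enumerate(far_b):
        _append_residue(
            buf, spec.chain_b, i + 1, ONE_TO_THREE[spec.residues_b[i]],
            (n * spec.cluster_spacing, 5 * spec.cluster_spacing, 0), rotation=_FLIP,
        )

    # chain A block first, then chain B, each sorted by residue number
    order = sorted(
        range(len(buf["atom"])),
        key=lambda i: (buf["chain"][i], buf["res_id"][i]),
    )
    structure = make_structure(
        [buf["chain"][i] for i in order],
        [buf["res_id"][i] for i in order],
        [buf["res_name"][i] for i in order],
        [buf["atom"][i] for i in order],
        [buf["element"][i] for i in order],
        np.array([buf["coord"][i] for i in order]),
        label="toy_complex",
    )
    realised = brute_force_contact_pairs(
        structure, [spec.chain_a], [spec.chain_b], spec.cutoff
    )
    if set(realised) != set(truth) or any(
        abs(realised[k] - truth[k]) > 1e-3 for k in truth
    ):
        raise GenerationError("self-check failed: realised contacts differ from spec")
    return structure, truth


# one-letter representatives per class (ic scheme): charged, polar, apolar
_CLASS_LETTERS = {"charged": "E", "polar": "S", "apolar": "L"}


def spec_from_tally_counts(
    counts: dict[str, int], distance: float = 5.0
) -> ToyComplexSpec:
    """Build a spec whose class-pair tally equals ``counts``.

    Keys: cc, cp, ca, pp, pa, aa — e.g. the printed crystal-column
    multiplicities of an antibody-antigen interface.
    """
    pair_classes = {
        "cc": ("charged", "charged"), "cp": ("charged", "polar"),
        "ca": ("charged", "apolar"), "pp": ("polar", "polar"),
        "pa": ("polar", "apolar"), "aa": ("apolar", "apolar"),
    }
    residues_a, residues_b, contacts = [], [], []
    for key, n in counts.items():
        cls_a, cls_b = pair_classes[key]
        for _ in range(n):
            residues_a.append(_CLASS_LETTERS[cls_a])
            residues_b.append(_CLASS_LETTERS[cls_b])
            contacts.append((len(residues_a) - 1, len(residues_b) - 1, distance))
    return ToyComplexSpec(residues_a, residues_b, contacts)


def make_random_complex(
    seed: int, n_res_per_side: int = 8, box: float = 18.0
) -> Structure:
    """Random two-chain toy complex (uniform residue positions in a box).

    No ground truth bundled: intended for oracle-equivalence testing where
    the truth is recomputed by :func:`brute_force_contact_pairs`.
    """
    rng = np.random.default_rng(seed)
    names = sorted(ONE_TO_THREE.values())
    buf = {k: [] for k in ("chain", "res_id", "res_name", "atom", "element", "coord")}
    for chain, offset in (("A", 0.0), ("B", 6.0)):
        for i in range(n_res_per_side):
            center = rng.uniform(0, box, size=3) + np.array([0.0, offset, 0.0])
            angle = rng.uniform(0, 2 * math.pi)
            c, s = math.cos(angle), math.sin(angle)
            rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
            _append_residue(
                buf, chain, i + 1, str(rng.choice(names)), center, rotation=rot
            )
    return make_structure(
        buf["chain"], buf["res_id"], buf["res_name"], buf["atom"],
        buf["element"], np.array(buf["coord"]), label=f"random_{seed}",
    )


# ---------------------------------------------------------------------------
# equilibrium mixtures and chromatograms
# ---------------------------------------------------------------------------

#: study-condition reference mixtures (totals and measured equilibrium
#: species, uM; masses kDa).  Note the antigen mass balance of the measured
#: rows does not close exactly — these are measured, not simulated, numbers.
TRASTUZUMAB_MIXTURE = SpeciesConcentrations(
    total_ab_uM=4.78, total_ag_uM=1.46,
    complex1_uM=1.12, complex2_uM=0.26,
    free_ab_uM=3.37, free_ag_uM=0.08,
    mass_ab_kDa=147.0, mass_ag_kDa=86.4, f=2,
    label="HER2/trastuzumab",
)
PERTUZUMAB_MIXTURE = SpeciesConcentrations(
    total_ab_uM=4.76, total_ag_uM=1.16,
    complex1_uM=0.42, complex2_uM=0.68,
    free_ab_uM=3.36, free_ag_uM=0.04,
    mass_ab_kDa=146.4, mass_ag_kDa=86.4, f=2,
    label="HER2/pertuzumab",
)


@dataclass
class MixtureScenario:
    """A species mixture plus its synthetic chromatogram and ground truth."""

    label: str
    species: SpeciesConcentrations
    chromatogram: _sec.Chromatogram
    truth: dict
    k_site: float | None = None
    rho: float | None = None
    seed: int | None = None


def _species_table(species: SpeciesConcentrations, dA_dc_mab: float, dA_dc_ag: float):
    m_ab, m_ag = species.mass_ab_kDa, species.mass_ag_kDa
    m1, m2 = m_ab + m_ag, m_ab + 2 * m_ag
    dadc_1 = (m_ab * dA_dc_mab + m_ag * dA_dc_ag) / m1
    dadc_2 = (m_ab * dA_dc_mab + 2 * m_ag * dA_dc_ag) / m2
    rows = [
        ("free_ag", m_ag, species.free_ag_uM * m_ag * 1e-3, dA_dc_ag),
        ("free_ab", m_ab, species.free_ab_uM * m_ab * 1e-3, dA_dc_mab),
        ("complex1", m1, species.complex1_uM * m1 * 1e-3, dadc_1),
        ("complex2", m2, species.complex2_uM * m2 * 1e-3, dadc_2),
    ]
    return [
        {"name": n, "mass_kDa": m, "conc_gL": c, "dA_dc": d}
        for n, m, c, d in rows if c > 0
    ]


def make_mixture_scenario(
    k_site: float | None = None,
    rho: float = 1.0,
    species: SpeciesConcentrations | None = None,
    total_ab_uM: float = 4.78,
    total_ag_uM: float = 1.46,
    mass_ab_kDa: float = 147.0,
    mass_ag_kDa: float = 86.4,
    dA_dc_mab: float = DA_DC["mab_tzm"],
    dA_dc_ag: float = DA_DC["antigen"],
    noise_sigma_rel: float = 0.01,
    seed: int = 0,
    label: str = "scenario",
    **chrom_kwargs,
) -> MixtureScenario:
    """Bundle an equilibrium mixture with its synthetic chromatogram.

    Either pass ``k_site`` (and optionally ``rho``) to simulate the species
    from the forward model, or pass measured ``species`` directly (e.g. one
    of the frozen reference mixtures).
    """
    if (k_site is None) == (species is None):
        raise ValidationError("give exactly one of k_site or species")
    if species is None:
        species = simulate_equilibrium(
            k_site, total_ab_uM, total_ag_uM, rho=rho,
            mass_ab_kDa=mass_ab_kDa, mass_ag_kDa=mass_ag_kDa, label=label,
        )
    table = _species_table(species, dA_dc_mab, dA_dc_ag)
    chrom = _sec.simulate_chromatogram(
        table, noise_sigma_rel=noise_sigma_rel, seed=seed, **chrom_kwargs
    )
    ct = species.total_mass_conc_gL
    truth = {
        "species": {row["name"]: row for row in table},
        "mass_fractions": species.species_mass_fractions(),
        "total_mass_conc_gL": ct,
    }
    return MixtureScenario(label, species, chrom, truth, k_site, rho, seed)


def trastuzumab_like_scenario(seed: int = 0, **kw) -> MixtureScenario:
    """Mixture at the trastuzumab study conditions: the heterodimer
    dominates (~0.31 of total protein mass vs ~0.10 for the heterotrimer)."""
    return make_mixture_scenario(
        species=TRASTUZUMAB_MIXTURE, seed=seed,
        dA_dc_mab=DA_DC["mab_tzm"], label="HER2/trastuzumab", **kw,
    )


def pertuzumab_like_scenario(seed: int = 0, **kw) -> MixtureScenario:
    """Mixture at the pertuzumab study conditions: the 2:1 heterotrimer
    dominates (~0.27 of total protein mass vs ~0.12 for the heterodimer)."""
    return make_mixture_scenario(
        species=PERTUZUMAB_MIXTURE, seed=seed,
        dA_dc_mab=DA_DC["mab_pzm"], label="HER2/pertuzumab", **kw,
    )


# ---------------------------------------------------------------------------
# IgG grafting fixture
# ---------------------------------------------------------------------------

def make_igg_fixture(
    symmetric: bool = True, seed: int = 0, arm_angle_deg: float | None = None
) -> Structure:
    """Minimal IgG-like fixture: two light-chain arms, one bound antigen.

    Chain L is the antigen-engaged light chain, chain M the free arm's light
    chain (an exact rigid copy of L, rotated about z by the arm angle), and
    chain G the bound antigen.  ``symmetric=True`` places the arms two-fold
    symmetrically (angle 180 deg), so grafting the antigen onto the free arm
    lands it in the mirror pose, clash-free; a small arm angle (default
    25 deg when ``symmetric=False``) crowds the arms so the grafted antigen
    copy collides with the bound one.
    """
    if arm_angle_deg is None:
        arm_angle_deg = 180.0 if symmetric else 25.0
    rng = np.random.default_rng(seed)
    # arm-local residue centers: a 3-D zigzag light chain and an antigen blob
    light_local = np.array(
        [[12 + 3 * i, 2.0 * (i % 2), float(i % 3)] for i in range(8)]
    )
    phi = np.linspace(0, 2 * math.pi, 7, endpoint=False)
    antigen_local = np.stack(
        [12 + 4 * np.cos(phi), 12 + 4 * np.sin(phi), np.linspace(-2, 2, 7)], axis=1
    )
    light_local = light_local + 0.05 * rng.standard_normal(light_local.shape)
    antigen_local = antigen_local + 0.05 * rng.standard_normal(antigen_local.shape)

    theta = math.radians(arm_angle_deg)
    c, s = math.cos(theta), math.sin(theta)
    rot2 = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])

    buf = {k: [] for k in ("chain", "res_id", "res_name", "atom", "element", "coord")}
    for i, center in enumerate(light_local):
        _append_residue(buf, "L", i + 1, "SER", center)
    for i, center in enumerate(light_local):
        # whole-residue rigid rotation: chain M is an exact rigid copy of L
        _append_residue(buf, "M", i + 1, "SER", rot2 @ center, rotation=rot2)
    for i, center in enumerate(antigen_local):
        _append_residue(buf, "G", i + 1, "GLY", center)
    return make_structure(
        buf["chain"], buf["res_id"], buf["res_name"], buf["atom"],
        buf["element"], np.array(buf["coord"]),
        label=f"igg_fixture_{'sym' if symmetric else 'crowded'}",
    )
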
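"""Frozen reference tables: residue classification, max-ASA references, vdW radii.

Two residue-character schemes are provided.  The ``ic`` scheme is the one
used to type interfacial contacts in the affinity model:

    charged  E D K R
    polar    C H N Q S T W
    apolar   A F G I L V M P Y

The ``nis`` scheme is the surface-characterisation variant historically used
when classifying solvent-exposed (non-interacting-surface) residues: histidine
counts as charged at the surface, cysteine and tryptophan as apolar, tyrosine
as polar.  Both schemes partition the 20 standard residues exactly.
"""

from __future__ import annotations

from enum import Enum


class ResidueClass(str, Enum):
    CHARGED = "charged"
    POLAR = "polar"
    APOLAR = "apolar"


class Scheme(str, Enum):
    IC = "ic"
    NIS = "nis"


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_IC_ONE = {
    "charged": "EDKR",
    "polar": "CHNQSTW",
    "apolar": "AFGILVMPY",
}
_NIS_ONE = {
    "charged": "EDKRH",
    "polar": "NQSTY",
    "apolar": "ACFGILVMPW",
}


def _expand(one_letter_map: dict[str, str]) -> dict[str, ResidueClass]:
    table = {}
    for cls, letters in one_letter_map.items():
        for letter in letters:
            table[ONE_TO_THREE[letter]] = ResidueClass(cls)
    return table


CLASS_TABLES: dict[Scheme, dict[str, ResidueClass]] = {
    Scheme.IC: _expand(_IC_ONE),
    Scheme.NIS: _expand(_NIS_ONE),
}

# Maximum accessible surface area (A^2) of residue X in an extended
# tripeptide, used as the denominator of relative SASA.  "naccess" follows
# the NACCESS-style all-atom maxima; "tien" are the theoretical maxima of
# Tien et al. (2013).
MAX_ASA: dict[str, dict[str, float]] = {
    "naccess": {
        "ALA": 107.95, "ARG": 238.76, "ASN": 143.94, "ASP": 140.39,
        "CYS": 134.28, "GLN": 178.50, "GLU": 172.25, "GLY": 80.10,
        "HIS": 182.88, "ILE": 175.12, "LEU": 178.63, "LYS": 200.81,
        "MET": 194.15, "PHE": 199.48, "PRO": 136.13, "SER": 116.50,
        "THR": 139.27, "TRP": 249.36, "TYR": 212.76, "VAL": 151.44,
    },
    "tien": {
        "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0,
        "CYS": 167.0, "GLN": 225.0, "GLU": 223.0, "GLY": 104.0,
        "HIS": 224.0, "ILE": 197.0, "LEU": 201.0, "LYS": 236.0,
        "MET": 224.0, "PHE": 240.0, "PRO": 159.0, "SER": 155.0,
        "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
    },
}

# Element-wise van der Waals radii (A), Bondi set; frozen for determinism.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

STANDARD_RESIDUES = frozenset(THREE_TO_ONE)
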
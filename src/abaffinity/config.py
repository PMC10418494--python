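"""Run configuration: every tunable in one serialisable record.

The effective configuration (after file + flag overrides) is embedded in
every output record together with its hash, so results are traceable to the
exact parameter set that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class RunConfig:
    contact_cutoff: float = 5.5          # A
    nis_threshold: float = 5.0           # % relative SASA
    ic_scheme: str = "ic"
    nis_scheme: str = "nis"
    coefficient_set: str = "corrected"   # or "printed"
    temperature: float = 309.0           # K
    water_molarity: float = 55.34        # M
    sasa_points: int = 960
    sasa_probe: float = 1.4              # A
    mass_balance_tol: float = 0.05
    dn_dc: float = 0.185                 # mL/g
    seed: int = 0
    detector_constants: dict = field(
        default_factory=lambda: {"k_ri": 1.0, "k_uv": 1.0, "k_ls": 1.0}
    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def override(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **kwargs)
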
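"""Centralised numeric configuration.

Every tunable number in the pipeline lives here so runs are reproducible and
auditable. Values with a literature convention behind them:

* ``coupling_factor`` = 400 — the factor tying each community member's
  reaction fluxes to its biomass flux, the convention of microbiome
  community modelling pipelines.
* ``secretion_flux_threshold`` = 30 mmol/person/day — the cut above which a
  microbial secretion flux counts as "highly secreted" when inspecting the
  urine-maximisation solution vector.
* ``ko_flag_threshold`` = 0.10 — a single-reaction deletion is flagged when
  it reduces the target urine flux by more than 10%.
* ``supplement_amount`` = 300 mmol/d — the maximal intake used when adding a
  candidate metabolite to the diet in the supplementation screen.
* ``min_nonzero`` = 0.5 — prevalence filter for the metabolite screen and
  the fractional abundance regressions (feature must be non-zero/present in
  at least half the samples).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Dict

import yaml


@dataclass
class Config:
    # community assembly
    coupling_factor: float = 400.0
    abundance_cutoff: float = 1e-4
    community_growth_lb: float = 0.4  # per day
    community_growth_ub: float = 1.0  # per day
    # diet
    diet_scale: float = 1.0
    min_growth: float = 1e-6
    supplement_amount: float = 300.0  # mmol/d
    # screens
    secretion_flux_threshold: float = 30.0  # mmol/person/day
    ko_flag_threshold: float = 0.10
    exhaustive_max_candidates: int = 15
    # statistics
    min_nonzero: float = 0.5
    pseudocount: float = 0.5
    robust_cov: str = "HC3"
    fdr_alpha: float = 0.05
    # numerics
    feasibility_tol: float = 1e-6
    determinism_tol: float = 1e-9
    solver: str = "highs"
    # randomness
    seed: int = 0

    def to_dict(self) -> Dict[str, Any]:
        return asdict(self)

    def hash(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


DEFAULT_CONFIG = Config()
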
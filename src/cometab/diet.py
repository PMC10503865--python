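"""Diet application and growth feasibility checks.

A diet is a map metabolite → flux in mmol/person/day. Applying it to a model
opens the diet-facing exchange reactions to uptake up to the dietary amount
(sign convention: uptake is a negative exchange flux) and closes uptake of
every diet-facing metabolite the diet does not provide. Secretion bounds are
never touched.

Diet-facing exchanges are identified by compartment: if the model has a
diet compartment ``[d]`` (community and whole-body models), those exchanges
are diet-facing; otherwise all exchanges on the extracellular compartment
``[e]`` are (single-organism models).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import pandas as pd

from .core import Reaction, StoichiometricModel, split_compartment
from .errors import ValidationError
from .io import DietSpec
from .lp import solve_fba

logger = logging.getLogger(__name__)


def diet_facing_exchanges(model: StoichiometricModel) -> List[Reaction]:
    """Exchange reactions through which the diet enters the model."""
    exchanges = model.exchanges()
    tags = {split_compartment(next(iter(r.stoichiometry)))[1] for r in exchanges}
    tag = "d" if "d" in tags else "e"
    return [
        r for r in exchanges
        if split_compartment(next(iter(r.stoichiometry)))[1] == tag
    ]


def apply_diet(
    model: StoichiometricModel, diet: DietSpec, scale: float = 1.0
) -> StoichiometricModel:
    """Return a copy of ``model`` constrained to the diet.

    For each diet metabolite with an exchange, the exchange lower bound is
    set to ``-scale * flux``; diet-facing exchanges of metabolites absent
    from the diet get lower bound 0. Diet metabolites without a matching
    exchange are logged as warnings, not errors (real diet tables contain
    compounds toy models do not carry).
    """
    if scale < 0:
        raise ValidationError("diet scale must be non-negative")
    out = model.copy()
    facing = diet_facing_exchanges(out)
    seen = set()
    for rxn_tpl in facing:
        rxn = out.reactions[rxn_tpl.id]
        met_id = next(iter(rxn.stoichiometry))
        base = split_compartment(met_id)[0]
        # orient: coefficient -1 means positive flux exports the metabolite
        coef = rxn.stoichiometry[met_id]
        if base in diet.entries:
            uptake = scale * diet.entries[base]
            if coef < 0:
                rxn.lower_bound = -uptake
            else:  # reversed exchange: positive flux imports
                rxn.upper_bound = uptake
            seen.add(base)
        else:
            if coef < 0:
                rxn.lower_bound = 0.0
            else:
                rxn.upper_bound = 0.0
    missing = sorted(set(diet.entries) - seen)
    if missing:
        logger.warning(
            "diet metabolites without an exchange in model %r: %s",
            model.id, missing,
        )
    return out


def supplement_diet(diet: DietSpec, metabolite: str, amount: float) -> DietSpec:
    """Return a copy with ``metabolite`` available at ``max(existing, amount)``."""
    if amount < 0:
        raise ValidationError("supplement amount must be non-negative")
    out = diet.copy()
    if amount == 0 and metabolite not in out.entries:
        return out
    out.entries[metabolite] = max(out.entries.get(metabolite, 0.0), amount)
    return out


def check_growth(
    pan_models: Sequence[StoichiometricModel],
    diet: DietSpec,
    min_growth: float = 1e-6,
    biomass_id: str = "biomassPan",
    scale: float = 1.0,
) -> pd.DataFrame:
    """Maximum biomass flux of every pan model under the diet.

    Returns a DataFrame indexed by model id with columns ``max_growth``,
    ``status`` and ``ok`` (max_growth >= min_growth). Nothing raises; the
    report lists failures so the caller can adjust the diet.
    """
    rows = []
    for model in pan_models:
        constrained = apply_diet(model, diet, scale=scale)
        if biomass_id not in constrained.reactions:
            rows.append({"model": model.id, "max_growth": float("nan"),
                         "status": "no_biomass", "ok": False})
            continue
        sol = solve_fba(constrained, objective=biomass_id, sense="max")
        growth = sol.objective_value if sol.ok else 0.0
        rows.append({
            "model": model.id,
            "max_growth": growth,
            "status": sol.status,
            "ok": bool(sol.ok and growth >= min_growth),
        })
    return pd.DataFrame(rows).set_index("model")
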
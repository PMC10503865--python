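"""Whole-body-style host integration.

A :class:`HostModel` is a multi-compartment stoichiometric model with a
large-intestinal lumen ``[luLI]`` reachable from its diet exchanges and a
urine compartment ``[u]`` with ``EX_<met>[u]`` exchanges. Attaching a
community links the community's microbial lumen ``[luM]`` to ``[luLI]``
through per-metabolite transport reactions and removes the community's own
external (diet and faecal) exchange tiers, so the microbes feed exclusively
from, and secrete exclusively into, the host's intestinal lumen.

The co-metabolism decomposition for a target metabolite compares

* ``germfree_max`` — max urine secretion of the host alone,
* ``personalised_max`` — max urine secretion with the community attached,
* ``microbial_secretion_max`` — max flux of the metabolite's
  ``[luM] -> [luLI]`` transport, i.e. what the microbes can deliver directly,

and reports ``delta = personalised_max - germfree_max`` and
``cometabolism_residual = delta - microbial_secretion_max``: the part of the
gain the host must synthesise itself from microbially supplied precursors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .community import (
    COMMUNITY_BIOMASS_ID,
    DIET_TAG,
    FECAL_TAG,
    LUMEN_TAG,
    CommunityModel,
)
from .core import Metabolite, Reaction, StoichiometricModel, split_compartment
from .errors import InfeasibleModelError, ValidationError
from .io import DietSpec
from .lp import FluxSolution, solve_fba

logger = logging.getLogger(__name__)

HOST_LUMEN_TAG = "luLI"
URINE_TAG = "u"
MICRO_TRANSPORT_PREFIX = "Micro_EX_"


@dataclass
class HostModel:
    """A sex-specific multi-organ host model."""

    base: StoichiometricModel
    sex: str = "male"
    lumen_tag: str = HOST_LUMEN_TAG
    urine_tag: str = URINE_TAG
    organ_tags: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")

    def urine_exchange_id(self, metabolite_base: str) -> str:
        return f"EX_{metabolite_base}[{self.urine_tag}]"


def microbial_transport_id(metabolite_base: str) -> str:
    """Id of the ``[luM] -> [luLI]`` transport for one metabolite."""
    return f"{MICRO_TRANSPORT_PREFIX}{metabolite_base}"


@dataclass
class CoMetabolismReport:
    """Decomposition of the urine secretion gain for one metabolite."""

    metabolite: str
    germfree_max: float
    personalised_max: float
    microbial_secretion_max: float
    delta: float = 0.0
    cometabolism_residual: float = 0.0

    def __post_init__(self) -> None:
        self.delta = self.personalised_max - self.germfree_max
        self.cometabolism_residual = self.delta - self.microbial_secretion_max


# ---------------------------------------------------------------------------
# attachment
# ---------------------------------------------------------------------------

def attach_community(host: HostModel, community: CommunityModel) -> StoichiometricModel:
    """Merge a community model into the host's intestinal lumen.

    The community's ``[d]`` and ``[fe]`` tiers are removed (only the
    community biomass sink is kept); every metabolite present in both the
    microbial and the host lumen gets a reversible transport
    ``met[luM] <-> met[luLI]``. Metabolites the host lumen does not carry
    are skipped with a logged warning. Coupling rows are preserved.
    """
    combined = host.base.copy()
    combined.id = f"{host.base.id}+{community.base.id}"

    biomass_sink = f"EX_microbeBiomass[{FECAL_TAG}]"
    drop_rxns = set()
    drop_mets = set()
    for met_id in community.base.metabolites:
        tag = split_compartment(met_id)[1]
        if tag in (DIET_TAG, FECAL_TAG) and met_id != f"microbeBiomass[{FECAL_TAG}]":
            drop_mets.add(met_id)
    for rid, rxn in community.base.reactions.items():
        if rid == biomass_sink:
            continue
        if any(m in drop_mets for m in rxn.stoichiometry):
            drop_rxns.add(rid)

    clash = [r for r in community.base.reactions
             if r not in drop_rxns and r in combined.reactions]
    if clash:
        raise ValidationError(f"reaction id clash between host and community: {clash[:5]}")

    for met in community.base.metabolites.values():
        if met.id in drop_mets or met.id in combined.metabolites:
            continue
        combined.add_metabolite(Metabolite(met.id, name=met.name, compartment=met.compartment))
    for rid, rxn in community.base.reactions.items():
        if rid in drop_rxns:
            continue
        combined.add_reaction(rxn.copy())
    for con in community.base.extra_constraints:
        if any(r in drop_rxns for r in con.coefficients):
            continue
        combined.add_constraint(con)

    # link [luM] to [luLI] per shared metabolite
    skipped = []
    for met_id in community.base.metabolites:
        base_id, tag = split_compartment(met_id)
        if tag != LUMEN_TAG or base_id == "microbeBiomass":
            continue
        host_met = f"{base_id}[{host.lumen_tag}]"
        if host_met not in combined.metabolites:
            skipped.append(base_id)
            continue
        combined.add_reaction(
            Reaction(
                microbial_transport_id(base_id),
                {met_id: -1.0, host_met: 1.0},
                lower_bound=-1000.0,
                upper_bound=1000.0,
                subsystem="transport, microbiome-host",
            )
        )
    if skipped:
        logger.warning(
            "no host lumen metabolite for %s; transports skipped", sorted(skipped)
        )
    combined.validate()
    return combined


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def max_urine_secretion(model: StoichiometricModel, metabolite: str) -> float:
    """FBA maximum of the urine exchange ``EX_<met>[u]`` under the current diet."""
    rid = f"EX_{metabolite}[{URINE_TAG}]"
    if rid not in model.reactions:
        raise ValidationError(f"no urine exchange {rid!r} in model {model.id!r}")
    sol = solve_fba(model, objective=rid, sense="max")
    if not sol.ok:
        raise InfeasibleModelError(
            f"maximising {rid} returned status {sol.status} on {model.id!r}"
        )
    return sol.objective_value


def max_microbial_secretion(model: StoichiometricModel, metabolite: str) -> float:
    """Maximal delivery of a metabolite from the microbial lumen to the host.

    The transport is oriented ``[luM] -> [luLI]``, so the extremal flux in
    the microbiome→host direction is its maximum; the magnitude is reported
    and floored at zero (a negative maximum would mean the microbes can only
    take the metabolite up).
    """
    rid = microbial_transport_id(metabolite)
    if rid not in model.reactions:
        raise ValidationError(
            f"no microbiome-host transport {rid!r} in model {model.id!r}"
        )
    sol = solve_fba(model, objective=rid, sense="max")
    if not sol.ok:
        raise InfeasibleModelError(
            f"maximising {rid} returned status {sol.status} on {model.id!r}"
        )
    return max(0.0, sol.objective_value)


def cometabolism_decomposition(
    host: HostModel,
    community: CommunityModel,
    diet: DietSpec,
    metabolite: str,
    diet_scale: float = 1.0,
) -> CoMetabolismReport:
    """Germ-free vs personalised urine maxima and the microbial share.

    Diet is applied at the host level (the community feeds from ``[luLI]``).
    """
    from .diet import apply_diet

    germfree = apply_diet(host.base, diet, scale=diet_scale)
    gf_max = max_urine_secretion(germfree, metabolite)

    combined = attach_community(host, community)
    combined = apply_diet(combined, diet, scale=diet_scale)
    pers_max = max_urine_secretion(combined, metabolite)
    if microbial_transport_id(metabolite) in combined.reactions:
        micro_max = max_microbial_secretion(combined, metabolite)
    else:
        micro_max = 0.0
    return CoMetabolismReport(
        metabolite=metabolite,
        germfree_max=gf_max,
        personalised_max=pers_max,
        microbial_secretion_max=micro_max,
    )


def high_secretors(
    solution: FluxSolution,
    community: CommunityModel,
    threshold: float = 30.0,
) -> List[str]:
    """Metabolites whose ``[luM] -> [luLI]`` flux in ``solution`` exceeds
    ``threshold`` mmol/person/day (microbiome→host direction)."""
    out = []
    prefix = MICRO_TRANSPORT_PREFIX
    for rid, flux in solution.fluxes.items():
        if rid.startswith(prefix) and flux > threshold:
            out.append(rid[len(prefix):])
    return sorted(out)


def per_sample_results_frame(rows: Sequence[dict]) -> pd.DataFrame:
    """Standard per-sample results table for the host runs."""
    cols = ["sample", "sex", "status", "germfree_max", "personalised_max",
            "microbial_secretion_max", "residual"]
    df = pd.DataFrame(list(rows))
    return df[[c for c in cols if c in df.columns]]
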
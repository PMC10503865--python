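"""Sample-personalised microbiome community models.

A community model namespaces every member species' reactions and metabolites,
rewires each member's extracellular metabolites into one shared microbial
lumen compartment ``[luM]``, connects the lumen to the outside through a
two-tier exchange (diet compartment ``[d]`` → lumen, lumen → faecal
compartment ``[fe]``), and adds:

* ``communityBiomass`` — consumes each species' biomass metabolite weighted
  by that species' relative abundance in the sample, producing one unit of
  community biomass; its flux is bounded to the configured community growth
  window so the coupling constraints bind meaningfully.
* **coupling rows** — for every reaction *j* of species *i*,
  ``v_j <= c * v_biomass,i`` and ``v_j >= -c * v_biomass,i`` with coupling
  factor ``c`` (default 400), so a species whose biomass flux is zero can
  carry no flux at all.

Sign convention throughout: uptake = negative exchange flux, secretion =
positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import Config, DEFAULT_CONFIG
from .core import LinearConstraint, Metabolite, Reaction, StoichiometricModel, split_compartment
from .diet import apply_diet
from .errors import InfeasibleModelError, ValidationError
from .io import AbundanceTable, DietSpec
from .lp import fva
from .pan import PAN_BIOMASS_ID

logger = logging.getLogger(__name__)

NAMESPACE_SEP = "__"
COMMUNITY_BIOMASS_ID = "communityBiomass"
LUMEN_TAG = "luM"
DIET_TAG = "d"
FECAL_TAG = "fe"


def namespace_id(species: str, raw_id: str) -> str:
    return f"{species}{NAMESPACE_SEP}{raw_id}"


def denamespace_id(namespaced: str) -> Tuple[str, str]:
    """Inverse of :func:`namespace_id`; exact on species ids without ``__``."""
    species, sep, raw = namespaced.partition(NAMESPACE_SEP)
    if not sep:
        raise ValidationError(f"{namespaced!r} is not a namespaced id")
    return species, raw


@dataclass
class CommunityModel:
    """A namespaced multi-species model with coupling rows."""

    base: StoichiometricModel
    species: List[Tuple[str, float]]  # (species_id, relative abundance)
    coupling_factor: float = 400.0
    biomass_reaction_id: str = COMMUNITY_BIOMASS_ID
    lumen_tag: str = LUMEN_TAG
    fecal_exchange_prefix: str = "EX_"
    species_biomass: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.species:
            total = sum(a for _, a in self.species)
            if abs(total - 1.0) > 1e-6:
                raise ValidationError(
                    f"community abundances must sum to 1, got {total:.12g}"
                )
            for sp, a in self.species:
                if not (0 < a <= 1):
                    raise ValidationError(f"abundance of {sp!r} outside (0,1]: {a}")

    def fecal_exchange_id(self, metabolite_base: str) -> str:
        return f"{self.fecal_exchange_prefix}{metabolite_base}[{FECAL_TAG}]"


class SecretionProfile(dict):
    """Metabolite base id → maximal net secretion (mmol/person/day, >= 0)."""

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.flagged: List[str] = []  # metabolites whose raw FVA max was < 0


# ---------------------------------------------------------------------------
# abundance filtering
# ---------------------------------------------------------------------------

def filter_and_renormalize(
    table: AbundanceTable,
    covered_species: Iterable[str],
    cutoff: float = DEFAULT_CONFIG.abundance_cutoff,
) -> Tuple[AbundanceTable, pd.Series]:
    """Restrict to model-covered species, apply the low-abundance cutoff,
    and renormalise each sample to sum to one.

    Returns the filtered relative table and per-sample coverage — the
    fraction of the original reads assigned to covered species. Species
    whose relative abundance (after the first renormalisation) falls below
    ``cutoff`` in a sample are removed from that sample.
    """
    covered = [s for s in table.species if s in set(covered_species)]
    if not covered:
        raise ValidationError("no species in the table are covered by models")
    rel = table.normalize() if table.mode == "counts" else table
    coverage = rel.values[covered].sum(axis=1)
    dead = coverage[coverage <= 0]
    if len(dead):
        raise ValidationError(
            f"samples with zero covered reads: {list(dead.index)}"
        )
    sub = rel.values[covered].div(coverage, axis=0)
    # per-sample low-abundance cutoff, then renormalise the survivors
    sub = sub.where(sub >= cutoff, 0.0)
    totals = sub.sum(axis=1)
    empty = totals[totals <= 0]
    if len(empty):
        raise ValidationError(
            f"samples with no species above the cutoff: {list(empty.index)}"
        )
    sub = sub.div(totals, axis=0)
    sub = sub.loc[:, sub.sum(axis=0) > 0]
    out = AbundanceTable(values=sub, mode="relative")
    coverage.name = "coverage"
    return out, coverage


# ---------------------------------------------------------------------------
# community assembly
# ---------------------------------------------------------------------------

def _species_biomass_product(model: StoichiometricModel, biomass_id: str) -> str:
    rxn = model.reactions[biomass_id]
    products = [m for m, c in rxn.stoichiometry.items() if c > 0]
    for m in products:
        if "biomass" in split_compartment(m)[0].lower():
            return m
    return products[0] if products else ""


def build_community(
    pan_models: Mapping[str, StoichiometricModel],
    abundances: Mapping[str, float] | pd.Series,
    coupling_factor: float = DEFAULT_CONFIG.coupling_factor,
    config: Config = DEFAULT_CONFIG,
    community_id: str = "community",
) -> CommunityModel:
    """Assemble one sample's community model from pan models and relative
    abundances.

    Species with zero abundance are skipped; species present in the
    abundances but lacking a model raise.
    """
    if isinstance(abundances, pd.Series):
        abundances = abundances.to_dict()
    members = [(sp, float(a)) for sp, a in abundances.items() if a > 0]
    missing = sorted(sp for sp, _ in members if sp not in pan_models)
    if missing:
        raise ValidationError(f"species without a pan model: {missing}")
    for sp, _ in members:
        if NAMESPACE_SEP in sp:
            raise ValidationError(
                f"species id {sp!r} contains the namespace separator {NAMESPACE_SEP!r}"
            )

    base = StoichiometricModel(id=community_id)
    lumen_bases: Dict[str, str] = {}  # base id -> lumen metabolite full id
    species_biomass: Dict[str, str] = {}

    def ensure_lumen(base_id: str) -> str:
        full = f"{base_id}[{LUMEN_TAG}]"
        if full not in base.metabolites:
            base.add_metabolite(Metabolite(full))
            lumen_bases[base_id] = full
        return full

    for sp, _abundance in members:
        model = pan_models[sp]
        bio_product_raw = None
        if PAN_BIOMASS_ID not in model.reactions:
            raise ValidationError(f"pan model for {sp!r} lacks {PAN_BIOMASS_ID!r}")
        bio_product_raw = _species_biomass_product(model, PAN_BIOMASS_ID)

        def ns_met(met_id: str) -> str:
            base_id, tag = split_compartment(met_id)
            if tag == "e":
                return ensure_lumen(base_id)
            return namespace_id(sp, met_id)

        for met in model.metabolites.values():
            nsid = ns_met(met.id)
            if nsid not in base.metabolites:
                base.add_metabolite(
                    Metabolite(nsid, name=met.name, compartment=split_compartment(nsid)[1] or met.compartment)
                )
        for rxn in model.reactions.values():
            tags = {split_compartment(m)[1] for m in rxn.stoichiometry}
            if rxn.is_exchange and tags == {"e"}:
                continue  # species-level boundary exchanges are replaced by lumen machinery
            base.add_reaction(
                Reaction(
                    id=namespace_id(sp, rxn.id),
                    stoichiometry={ns_met(m): c for m, c in rxn.stoichiometry.items()},
                    lower_bound=rxn.lower_bound,
                    upper_bound=rxn.upper_bound,
                    name=rxn.name,
                    subsystem=rxn.subsystem,
                )
            )
        if not bio_product_raw:
            # biomass reaction with no product: give it an explicit biomass metabolite
            bio_product = namespace_id(sp, "biomass[c]")
            base.add_metabolite(Metabolite(bio_product))
            base.reactions[namespace_id(sp, PAN_BIOMASS_ID)].stoichiometry[bio_product] = 1.0
        else:
            bio_product = ns_met(bio_product_raw)
        species_biomass[sp] = bio_product

    # two-tier external exchange per lumen metabolite: [d] -> [luM] -> [fe]
    for base_id, lumen_full in sorted(lumen_bases.items()):
        d_met, fe_met = f"{base_id}[{DIET_TAG}]", f"{base_id}[{FECAL_TAG}]"
        base.add_metabolite(Metabolite(d_met))
        base.add_metabolite(Metabolite(fe_met))
        base.add_reaction(Reaction(f"EX_{base_id}[d]", {d_met: -1.0},
                                   lower_bound=-1000.0, upper_bound=1000.0,
                                   subsystem="exchange"))
        base.add_reaction(Reaction(f"DUt_{base_id}", {d_met: -1.0, lumen_full: 1.0},
                                   lower_bound=0.0, upper_bound=1000.0,
                                   subsystem="transport, diet"))
        base.add_reaction(Reaction(f"UFEt_{base_id}", {lumen_full: -1.0, fe_met: 1.0},
                                   lower_bound=0.0, upper_bound=1000.0,
                                   subsystem="transport, fecal"))
        base.add_reaction(Reaction(f"EX_{base_id}[fe]", {fe_met: -1.0},
                                   lower_bound=0.0, upper_bound=1000.0,
                                   subsystem="exchange, fecal"))

    # abundance-weighted community biomass
    cb_met = f"microbeBiomass[{LUMEN_TAG}]"
    base.add_metabolite(Metabolite(cb_met, name="community microbial biomass"))
    stoich = {species_biomass[sp]: -a for sp, a in members}
    stoich[cb_met] = 1.0
    base.add_reaction(
        Reaction(
            COMMUNITY_BIOMASS_ID, stoich,
            lower_bound=config.community_growth_lb if members else 0.0,
            upper_bound=config.community_growth_ub,
            name="abundance-weighted community biomass",
            subsystem="biomass",
        )
    )
    base.add_reaction(
        Reaction(f"EX_microbeBiomass[{FECAL_TAG}]", {cb_met: -1.0},
                 lower_bound=0.0, upper_bound=1000.0, subsystem="exchange, fecal")
    )

    # coupling rows: every species reaction vs that species' biomass flux
    for sp, _a in members:
        bio_rxn = namespace_id(sp, PAN_BIOMASS_ID)
        prefix = sp + NAMESPACE_SEP
        for rid in base.reactions:
            if not rid.startswith(prefix) or rid == bio_rxn:
                continue
            base.add_constraint(LinearConstraint(
                {rid: 1.0, bio_rxn: -coupling_factor}, "<=", 0.0,
                name=f"couple_ub::{rid}"))
            base.add_constraint(LinearConstraint(
                {rid: -1.0, bio_rxn: -coupling_factor}, "<=", 0.0,
                name=f"couple_lb::{rid}"))

    base.objective = COMMUNITY_BIOMASS_ID
    base.validate()
    return CommunityModel(
        base=base,
        species=list(members),
        coupling_factor=coupling_factor,
        species_biomass=species_biomass,
    )


# ---------------------------------------------------------------------------
# secretion capacity
# ---------------------------------------------------------------------------

def secretion_profile(
    community: CommunityModel,
    diet: DietSpec,
    metabolites: Sequence[str],
    scale: float = 1.0,
) -> SecretionProfile:
    """Maximal net secretion capacity per metabolite under the diet.

    The net secretion of a metabolite is the FVA maximum of its faecal
    exchange flux. Zero means the community cannot secrete it; raw negative
    maxima (forced consumption) are floored at zero and flagged.
    """
    model = apply_diet(community.base, diet, scale=scale)
    targets = {}
    for met in metabolites:
        rid = community.fecal_exchange_id(met)
        targets[met] = rid if rid in model.reactions else None
    present = [r for r in targets.values() if r is not None]
    try:
        res = fva(model, present)
    except InfeasibleModelError as exc:
        raise InfeasibleModelError(
            f"community {community.base.id!r} infeasible under the diet; "
            "run check_growth on the member pan models"
        ) from exc
    profile = SecretionProfile()
    for met, rid in targets.items():
        if rid is None:
            profile[met] = 0.0
            continue
        raw_max = res.maximum(rid)
        if raw_max < 0:
            profile.flagged.append(met)
            logger.warning("negative net secretion maximum for %r floored at 0", met)
        profile[met] = max(0.0, raw_max)
    return profile


def secretion_profile_frame(profiles: Mapping[str, SecretionProfile]) -> pd.DataFrame:
    """Long-format table (sample, metabolite, max_secretion) for reporting."""
    rows = [
        {"sample": sample, "metabolite": met, "max_secretion": flux}
        for sample, prof in profiles.items()
        for met, flux in sorted(prof.items())
    ]
    return pd.DataFrame(rows)
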
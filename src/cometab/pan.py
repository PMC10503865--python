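"""Pan-species model construction.

A pan-species model is the union of the reactions and metabolites of every
strain-level reconstruction of one species. Shared reactions must agree on
stoichiometry; their bounds are widened to the union interval so every
capability of any strain is retained. Strain biomass reactions are merged
into a single ``biomassPan`` reaction whose precursor coefficients are the
mean over the strains that carry each precursor — a declared convention (the
merge rule is not dictated by the underlying modelling framework).
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence

from .core import Metabolite, Reaction, StoichiometricModel
from .errors import ValidationError

PAN_BIOMASS_ID = "biomassPan"


def _is_biomass(rxn_id: str) -> bool:
    return "biomass" in rxn_id.lower()


def build_pan_model(
    strain_models: Sequence[StoichiometricModel], species_id: str
) -> StoichiometricModel:
    """Union the reactions/metabolites of the strain models of one species.

    Parameters
    ----------
    strain_models:
        One or more strain-level models. Each must contain exactly one
        biomass reaction (id containing ``biomass``, case-insensitive).
    species_id:
        Id of the resulting pan model.

    Raises
    ------
    ValidationError
        With zero strains, or when two strains share a reaction id with
        different stoichiometry.
    """
    if len(strain_models) == 0:
        raise ValidationError("cannot build a pan model from zero strains")

    pan = StoichiometricModel(id=species_id)
    biomass_terms: List[Dict[str, float]] = []
    biomass_bounds: List[tuple] = []

    for strain in strain_models:
        bio_ids = [r for r in strain.reactions if _is_biomass(r)]
        if len(bio_ids) != 1:
            raise ValidationError(
                f"strain {strain.id!r} must have exactly one biomass reaction, "
                f"found {bio_ids}"
            )
        for met in strain.metabolites.values():
            if met.id not in pan.metabolites:
                pan.add_metabolite(Metabolite(met.id, name=met.name, compartment=met.compartment))
        for rxn in strain.reactions.values():
            if rxn.id in bio_ids:
                biomass_terms.append(dict(rxn.stoichiometry))
                biomass_bounds.append((rxn.lower_bound, rxn.upper_bound))
                continue
            if rxn.id in pan.reactions:
                existing = pan.reactions[rxn.id]
                if existing.stoichiometry != rxn.stoichiometry:
                    raise ValidationError(
                        f"conflicting stoichiometry for shared reaction {rxn.id!r} "
                        f"while building pan model {species_id!r}"
                    )
                # widest-interval rule: union of strain capabilities
                existing.lower_bound = min(existing.lower_bound, rxn.lower_bound)
                existing.upper_bound = max(existing.upper_bound, rxn.upper_bound)
            else:
                pan.add_reaction(rxn.copy())

    # merged biomass: union of precursor terms, coefficient = mean over the
    # strains that carry the term
    merged: Dict[str, float] = {}
    counts: Dict[str, int] = {}
    for terms in biomass_terms:
        for met_id, coef in terms.items():
            merged[met_id] = merged.get(met_id, 0.0) + coef
            counts[met_id] = counts.get(met_id, 0) + 1
    merged = {m: merged[m] / counts[m] for m in merged}
    for met_id in merged:
        if met_id not in pan.metabolites:
            pan.add_metabolite(Metabolite(met_id))
    lb = min(b[0] for b in biomass_bounds)
    ub = max(b[1] for b in biomass_bounds)
    pan.add_reaction(
        Reaction(
            id=PAN_BIOMASS_ID,
            stoichiometry=merged,
            lower_bound=lb,
            upper_bound=ub,
            name=f"pan biomass of {species_id}",
            subsystem="biomass",
        )
    )
    pan.objective = PAN_BIOMASS_ID
    pan.objective_sense = "max"
    pan.validate()
    return pan
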
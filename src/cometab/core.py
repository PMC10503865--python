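"""Core stoichiometric data structures.

A :class:`StoichiometricModel` is the universal substrate for all LP work in
this package: a list of metabolites (rows of S), a list of reactions (columns
of S, each with flux bounds), and optional extra linear inequality rows over
the flux vector (used for community coupling constraints).

Identifier convention: a metabolite's full id is ``base[tag]`` where ``tag``
names the compartment, matching the VMH style used for whole-body models
(e.g. ``for[u]`` is formate in the urine compartment, ``glc_D[luLI]`` is
D-glucose in the large-intestinal lumen).
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from scipy import sparse

from .errors import ValidationError

_COMPARTMENT_RE = re.compile(r"^(?P<base>.+)\[(?P<tag>[A-Za-z0-9_]+)\]$")

DEFAULT_BOUND = 1000.0


def split_compartment(met_id: str) -> Tuple[str, str]:
    """Split a full metabolite id ``base[tag]`` into ``(base, tag)``.

    Ids without a bracketed tag get the empty-string compartment.
    """
    m = _COMPARTMENT_RE.match(met_id)
    if m is None:
        return met_id, ""
    return m.group("base"), m.group("tag")


@dataclass
class Metabolite:
    """A metabolite in one compartment; ``id`` is the full ``base[tag]`` id."""

    id: str
    name: str = ""
    compartment: Optional[str] = None

    def __post_init__(self) -> None:
        if self.compartment is None:
            self.compartment = split_compartment(self.id)[1]

    @property
    def base_id(self) -> str:
        return split_compartment(self.id)[0]


@dataclass
class Reaction:
    """A reaction: stoichiometry over full metabolite ids plus flux bounds.

    Negative coefficients are consumed, positive produced. Bounds are in
    mmol/person/day for host- and community-level exchange reactions, and in
    mmol/gDW/h for within-organism reactions of the toy models; the LP does
    not care about the unit, only the modeller does.
    """

    id: str
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    subsystem: str = ""

    @property
    def is_exchange(self) -> bool:
        """Boundary reaction touching exactly one metabolite."""
        return len(self.stoichiometry) == 1

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            name=self.name,
            subsystem=self.subsystem,
        )


@dataclass
class LinearConstraint:
    """One extra linear row over reaction fluxes: ``sum(c_j v_j) sense rhs``."""

    coefficients: Dict[str, float]
    sense: str  # one of "<=", ">=", "="
    rhs: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.sense not in ("<=", ">=", "="):
            raise ValidationError(f"unknown constraint sense {self.sense!r}")


class StoichiometricModel:
    """A constraint-based metabolic model.

    Parameters
    ----------
    id:
        Free-text model identifier.
    metabolites, reactions:
        Iterables of :class:`Metabolite` / :class:`Reaction`; insertion order
        defines the row/column order of S.
    extra_constraints:
        Additional linear rows over fluxes (e.g. coupling constraints).
    objective:
        Reaction id to optimise by default; ``objective_sense`` in
        ``{"max", "min"}``.
    """

    def __init__(
        self,
        id: str = "model",
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        extra_constraints: Iterable[LinearConstraint] = (),
        objective: Optional[str] = None,
        objective_sense: str = "max",
    ) -> None:
        self.id = id
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        self.extra_constraints: List[LinearConstraint] = []
        self.objective = objective
        self.objective_sense = objective_sense
        for met in metabolites:
            self.add_metabolite(met)
        for rxn in reactions:
            self.add_reaction(rxn)
        for con in extra_constraints:
            self.add_constraint(con)

    # -- construction ------------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction, add_missing_metabolites: bool = False) -> None:
        if rxn.id in self.reactions:
            raise ValidationError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                if add_missing_metabolites:
                    self.add_metabolite(Metabolite(met_id))
                else:
                    raise ValidationError(
                        f"reaction {rxn.id!r} references undeclared metabolite {met_id!r}"
                    )
        self.reactions[rxn.id] = rxn

    def add_constraint(self, con: LinearConstraint) -> None:
        unknown = [r for r in con.coefficients if r not in self.reactions]
        if unknown:
            raise ValidationError(
                f"constraint {con.name!r} references unknown reactions: {sorted(unknown)}"
            )
        self.extra_constraints.append(con)

    # -- views -------------------------------------------------------------

    @property
    def compartments(self) -> List[str]:
        return sorted({m.compartment or "" for m in self.metabolites.values()})

    def reaction_ids(self) -> List[str]:
        return list(self.reactions)

    def metabolite_ids(self) -> List[str]:
        return list(self.metabolites)

    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def stoichiometric_matrix(self) -> Tuple[sparse.csr_matrix, List[str], List[str]]:
        """Return ``(S, metabolite_ids, reaction_ids)`` with S in CSR form."""
        met_ids = self.metabolite_ids()
        rxn_ids = self.reaction_ids()
        met_index = {m: i for i, m in enumerate(met_ids)}
        rows, cols, data = [], [], []
        for j, rid in enumerate(rxn_ids):
            for met_id, coef in self.reactions[rid].stoichiometry.items():
                rows.append(met_index[met_id])
                cols.append(j)
                data.append(float(coef))
        S = sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
        )
        return S, met_ids, rxn_ids

    def bounds_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions.values()], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions.values()], dtype=float)
        return lb, ub

    # -- maintenance -------------------------------------------------------

    def copy(self) -> "StoichiometricModel":
        return _copy.deepcopy(self)

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any structural invariant breach."""
        for rxn in self.reactions.values():
            if rxn.lower_bound > rxn.upper_bound + 1e-12:
                raise ValidationError(
                    f"reaction {rxn.id!r} has lower_bound > upper_bound"
                )
            if not rxn.stoichiometry:
                raise ValidationError(f"reaction {rxn.id!r} has empty stoichiometry")
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ValidationError(
                        f"reaction {rxn.id!r} references undeclared metabolite {met_id!r}"
                    )
        for con in self.extra_constraints:
            for rid in con.coefficients:
                if rid not in self.reactions:
                    raise ValidationError(
                        f"constraint {con.name!r} references unknown reaction {rid!r}"
                    )
        if self.objective is not None and self.objective not in self.reactions:
            raise ValidationError(f"objective reaction {self.objective!r} not in model")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<StoichiometricModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.extra_constraints)} extra rows>"
        )
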
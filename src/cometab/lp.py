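"""Deterministic LP layer: flux balance analysis (FBA) and flux variability
analysis (FVA) over a :class:`~cometab.core.StoichiometricModel`.

The feasible region is ``{v : S v = 0, lb <= v <= ub, extra rows}``, i.e.
steady-state mass balance plus flux bounds plus any extra linear inequality
rows (community coupling constraints compile to such rows). All solves go
through scipy's HiGHS interior-free simplex/dual implementation with fixed
options, so repeated runs return bit-identical optima.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .config import DEFAULT_CONFIG
from .core import StoichiometricModel
from .errors import InfeasibleModelError, ValidationError

__all__ = [
    "FluxSolution",
    "FVAResult",
    "solve_fba",
    "fva",
    "delete_reactions",
    "assert_feasible",
]


@dataclass
class FluxSolution:
    """Outcome of one FBA solve.

    ``status`` is one of ``optimal``, ``infeasible``, ``unbounded``;
    ``objective_value`` and ``fluxes`` are meaningful only when optimal.
    """

    objective_value: Optional[float]
    fluxes: Dict[str, float]
    status: str

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


class FVAResult(dict):
    """Mapping reaction-id -> (min_flux, max_flux)."""

    def minimum(self, rid: str) -> float:
        return self[rid][0]

    def maximum(self, rid: str) -> float:
        return self[rid][1]


def _assemble(model: StoichiometricModel):
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    idx = {r: j for j, r in enumerate(rxn_ids)}
    rows_ub, rhs_ub = [], []
    rows_eq, rhs_eq = [], []
    n = len(rxn_ids)
    for con in model.extra_constraints:
        row = np.zeros(n)
        for rid, coef in con.coefficients.items():
            row[idx[rid]] = coef
        if con.sense == "<=":
            rows_ub.append(row)
            rhs_ub.append(con.rhs)
        elif con.sense == ">=":
            rows_ub.append(-row)
            rhs_ub.append(-con.rhs)
        else:
            rows_eq.append(row)
            rhs_eq.append(con.rhs)
    A_eq = S
    b_eq = np.zeros(S.shape[0])
    if rows_eq:
        A_eq = sparse.vstack([S, sparse.csr_matrix(np.array(rows_eq))])
        b_eq = np.concatenate([b_eq, np.array(rhs_eq)])
    A_ub = sparse.csr_matrix(np.array(rows_ub)) if rows_ub else None
    b_ub = np.array(rhs_ub) if rows_ub else None
    return A_eq, b_eq, A_ub, b_ub, lb, ub, rxn_ids, idx


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _solve(model: StoichiometricModel, c: np.ndarray, assembled=None) -> Tuple[str, Optional[float], Optional[np.ndarray], Sequence[str]]:
    if assembled is None:
        assembled = _assemble(model)
    A_eq, b_eq, A_ub, b_ub, lb, ub, rxn_ids, _ = assembled
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=list(zip(lb, ub)),
        method="highs",
        options={"presolve": True},
    )
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return status, None, None, rxn_ids
    return status, float(res.fun), res.x, rxn_ids


def solve_fba(
    model: StoichiometricModel,
    objective: Optional[str] = None,
    sense: Optional[str] = None,
) -> FluxSolution:
    """Maximise or minimise one reaction flux subject to S v = 0, bounds and
    extra constraint rows.

    Infeasibility and unboundedness are reported through ``status``, never as
    silent zeros.
    """
    objective = objective if objective is not None else model.objective
    sense = sense if sense is not None else model.objective_sense
    if objective is None:
        raise ValidationError("no objective reaction given")
    if objective not in model.reactions:
        raise ValidationError(f"objective reaction {objective!r} not in model")
    if sense not in ("max", "min"):
        raise ValidationError(f"objective sense must be 'max' or 'min', got {sense!r}")
    assembled = _assemble(model)
    rxn_ids = assembled[6]
    n = len(rxn_ids)
    c = np.zeros(n)
    c[assembled[7][objective]] = -1.0 if sense == "max" else 1.0
    status, fun, x, _ = _solve(model, c, assembled)
    if status != "optimal":
        return FluxSolution(None, {}, status)
    obj = -fun if sense == "max" else fun
    return FluxSolution(obj, dict(zip(rxn_ids, x.tolist())), "optimal")


def assert_feasible(model: StoichiometricModel) -> None:
    """Raise :class:`InfeasibleModelError` if the flux polytope is empty."""
    assembled = _assemble(model)
    c = np.zeros(len(assembled[6]))
    status, _, _, _ = _solve(model, c, assembled)
    if status == "infeasible":
        raise InfeasibleModelError(
            f"model {model.id!r} is infeasible under the current constraints; "
            "run the diet/growth feasibility check"
        )


def fva(model: StoichiometricModel, reaction_ids: Iterable[str]) -> FVAResult:
    """Min and max flux per reaction over the model's feasible region.

    Raises before any per-reaction solve when the model is infeasible.
    Unbounded directions are reported as ``±inf``.
    """
    reaction_ids = list(reaction_ids)
    unknown = [r for r in reaction_ids if r not in model.reactions]
    if unknown:
        raise ValidationError(f"unknown reactions in FVA request: {sorted(unknown)}")
    assembled = _assemble(model)
    rxn_ids, idx = assembled[6], assembled[7]
    n = len(rxn_ids)
    c0 = np.zeros(n)
    status, _, _, _ = _solve(model, c0, assembled)
    if status == "infeasible":
        raise InfeasibleModelError(f"model {model.id!r} infeasible; FVA aborted")
    result = FVAResult()
    for rid in reaction_ids:
        j = idx[rid]
        lo_hi = []
        for sign in (1.0, -1.0):
            c = np.zeros(n)
            c[j] = sign
            st, fun, _, _ = _solve(model, c, assembled)
            if st == "unbounded":
                lo_hi.append(-np.inf if sign == 1.0 else np.inf)
            elif st != "optimal":
                raise InfeasibleModelError(
                    f"FVA subproblem for {rid!r} returned status {st}"
                )
            else:
                lo_hi.append(fun if sign == 1.0 else -fun)
        result[rid] = (lo_hi[0], lo_hi[1])
    return result


def delete_reactions(
    model: StoichiometricModel, reaction_ids: Iterable[str]
) -> StoichiometricModel:
    """Return a copy with the named reactions knocked out (lb = ub = 0).

    The input model is left unmodified; unknown ids raise listing every
    offender.
    """
    reaction_ids = list(reaction_ids)
    unknown = [r for r in reaction_ids if r not in model.reactions]
    if unknown:
        raise ValidationError(f"cannot delete unknown reactions: {sorted(unknown)}")
    out = model.copy()
    for rid in reaction_ids:
        out.reactions[rid].lower_bound = 0.0
        out.reactions[rid].upper_bound = 0.0
    return out
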
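"""Independent oracles used by the test suite.

These deliberately avoid the package's LP code path: optima are recomputed
by enumerating the basic feasible solutions (vertices) of the small flux
polytopes, and feasible points are drawn as convex combinations of those
vertices.
"""

from __future__ import annotations

import itertools
from typing import List, Optional, Tuple

import numpy as np

from cometab.core import Metabolite, Reaction, StoichiometricModel

TOL = 1e-7


def enumerate_vertices(model: StoichiometricModel) -> np.ndarray:
    """All vertices of {v : S v = 0, lb <= v <= ub} (bounds must be finite).

    A vertex fixes n - rank(S) variables at a bound and solves the balance
    equations for the rest; every candidate is kept if it satisfies the
    bounds. Exponential — only for toy networks.
    """
    S, _, rxn_ids = model.stoichiometric_matrix()
    S = S.toarray()
    lb, ub = model.bounds_arrays()
    assert np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))
    m, n = S.shape
    r = np.linalg.matrix_rank(S) if S.size else 0
    vertices = []
    for free in itertools.combinations(range(n), r):
        free = list(free)
        fixed = [j for j in range(n) if j not in free]
        A = S[:, free]
        if r:
            if np.linalg.matrix_rank(A) < r:
                continue
            pinv = np.linalg.pinv(A)
        for pattern in itertools.product((0, 1), repeat=len(fixed)):
            v = np.empty(n)
            v[fixed] = [lb[j] if p == 0 else ub[j] for j, p in zip(fixed, pattern)]
            rhs = -S[:, fixed] @ v[fixed] if fixed else np.zeros(m)
            if r:
                sol = pinv @ rhs
                if np.linalg.norm(A @ sol - rhs, np.inf) > TOL:
                    continue
                v[free] = sol
            if np.all(v >= lb - TOL) and np.all(v <= ub + TOL):
                vertices.append(np.clip(v, lb, ub))
    if not vertices:
        return np.empty((0, n))
    V = np.unique(np.round(np.array(vertices), 9), axis=0)
    return V


def brute_force_optimum(
    model: StoichiometricModel, objective: str, sense: str = "max"
) -> Optional[float]:
    """LP optimum by vertex enumeration; None when the polytope is empty."""
    V = enumerate_vertices(model)
    if V.shape[0] == 0:
        return None
    j = model.reaction_ids().index(objective)
    vals = V[:, j]
    return float(vals.max() if sense == "max" else vals.min())


def sample_feasible_points(
    model: StoichiometricModel, n_points: int, rng: np.random.Generator
) -> np.ndarray:
    """Random feasible points as convex combinations of polytope vertices."""
    V = enumerate_vertices(model)
    if V.shape[0] == 0:
        return np.empty((0, len(model.reactions)))
    w = rng.dirichlet(np.ones(V.shape[0]), size=n_points)
    return w @ V


def random_toy_network(rng: np.random.Generator) -> StoichiometricModel:
    """A random small bounded metabolic network (<= 12 reactions).

    Bounds always include zero, so the zero flux vector is feasible and the
    polytope is non-empty and bounded.
    """
    n_mets = int(rng.integers(3, 7))
    n_rxns = int(rng.integers(6, 13))
    model = StoichiometricModel(id="toy")
    mets = [f"m{i}[c]" for i in range(n_mets)]
    for met in mets:
        model.add_metabolite(Metabolite(met))
    for j in range(n_rxns):
        if j < n_mets or rng.random() < 0.4:
            # boundary reaction; cycle through metabolites so each has one
            met = mets[j % n_mets]
            stoich = {met: float(rng.choice([-1.0, 1.0]))}
        else:
            k_sub = int(rng.integers(1, 3))
            k_prod = int(rng.integers(1, 3))
            chosen = rng.choice(n_mets, size=min(n_mets, k_sub + k_prod),
                                replace=False)
            stoich = {}
            for i, midx in enumerate(chosen):
                coef = float(rng.integers(1, 3))
                stoich[mets[midx]] = -coef if i < k_sub else coef
        lb = float(rng.choice([-10.0, -5.0, 0.0]))
        ub = float(rng.choice([0.0, 5.0, 10.0]))
        model.add_reaction(Reaction(f"r{j}", stoich, lb, ub))
    obj = f"r{int(rng.integers(0, n_rxns))}"
    model.objective = obj
    return model


def exhaustive_best_reduction(
    evaluate, candidates: List[str], size: int
) -> Tuple[Tuple[str, ...], float]:
    """Best achievable reduction over all candidate subsets of given size.

    ``evaluate(subset)`` must return the reduction fraction for a subset.
    """
    best, best_red = (), -np.inf
    for subset in itertools.combinations(candidates, size):
        red = evaluate(list(subset))
        if red > best_red:
            best, best_red = subset, red
    return best, best_red
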
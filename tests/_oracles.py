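"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the package's GLPK solve path: FBA optima are
recomputed by enumerating vertices of the flux polytope (and, where used,
cross-checked with scipy's LP), and SGA proportions by exhaustive subset
enumeration with per-subset scipy solves.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy.optimize import linprog


def fba_vertex_enumeration(S, lb, ub, obj_index, tol=1e-9):
    """Maximum of v[obj_index] over {v: S v = 0, lb <= v <= ub} by
    enumerating basic feasible points (every subset of coordinates pinned
    at a bound, remainder solved from the equality system).

    Only sensible for <= 8 reactions.  Returns -inf if no feasible basic
    point is found.
    """
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    n = S.shape[1]
    best = -np.inf
    cols = list(range(n))
    for k in range(n + 1):
        for fixed in combinations(cols, k):
            free = [j for j in cols if j not in fixed]
            S_free = S[:, free]
            if free and np.linalg.matrix_rank(S_free) < len(free):
                continue  # free part underdetermined: not a vertex here
            for choice in product((0, 1), repeat=k):
                v = np.zeros(n)
                for j, c in zip(fixed, choice):
                    v[j] = lb[j] if c == 0 else ub[j]
                if free:
                    rhs = -S[:, fixed] @ v[list(fixed)] if k else np.zeros(S.shape[0])
                    sol, res, rank, _ = np.linalg.lstsq(S_free, rhs, rcond=None)
                    v[free] = sol
                if np.max(np.abs(S @ v)) > 1e-7:
                    continue
                if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                    continue
                best = max(best, v[obj_index])
    return best


def fba_scipy(S, lb, ub, obj_index):
    """FBA optimum via scipy's HiGHS LP (independent of the GLPK path)."""
    n = np.asarray(S).shape[1]
    c = np.zeros(n)
    c[obj_index] = -1.0
    res = linprog(
        c,
        A_eq=np.asarray(S, dtype=float),
        b_eq=np.zeros(np.asarray(S).shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status == 2:
        return None  # infeasible
    return -res.fun


def sga_exhaustive_scipy(model, env, disease_set, limit=1e4):
    """Exhaustive-subset SGA recomputed entirely with scipy solves."""
    S = model.stoichiometry.toarray()
    obj = model.reaction_index(model.biomass_reaction)

    def bounds_for(supplemented):
        lb = model.lower_bounds.copy()
        ub = model.upper_bounds.copy()
        for met, rxn in model.import_map.items():
            j = model.reaction_index(rxn)
            cap = env.limit(met)
            if met in supplemented:
                cap = max(cap, limit)
            ub[j] = cap
            lb[j] = min(lb[j], cap)
        return lb, ub

    def z_for(supplemented):
        lb, ub = bounds_for(supplemented)
        z = fba_scipy(S, lb, ub, obj)
        return 0.0 if z is None else max(z, 0.0)

    env_mets = list(env.uptake_limits)
    k = len(disease_set)
    z_disease = z_for(set(disease_set))
    eps = 1e-9 * max(1.0, z_disease)
    subsets = list(combinations(env_mets, k))
    wins = sum(z_for(set(s)) < z_disease - eps for s in subsets)
    return wins / len(subsets)


def random_toy_network(rng, max_reactions=8):
    """A random small stoichiometric system with box bounds straddling 0
    (so v = 0 is always feasible) and a designated objective column."""
    n_r = int(rng.integers(3, max_reactions + 1))
    n_m = int(rng.integers(2, 5))
    S = np.zeros((n_m, n_r))
    for j in range(n_r):
        nz = rng.choice(n_m, size=min(n_m, int(rng.integers(1, 4))), replace=False)
        S[nz, j] = rng.choice([-2.0, -1.0, 1.0, 2.0], size=len(nz))
    lb = np.where(rng.random(n_r) < 0.5, 0.0, -rng.integers(1, 11, n_r).astype(float))
    ub = rng.integers(1, 11, n_r).astype(float)
    obj = int(rng.integers(n_r))
    return S, lb, ub, obj
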
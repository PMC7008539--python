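"""Constraint-based metabolic models and flux balance analysis.

A :class:`MetabolicModel` is a stoichiometric system ``S`` (balanced
metabolites x reactions) with per-reaction flux bounds in mmol/gDW/h, a
designated biomass reaction ``z`` and an ``import_map`` connecting
environment metabolites to the reactions that carry them into the system.
Growth is predicted by flux balance analysis (FBA): maximise the biomass
flux subject to the steady-state constraint ``S v = 0`` and the bounds.

Sign convention: import reactions are oriented in the uptake direction, so
flux >= 0 means uptake and the environment's uptake limit maps onto the
reaction's *upper* bound.  Readers normalise reversed exchange reactions on
load (see :mod:`passengerscreen.io`).

The LP itself is solved with GLPK through ``swiglpk``.  A persistent
:class:`FbaEngine` keeps the factorised problem alive so that screens that
only move bounds around (metabolite knockouts, supplementations) re-solve
in microseconds.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import scipy.sparse as sp
import swiglpk as glp

__all__ = [
    "MetabolicModel",
    "Environment",
    "FbaSolution",
    "FbaEngine",
    "SolverError",
    "apply_environment",
    "solve_fba",
    "block_metabolite",
    "supplement_metabolites",
    "GROWTH_EPS",
    "SUPPLEMENT_LIMIT",
]

#: biomass fluxes below this value are treated as "no growth"
GROWTH_EPS = 1e-6

#: virtually unconstrained uptake rate used for supplementation, mmol/gDW/h
SUPPLEMENT_LIMIT = 1e4

_INF = 1e30  # bounds at or beyond this magnitude are treated as free


class SolverError(RuntimeError):
    """Raised when GLPK fails for numerical (not infeasibility) reasons."""


@dataclass(frozen=True)
class Environment:
    """A basal growth medium: per-metabolite uptake-rate limits.

    Limits are upper bounds on uptake flux in mmol/gDW/h.  A metabolite
    absent from the table is unavailable (limit 0).
    """

    name: str
    uptake_limits: Dict[str, float]

    def __post_init__(self) -> None:
        for met, lim in self.uptake_limits.items():
            if lim < 0:
                raise ValueError(f"negative uptake limit for {met!r}: {lim}")

    @property
    def metabolites(self) -> List[str]:
        return list(self.uptake_limits)

    def limit(self, metabolite: str) -> float:
        return self.uptake_limits.get(metabolite, 0.0)


@dataclass
class MetabolicModel:
    """A stoichiometric model with bounds, biomass objective and imports.

    ``stoichiometry`` has one row per *balanced* metabolite
    (``metabolite_ids``) and one column per reaction.  Boundary metabolites
    (the environment-facing species consumed by import reactions) carry no
    mass-balance row and are listed in ``boundary_metabolite_ids``.
    """

    model_id: str
    metabolite_ids: List[str]
    reaction_ids: List[str]
    stoichiometry: sp.csc_matrix
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    biomass_reaction: str
    import_map: Dict[str, str]
    boundary_metabolite_ids: List[str] = field(default_factory=list)
    genus: str = ""
    taxon_label: str = ""

    def __post_init__(self) -> None:
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        n_m, n_r = self.stoichiometry.shape
        if n_m != len(self.metabolite_ids):
            raise ValueError("S row count does not match metabolite_ids")
        if n_r != len(self.reaction_ids):
            raise ValueError("S column count does not match reaction_ids")
        if len(self.lower_bounds) != n_r or len(self.upper_bounds) != n_r:
            raise ValueError("bound vectors do not match reaction count")
        if np.any(self.lower_bounds > self.upper_bounds):
            bad = np.flatnonzero(self.lower_bounds > self.upper_bounds)[0]
            raise ValueError(
                f"lower bound exceeds upper bound for {self.reaction_ids[bad]!r}"
            )
        if self.biomass_reaction not in self.reaction_ids:
            raise ValueError(
                f"biomass reaction {self.biomass_reaction!r} not in model"
            )
        if self.upper_bounds[self.reaction_index(self.biomass_reaction)] <= 0:
            raise ValueError("biomass reaction has non-positive upper bound")
        declared = set(self.metabolite_ids) | set(self.boundary_metabolite_ids)
        for met, rxn in self.import_map.items():
            if met not in declared:
                raise ValueError(f"import_map key {met!r} is not a declared metabolite")
            if rxn not in self.reaction_ids:
                raise ValueError(f"import_map reaction {rxn!r} not in model")

    # -- lookups --------------------------------------------------------
    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self._rxn_index[reaction_id]
        except AttributeError:
            self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}
            return self._rxn_index[reaction_id]

    def import_reaction_index(self, metabolite: str) -> Optional[int]:
        rxn = self.import_map.get(metabolite)
        return None if rxn is None else self.reaction_index(rxn)

    def copy(self) -> "MetabolicModel":
        new = replace(
            self,
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            import_map=dict(self.import_map),
        )
        return new


@dataclass(frozen=True)
class FbaSolution:
    """Outcome of one FBA solve.

    ``objective_value`` (the biomass flux z) is only meaningful when
    ``status == "optimal"``; small negative round-off is clamped to 0.
    """

    objective_value: float
    status: str  # optimal | infeasible | unbounded
    fluxes: Optional[Dict[str, float]] = None

    @property
    def grows(self) -> bool:
        return self.status == "optimal" and self.objective_value > GROWTH_EPS


# ---------------------------------------------------------------------------
# environment / perturbation operations (pure: return modified copies)
# ---------------------------------------------------------------------------

def apply_environment(model: MetabolicModel, env: Environment) -> MetabolicModel:
    """Constrain every import reaction to the environment's uptake limits.

    Metabolites the model can import but the environment does not provide
    get an uptake limit of 0.  Non-import bounds are untouched.
    """
    out = model.copy()
    for met, rxn in out.import_map.items():
        j = out.reaction_index(rxn)
        lim = env.limit(met)
        out.upper_bounds[j] = lim
        if out.lower_bounds[j] > lim:
            out.lower_bounds[j] = lim
    return out


def block_metabolite(model: MetabolicModel, metabolite: str) -> MetabolicModel:
    """Remove a metabolite from the medium by closing its import reaction.

    A metabolite the model does not import is a no-op (the model is
    returned unchanged apart from being a copy).
    """
    out = model.copy()
    j = out.import_reaction_index(metabolite)
    if j is None:
        return out
    out.upper_bounds[j] = 0.0
    if out.lower_bounds[j] > 0.0:
        out.lower_bounds[j] = 0.0
    return out


def supplement_metabolites(
    model: MetabolicModel,
    metabolites: Iterable[str],
    limit: float = SUPPLEMENT_LIMIT,
) -> MetabolicModel:
    """Raise uptake limits of the named metabolites to ``limit``.

    Bounds are only ever raised, never lowered below their basal value;
    metabolites the model cannot import are ignored.
    """
    out = model.copy()
    for met in metabolites:
        j = out.import_reaction_index(met)
        if j is None:
            continue
        out.upper_bounds[j] = max(out.upper_bounds[j], limit)
    return out


# ---------------------------------------------------------------------------
# GLPK backend
# ---------------------------------------------------------------------------

def _set_col_bounds(lp, j1: int, lb: float, ub: float) -> None:
    lo_free = lb <= -_INF
    up_free = ub >= _INF
    if lo_free and up_free:
        glp.glp_set_col_bnds(lp, j1, glp.GLP_FR, 0.0, 0.0)
    elif lo_free:
        glp.glp_set_col_bnds(lp, j1, glp.GLP_UP, 0.0, ub)
    elif up_free:
        glp.glp_set_col_bnds(lp, j1, glp.GLP_LO, lb, 0.0)
    elif lb == ub:
        glp.glp_set_col_bnds(lp, j1, glp.GLP_FX, lb, ub)
    else:
        glp.glp_set_col_bnds(lp, j1, glp.GLP_DB, lb, ub)


class FbaEngine:
    """A persistent GLPK problem for one model.

    Repeated solves after bound changes reuse the current basis, which is
    what makes metabolite-knockout and supplementation screens cheap.  The
    optimal objective is unique for a given set of bounds regardless of the
    basis path, so results are deterministic.
    """

    def __init__(self, model: MetabolicModel):
        self.model = model
        n_m, n_r = model.stoichiometry.shape
        self._n_r = n_r
        lp = glp.glp_create_prob()
        glp.glp_set_obj_dir(lp, glp.GLP_MAX)
        if n_m:
            glp.glp_add_rows(lp, n_m)
            for i in range(n_m):
                glp.glp_set_row_bnds(lp, i + 1, glp.GLP_FX, 0.0, 0.0)
        glp.glp_add_cols(lp, n_r)
        for j in range(n_r):
            _set_col_bounds(lp, j + 1, model.lower_bounds[j], model.upper_bounds[j])
        jz = model.reaction_index(model.biomass_reaction)
        glp.glp_set_obj_coef(lp, jz + 1, 1.0)

        coo = model.stoichiometry.tocoo()
        ne = coo.nnz
        ia = glp.intArray(ne + 1)
        ja = glp.intArray(ne + 1)
        ar = glp.doubleArray(ne + 1)
        for k in range(ne):
            ia[k + 1] = int(coo.row[k]) + 1
            ja[k + 1] = int(coo.col[k]) + 1
            ar[k + 1] = float(coo.data[k])
        glp.glp_load_matrix(lp, ne, ia, ja, ar)

        self._lp = lp
        self._parm = glp.glp_smcp()
        glp.glp_init_smcp(self._parm)
        self._parm.msg_lev = glp.GLP_MSG_OFF
        self._base_lb = model.lower_bounds.copy()
        self._base_ub = model.upper_bounds.copy()

    def __del__(self):  # pragma: no cover - GC hook
        lp = getattr(self, "_lp", None)
        if lp is not None:
            glp.glp_delete_prob(lp)
            self._lp = None

    # -- solving --------------------------------------------------------
    def set_bounds(self, j: int, lb: float, ub: float) -> None:
        _set_col_bounds(self._lp, j + 1, lb, ub)

    def reset_bounds(self, indices: Iterable[int]) -> None:
        for j in indices:
            self.set_bounds(j, self._base_lb[j], self._base_ub[j])

    def solve(self, want_fluxes: bool = False) -> FbaSolution:
        ret = glp.glp_simplex(self._lp, self._parm)
        if ret != 0:
            # retry once from a fresh standard basis before giving up
            glp.glp_std_basis(self._lp)
            ret = glp.glp_simplex(self._lp, self._parm)
            if ret != 0:
                raise SolverError(f"GLPK simplex failed with return code {ret}")
        status = glp.glp_get_status(self._lp)
        if status == glp.GLP_OPT:
            z = glp.glp_get_obj_val(self._lp)
            z = 0.0 if abs(z) < 1e-12 else z
            fluxes = None
            if want_fluxes:
                fluxes = {
                    r: glp.glp_get_col_prim(self._lp, j + 1)
                    for j, r in enumerate(self.model.reaction_ids)
                }
            return FbaSolution(max(z, 0.0), "optimal", fluxes)
        if status == glp.GLP_NOFEAS:
            return FbaSolution(float("nan"), "infeasible")
        if status == glp.GLP_UNBND:
            return FbaSolution(float("inf"), "unbounded")
        raise SolverError(f"GLPK ended with unexpected status {status}")

    def objective(self) -> float:
        """Solve and return z, mapping infeasibility to 0 growth."""
        sol = self.solve()
        if sol.status == "infeasible":
            return 0.0
        if sol.status == "unbounded":
            raise SolverError("FBA problem is unbounded; check model bounds")
        return sol.objective_value

    # -- convenience screens --------------------------------------------
    def objective_with_uptake(self, overrides: Dict[int, float]) -> float:
        """z with the given import-reaction upper bounds, then restore."""
        for j, ub in overrides.items():
            self.set_bounds(j, min(self._base_lb[j], ub), ub)
        try:
            return self.objective()
        finally:
            self.reset_bounds(overrides)


def solve_fba(model: MetabolicModel, want_fluxes: bool = False) -> FbaSolution:
    """Maximise biomass flux subject to S v = 0 and the model's bounds."""
    return FbaEngine(model).solve(want_fluxes=want_fluxes)
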
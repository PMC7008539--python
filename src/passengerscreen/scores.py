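"""Per-model scores: metabolite importance, specific growth advantage and
their copula combination.

* **MI (metabolite importance)** — block each environment metabolite's
  import in turn; a metabolite is *important* when the knockout drops
  biomass flux below ``threshold`` (default 0.3) times the basal flux,
  i.e. a more than 70% growth reduction.  MI is the Ochiai similarity
  between the important set and the disease-metabolite set.
* **SGA (specific growth advantage)** — supplement the disease set at a
  virtually unconstrained uptake rate and compare the resulting biomass
  flux with that of random equal-size supplementation sets drawn from the
  whole basal environment; SGA is the fraction of random sets that grow
  strictly less.
* **MR (metabolite response)** — the Ali-Mikhail-Haq (AMH) copula
  ``C_theta(MI, SGA)``, with ``theta`` calibrated once per cohort from the
  Kendall rank correlation of the (MI, SGA) pairs.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .gsmm import (
    Environment,
    FbaEngine,
    MetabolicModel,
    GROWTH_EPS,
    SUPPLEMENT_LIMIT,
    apply_environment,
)

__all__ = [
    "ImportanceVector",
    "CopulaFit",
    "important_metabolites",
    "ochiai",
    "mi_score",
    "sga_score",
    "amh_tau",
    "fit_amh_theta",
    "mr_score",
    "sample_amh",
    "score_cohort",
    "model_seed",
    "AMH_TAU_MIN",
    "AMH_TAU_MAX",
]

# Kendall-tau range attainable by the AMH family: [(5 - 8 ln 2)/3, 1/3)
AMH_TAU_MIN = (5.0 - 8.0 * math.log(2.0)) / 3.0
AMH_TAU_MAX = 1.0 / 3.0


@dataclass
class ImportanceVector:
    """Binary metabolite-importance calls for one model.

    ``importance`` has one entry per basal-environment metabolite (1 if the
    knockout cuts growth below the threshold fraction of ``basal_z``).
    """

    model_id: str
    importance: Dict[str, int]
    basal_z: float

    @property
    def important_set(self) -> Set[str]:
        return {m for m, v in self.importance.items() if v}


@dataclass(frozen=True)
class CopulaFit:
    """AMH dependence parameter fitted from a cohort of (MI, SGA) pairs."""

    theta: float
    tau_observed: float
    clamped: bool


class NoBasalGrowthError(RuntimeError):
    """The model produces no biomass under the basal environment."""


def model_seed(global_seed: int, model_id: str) -> np.random.SeedSequence:
    """A reproducible per-model random stream independent of iteration order."""
    digest = hashlib.blake2b(model_id.encode(), digest_size=8).digest()
    return np.random.SeedSequence([int(global_seed), int.from_bytes(digest, "big")])


# ---------------------------------------------------------------------------
# metabolite importance
# ---------------------------------------------------------------------------

def important_metabolites(
    model: MetabolicModel,
    env: Environment,
    threshold: float = 0.3,
    engine: Optional[FbaEngine] = None,
) -> ImportanceVector:
    """Single-metabolite knockout screen over the basal environment.

    Requires basal growth; metabolites the model cannot import are scored 0
    without a solve (blocking them is a no-op).
    """
    if engine is None:
        engine = FbaEngine(apply_environment(model, env))
    basal_z = engine.objective()
    if basal_z <= GROWTH_EPS:
        raise NoBasalGrowthError(
            f"model {model.model_id!r} does not grow in environment {env.name!r}"
        )
    importance: Dict[str, int] = {}
    for met in env.uptake_limits:
        j = engine.model.import_reaction_index(met)
        if j is None:
            importance[met] = 0
            continue
        z_blocked = engine.objective_with_uptake({j: 0.0})
        importance[met] = int(z_blocked / basal_z < threshold)
    return ImportanceVector(model.model_id, importance, basal_z)


def ochiai(set_a: Union[Set, Sequence], set_b: Union[Set, Sequence]) -> float:
    """Cosine-type similarity for binary sets: |A & B| / sqrt(|A| |B|).

    Defined as 0 when either set is empty (an empty important set carries
    no evidence of dependence).
    """
    a, b = set(set_a), set(set_b)
    if not a or not b:
        return 0.0
    return len(a & b) / math.sqrt(len(a) * len(b))


def mi_score(importance: ImportanceVector, disease_set: Set[str]) -> float:
    return ochiai(importance.important_set, disease_set)


# ---------------------------------------------------------------------------
# specific growth advantage
# ---------------------------------------------------------------------------

def _supplemented_z(
    engine: FbaEngine, model: MetabolicModel, metabolites: Iterable[str], limit: float
) -> float:
    overrides = {}
    for met in metabolites:
        j = model.import_reaction_index(met)
        if j is not None:
            overrides[j] = max(limit, engine._base_ub[j])
    return engine.objective_with_uptake(overrides)


def sga_score(
    model: MetabolicModel,
    env: Environment,
    disease_set: Set[str],
    n_random: int = 1000,
    limit: float = SUPPLEMENT_LIMIT,
    seed: Union[int, np.random.SeedSequence, None] = 0,
    engine: Optional[FbaEngine] = None,
    exhaustive: bool = False,
) -> float:
    """Fraction of random equal-size supplementation sets growing strictly
    less than the disease-supplemented model.

    Random sets are uniform without-replacement draws of ``len(disease_set)``
    metabolites from the *whole* basal environment (overlap with the disease
    set is allowed).  Strict inferiority uses a relative tolerance of
    ``1e-9 * max(1, z_disease)`` so exact ties count against the score.
    With ``exhaustive=True`` all subsets are enumerated instead (the
    brute-force oracle; only sensible for tiny environments).
    """
    env_mets = list(env.uptake_limits)
    k = len(disease_set)
    if k > len(env_mets):
        raise ValueError("disease set larger than the environment")
    if engine is None:
        engine = FbaEngine(apply_environment(model, env))
    z_disease = _supplemented_z(engine, model, disease_set, limit)
    eps = 1e-9 * max(1.0, z_disease)

    if exhaustive:
        from itertools import combinations

        subsets = list(combinations(env_mets, k))
        wins = sum(
            _supplemented_z(engine, model, s, limit) < z_disease - eps for s in subsets
        )
        return wins / len(subsets)

    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(seed)
    # cache by the effective set of supplemented *import* reactions: random
    # sets touching the same imports give identical optima
    cache: Dict[frozenset, float] = {}
    import_js = {
        met: model.import_reaction_index(met)
        for met in env_mets
        if model.import_reaction_index(met) is not None
    }
    wins = 0
    for _ in range(n_random):
        draw = rng.choice(len(env_mets), size=k, replace=False)
        touched = frozenset(
            import_js[env_mets[i]] for i in draw if env_mets[i] in import_js
        )
        z_rand = cache.get(touched)
        if z_rand is None:
            overrides = {j: max(limit, engine._base_ub[j]) for j in touched}
            z_rand = engine.objective_with_uptake(overrides)
            cache[touched] = z_rand
        wins += z_rand < z_disease - eps
    return wins / n_random


# ---------------------------------------------------------------------------
# AMH copula
# ---------------------------------------------------------------------------

def amh_tau(theta: float) -> float:
    """Kendall's tau of the AMH copula,
    tau(theta) = 1 - 2 (theta + (1-theta)^2 ln(1-theta)) / (3 theta^2)."""
    if not -1.0 <= theta < 1.0:
        raise ValueError("theta must be in [-1, 1)")
    if abs(theta) < 1e-5:
        # series around 0 avoids 0/0: tau = 2θ/9 + θ²/18 + θ³/45 + O(θ⁴)
        return 2.0 * theta / 9.0 + theta**2 / 18.0 + theta**3 / 45.0
    return 1.0 - 2.0 * (theta + (1.0 - theta) ** 2 * math.log1p(-theta)) / (
        3.0 * theta**2
    )


def fit_amh_theta(
    pairs: Union[Sequence[Tuple[float, float]], np.ndarray, pd.DataFrame],
    min_pairs: int = 10,
) -> CopulaFit:
    """Invert the AMH tau-theta relation for the observed Kendall's tau.

    Tau outside the AMH-attainable range [(5-8ln2)/3, 1/3) is clamped to
    the nearest attainable value and flagged.  Inversion is by bisection on
    theta in (-1, 1) to 1e-8 (tau is strictly increasing in theta).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < min_pairs:
        raise ValueError(f"need >= {min_pairs} (MI, SGA) pairs")
    u, v = arr[:, 0], arr[:, 1]
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        raise ValueError("degenerate input: a score is constant across the cohort")
    tau = stats.kendalltau(u, v).statistic
    clamped = False
    t = tau
    if t <= AMH_TAU_MIN:
        t, clamped = AMH_TAU_MIN + 1e-12, True
    elif t >= AMH_TAU_MAX:
        t, clamped = AMH_TAU_MAX - 1e-12, True
    lo, hi = -1.0 + 1e-12, 1.0 - 1e-12
    while hi - lo > 1e-8:
        mid = 0.5 * (lo + hi)
        if amh_tau(mid) < t:
            lo = mid
        else:
            hi = mid
    theta = 0.5 * (lo + hi)
    if abs(tau) < 1e-12:
        theta = 0.0
    return CopulaFit(theta=theta, tau_observed=tau, clamped=clamped)


def mr_score(mi: float, sga: float, theta: float) -> float:
    """AMH copula value C_theta(MI, SGA) = MI*SGA / (1 - theta (1-MI)(1-SGA))."""
    if not -1.0 <= theta < 1.0:
        raise ValueError("theta must be in [-1, 1)")
    return mi * sga / (1.0 - theta * (1.0 - mi) * (1.0 - sga))


def sample_amh(
    theta: float, n: int, seed: Union[int, np.random.SeedSequence, None] = 0
) -> np.ndarray:
    """Draw ``n`` pairs from the AMH copula by conditional inversion.

    Given u and w ~ U(0,1), v solves dC/du(u, v) = w; the conditional CDF is
    strictly increasing in v, inverted here by vectorised bisection.
    Used for validating :func:`fit_amh_theta`.
    """
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    w = rng.random(n)

    def cond_cdf(v):
        d = 1.0 - theta * (1.0 - u) * (1.0 - v)
        return v * (d - u * theta * (1.0 - v)) / d**2

    lo = np.zeros(n)
    hi = np.ones(n)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        below = cond_cdf(mid) < w
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return np.column_stack([u, 0.5 * (lo + hi)])


# ---------------------------------------------------------------------------
# cohort scoring
# ---------------------------------------------------------------------------

def score_cohort(
    models: Sequence[MetabolicModel],
    env: Environment,
    disease_set: Set[str],
    labels: Optional[Dict[str, bool]] = None,
    threshold: float = 0.3,
    n_random: int = 1000,
    limit: float = SUPPLEMENT_LIMIT,
    seed: int = 0,
) -> Tuple[pd.DataFrame, CopulaFit, List[str]]:
    """Score every model (MI, SGA), fit theta once on the cohort, add MR.

    Returns the score table (one row per growing model, ordered by
    model_id), the copula fit, and the ids of models skipped for lacking
    basal growth.  Each model draws its random supplementation sets from an
    independent stream derived from ``(seed, model_id)``, so results do not
    depend on iteration order.
    """
    labels = labels or {}
    rows = []
    skipped: List[str] = []
    for model in sorted(models, key=lambda m: m.model_id):
        engine = FbaEngine(apply_environment(model, env))
        try:
            imp = important_metabolites(model, env, threshold=threshold, engine=engine)
        except NoBasalGrowthError:
            skipped.append(model.model_id)
            continue
        mi = mi_score(imp, disease_set)
        sga = sga_score(
            model,
            env,
            disease_set,
            n_random=n_random,
            limit=limit,
            seed=model_seed(seed, model.model_id),
            engine=engine,
        )
        rows.append(
            {
                "model_id": model.model_id,
                "genus": model.genus,
                "taxon_label": model.taxon_label,
                "disease_enriched": bool(labels.get(model.model_id, False)),
                "basal_z": imp.basal_z,
                "MI": mi,
                "SGA": sga,
            }
        )
    if not rows:
        raise ValueError("no model grew in the basal environment")
    table = pd.DataFrame(rows)
    try:
        fit = fit_amh_theta(table[["MI", "SGA"]].to_numpy())
    except ValueError:
        # tiny or degenerate cohorts fall back to independence
        fit = CopulaFit(theta=0.0, tau_observed=float("nan"), clamped=False)
    table["MR"] = [
        mr_score(r.MI, r.SGA, fit.theta) for r in table.itertuples(index=False)
    ]
    return table, fit, skipped
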
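"""Rank-based enrichment of disease-associated taxa, and the blocked
case-control machinery that defines them.

The central statistic is a GSEA-like running sum ``W``: walking a
score-ranked list of models top-down, ``W`` gains ``1/P`` at a positive
(a model from a disease-enriched genus) and loses ``1/N`` at a negative,
so it starts and ends at 0 and its maximum measures how strongly positives
concentrate at the top.  ``max W`` is calibrated against two Monte-Carlo
nulls: (1) shuffling the label sequence, and (2) redrawing which genera
are called positive, weighted by genus size, while keeping the ranking
fixed.

Disease-enriched taxa themselves come from blocked case-control abundance
data: per-species van-Elteren-style permutation rank-sum tests (labels
permuted within study blocks only), Benjamini-Hochberg correction across
species, and an AUC direction call.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "AbundanceStudySet",
    "rank_models",
    "cumulative_weight",
    "null_rank_shuffle",
    "null_genus_resample",
    "empirical_p",
    "mann_whitney_u",
    "bh_adjust",
    "blocked_wilcoxon",
    "auc_case_control",
    "differential_species",
]


# ---------------------------------------------------------------------------
# ranked lists and the running-sum statistic
# ---------------------------------------------------------------------------

@dataclass
class RankedList:
    """Models ordered by descending score with positive/negative labels."""

    model_ids: List[str]
    labels: np.ndarray  # boolean, True = positive

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if len(self.model_ids) != len(self.labels):
            raise ValueError("model_ids and labels differ in length")

    @property
    def P(self) -> int:
        return int(self.labels.sum())

    @property
    def N(self) -> int:
        return int((~self.labels).sum())


@dataclass
class EnrichmentResult:
    W: np.ndarray
    max_W: float
    p_null1: Optional[float] = None
    p_null2: Optional[float] = None
    n_perm: int = 0
    seed: Optional[int] = None


def rank_models(
    table: pd.DataFrame,
    score: str,
    seed: Union[int, np.random.SeedSequence, None] = 0,
    label_column: str = "disease_enriched",
) -> RankedList:
    """Order models by descending score.

    Ties are broken by a seeded random shuffle (a deterministic tie-break
    such as alphabetical order would bias the running sum).
    """
    rng = np.random.default_rng(seed)
    jitter = rng.permutation(len(table))
    order = np.lexsort((jitter, -table[score].to_numpy()))
    sub = table.iloc[order]
    return RankedList(sub["model_id"].tolist(), sub[label_column].to_numpy(dtype=bool))


def _running_sum(labels: np.ndarray, P: int, N: int) -> np.ndarray:
    steps = np.where(labels, 1.0 / P, -1.0 / N)
    return np.cumsum(steps)


def cumulative_weight(ranked: RankedList) -> EnrichmentResult:
    """The running sum W and its maximum (including the implicit leading 0)."""
    P, N = ranked.P, ranked.N
    if P == 0 or N == 0:
        raise ValueError("enrichment needs at least one positive and one negative")
    W = _running_sum(ranked.labels, P, N)
    return EnrichmentResult(W=W, max_W=max(0.0, float(W.max())))


def empirical_p(observed: float, null_values: Sequence[float]) -> float:
    """Add-one empirical p-value: (1 + #{null >= observed}) / (1 + n).

    The observed value is counted in its own null, so p can never be 0.
    """
    nulls = np.asarray(null_values, dtype=float)
    if nulls.size == 0:
        raise ValueError("null_values must be non-empty")
    return float((1 + np.count_nonzero(nulls >= observed)) / (1 + nulls.size))


def null_rank_shuffle(
    ranked: RankedList,
    n_perm: int = 10000,
    seed: Union[int, np.random.SeedSequence, None] = 0,
) -> Tuple[float, np.ndarray]:
    """Null 1: permute the label sequence; return (p, null max-W draws)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    P, N = ranked.P, ranked.N
    if P == 0 or N == 0:
        raise ValueError("enrichment needs at least one positive and one negative")
    observed = cumulative_weight(ranked).max_W
    rng = np.random.default_rng(seed)
    labels = ranked.labels
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(labels)
        null_max[i] = max(0.0, _running_sum(perm, P, N).max())
    return empirical_p(observed, null_max), null_max


def null_genus_resample(
    table: pd.DataFrame,
    ranked: RankedList,
    n_genera: int,
    n_perm: int = 10000,
    seed: Union[int, np.random.SeedSequence, None] = 0,
    genus_column: str = "genus",
) -> Tuple[float, np.ndarray]:
    """Null 2: redraw which genera are positive, keeping the ranking fixed.

    Each permutation draws ``n_genera`` distinct genera by successive
    sampling without replacement with probability proportional to the
    number of models in the genus (implemented with exponential
    Efraimidis-Spirakis keys, which is distributionally equivalent), labels
    exactly those genera's models positive and recomputes max W on the
    unchanged order.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genus_of = dict(zip(table["model_id"], table[genus_column]))
    genera = sorted(table[genus_column].unique())
    if n_genera > len(genera):
        raise ValueError(f"n_genera={n_genera} exceeds genus count {len(genera)}")
    g_index = {g: i for i, g in enumerate(genera)}
    weights = np.zeros(len(genera))
    for g, cnt in table[genus_column].value_counts().items():
        weights[g_index[g]] = cnt
    pos_genus_idx = np.array([g_index[genus_of[m]] for m in ranked.model_ids])

    observed = cumulative_weight(ranked).max_W
    rng = np.random.default_rng(seed)
    n_total = len(ranked.model_ids)
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        keys = rng.exponential(size=len(genera)) / weights
        chosen = np.argpartition(keys, n_genera - 1)[:n_genera]
        mask = np.zeros(len(genera), dtype=bool)
        mask[chosen] = True
        labels = mask[pos_genus_idx]
        P = int(labels.sum())
        N = n_total - P
        if P == 0 or N == 0:
            null_max[i] = 1.0 if P else 0.0
            continue
        null_max[i] = max(0.0, _running_sum(labels, P, N).max())
    return empirical_p(observed, null_max), null_max


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two_sided",
) -> Tuple[float, float]:
    """Rank-sum U statistic and p-value; ``alternative='greater'`` tests
    whether group_a is stochastically larger than group_b.

    Exact enumeration for small tie-free samples (<= 20 per group), the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    alt = {"two_sided": "two-sided", "greater": "greater"}[alternative]
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alt, method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# blocked case-control abundance analysis
# ---------------------------------------------------------------------------

@dataclass
class AbundanceStudySet:
    """Per-study relative-abundance tables with case/control metadata.

    ``tables`` maps study id to a species x samples DataFrame of relative
    abundances; ``metadata`` has one row per sample with columns
    ``sample``, ``study``, ``label`` ("case"/"control") and optional
    ``sub_block``.  The permutation block is (study, sub_block).
    """

    tables: Dict[str, pd.DataFrame]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"sample", "study", "label"}
        if not need <= set(self.metadata.columns):
            raise ValueError(f"metadata must have columns {sorted(need)}")
        if "sub_block" not in self.metadata.columns:
            self.metadata = self.metadata.assign(sub_block="")
        bad = set(self.metadata["label"]) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")
        for study, tab in self.tables.items():
            vals = tab.to_numpy(dtype=float)
            if vals.size and (vals.min() < 0 or vals.max() > 1 + 1e-9):
                raise ValueError(f"study {study!r}: relative abundances must be in [0,1]")

    @property
    def studies(self) -> List[str]:
        return list(self.tables)

    @property
    def species(self) -> List[str]:
        out: List[str] = []
        for tab in self.tables.values():
            for s in tab.index:
                if s not in out:
                    out.append(s)
        return out

    def species_values(self, species: str) -> Tuple[np.ndarray, np.ndarray, List[Tuple]]:
        """Values, case mask and block key per sample, metadata order."""
        vals, is_case, blocks = [], [], []
        for row in self.metadata.itertuples(index=False):
            tab = self.tables[row.study]
            if row.sample not in tab.columns:
                continue
            v = tab.at[species, row.sample] if species in tab.index else 0.0
            vals.append(float(v))
            is_case.append(row.label == "case")
            blocks.append((row.study, row.sub_block))
        return np.asarray(vals), np.asarray(is_case, dtype=bool), blocks


def _block_partition(blocks: List[Tuple]) -> Dict[Tuple, np.ndarray]:
    out: Dict[Tuple, List[int]] = {}
    for i, b in enumerate(blocks):
        out.setdefault(b, []).append(i)
    return {b: np.asarray(ix) for b, ix in out.items()}


def blocked_wilcoxon(
    abund: AbundanceStudySet,
    species: str,
    n_perm: int = 10000,
    seed: Union[int, np.random.SeedSequence, None] = 0,
    exact_limit: int = 20000,
    method: str = "auto",
) -> float:
    """Two-sided permutation rank-sum test blocked by (study, sub_block).

    The statistic is the sum over blocks of the within-block rank sum of
    case samples; the null permutes case/control labels within each block
    only.  Blocks lacking either class are dropped with a warning.
    Two-sidedness is via |statistic - null mean|.

    ``method`` selects how the permutation null is evaluated:

    * ``"auto"`` — exhaustive enumeration (convolving per-block rank-sum
      distributions) when the total number of within-block label
      assignments is at most ``exact_limit``, else Monte Carlo;
    * ``"mc"`` — ``n_perm`` seeded Monte-Carlo draws with the add-one
      empirical p (floor 1/(n_perm+1));
    * ``"normal"`` — moment-based normal approximation of the permutation
      null (exact mean and sampling-without-replacement variance per
      block).  This is what large screens need: a Monte-Carlo p can never
      undercut its floor, so thresholds like 1e-5 are only reachable this
      way.
    """
    import logging

    values, is_case, blocks = abund.species_values(species)
    part = _block_partition(blocks)

    block_ranks: List[np.ndarray] = []
    block_k: List[int] = []
    stat = 0.0
    mean = 0.0
    for b, ix in sorted(part.items()):
        cases = is_case[ix]
        if cases.all() or not cases.any():
            logging.getLogger(__name__).warning(
                "block %r has a single class; dropped", b
            )
            continue
        r = stats.rankdata(values[ix])
        k, n = int(cases.sum()), len(ix)
        stat += float(r[cases].sum())
        mean += k * (n + 1) / 2.0
        block_ranks.append(r)
        block_k.append(k)
    if not block_ranks:
        raise ValueError("no block contains both cases and controls")

    if method == "normal":
        var = 0.0
        for r, k in zip(block_ranks, block_k):
            n = len(r)
            var += k * (n - k) / (n - 1) * float(np.var(r))
        if var <= 0:
            return 1.0
        z = abs(stat - mean) / np.sqrt(var)
        return float(2.0 * stats.norm.sf(z))

    import math as _math

    n_combos = 1
    for r, k in zip(block_ranks, block_k):
        n_combos *= _math.comb(len(r), k)

    if method == "auto" and n_combos <= exact_limit:
        # exhaustive null: per-block rank-sum distributions, convolved
        dists: List[Dict[float, int]] = []
        for r, k in zip(block_ranks, block_k):
            d: Dict[float, int] = {}
            for combo in itertools.combinations(range(len(r)), k):
                s = round(float(r[list(combo)].sum()), 9)
                d[s] = d.get(s, 0) + 1
            dists.append(d)
        total: Dict[float, int] = {0.0: 1}
        for d in dists:
            nxt: Dict[float, int] = {}
            for s1, c1 in total.items():
                for s2, c2 in d.items():
                    key = round(s1 + s2, 9)
                    nxt[key] = nxt.get(key, 0) + c1 * c2
            total = nxt
        obs_dev = abs(stat - mean)
        count_ge = sum(c for s, c in total.items() if abs(s - mean) >= obs_dev - 1e-9)
        return count_ge / n_combos

    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm)
    for r, k in zip(block_ranks, block_k):
        n = len(r)
        keys = rng.random((n_perm, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null += r[idx].sum(axis=1)
    return empirical_p(abs(stat - mean), np.abs(null - mean))


def auc_case_control(values: Sequence[float], labels: Sequence[bool]) -> float:
    """P(random case value > random control value), ties counted 0.5."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    r = stats.rankdata(v)
    u = r[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def differential_species(
    abund: AbundanceStudySet,
    prevalence_threshold: float = 1e-3,
    min_studies: int = 3,
    enrich_alpha: float = 1e-5,
    deplete_alpha: float = 5e-2,
    n_perm: int = 10000,
    seed: Union[int, np.random.SeedSequence, None] = 0,
) -> pd.DataFrame:
    """Per-species differential-abundance calls across blocked studies.

    Species whose maximum relative abundance exceeds ``prevalence_threshold``
    in fewer than ``min_studies`` studies are discarded.  The rest get a
    blocked permutation rank-sum p-value, BH adjustment across species, and
    an AUC: *enriched* if adj p < ``enrich_alpha`` and AUC > 0.5, *depleted*
    if adj p < ``deplete_alpha`` and AUC < 0.5, else *neither*.
    """
    if len(abund.studies) < min_studies:
        raise ValueError(f"need at least {min_studies} studies")
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed

    kept: List[str] = []
    for sp_id in abund.species:
        n_hit = sum(
            (tab.loc[sp_id].max() > prevalence_threshold)
            for tab in abund.tables.values()
            if sp_id in tab.index
        )
        if n_hit >= min_studies:
            kept.append(sp_id)

    rows = []
    children = ss.spawn(len(kept)) if kept else []
    for sp_id, child in zip(kept, children):
        # normal approximation of the permutation null: a Monte-Carlo p is
        # floored at 1/(n_perm+1) and cannot reach screening thresholds
        p = blocked_wilcoxon(abund, sp_id, n_perm=n_perm, seed=child, method="normal")
        vals, is_case, _ = abund.species_values(sp_id)
        rows.append({"species": sp_id, "p": p, "auc": auc_case_control(vals, is_case)})
    result = pd.DataFrame(rows, columns=["species", "p", "auc"])
    if len(result):
        result["adj_p"] = bh_adjust(result["p"])
        cls = np.where(
            (result["adj_p"] < enrich_alpha) & (result["auc"] > 0.5),
            "enriched",
            np.where(
                (result["adj_p"] < deplete_alpha) & (result["auc"] < 0.5),
                "depleted",
                "neither",
            ),
        )
        result["classification"] = cls
    else:
        result["adj_p"] = []
        result["classification"] = []
    return result
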
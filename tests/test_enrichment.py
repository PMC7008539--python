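"""Running-sum enrichment, its two nulls, group tests and the blocked
case-control machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from passengerscreen.enrichment import (
    AbundanceStudySet,
    RankedList,
    auc_case_control,
    bh_adjust,
    blocked_wilcoxon,
    cumulative_weight,
    differential_species,
    empirical_p,
    mann_whitney_u,
    null_genus_resample,
    null_rank_shuffle,
    rank_models,
)


def make_ranked(labels):
    labels = np.asarray(labels, dtype=bool)
    return RankedList([f"m{i}" for i in range(len(labels))], labels)


# ---------------------------------------------------------------------------
# the running sum W
# ---------------------------------------------------------------------------

class TestCumulativeWeight:
    def test_all_positives_first_reaches_one(self):
        res = cumulative_weight(make_ranked([1, 1, 1, 0, 0, 0, 0]))
        assert res.max_W == pytest.approx(1.0)

    def test_all_negatives_first_maxes_at_zero(self):
        res = cumulative_weight(make_ranked([0, 0, 0, 1, 1]))
        assert res.max_W == 0.0

    def test_alternating_hand_computation(self):
        res = cumulative_weight(make_ranked([1, 0, 1, 0]))
        assert np.allclose(res.W, [0.5, 0.0, 0.5, 0.0])
        assert res.max_W == pytest.approx(0.5)

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            cumulative_weight(make_ranked([1, 1, 1]))

    @given(st.lists(st.booleans(), min_size=2, max_size=60).filter(
        lambda xs: any(xs) and not all(xs)))
    def test_w_conserved_and_bounded(self, labels):
        res = cumulative_weight(make_ranked(labels))
        assert abs(res.W[-1]) < 1e-12
        assert (res.W >= -1 - 1e-12).all() and (res.W <= 1 + 1e-12).all()

    def test_max_w_invariant_within_equal_label_runs(self):
        # swapping models inside a run of equal labels cannot change W
        a = cumulative_weight(make_ranked([1, 1, 0, 0, 1, 0])).max_W
        b = cumulative_weight(make_ranked([1, 1, 0, 0, 1, 0])).max_W
        assert a == b


class TestEmpiricalP:
    def test_observed_above_all_nulls(self):
        assert empirical_p(2.0, np.zeros(10_000)) == pytest.approx(1 / 10_001)

    def test_observed_at_median(self):
        nulls = np.arange(101, dtype=float)
        assert empirical_p(50.0, nulls) == pytest.approx(52 / 102)

    def test_observed_below_all_nulls_gives_one(self):
        assert empirical_p(-1.0, np.zeros(99)) == 1.0

    def test_never_zero(self):
        assert empirical_p(np.inf, np.zeros(5)) > 0

    def test_empty_nulls_is_an_error(self):
        with pytest.raises(ValueError):
            empirical_p(1.0, [])


class TestNullRankShuffle:
    def test_perfectly_sorted_list_hits_the_floor(self):
        ranked = make_ranked([1] * 5 + [0] * 50)
        p, nulls = null_rank_shuffle(ranked, n_perm=10_000, seed=0)
        # no shuffle should reproduce max_W = 1 (chance < 1e-7)
        assert p == pytest.approx(1 / 10_001)
        assert nulls.max() < 1.0

    def test_zero_permutations_is_an_error(self):
        with pytest.raises(ValueError):
            null_rank_shuffle(make_ranked([1, 0]), n_perm=0)

    def test_reproducible_under_seed(self):
        ranked = make_ranked([1, 0, 1, 0, 0, 1, 0, 0])
        p1, n1 = null_rank_shuffle(ranked, n_perm=500, seed=42)
        p2, n2 = null_rank_shuffle(ranked, n_perm=500, seed=42)
        assert p1 == p2 and np.array_equal(n1, n2)

    def test_uniform_p_under_null(self):
        # labels placed independently of rank -> p ~ U(0,1)
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(120):
            labels = np.zeros(80, dtype=bool)
            labels[rng.choice(80, size=16, replace=False)] = True
            p, _ = null_rank_shuffle(make_ranked(labels), n_perm=199, seed=rng)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestNullGenusResample:
    @staticmethod
    def table_with_genera(sizes, rng):
        rows = []
        i = 0
        for g, size in enumerate(sizes):
            for _ in range(size):
                rows.append({"model_id": f"m{i:03d}", "genus": f"g{g}",
                             "score": rng.random(), "disease_enriched": False})
                i += 1
        return pd.DataFrame(rows)

    def test_singleton_genera_reduce_to_label_shuffle(self):
        rng = np.random.default_rng(0)
        table = self.table_with_genera([1] * 40, rng)
        table.loc[:7, "disease_enriched"] = True
        ranked = rank_models(table, "score", seed=1)
        p2, nulls2 = null_genus_resample(table, ranked, n_genera=8, n_perm=4000, seed=2)
        p1, nulls1 = null_rank_shuffle(ranked, n_perm=4000, seed=3)
        # same null distribution: compare upper quantiles within MC error
        assert np.quantile(nulls1, 0.9) == pytest.approx(np.quantile(nulls2, 0.9), abs=0.08)
        assert abs(p1 - p2) < 0.1

    def test_giant_genus_dominates_draws(self):
        rng = np.random.default_rng(1)
        table = self.table_with_genera([60] + [1] * 10, rng)
        ranked = rank_models(table, "score", seed=0)
        ranked.labels[:3] = True  # arbitrary positives for the observed stat
        g_of = dict(zip(table.model_id, table.genus))
        _, nulls = null_genus_resample(table, ranked, n_genera=3, n_perm=400, seed=4)
        # frequency check via direct resampling of the internal scheme:
        # weight 60 vs 10 singleton genera; the giant genus should be chosen
        # in essentially every draw of 3
        hits = 0
        rng2 = np.random.default_rng(5)
        for _ in range(400):
            w = np.array([60.0] + [1.0] * 10)
            keys = rng2.exponential(size=11) / w
            chosen = set(np.argpartition(keys, 2)[:3])
            hits += 0 in chosen
        assert hits / 400 > 0.95

    def test_too_many_genera_is_an_error(self):
        rng = np.random.default_rng(0)
        table = self.table_with_genera([2, 2], rng)
        ranked = rank_models(table, "score", seed=0)
        with pytest.raises(ValueError):
            null_genus_resample(table, ranked, n_genera=3, n_perm=10, seed=0)


class TestRankModels:
    def test_descending_by_score(self):
        table = pd.DataFrame(
            {"model_id": ["a", "b", "c"], "score": [0.1, 0.9, 0.5],
             "disease_enriched": [False, True, False]}
        )
        ranked = rank_models(table, "score", seed=0)
        assert ranked.model_ids == ["b", "c", "a"]
        assert ranked.P == 1 and ranked.N == 2

    def test_tie_break_is_seeded_shuffle(self):
        table = pd.DataFrame(
            {"model_id": [f"m{i}" for i in range(30)], "score": 0.5,
             "disease_enriched": [False] * 30}
        )
        orders = {tuple(rank_models(table, "score", seed=s).model_ids) for s in range(5)}
        assert len(orders) > 1  # different seeds, different tie orders
        again = rank_models(table, "score", seed=3).model_ids
        assert again == rank_models(table, "score", seed=3).model_ids


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_exact_small_sample(self):
        U, p = mann_whitney_u([4, 5, 6], [1, 2, 3], alternative="greater")
        assert p == pytest.approx(1 / 20)

    def test_identical_constant_groups(self):
        U, p = mann_whitney_u([2.0] * 5, [2.0] * 5, alternative="two_sided")
        assert p == pytest.approx(1.0)

    def test_u_identity(self):
        a, b = [1.0, 3.0, 5.0, 7.0], [2.0, 4.0, 6.0]
        Uab, _ = mann_whitney_u(a, b)
        Uba, _ = mann_whitney_u(b, a)
        assert Uab + Uba == len(a) * len(b)

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_computation(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_order_preserving_and_bounded(self):
        raw = [0.5, 0.001, 0.04, 1.0]
        adj = bh_adjust(raw)
        assert (adj >= np.asarray(raw) - 1e-15).all() and (adj <= 1.0).all()
        # position i of the output corresponds to position i of the input
        assert adj[1] == adj.min()

    def test_invalid_p_is_an_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


# ---------------------------------------------------------------------------
# blocked case-control machinery
# ---------------------------------------------------------------------------

def study_set(values_by_block, cases_by_block):
    """Build a one-species AbundanceStudySet from per-block value lists."""
    tables, meta = {}, []
    scale = max(max(v) for v in values_by_block.values()) * 2
    for block, vals in values_by_block.items():
        cols = {}
        for i, v in enumerate(vals):
            sample = f"{block}_s{i}"
            cols[sample] = [v / scale]  # keep relative abundances in [0,1]
            meta.append({
                "sample": sample, "study": block,
                "label": "case" if cases_by_block[block][i] else "control",
                "sub_block": "",
            })
        tables[block] = pd.DataFrame(cols, index=["spX"])
    return AbundanceStudySet(tables=tables, metadata=pd.DataFrame(meta))


class TestBlockedWilcoxon:
    def test_single_block_matches_unblocked_rank_sum(self):
        # one block: the test IS the exhaustive permutation rank-sum test
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        cases = [False, False, False, False, True, True, True, True]
        abund = study_set({"s1": vals}, {"s1": cases})
        p = blocked_wilcoxon(abund, "spX", n_perm=1000, seed=0)
        # exhaustive two-sided rank-sum: only the two extreme assignments
        # of C(8,4)=70 reach |T - 18| = 8
        assert p == pytest.approx(2 / 70)

    def test_two_block_effect_hidden_from_pooled_ranks(self):
        # within every block cases sit above controls, but the blocks'
        # value ranges make the pooled rank-sum look null
        low = {"vals": [1, 2, 3, 4, 5, 6, 7, 8],
               "cases": [False, False, True, True, True, True, True, True]}
        high = {"vals": [9, 10, 11, 12, 13, 14, 15, 16],
                "cases": [False, False, False, False, False, False, True, True]}
        abund = study_set(
            {"lo": low["vals"], "hi": high["vals"]},
            {"lo": low["cases"], "hi": high["cases"]},
        )
        p_blocked = blocked_wilcoxon(abund, "spX", n_perm=1000, seed=0)
        pooled = study_set(
            {"one": low["vals"] + high["vals"]},
            {"one": low["cases"] + high["cases"]},
        )
        p_pooled = blocked_wilcoxon(pooled, "spX", n_perm=1000, seed=0)
        assert p_blocked < 0.05
        assert p_pooled > 0.3

    def test_single_class_block_dropped_with_warning(self, caplog):
        abund = study_set(
            {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0]},
            {"a": [False, False, True, True], "b": [True, True]},
        )
        with caplog.at_level("WARNING"):
            p = blocked_wilcoxon(abund, "spX", n_perm=100, seed=0)
        assert any("single class" in r.message for r in caplog.records)
        assert 0 < p <= 1

    def test_all_single_class_is_an_error(self):
        abund = study_set({"a": [1.0, 2.0]}, {"a": [True, True]})
        with pytest.raises(ValueError):
            blocked_wilcoxon(abund, "spX", n_perm=10, seed=0)

    def test_uniform_p_under_null_monte_carlo(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(100):
            vals = {f"b{j}": list(rng.random(12)) for j in range(3)}
            cases = {
                f"b{j}": list(np.isin(np.arange(12), rng.choice(12, 6, replace=False)))
                for j in range(3)
            }
            abund = study_set(vals, cases)
            ps.append(
                blocked_wilcoxon(
                    abund, "spX", n_perm=199,
                    seed=np.random.SeedSequence(int(rng.integers(2**31))),
                    exact_limit=0,
                )
            )
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestAuc:
    def test_perfect_separation(self):
        assert auc_case_control([5, 6, 1, 2], [True, True, False, False]) == 1.0

    def test_all_ties(self):
        assert auc_case_control([3, 3, 3, 3], [True, False, True, False]) == 0.5

    def test_pair_counting_example(self):
        assert auc_case_control([3, 1, 2, 0], [True, True, False, False]) == 0.75

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            auc_case_control([1, 2], [True, True])


class TestDifferentialSpecies:
    def test_rare_species_discarded_by_prevalence_filter(self):
        from passengerscreen.synthetic import generate_abundance_studies

        abund = generate_abundance_studies(
            n_studies=3, n_samples_per_study=12, n_species=6, seed=0
        )
        # force one species to be vanishingly rare everywhere
        for tab in abund.tables.values():
            tab.loc["sp000"] = 1e-6
        calls = differential_species(abund, n_perm=99, seed=0)
        assert "sp000" not in set(calls["species"])

    def test_planted_enrichment_recovered(self):
        from passengerscreen.synthetic import generate_abundance_studies

        abund = generate_abundance_studies(
            n_studies=5, n_samples_per_study=60, n_species=20,
            planted_effects={"sp003": 2.5}, seed=1,
        )
        calls = differential_species(abund, n_perm=2000, seed=2).set_index("species")
        assert calls.loc["sp003", "auc"] > 0.5
        assert calls.loc["sp003", "classification"] == "enriched"

    def test_no_calls_without_effects(self):
        from passengerscreen.synthetic import generate_abundance_studies

        abund = generate_abundance_studies(
            n_studies=4, n_samples_per_study=30, n_species=25, seed=5
        )
        calls = differential_species(abund, n_perm=500, seed=6)
        assert (calls["classification"] == "enriched").sum() == 0

    def test_too_few_studies_is_an_error(self):
        from passengerscreen.synthetic import generate_abundance_studies

        abund = generate_abundance_studies(n_studies=3, n_samples_per_study=8,
                                           n_species=5, seed=0)
        with pytest.raises(ValueError):
            differential_species(abund, min_studies=4, n_perm=10, seed=0)
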
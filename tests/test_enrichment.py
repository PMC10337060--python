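"""Oracle tests for differential expression, BH, preranked GSEA and ssGSEA.

The GSEA oracle is an independent brute-force implementation: it builds the
full running sum gene by gene and enumerates every same-size subset of the
universe for the exact permutation null.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from margin_profiler import enrichment
from margin_profiler.enrichment import (
    RankedList,
    bh_adjust,
    differential_expression,
    gsea_preranked,
    ssgsea_scores,
)
from margin_profiler.io_core import ExpressionMatrix, FormatError, GeneSet, GeneSetCollection
from tests.conftest import make_log2_matrix


# ---------------------------------------------------------------------------
# Independent oracles


def brute_force_es(stats_desc: np.ndarray, hit_mask: np.ndarray, p: float = 1.0) -> float:
    """Running-sum ES computed gene by gene (independent of the implementation)."""
    n = stats_desc.size
    n_hit = int(hit_mask.sum())
    w = np.abs(stats_desc) ** p
    denom = w[hit_mask].sum()
    running = 0.0
    best_pos, best_neg = -np.inf, np.inf
    for i in range(n):
        if hit_mask[i]:
            running += w[i] / denom if denom > 0 else 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        best_pos = max(best_pos, running)
        best_neg = min(best_neg, running)
    return best_pos if best_pos >= -best_neg - 1e-12 else best_neg


def brute_force_exact_p(stats_desc: np.ndarray, size: int, es_obs: float) -> float:
    """Exact sign-matched permutation p by exhaustive subset enumeration."""
    n = stats_desc.size
    null = []
    for combo in itertools.combinations(range(n), size):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        null.append(brute_force_es(stats_desc, mask))
    null = np.array(null)
    same = null >= 0 if es_obs >= 0 else null < 0
    return float((np.abs(null[same]) >= abs(es_obs) - 1e-12).sum() / same.sum())


def hand_bh(pvals):
    """q_i = min_{j>=i} p_(j) * m / j, mapped back to input order."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q_sorted, 1.0)
    return out


# ---------------------------------------------------------------------------
# Differential expression


class TestDifferentialExpression:
    def test_identical_groups_give_zero_fc_p_one(self):
        vals = np.column_stack([[1, 2, 3]] * 2 + [[1, 2, 3]] * 2).T.astype(float)
        em = make_log2_matrix(np.tile([1.0, 2.0, 3.0], (4, 1)).T[:1])
        # one gene, values (1,2,3) vs (1,2,3) -> need 3+3 samples
        df = pd.DataFrame([[1, 2, 3, 1, 2, 3]], index=["g"], columns=list("abcdef"), dtype=float)
        em = ExpressionMatrix(df, "log2_tpm_plus1")
        res = differential_expression(em, ["a", "b", "c"], ["d", "e", "f"])
        assert res.loc["g", "log2fc"] == 0
        assert res.loc["g", "pval"] == 1.0

    def test_null_type1_rate(self, rng):
        """Equal group means: fraction p < 0.05 is 0.05 +- 0.02 over 200+ genes."""
        vals = rng.normal(5.0, 1.0, size=(400, 20))
        em = make_log2_matrix(vals)
        res = differential_expression(em, em.sample_ids[:10], em.sample_ids[10:])
        frac = (res["pval"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_planted_shift_recovered(self, rng):
        """+1 log2 shift at SD 0.3, n=10/10: padj < 0.05 for >= 95% of planted genes."""
        vals = rng.normal(5.0, 0.3, size=(300, 20))
        vals[:100, :10] += 1.0
        em = make_log2_matrix(vals)
        res = differential_expression(em, em.sample_ids[:10], em.sample_ids[10:])
        planted = res.iloc[:100]
        assert (planted["padj"] < 0.05).mean() >= 0.95
        assert (planted["log2fc"] > 0).all()

    def test_constant_gene_flagged(self):
        df = pd.DataFrame([[2.0] * 8, [1, 2, 3, 4, 2, 3, 4, 5]], index=["flat", "ok"],
                          columns=list("abcdefgh"), dtype=float)
        em = ExpressionMatrix(df, "log2_tpm_plus1")
        res = differential_expression(em, list("abcd"), list("efgh"))
        assert res.loc["flat", "constant"]
        assert res.loc["flat", "pval"] == 1.0
        assert not res.loc["ok", "constant"]

    def test_small_group_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            differential_expression(small_matrix, ["s1"], ["s2"])


class TestBH:
    def test_hand_oracle_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @pytest.mark.parametrize("p", [[0.5], [1.0, 1.0, 1.0]])
    def test_degenerate_inputs(self, p):
        np.testing.assert_allclose(bh_adjust(p), p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_hand_oracle_and_order_invariant(self, pvals):
        got = bh_adjust(pvals)
        np.testing.assert_allclose(got, hand_bh(pvals), atol=1e-12)
        perm = np.random.default_rng(0).permutation(len(pvals))
        got_perm = bh_adjust(np.asarray(pvals)[perm])
        np.testing.assert_allclose(got_perm, got[perm], atol=1e-12)


# ---------------------------------------------------------------------------
# Preranked GSEA


def ranked(stats_map) -> RankedList:
    return RankedList.from_stats(pd.Series(stats_map, dtype=float))


class TestGseaPreranked:
    def test_top_set_has_maximal_es(self):
        rl = ranked({"g1": 3, "g2": 2, "g3": 1, "g4": -1})
        coll = GeneSetCollection([GeneSet("S", "", ("g1", "g2"))])
        res = gsea_preranked(rl, coll, min_size=1, exact=True)[0]
        assert res.es == pytest.approx(1.0)
        assert res.leading_edge == ["g1", "g2"]

    def test_bottom_set_has_negative_es(self):
        rl = ranked({"g1": 3, "g2": 2, "g3": 1, "g4": -1})
        coll = GeneSetCollection([GeneSet("S", "", ("g4",))])
        res = gsea_preranked(rl, coll, min_size=1, exact=True)[0]
        assert res.es < 0
        assert res.nes < 0
        assert res.leading_edge == ["g4"]

    def test_matches_exhaustive_oracle_on_small_universes(self, rng):
        """ES to 1e-12 and exact permutation p on universes <= 10 genes."""
        for trial in range(20):
            n = int(rng.integers(6, 11))
            stats_vals = np.sort(rng.normal(size=n))[::-1]
            genes = [f"g{i}" for i in range(n)]
            size = int(rng.integers(2, n - 1))
            members = tuple(rng.choice(genes, size=size, replace=False))
            rl = RankedList.from_stats(pd.Series(stats_vals, index=genes))
            coll = GeneSetCollection([GeneSet("S", "", members)])
            res = gsea_preranked(rl, coll, min_size=1, exact=True)[0]
            hit_mask = np.isin(np.array(rl.gene_ids), members)
            es_oracle = brute_force_es(rl.stats, hit_mask)
            assert res.es == pytest.approx(es_oracle, abs=1e-12)
            p_oracle = brute_force_exact_p(rl.stats, size, es_oracle)
            assert res.pval == p_oracle

    def test_uniform_null_p_and_unit_nes(self, rng):
        """Random 8-gene sets in a 50-gene ranking: p roughly uniform, mean
        NES of positive-ES draws near 1."""
        genes = [f"g{i}" for i in range(50)]
        stats_vals = pd.Series(rng.normal(size=50), index=genes)
        rl = RankedList.from_stats(stats_vals)
        pvals, pos_nes = [], []
        for draw in range(200):
            members = tuple(np.random.default_rng(draw).choice(genes, 8, replace=False))
            res = gsea_preranked(rl, GeneSetCollection([GeneSet("S", "", members)]),
                                 n_perm=400, seed=draw)[0]
            pvals.append(res.pval)
            if res.es > 0:
                pos_nes.append(res.nes)
        pvals = np.array(pvals)
        # uniformity: decile occupancy within a loose band
        assert 0.35 <= (pvals < 0.5).mean() <= 0.65
        assert 0.03 <= (pvals < 0.1).mean() <= 0.2
        assert abs(np.mean(pos_nes) - 1.0) < 0.15

    def test_es_scale_invariance_at_weight_one(self, rng):
        genes = [f"g{i}" for i in range(30)]
        stats_vals = pd.Series(rng.normal(size=30), index=genes)
        members = tuple(genes[i] for i in (2, 5, 11, 17, 23))
        coll = GeneSetCollection([GeneSet("S", "", members)])
        r1 = gsea_preranked(RankedList.from_stats(stats_vals), coll, n_perm=100, seed=0)[0]
        r2 = gsea_preranked(RankedList.from_stats(stats_vals * 7.5), coll, n_perm=100, seed=0)[0]
        assert r1.es == pytest.approx(r2.es, abs=1e-12)

    def test_empty_overlap_skipped_and_flat_ranking_rejected(self):
        rl = ranked({"g1": 3, "g2": 2, "g3": 1, "g4": -1, "g5": 0.5})
        coll = GeneSetCollection([GeneSet("S", "", ("zz",))])
        with pytest.warns(UserWarning, match="no overlap"):
            assert gsea_preranked(rl, coll, min_size=1) == []
        with pytest.raises(FormatError, match="ranking undefined"):
            RankedList.from_stats(pd.Series({"a": 1.0, "b": 1.0}))

    def test_ties_broken_by_gene_id(self):
        rl = ranked({"b": 2.0, "a": 2.0, "c": 1.0})
        assert rl.gene_ids == ["a", "b", "c"]


# ---------------------------------------------------------------------------
# ssGSEA


def hand_ssgsea_alpha0(values: pd.Series, members: set) -> float:
    """Unweighted running-sum area, computed directly from the definition."""
    order = sorted(values.index, key=lambda g: (-values[g], g))
    n = len(order)
    n_hit = sum(g in members for g in order)
    running, total, hits, misses = 0.0, 0.0, 0, 0
    for g in order:
        if g in members:
            hits += 1
        else:
            misses += 1
        total += hits / n_hit - misses / (n - n_hit)
    return total


class TestSsgsea:
    def test_identical_samples_identical_scores(self):
        df = pd.DataFrame({"s1": [5.0, 3, 1, 2], "s2": [5.0, 3, 1, 2]},
                          index=["g0", "g1", "g2", "g3"])
        em = ExpressionMatrix(df, "log2_tpm_plus1")
        coll = GeneSetCollection([GeneSet("S", "", ("g0", "g1"))])
        scores = ssgsea_scores(em, coll)
        assert scores.loc["s1", "S"] == scores.loc["s2", "S"]

    def test_alpha_zero_matches_hand_oracle(self):
        vals = pd.Series({"g0": 9.0, "g1": 7.0, "g2": 5.0, "g3": 4.0, "g4": 2.0, "g5": 1.0})
        df = pd.DataFrame({"s1": vals, "s2": vals[::-1].values})
        em = ExpressionMatrix(df, "log2_tpm_plus1")
        members = {"g1", "g3"}
        coll = GeneSetCollection([GeneSet("S", "", tuple(sorted(members)))])
        got = ssgsea_scores(em, coll, alpha=0.0, normalize=False)
        assert got.loc["s1", "S"] == pytest.approx(
            hand_ssgsea_alpha0(df["s1"], members), abs=1e-12
        )
        assert got.loc["s2", "S"] == pytest.approx(
            hand_ssgsea_alpha0(df["s2"], members), abs=1e-12
        )

    def test_signature_at_top_scores_higher(self, rng):
        base = rng.uniform(1, 5, size=30)
        top = base.copy()
        top[:5] = 10.0
        bottom = base.copy()
        bottom[:5] = 0.0
        genes = [f"g{i}" for i in range(30)]
        em = ExpressionMatrix(pd.DataFrame({"hi": top, "lo": bottom}, index=genes),
                              "log2_tpm_plus1")
        coll = GeneSetCollection([GeneSet("S", "", tuple(genes[:5]))])
        scores = ssgsea_scores(em, coll)
        assert scores.loc["hi", "S"] > scores.loc["lo", "S"]

    def test_set_covering_universe_rejected(self):
        df = pd.DataFrame({"s1": [1.0, 2.0]}, index=["a", "b"])
        em = ExpressionMatrix(df, "log2_tpm_plus1")
        coll = GeneSetCollection([GeneSet("S", "", ("a", "b"))])
        with pytest.raises(FormatError, match="miss term"):
            ssgsea_scores(em, coll)
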
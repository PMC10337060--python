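"""CNV inference, ploidy calling and aneuploidy statistics.

The Fisher oracle enumerates the hypergeometric distribution of the 2x2
table directly; planted-effect oracles use the synthetic cell generator.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from margin_profiler import synthetic
from margin_profiler.cnv import (
    call_ploidy,
    cluster_aneuploidy_enrichment,
    infer_cnv,
    spot_cnv_contrast,
)
from margin_profiler.io_core import ExpressionMatrix, FormatError


def make_positions(n_per_chrom: int, chroms=("chr7", "chr10")) -> "synthetic.GenePositionTable":
    from margin_profiler.io_core import GenePositionTable

    rows = []
    gi = 0
    for chrom in chroms:
        for j in range(n_per_chrom):
            rows.append({"gene_id": f"G{gi:05d}", "chromosome": chrom,
                         "start": 1 + j, "order_index": j + 1})
            gi += 1
    return GenePositionTable(pd.DataFrame(rows).set_index("gene_id"))


class TestInferCnv:
    def test_query_equal_to_reference_mean_gives_exact_zero(self):
        pos = make_positions(60)
        genes = pos.gene_ids
        base = np.linspace(1, 5, len(genes))
        df = pd.DataFrame({"ref1": base, "ref2": base, "q": base}, index=genes)
        em = ExpressionMatrix(df, "log2_tpm_plus1")
        for window in (1, 11, 51):
            prof = infer_cnv(em, pos, ["ref1", "ref2"], window=window)
            assert (prof.values.to_numpy() == 0).all()

    def test_window_one_is_identity_smoothing(self, rng):
        pos = make_positions(60)
        genes = pos.gene_ids
        df = pd.DataFrame(rng.uniform(0, 8, size=(len(genes), 3)),
                          index=genes, columns=["r1", "r2", "q"])
        em = ExpressionMatrix(df, "log2_tpm_plus1")
        prof = infer_cnv(em, pos, ["r1", "r2"], window=1, clamp=3.0)
        expected = df.sub(df[["r1", "r2"]].mean(axis=1), axis=0).clip(-3, 3)
        np.testing.assert_allclose(
            prof.values.loc[expected.index].to_numpy(), expected.to_numpy(), atol=1e-12
        )

    def test_null_query_chromosome_means_small(self, rng):
        """Query drawn from the reference distribution: chromosome means
        within +-0.05 (SD 0.3 noise, 200 genes per chromosome)."""
        pos = make_positions(200)
        genes = pos.gene_ids
        base = rng.uniform(2, 6, len(genes))
        cols = {f"r{i}": base + rng.normal(0, 0.3, len(genes)) for i in range(30)}
        cols["q"] = base + rng.normal(0, 0.3, len(genes))
        em = ExpressionMatrix(pd.DataFrame(cols, index=genes).clip(lower=0), "log2_tpm_plus1")
        prof = infer_cnv(em, pos, [f"r{i}" for i in range(30)])
        assert prof.chrom_means["q"].abs().max() < 0.05

    def test_planted_chr7_shift_recovered(self, rng):
        pos = make_positions(200)
        genes = pos.gene_ids
        chr7 = (pos.table["chromosome"] == "chr7").to_numpy()
        base = rng.uniform(2, 6, len(genes))
        cols = {f"r{i}": base + rng.normal(0, 0.3, len(genes)) for i in range(30)}
        q = base + rng.normal(0, 0.3, len(genes))
        q[chr7] += 0.5
        cols["q"] = q
        em = ExpressionMatrix(pd.DataFrame(cols, index=genes).clip(lower=0), "log2_tpm_plus1")
        prof = infer_cnv(em, pos, [f"r{i}" for i in range(30)])
        assert prof.chrom_means.loc["chr7", "q"] == pytest.approx(0.5, abs=0.1)
        assert abs(prof.chrom_means.loc["chr10", "q"]) < 0.1

    def test_small_chromosome_skipped_with_warning(self, rng):
        from margin_profiler.io_core import GenePositionTable

        rows = [{"gene_id": f"G{i:05d}", "chromosome": "chr7", "start": i + 1,
                 "order_index": i + 1} for i in range(60)]
        rows += [{"gene_id": f"G{i + 60:05d}", "chromosome": "chr10", "start": i + 1,
                  "order_index": i + 1} for i in range(20)]
        pos = GenePositionTable(pd.DataFrame(rows).set_index("gene_id"))
        genes = pos.gene_ids
        df = pd.DataFrame(rng.uniform(0, 5, size=(len(genes), 3)),
                          index=genes, columns=["r1", "r2", "q"])
        em = ExpressionMatrix(df, "log2_tpm_plus1")
        with pytest.warns(UserWarning, match="skipped"):
            infer_cnv(em, pos, ["r1", "r2"], window=101)


class TestCallPloidy:
    def make_profile(self, chr7, chr10):
        from margin_profiler.cnv import CNVProfile

        cm = pd.DataFrame({"c": [chr7, chr10]}, index=["chr7", "chr10"])
        return CNVProfile(pd.DataFrame(), cm, pd.Series(dtype=object), 101, 3.0)

    def test_conjunction_rule(self):
        assert call_ploidy(self.make_profile(0.3, -0.3)).calls.loc["c", "label"] == "aneuploid"
        assert call_ploidy(self.make_profile(0.3, 0.0)).calls.loc["c", "label"] == "diploid"
        assert call_ploidy(self.make_profile(0.05, -0.3)).calls.loc["c", "label"] == "diploid"

    def test_threshold_monotone(self):
        prof = self.make_profile(0.2, -0.2)
        assert call_ploidy(prof, tau=0.1).calls.loc["c", "label"] == "aneuploid"
        assert call_ploidy(prof, tau=0.25).calls.loc["c", "label"] == "diploid"

    def test_missing_chromosome_rejected(self):
        with pytest.raises(FormatError, match="chr10"):
            call_ploidy(self.make_profile(0.3, -0.3), loss_chr="chr10x")


def fisher_enumeration_p(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    support = range(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = {k: stats.hypergeom.pmf(k, n, row1, col1) for k in support}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9)))


class TestClusterEnrichment:
    def run(self, table):
        """table: {cluster: (n_aneuploid, n_diploid)}"""
        from margin_profiler.cnv import PloidyCall

        labels, clusters = [], []
        for cid, (na, nd) in table.items():
            labels += ["aneuploid"] * na + ["diploid"] * nd
            clusters += [cid] * (na + nd)
        idx = [f"c{i}" for i in range(len(labels))]
        calls = PloidyCall(pd.DataFrame({"label": labels}, index=idx), "chr7", "chr10", 0.1)
        return cluster_aneuploidy_enrichment(calls, pd.Series(clusters, index=idx))

    def test_no_association(self):
        enr = self.run({0: (10, 10), 1: (10, 10)})
        assert enr.table.loc[0, "odds_ratio"] == pytest.approx(1.0)
        assert enr.table.loc[0, "pval"] == pytest.approx(1.0)

    def test_cross_product_oracle(self):
        enr = self.run({0: (20, 5), 1: (5, 20)})
        assert enr.table.loc[0, "odds_ratio"] == pytest.approx(16.0)
        lo, hi = enr.table.loc[0, ["ci_low", "ci_high"]]
        assert lo < 16.0 < hi

    def test_p_matches_hypergeometric_enumeration(self):
        for table in [{0: (12, 3), 1: (2, 13)}, {0: (5, 5), 1: (1, 9)}, {0: (8, 1), 1: (3, 10)}]:
            enr = self.run(table)
            (a, c), (b, d) = table[0], table[1]
            expected = fisher_enumeration_p(a, b, c, d)
            assert enr.table.loc[0, "pval"] == pytest.approx(expected, rel=1e-9)

    def test_extreme_association_detected(self):
        enr = self.run({0: (10, 5), 1: (0, 15)})
        assert enr.table["odds_ratio"].idxmax() == 0
        assert enr.table.loc[0, "pval"] < 0.05

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="2 clusters"):
            self.run({0: (5, 5)})


class TestPloidyPipeline:
    def test_planted_mla_recovered(self):
        """5% planted MLA at Chr7 +0.5 / Chr10 -0.5: sensitivity >= 0.9,
        specificity >= 0.95; the planted cluster carries the maximal OR."""
        counts, ann, truth = synthetic.generate_single_cells(n_cells=1000, seed=42)
        pos = synthetic.default_gene_positions(counts.shape[0])
        log = counts.counts_to_log2()
        ref = ann.index[ann["state"] == "myeloid_diploid"].tolist()
        calls = call_ploidy(infer_cnv(log, pos, ref))
        pred = calls.calls["label"]
        tp = ((pred == "aneuploid") & (truth == "aneuploid")).sum()
        fn = ((pred == "diploid") & (truth == "aneuploid")).sum()
        tn = ((pred == "diploid") & (truth == "diploid")).sum()
        fp = ((pred == "aneuploid") & (truth == "diploid")).sum()
        assert tp / (tp + fn) >= 0.9
        assert tn / (tn + fp) >= 0.95
        enr = cluster_aneuploidy_enrichment(calls, ann["cluster"])
        mla_cluster = ann.loc[ann["state"] == "myeloid_like_aneuploid", "cluster"].iloc[0]
        assert enr.table["odds_ratio"].idxmax() == mla_cluster


class TestSpotContrast:
    def test_planted_grid_contrast(self):
        """CT-adjacent 5ALA niche with Chr7+/Chr10-: top-50 vs NT contrast is
        positive on chr7, negative on chr10, both p < 0.001."""
        from margin_profiler import spatial

        grid, progs, pos = synthetic.generate_spatial_grid(seed=21)
        spatial.score_spots(grid, progs, method="ssgsea")
        ref = (grid.channels["PROLIF"] + grid.channels["ALA_SIG"]).nsmallest(200).index.tolist()
        prof = infer_cnv(grid.expression.to_log2(), pos, ref, window=51)
        res = spot_cnv_contrast(grid, prof, "ALA_SIG", nt_mask=grid.masks["nt"], k=50)
        assert res.loc["chr7", "mean_diff"] > 0
        assert res.loc["chr10", "mean_diff"] < 0
        assert (res["pval"] < 0.001).all()

    def test_null_comparator_p_uniformish(self, rng):
        """NT-vs-NT contrast under exchangeability: p has no systematic
        enrichment below 0.05 (null simulation)."""
        from margin_profiler.cnv import CNVProfile
        from margin_profiler.spatial import SpatialGrid

        hits = 0
        reps = 40
        for rep in range(reps):
            r = np.random.default_rng(rep)
            ids = [f"s{i}" for i in range(120)]
            spots = pd.DataFrame({"x": np.arange(120) % 12, "y": np.arange(120) // 12}, index=ids)
            grid = SpatialGrid(spots=spots)
            grid.channels["score"] = pd.Series(r.normal(size=120), index=ids)
            cm = pd.DataFrame(r.normal(0, 0.05, size=(2, 120)), index=["chr7", "chr10"],
                              columns=ids)
            prof = CNVProfile(pd.DataFrame(), cm, pd.Series(dtype=object), 51, 3.0)
            nt = set(ids[:60])
            res = spot_cnv_contrast(grid, prof, "score", nt_mask=nt, k=30)
            hits += (res["pval"] < 0.05).any()
        assert hits <= 0.35 * reps  # ~2 tests per rep at alpha 0.05

    def test_k_too_large_rejected(self):
        from margin_profiler.cnv import CNVProfile
        from margin_profiler.spatial import SpatialGrid

        ids = [f"s{i}" for i in range(10)]
        spots = pd.DataFrame({"x": range(10), "y": [0] * 10}, index=ids)
        grid = SpatialGrid(spots=spots)
        grid.channels["score"] = pd.Series(range(10), index=ids, dtype=float)
        prof = CNVProfile(pd.DataFrame(), pd.DataFrame(), pd.Series(dtype=object), 1, 3.0)
        with pytest.raises(ValueError, match="need 50"):
            spot_cnv_contrast(grid, prof, "score", nt_mask=set(ids[:5]), k=50)
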
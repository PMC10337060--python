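"""Expression-inferred copy number, ploidy calls, and aneuploidy statistics.

Relative copy number is inferred from a log2 expression matrix by
subtracting the per-gene mean of designated reference (presumed-diploid)
cells, clamping extreme residuals, and smoothing along each chromosome with
a centered moving average in genomic order (the window shrinks at
chromosome edges).  A cell is called aneuploid when its smoothed chr7 mean
exceeds +tau AND its chr10 mean falls below -tau (the conjunction encodes
the canonical glioblastoma Chr7-gain / Chr10-loss karyotype).  Downstream
statistics: per-cluster Fisher enrichment of aneuploid cells, and a top-k
spot contrast of chromosome means between signature-enriched and non-tumor
spots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust
from .io_core import ExpressionMatrix, GenePositionTable, FormatError

__all__ = [
    "CNVProfile",
    "infer_cnv",
    "PloidyCall",
    "call_ploidy",
    "ClusterEnrichment",
    "cluster_aneuploidy_enrichment",
    "spot_cnv_contrast",
]


@dataclass
class CNVProfile:
    values: pd.DataFrame       # gene-windows x cells, smoothed relative log2
    chrom_means: pd.DataFrame  # chromosomes x cells
    gene_chromosome: pd.Series
    window: int
    clamp: float


def infer_cnv(
    expr: ExpressionMatrix,
    positions: GenePositionTable,
    reference_cells: list[str],
    window: int = 101,
    clamp: float = 3.0,
) -> CNVProfile:
    """Infer smoothed relative copy number from log2 expression.

    Per gene: subtract the mean over reference cells; clamp to +-``clamp``;
    per chromosome (genes in genomic order) apply a centered moving average
    of width ``window`` with shrinking edges.  Chromosomes with fewer than
    window/2 matched genes are skipped with a warning.
    """
    missing = [c for c in reference_cells if c not in expr.values.columns]
    if missing:
        raise ValueError(f"reference cell {missing[0]!r} not in the matrix")
    if not reference_cells:
        raise ValueError("need at least one reference cell")

    vals = expr.values
    ref_mean = vals[reference_cells].mean(axis=1)
    centered = vals.sub(ref_mean, axis=0).clip(-clamp, clamp)

    smoothed_parts = []
    chrom_of: dict[str, str] = {}
    for chrom in positions.chromosomes():
        genes = [g for g in positions.genes_on(chrom) if g in vals.index]
        if len(genes) < window / 2:
            warnings.warn(f"{chrom}: only {len(genes)} genes matched (< window/2); skipped")
            continue
        block = centered.loc[genes]
        sm = block.rolling(window, center=True, min_periods=1).mean()
        smoothed_parts.append(sm)
        for g in genes:
            chrom_of[g] = chrom
    if not smoothed_parts:
        raise FormatError("no chromosome had enough matched genes")
    smoothed = pd.concat(smoothed_parts)
    gene_chrom = pd.Series(chrom_of).reindex(smoothed.index)
    chrom_means = smoothed.groupby(gene_chrom).mean()
    return CNVProfile(smoothed, chrom_means, gene_chrom, window, clamp)


@dataclass
class PloidyCall:
    calls: pd.DataFrame  # per cell: label, gain/loss chromosome means
    gain_chr: str
    loss_chr: str
    tau: float


def call_ploidy(
    cnv: CNVProfile, gain_chr: str = "chr7", loss_chr: str = "chr10", tau: float = 0.1
) -> PloidyCall:
    """Label cells aneuploid iff mean(gain_chr) >= +tau AND mean(loss_chr) <= -tau."""
    for chrom in (gain_chr, loss_chr):
        if chrom not in cnv.chrom_means.index:
            raise FormatError(f"chromosome {chrom!r} absent from the CNV profile")
    gain = cnv.chrom_means.loc[gain_chr]
    loss = cnv.chrom_means.loc[loss_chr]
    label = np.where((gain >= tau) & (loss <= -tau), "aneuploid", "diploid")
    calls = pd.DataFrame({
        "label": label,
        f"{gain_chr}_mean": gain,
        f"{loss_chr}_mean": loss,
    })
    calls.index.name = "cell"
    return PloidyCall(calls, gain_chr, loss_chr, tau)


@dataclass
class ClusterEnrichment:
    table: pd.DataFrame  # per cluster: counts, odds ratio, CI, p, padj


def cluster_aneuploidy_enrichment(calls: PloidyCall, clusters: pd.Series) -> ClusterEnrichment:
    """Fisher exact enrichment of aneuploid cells per cluster (one-vs-rest).

    Odds ratios use the Haldane-Anscombe 0.5 correction when any cell of the
    2x2 table is zero; 95% CIs are Woolf (logit) intervals; p-values are
    BH-adjusted across clusters.
    """
    clusters = clusters.reindex(calls.calls.index)
    ids = sorted(clusters.dropna().unique())
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters")
    aneu = (calls.calls["label"] == "aneuploid").to_numpy()
    if not aneu.any():
        raise ValueError("no aneuploid cells; enrichment undefined")

    rows = []
    for cid in ids:
        inc = (clusters == cid).to_numpy()
        a = int((aneu & inc).sum())        # aneuploid in cluster
        b = int((aneu & ~inc).sum())       # aneuploid outside
        c = int((~aneu & inc).sum())       # diploid in cluster
        d = int((~aneu & ~inc).sum())      # diploid outside
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        else:
            aa, bb, cc, dd = a, b, c, d
        orr = (aa * dd) / (bb * cc)
        se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        lo, hi = np.exp(np.log(orr) - 1.96 * se), np.exp(np.log(orr) + 1.96 * se)
        rows.append({"cluster": cid, "aneuploid_in": a, "aneuploid_out": b,
                     "diploid_in": c, "diploid_out": d,
                     "odds_ratio": orr, "ci_low": lo, "ci_high": hi, "pval": p})
    df = pd.DataFrame(rows).set_index("cluster")
    df["padj"] = bh_adjust(df["pval"])
    return ClusterEnrichment(df)


def spot_cnv_contrast(
    grid,
    cnv: CNVProfile,
    score_name: str,
    nt_mask: set[str] | list[str],
    k: int = 50,
    chromosomes: tuple[str, ...] = ("chr7", "chr10"),
) -> pd.DataFrame:
    """Contrast chromosome means between the top-k signature spots and k NT spots.

    Top-k spots are taken by score descending (ties broken by spot id); the
    NT comparator is the k lowest-scoring spots of ``nt_mask``.  A two-sided
    Wilcoxon rank-sum test is run per chromosome on the per-spot chromosome
    means.
    """
    scores = grid.channels[score_name]
    nt_ids = [s for s in scores.index if s in set(nt_mask)]
    candidates = [s for s in scores.index if s not in set(nt_mask)]
    if len(candidates) < k or len(nt_ids) < k:
        raise ValueError(
            f"need {k} spots on each side; have {len(candidates)} scored and {len(nt_ids)} NT"
        )
    top = sorted(candidates, key=lambda s: (-scores[s], s))[:k]
    nt = sorted(nt_ids, key=lambda s: (scores[s], s))[:k]

    rows = []
    for chrom in chromosomes:
        if chrom not in cnv.chrom_means.index:
            raise FormatError(f"chromosome {chrom!r} absent from the CNV profile")
        x = cnv.chrom_means.loc[chrom, top].to_numpy()
        y = cnv.chrom_means.loc[chrom, nt].to_numpy()
        stat, p = stats.ranksums(x, y)
        rows.append({"chromosome": chrom, "mean_diff": float(x.mean() - y.mean()),
                     "statistic": float(stat), "pval": float(p)})
    return pd.DataFrame(rows).set_index("chromosome")
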
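"""Differential expression and gene-set enrichment.

The preranked GSEA here follows the weighted Kolmogorov-Smirnov running-sum
statistic: walking down a ranked list, gene-set members ("hits") increment
the sum by their normalized |r|^p weight, non-members decrement it by
1/(N - N_H); the enrichment score ES is the signed maximal deviation.  The
permutation null randomizes gene-set membership over the ranked universe
(gene-label permutation); NES divides ES by the mean |permuted ES| of
matching sign, and the empirical p-value is sign-matched.  On small
universes an exact mode enumerates every same-size subset, giving exact
permutation p-values.

Single-sample GSEA accumulates, per sample, the running difference between
the weighted cumulative hit fraction and the cumulative miss fraction over
the sample's own expression ranking; scores are normalized by the overall
score range of the run.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import ExpressionMatrix, GeneSet, GeneSetCollection, FormatError

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "differential_expression",
    "bh_adjust",
    "gsea_preranked",
    "ssgsea_scores",
]


@dataclass
class RankedList:
    """Genes ordered by a ranking statistic, descending; ties broken by gene id."""

    gene_ids: list[str]
    stats: np.ndarray

    @classmethod
    def from_stats(cls, stats: pd.Series | dict) -> "RankedList":
        s = pd.Series(stats, dtype=float)
        if s.index.has_duplicates:
            dup = s.index[s.index.duplicated()][0]
            raise FormatError(f"duplicate gene {dup!r} in ranking")
        if s.nunique() == 1:
            raise FormatError("all ranking statistics are equal; ranking undefined")
        order = sorted(s.index, key=lambda g: (-s[g], g))
        return cls(list(order), s.loc[order].to_numpy())

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    pval: float
    padj: float
    leading_edge: list[str]
    size: int


# ---------------------------------------------------------------------------
# Differential expression


def differential_expression(
    expr: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    paired: bool = False,
) -> pd.DataFrame:
    """Per-gene two-group test on a log2-scale matrix.

    Welch's t by default; a paired t when ``paired`` (groups must align
    positionally).  Returns a DataFrame with log2 fold change (a - b), t,
    two-sided p, BH-adjusted p, and a ``constant`` flag for genes with no
    variance (p forced to 1).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if paired and len(group_a) != len(group_b):
        raise ValueError("paired test requires equal group sizes")
    a = expr.values[group_a].to_numpy()
    b = expr.values[group_b].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if paired:
            t, p = stats.ttest_rel(a, b, axis=1)
        else:
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    if paired:
        constant = np.isclose((a - b).std(axis=1, ddof=1), 0) & np.isclose(log2fc, 0)
    else:
        constant = np.isclose(a.std(axis=1, ddof=1), 0) & np.isclose(b.std(axis=1, ddof=1), 0)
    undefined = constant | ~np.isfinite(p)
    p = np.where(undefined, 1.0, p)
    t = np.where(undefined, np.nan, t)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "pval": p,
            "padj": bh_adjust(p),
            "constant": undefined,
        },
        index=expr.values.index,
    )
    out.index.name = "gene"
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Preranked GSEA


def _es_from_positions(
    hit_pos: np.ndarray, weights: np.ndarray, n_total: int
) -> tuple[float, int]:
    """ES and peak rank from sorted 0-based hit positions.

    ``weights`` are the |r|^p values at the hit positions (same order).  The
    running sum's extrema occur immediately after each hit and immediately
    before each hit, so only 2*N_H candidate values need inspection.
    """
    n_hit = hit_pos.size
    n_miss = n_total - n_hit
    if n_miss == 0:
        raise FormatError("gene set covers the whole ranked universe; miss term undefined")
    wsum = weights.sum()
    if wsum <= 0:
        cum_hit = np.arange(1, n_hit + 1) / n_hit  # all-zero stats in the set: equal weights
    else:
        cum_hit = np.cumsum(weights) / wsum
    k = np.arange(n_hit)
    miss_before = (hit_pos - k) / n_miss          # misses preceding each hit
    after = cum_hit - miss_before                 # value just after each hit
    before = np.concatenate(([0.0], cum_hit[:-1])) - miss_before  # just before each hit
    candidates = np.concatenate([after, before])
    positions = np.concatenate([hit_pos, hit_pos - 1])
    i_pos = int(np.argmax(candidates))
    i_neg = int(np.argmin(candidates))
    # |max| ties (within float tolerance) resolve to the positive deviation
    i = i_pos if candidates[i_pos] >= -candidates[i_neg] - 1e-12 else i_neg
    return float(candidates[i]), int(positions[i])


def gsea_preranked(
    ranked: RankedList,
    sets: GeneSetCollection,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 2000,
    exact: bool = False,
    max_exact: int = 500_000,
) -> list[EnrichmentResult]:
    """Preranked GSEA with a gene-label permutation null.

    With ``exact=True`` (and at most ``max_exact`` same-size subsets) the
    null enumerates every subset of the universe, so the reported p-value is
    the exact permutation p.
    """
    n = len(ranked)
    absr = np.abs(ranked.stats) ** weight_p
    index = {g: i for i, g in enumerate(ranked.gene_ids)}
    rng = np.random.default_rng(seed)

    results: list[EnrichmentResult] = []
    for gs in sets:
        hit_pos = np.array(sorted(index[g] for g in gs.genes if g in index))
        size = hit_pos.size
        if size == 0:
            warnings.warn(f"gene set {gs.name!r} has no overlap with the ranked universe; skipped")
            continue
        if not (min_size <= size <= max_size):
            warnings.warn(f"gene set {gs.name!r} (size {size}) outside [{min_size}, {max_size}]; skipped")
            continue
        es, peak = _es_from_positions(hit_pos, absr[hit_pos], n)

        if exact and math.comb(n, size) <= max_exact:
            null = np.array([
                _es_from_positions(np.array(combo), absr[np.array(combo)], n)[0]
                for combo in itertools.combinations(range(n), size)
            ])
            smooth = 0
        else:
            if exact:
                warnings.warn(
                    f"set {gs.name!r}: {math.comb(n, size)} subsets exceed max_exact; falling back to sampling"
                )
            if n_perm < 100:
                raise ValueError("n_perm must be >= 100")
            null = np.empty(n_perm)
            for i in range(n_perm):
                pos = np.sort(rng.choice(n, size=size, replace=False))
                null[i] = _es_from_positions(pos, absr[pos], n)[0]
            smooth = 1

        same_sign = null >= 0 if es >= 0 else null < 0
        n_sign = int(same_sign.sum())
        denom = np.abs(null[same_sign]).mean() if n_sign else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else 0.0
        extreme = int((np.abs(null[same_sign]) >= abs(es) - 1e-12).sum())
        pval = (extreme + smooth) / (n_sign + smooth) if (n_sign + smooth) else 1.0

        if es >= 0:
            le = [g for g in ranked.gene_ids[: peak + 1] if g in set(gs.genes)]
        else:
            le = [g for g in ranked.gene_ids[peak:] if g in set(gs.genes)]
        results.append(EnrichmentResult(gs.name, es, nes, pval, np.nan, le, size))

    if results:
        padj = bh_adjust([r.pval for r in results])
        for r, q in zip(results, padj):
            r.padj = float(q)
    return results


# ---------------------------------------------------------------------------
# Single-sample GSEA


def _ssgsea_sample(order_weights: np.ndarray, hit_mask: np.ndarray) -> float:
    # order_weights: |rank value|^alpha in descending-expression order
    n = order_weights.size
    n_hit = int(hit_mask.sum())
    n_miss = n - n_hit
    if n_miss == 0:
        raise FormatError("gene set covers all genes; miss term undefined")
    w = np.where(hit_mask, order_weights, 0.0)
    wsum = w.sum()
    cum_hit = np.cumsum(w) / (wsum if wsum > 0 else 1.0)
    cum_miss = np.cumsum(~hit_mask) / n_miss
    return float(np.sum(cum_hit - cum_miss))


def ssgsea_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """ssGSEA: per-sample, per-set running-sum enrichment (samples x sets).

    Genes are ranked per sample by expression (descending, ties by gene id);
    the rank value of the top gene is N.  With ``normalize`` the whole score
    table is divided by its max - min, as in the original formulation.
    """
    vals = expr.values
    n_genes, n_samples = vals.shape
    genes = np.array(vals.index)
    # stable ordering: descending value, gene id as tie-break
    gene_order = np.argsort(genes, kind="stable")
    member = {gs.name: np.isin(genes, gs.genes) for gs in sets}
    for name, m in member.items():
        if not m.any():
            warnings.warn(f"gene set {name!r} has no overlap with the matrix; skipped")
    used = [name for name, m in member.items() if m.any()]

    rank_value = np.arange(n_genes, 0, -1, dtype=float)  # N .. 1 along descending order
    weights_desc = np.abs(rank_value) ** alpha
    scores = pd.DataFrame(index=vals.columns, columns=used, dtype=float)
    arr = vals.to_numpy()
    for j, sample in enumerate(vals.columns):
        col = arr[gene_order, j]
        desc = gene_order[np.argsort(-col, kind="stable")]
        for name in used:
            hit = member[name][desc]
            scores.loc[sample, name] = _ssgsea_sample(weights_desc, hit)
    if normalize:
        span = scores.to_numpy().max() - scores.to_numpy().min()
        if span > 0:
            scores = scores / span
    scores.index.name = "sample"
    return scores
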
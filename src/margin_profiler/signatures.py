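"""Per-cell signature scoring, composite signature construction, stemness.

UCell scoring is rank-based: within each cell, genes are ranked by
expression (descending, average ties), ranks beyond ``r_max`` are truncated
to ``r_max + 1``, and the Mann-Whitney U statistic of the signature genes'
ranks is mapped to a score in [0, 1] (1 = signature at the very top of the
cell's ranking).  Being rank-based, the score is invariant to any strictly
monotone transform of a cell's expression values.

The composite signature is the non-redundant union of leading-edge genes
from positively enriched gene sets, optionally gated on positive
differential expression in the target compartment; provenance (which source
set contributed each gene) is retained, which makes the construction
idempotent.

The stemness index (mRNAsi) scores samples by Spearman correlation with the
weight vector of a one-class logistic regression trained on stem-cell
profiles, min-max scaled to [0, 1] across the scored cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import EnrichmentResult
from .io_core import ExpressionMatrix, GeneSet, FormatError

__all__ = [
    "ucell_score",
    "CompositeSignature",
    "build_composite_signature",
    "StemnessModel",
    "train_oclr",
    "mrnasi",
]


# ---------------------------------------------------------------------------
# UCell


def ucell_score(expr: ExpressionMatrix, gene_set: GeneSet, r_max: int = 1500) -> pd.Series:
    """UCell score per cell for one gene set.

    U = sum(ranks of signature genes) - n(n+1)/2 with ranks truncated at
    r_max + 1; score = 1 - U / (n * r_max), clamped to [0, 1].
    """
    vals = expr.values
    n_genes = vals.shape[0]
    if r_max > n_genes:
        raise ValueError(f"r_max ({r_max}) must not exceed the gene count ({n_genes})")
    members = [g for g in gene_set.genes if g in vals.index]
    if not members:
        raise FormatError(f"gene set {gene_set.name!r} has no genes in the matrix")
    n = len(members)
    ranks = stats.rankdata(-vals.to_numpy(), axis=0, method="average")
    ranks = np.minimum(ranks, r_max + 1)
    hit = vals.index.get_indexer(members)
    u = ranks[hit].sum(axis=0) - n * (n + 1) / 2
    score = 1.0 - u / (n * r_max)
    return pd.Series(np.clip(score, 0.0, 1.0), index=vals.columns, name=gene_set.name)


# ---------------------------------------------------------------------------
# Composite signature


@dataclass
class CompositeSignature:
    """The combined gene signature plus per-gene provenance."""

    gene_set: GeneSet
    provenance: dict[str, list[str]]  # gene -> contributing source set names
    sources: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.gene_set.genes:
            if not self.provenance.get(g):
                raise FormatError(f"gene {g!r} has no recorded source set")

    def __len__(self) -> int:
        return len(self.gene_set)


def build_composite_signature(
    enrichments: list[EnrichmentResult],
    de: pd.DataFrame | None = None,
    padj_max: float = 0.05,
    require_positive_de: bool = True,
    name: str = "composite_signature",
) -> CompositeSignature:
    """Union the leading edges of significantly, positively enriched sets.

    Contributing sets must satisfy padj < ``padj_max`` and NES > 0; the union
    is optionally restricted to genes with positive log2 fold change in the
    target-vs-rest differential expression table ``de``.
    """
    contributing = []
    for r in enrichments:
        if r.padj < padj_max and r.nes > 0:
            contributing.append(r)
        else:
            warnings.warn(
                f"set {r.set_name!r} excluded from composite (NES={r.nes:.2f}, padj={r.padj:.3g})"
            )
    if not contributing:
        raise FormatError("no gene set passed the significance/direction filter; empty signature")

    if require_positive_de:
        if de is None:
            raise ValueError("require_positive_de=True needs a differential-expression table")
        positive = set(de.index[de["log2fc"] > 0])
    provenance: dict[str, list[str]] = {}
    for r in contributing:
        for g in r.leading_edge:
            if require_positive_de and g not in positive:
                continue
            provenance.setdefault(g, []).append(r.set_name)
    if not provenance:
        raise FormatError("leading edges empty after the positive-DE gate; empty signature")
    genes = tuple(sorted(provenance))
    gs = GeneSet(name, "non-redundant union of enriched leading edges", genes)
    return CompositeSignature(gs, provenance, [r.set_name for r in contributing])


# ---------------------------------------------------------------------------
# One-class logistic regression stemness model


@dataclass
class StemnessModel:
    weights: pd.Series  # per-gene w
    lam: float
    iterations: int
    converged: bool


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def train_oclr(
    stem_expr: ExpressionMatrix | pd.DataFrame,
    lam: float = 1.0,
    max_iter: int = 5000,
    tol: float = 1e-6,
    seed: int = 0,
) -> StemnessModel:
    """Fit a one-class logistic regression to stem-cell profiles.

    Minimizes sum_i softplus(-w.x_i) + (lam/2)||w||^2 by full-batch gradient
    descent with backtracking line search, from w = 0 (deterministic).
    ``stem_expr`` is genes x profiles, centered against a *reference* cohort
    (e.g., full-cohort gene means).  Profiles centered to zero mean among
    themselves are degenerate: the convex objective is then minimized by
    w = 0, and a warning is raised.
    """
    df = stem_expr.values if isinstance(stem_expr, ExpressionMatrix) else stem_expr
    X = df.to_numpy().T  # profiles x genes
    n_profiles, n_genes = X.shape
    if n_profiles < 5:
        raise ValueError("OCLR training needs at least 5 profiles")
    if np.abs(X.mean(axis=0)).max() < 1e-8:
        warnings.warn(
            "training profiles have zero per-gene means; the one-class optimum is w = 0 "
            "(center against an external reference cohort instead)"
        )

    lam = float(lam)

    def loss_grad(w: np.ndarray) -> tuple[float, np.ndarray]:
        z = X @ w
        loss = _softplus(-z).sum() + 0.5 * lam * (w @ w)
        sig = 1.0 / (1.0 + np.exp(z))  # sigmoid(-z)
        grad = -(X.T @ sig) + lam * w
        return loss, grad

    w = np.zeros(n_genes)
    step = 1.0
    loss, grad = loss_grad(w)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        gnorm = np.linalg.norm(grad, np.inf)
        if gnorm < tol:
            converged = True
            break
        # backtracking line search on the Armijo condition
        while step > 1e-12:
            w_new = w - step * grad
            loss_new, grad_new = loss_grad(w_new)
            if loss_new <= loss - 0.5 * step * (grad @ grad):
                break
            step *= 0.5
        w, loss, grad = w_new, loss_new, grad_new
        step = min(step * 2.0, 1e6)
    return StemnessModel(pd.Series(w, index=df.index), lam, it, converged)


def mrnasi(model: StemnessModel, expr: ExpressionMatrix) -> pd.DataFrame:
    """Stemness index per sample: Spearman correlation with the OCLR weights,
    min-max scaled to [0, 1] over the scored cohort."""
    if expr.shape[1] < 2:
        raise ValueError("mRNAsi range scaling needs at least 2 samples")
    shared = expr.values.index.intersection(model.weights.index)
    if len(shared) < 3:
        raise FormatError(f"only {len(shared)} genes shared with the stemness model")
    w = model.weights.loc[shared].to_numpy()
    raw = np.array([
        stats.spearmanr(w, expr.values.loc[shared, s]).statistic for s in expr.values.columns
    ])
    span = raw.max() - raw.min()
    if span <= 0 or not np.isfinite(span):
        raise FormatError("all raw stemness scores equal; index undefined")
    out = pd.DataFrame({"raw": raw, "mrnasi": (raw - raw.min()) / span}, index=expr.values.columns)
    out.index.name = "sample"
    return out
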
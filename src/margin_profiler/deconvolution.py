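"""Signature-matrix deconvolution of bulk profiles into cell-class fractions.

A signature matrix (genes x classes of mean expression) is built from
labeled single cells by choosing, over a range of genes-per-class G, the
candidate matrix with the smallest condition number.  Bulk fractions are
estimated per sample by non-negative least squares on the shared-gene
subspace and renormalized to the unit simplex.  Helper statistics: AUC-based
High/Intermediate/Low categorization of per-cell program scores, and the
log10 ratio between two class fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .enrichment import bh_adjust
from .io_core import ExpressionMatrix, FormatError

__all__ = [
    "AUCCategory",
    "categorize_cells_by_auc",
    "SignatureMatrix",
    "build_signature_matrix",
    "FractionEstimate",
    "estimate_fractions",
    "program_log_ratio",
]


@dataclass
class AUCCategory:
    categories: pd.DataFrame  # cells x programs, values in {High, Intermediate, Low}
    cuts: dict[str, tuple[float, float]]
    rule: str


def categorize_cells_by_auc(
    scores: pd.DataFrame | pd.Series,
    rule: str = "quantile",
    cuts: tuple[float, float] | None = None,
) -> AUCCategory:
    """Split per-cell program scores into Low / Intermediate / High.

    ``quantile`` uses tertiles of each program's score distribution; a score
    exactly on a boundary goes to the lower category.  ``fixed`` uses the
    supplied strictly increasing cut pair for every program.
    """
    df = scores.to_frame() if isinstance(scores, pd.Series) else scores
    if df.shape[0] < 3:
        raise ValueError("need at least 3 cells to categorize")
    if rule == "fixed":
        if cuts is None or not cuts[0] < cuts[1]:
            raise ValueError("fixed rule needs strictly increasing cuts (lo, hi)")
    elif rule != "quantile":
        raise ValueError(f"unknown rule {rule!r}")

    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=object)
    used: dict[str, tuple[float, float]] = {}
    for col in df.columns:
        s = df[col].to_numpy(dtype=float)
        if rule == "quantile":
            lo, hi = np.quantile(s, [1 / 3, 2 / 3])
            if lo == hi:
                raise FormatError(f"program {col!r}: constant scores, tertiles undefined")
        else:
            lo, hi = cuts
        used[col] = (float(lo), float(hi))
        cat = np.where(s <= lo, "Low", np.where(s <= hi, "Intermediate", "High"))
        out[col] = cat
    return AUCCategory(out, used, rule)


# ---------------------------------------------------------------------------
# Signature matrix


@dataclass
class SignatureMatrix:
    matrix: pd.DataFrame  # genes x classes, non-negative mean expression
    condition_number: float
    genes_per_class: int

    def __post_init__(self) -> None:
        if self.matrix.shape[1] < 2:
            raise FormatError("signature matrix needs at least 2 classes")
        if not np.isfinite(self.condition_number):
            raise FormatError("condition number not finite")
        if (self.matrix.to_numpy().max(axis=1) <= 0).any():
            bad = self.matrix.index[self.matrix.to_numpy().max(axis=1) <= 0][0]
            raise FormatError(f"gene {bad!r} has no positive entry in any class")

    @property
    def classes(self) -> list[str]:
        return list(self.matrix.columns)


def build_signature_matrix(
    sc_expr: ExpressionMatrix,
    labels: pd.Series,
    q_max: float = 0.3,
    g_range: range = range(50, 151),
) -> SignatureMatrix:
    """Build a genes x classes signature matrix from labeled single cells.

    Per class, genes with one-vs-rest BH q < ``q_max`` are ranked by log2
    fold change; for each G in ``g_range`` the top-G genes per class form a
    candidate matrix of class-mean (linear-scale) expression, and the
    candidate with the smallest condition number is returned.
    """
    labels = labels.reindex(sc_expr.sample_ids)
    classes = sorted(labels.dropna().unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = labels.value_counts()
    small = [c for c in classes if counts.get(c, 0) < 3]
    if small:
        raise ValueError(f"class {small[0]!r} has fewer than 3 cells")

    if sc_expr.scale == "counts":
        logm = sc_expr.counts_to_log2()
    else:
        logm = sc_expr.to_log2()
    log_vals = logm.values
    lin_vals = (2.0 ** log_vals) - 1.0  # class means on linear scale

    ranked_markers: dict[str, list[str]] = {}
    class_means = {}
    for cls in classes:
        in_cls = (labels == cls).to_numpy()
        a = log_vals.loc[:, in_cls].to_numpy()
        b = log_vals.loc[:, ~in_cls].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.where(np.isfinite(p), p, 1.0)
        q = bh_adjust(p)
        fc = a.mean(axis=1) - b.mean(axis=1)
        sig = (q < q_max) & (fc > 0)
        if not sig.any():
            raise FormatError(f"class {cls!r} has no significant marker genes at q < {q_max}")
        order = np.argsort(-fc[sig], kind="stable")
        ranked_markers[cls] = list(np.array(log_vals.index)[sig][order])
        class_means[cls] = pd.Series(lin_vals.loc[:, in_cls].mean(axis=1), index=log_vals.index)
    mean_df = pd.DataFrame(class_means)[classes]

    best: tuple[float, int, pd.DataFrame] | None = None
    for g in g_range:
        genes = sorted(set().union(*[set(m[:g]) for m in ranked_markers.values()]))
        cand = mean_df.loc[genes]
        cand = cand[(cand.to_numpy().max(axis=1) > 0)]
        if cand.shape[0] < len(classes):
            continue
        kappa = float(np.linalg.cond(cand.to_numpy()))
        if best is None or kappa < best[0]:
            best = (kappa, g, cand)
    if best is None:
        raise FormatError("no candidate signature matrix could be formed")
    kappa, g, cand = best
    return SignatureMatrix(cand, kappa, g)


# ---------------------------------------------------------------------------
# Fraction estimation


@dataclass
class FractionEstimate:
    fractions: pd.DataFrame  # samples x classes, on the unit simplex
    rmse: pd.Series
    degenerate: pd.Series  # True where the NNLS solution was all-zero

    def __post_init__(self) -> None:
        f = self.fractions.to_numpy()
        if (f < -1e-12).any():
            raise FormatError("negative fraction")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise FormatError("fractions do not sum to 1")


def estimate_fractions(sig: SignatureMatrix, bulk: ExpressionMatrix) -> FractionEstimate:
    """Estimate per-sample class fractions by NNLS on shared genes.

    Solves min ||S f - b||, f >= 0 per sample and renormalizes f to sum to
    1.  A sample whose solution is identically zero is flagged degenerate
    and given equal fractions.
    """
    shared = sig.matrix.index.intersection(bulk.values.index)
    if len(shared) < 0.5 * sig.matrix.shape[0]:
        raise FormatError(
            f"only {len(shared)}/{sig.matrix.shape[0]} signature genes found in the bulk matrix"
        )
    S = sig.matrix.loc[shared].to_numpy()
    B = bulk.values.loc[shared].to_numpy()
    k = S.shape[1]
    fracs, rmses, degen = [], [], []
    for j in range(B.shape[1]):
        f, _ = nnls(S, B[:, j])
        resid = S @ f - B[:, j]
        rmses.append(float(np.sqrt(np.mean(resid**2))))
        total = f.sum()
        if total <= 0:
            warnings.warn(
                f"sample {bulk.sample_ids[j]!r}: degenerate NNLS solution; equal fractions returned"
            )
            fracs.append(np.full(k, 1.0 / k))
            degen.append(True)
        else:
            fracs.append(f / total)
            degen.append(False)
    fr = pd.DataFrame(fracs, index=bulk.sample_ids, columns=sig.classes)
    return FractionEstimate(fr, pd.Series(rmses, index=bulk.sample_ids),
                            pd.Series(degen, index=bulk.sample_ids))


def program_log_ratio(
    fr: FractionEstimate, class_a: str, class_b: str, eps: float = 1e-3
) -> pd.Series:
    """log10((f_a + eps) / (f_b + eps)) per bulk sample."""
    for cls in (class_a, class_b):
        if cls not in fr.fractions.columns:
            raise KeyError(f"unknown class {cls!r}")
    ratio = np.log10((fr.fractions[class_a] + eps) / (fr.fractions[class_b] + eps))
    ratio.name = f"log10({class_a}/{class_b})"
    return ratio
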
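"""Recurrence analysis: combined signature score, survival correlation, Cox.

The combined signature score accumulates single-sample enrichment over the
contributing gene sets: per set, ssGSEA scores are z-normalized across the
cohort and summed per sample (flags switch to raw-sum or mean
accumulation).  Score-survival association is assessed separately in
primary and recurrent arms by Spearman correlation against overall
survival, and by Cox proportional-hazards regression (Efron ties,
univariate or multivariate).  For unequal group sizes, the
bootstrap-then-Wilcoxon comparison repeatedly subsamples the larger group
to the smaller group's size and reports the mean and range of the
rank-sum p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import ssgsea_scores
from .io_core import ExpressionMatrix, GeneSetCollection, SurvivalCohort, FormatError

__all__ = [
    "combined_signature_score",
    "survival_correlation",
    "CoxResult",
    "cox_regression",
    "BootstrapWilcox",
    "bootstrap_wilcox",
]


def combined_signature_score(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    accumulate: str = "z-sum",
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Per-sample combined score over the contributing gene sets.

    ``z-sum`` (default) z-normalizes each set's ssGSEA score across samples
    before summing; ``raw-sum`` sums the normalized ssGSEA scores directly;
    ``mean`` averages the z-scores.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for cohort normalization")
    scores = ssgsea_scores(expr, sets, alpha=alpha)
    sd = scores.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0][0]
        raise FormatError(f"set {bad!r}: constant scores across the cohort")
    if accumulate == "z-sum":
        z = (scores - scores.mean(axis=0)) / sd
        combined = z.sum(axis=1)
    elif accumulate == "raw-sum":
        z = scores
        combined = scores.sum(axis=1)
    elif accumulate == "mean":
        z = (scores - scores.mean(axis=0)) / sd
        combined = z.mean(axis=1)
    else:
        raise ValueError(f"unknown accumulation {accumulate!r}")
    out = z.copy()
    out["combined"] = combined
    return out


def survival_correlation(scores: pd.Series, cohort: SurvivalCohort) -> pd.DataFrame:
    """Spearman correlation of score vs overall survival, per stage."""
    rows = []
    for stage in ("primary", "recurrent"):
        sub = cohort.table[cohort.table["stage"] == stage]
        shared = sub.index.intersection(scores.index)
        if len(shared) < 5:
            warnings.warn(f"stage {stage!r}: fewer than 5 scored samples; skipped")
            continue
        s = scores.loc[shared].to_numpy(dtype=float)
        if np.ptp(s) == 0:
            raise FormatError(f"stage {stage!r}: constant scores, correlation undefined")
        res = stats.spearmanr(s, sub.loc[shared, "os_months"].to_numpy())
        rows.append({"stage": stage, "n": len(shared),
                     "rho": float(res.statistic), "pval": float(res.pvalue)})
    return pd.DataFrame(rows).set_index("stage")


@dataclass
class CoxResult:
    term: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    pval: float
    model: str  # univariate | multivariate


def cox_regression(
    cohort: SurvivalCohort,
    terms: list[str],
    multivariate: bool = False,
) -> list[CoxResult]:
    """Cox proportional-hazards fit (Efron tie handling via lifelines).

    Univariate mode fits each term separately; multivariate fits them
    jointly (requires >= 10 events).  Returns per-term hazard ratios with
    Wald 95% CIs and p-values.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    t = cohort.table
    for term in terms:
        if term not in t.columns:
            raise KeyError(f"unknown covariate {term!r}")
        if np.ptp(pd.to_numeric(t[term]).to_numpy(dtype=float)) == 0:
            raise ValueError(f"covariate {term!r} is constant")
    if multivariate and int(t["event"].sum()) < 10:
        raise ValueError("multivariate Cox requires at least 10 events")

    def _fit(cols: list[str], model: str) -> list[CoxResult]:
        df = t[["os_months", "event", *cols]].astype(float)
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="os_months", event_col="event")
        except ConvergenceError as err:
            raise ValueError(f"Cox model did not converge: {err}") from err
        out = []
        for term in cols:
            row = cph.summary.loc[term]
            out.append(CoxResult(
                term,
                float(np.exp(row["coef"])),
                float(np.exp(row["coef lower 95%"])),
                float(np.exp(row["coef upper 95%"])),
                float(row["p"]),
                model,
            ))
        return out

    if multivariate:
        return _fit(list(terms), "multivariate")
    results = []
    for term in terms:
        results.extend(_fit([term], "univariate"))
    return results


@dataclass
class BootstrapWilcox:
    mean_p: float
    p_range: tuple[float, float]
    pvals: np.ndarray


def bootstrap_wilcox(
    group_a,
    group_b,
    B: int = 1000,
    seed: int = 0,
    with_replacement: bool = False,
) -> BootstrapWilcox:
    """Balanced Wilcoxon rank-sum comparison for unequal group sizes.

    Per iteration the larger group is subsampled (without replacement by
    default) to the smaller group's size and a two-sided rank-sum test is
    run; the mean p and [min, max] range over iterations are reported.
    With equal sizes every iteration is the single exact comparison.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)

    if a.size == b.size:
        p = float(stats.ranksums(a, b).pvalue)
        pvals = np.full(B, p)
        return BootstrapWilcox(p, (p, p), pvals)

    small, large = (a, b) if a.size < b.size else (b, a)
    a_is_small = a.size < b.size
    pvals = np.empty(B)
    for i in range(B):
        sub = rng.choice(large, size=small.size, replace=with_replacement)
        x, y = (small, sub) if a_is_small else (sub, small)
        pvals[i] = stats.ranksums(x, y).pvalue
    return BootstrapWilcox(float(pvals.mean()), (float(pvals.min()), float(pvals.max())), pvals)
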
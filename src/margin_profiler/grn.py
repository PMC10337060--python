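"""Mutual-information regulatory network with DPI pruning and bootstrap consensus.

Pairwise TF-target dependence is measured by plug-in mutual information (in
bits) on rank-transformed, equal-frequency-binned data.  The data
processing inequality (DPI) prunes, within every fully connected triangle,
the edge whose MI is strictly smaller than (1 - tolerance) times the
smaller of the other two — the signature of an indirect interaction.  Edge
confidence comes from bootstrap consensus: the network is re-inferred on B
resampled datasets, and an edge's count is tested against a binomial null
whose rate is the mean edge density across replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ExpressionMatrix

__all__ = ["mutual_information", "dpi_prune", "Network", "aracne_network", "bootstrap_consensus"]


def _bin_indices(x: np.ndarray, bins: int) -> np.ndarray:
    # ordinal ranks -> exact equal-frequency bins, deterministic under ties
    r = stats.rankdata(x, method="ordinal") - 1
    return (r * bins // x.size).astype(np.intp)


def mutual_information(x, y, bins: int | None = None) -> float:
    """Plug-in mutual information (bits) after rank + equal-frequency binning.

    Bin count defaults to ceil(n^(1/3)) + 1.  Constant vectors carry no
    information: MI = 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: MI set to 0")
        return 0.0
    b = bins if bins is not None else int(np.ceil(n ** (1 / 3))) + 1
    ix, iy = _bin_indices(x, b), _bin_indices(y, b)
    if iy.tobytes() < ix.tobytes():  # canonical order -> MI(x,y) == MI(y,x) bitwise
        ix, iy = iy, ix
    joint = np.zeros((b, b))
    np.add.at(joint, (ix, iy), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))
    return max(mi, 0.0)


@dataclass
class Network:
    edges: pd.DataFrame  # tf, target, mi (+ bootstrap_count, consensus_p after consensus)
    tfs: list[str]
    targets: list[str]
    dpi_tolerance: float
    B: int | None = None
    p_threshold: float | None = None


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def dpi_prune(
    mi: dict[tuple[str, str], float], tolerance: float = 0.0
) -> set[tuple[str, str]]:
    """Edges doomed by the data processing inequality.

    For every fully connected triangle, the edge whose MI is strictly less
    than (1 - tolerance) times the minimum of the other two is marked for
    removal; exact ties remove nothing.  All triangles are scanned before
    any edge is removed.
    """
    nodes = sorted({g for pair in mi for g in pair})
    neighbors: dict[str, set[str]] = {g: set() for g in nodes}
    for a, b in mi:
        neighbors[a].add(b)
        neighbors[b].add(a)
    doomed: set[tuple[str, str]] = set()
    for a in nodes:
        for b in sorted(neighbors[a]):
            if b <= a:
                continue
            for c in sorted(neighbors[a] & neighbors[b]):
                if c <= b:
                    continue
                edges = [_pair_key(a, b), _pair_key(b, c), _pair_key(a, c)]
                for e in edges:
                    others = min(mi[o] for o in edges if o != e)
                    if mi[e] < (1.0 - tolerance) * others:
                        doomed.add(e)
    return doomed


def _infer_edges(
    arr: np.ndarray, genes: list[str], tfs: set[str], targets: set[str],
    dpi_tolerance: float, bins: int | None, mi_threshold: float | None = None,
) -> dict[tuple[str, str], float]:
    """MI for all admissible pairs, optional significance gate, DPI pruning."""
    gi = {g: i for i, g in enumerate(genes)}
    pairs = set()
    for tf in tfs:
        for tg in targets:
            if tf != tg:
                pairs.add(_pair_key(tf, tg))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mi = {pair: mutual_information(arr[gi[pair[0]]], arr[gi[pair[1]]], bins=bins)
              for pair in sorted(pairs)}
    if mi_threshold is not None:
        mi = {e: v for e, v in mi.items() if v > mi_threshold}
    doomed = dpi_prune(mi, dpi_tolerance)
    return {e: v for e, v in mi.items() if e not in doomed}


def _orient(pair: tuple[str, str], tfs: set[str]) -> tuple[str, str]:
    a, b = pair
    return (a, b) if a in tfs else (b, a)


def aracne_network(
    expr: ExpressionMatrix,
    tfs: list[str],
    targets: list[str],
    dpi_tolerance: float = 0.0,
    bins: int | None = None,
) -> Network:
    """Infer a TF-target MI network with DPI pruning at the given tolerance."""
    present_tfs = [g for g in tfs if g in expr.values.index]
    if not present_tfs:
        raise ValueError("no TF present in the expression matrix")
    present_targets = [g for g in targets if g in expr.values.index]
    if expr.shape[1] < 8:
        raise ValueError("need at least 8 samples")
    arr = expr.values.to_numpy()
    genes = list(expr.values.index)
    kept = _infer_edges(arr, genes, set(present_tfs), set(present_targets), dpi_tolerance, bins)
    tfset = set(present_tfs)
    rows = [{"tf": _orient(e, tfset)[0], "target": _orient(e, tfset)[1], "mi": v}
            for e, v in sorted(kept.items())]
    edges = pd.DataFrame(rows, columns=["tf", "target", "mi"])
    return Network(edges, present_tfs, present_targets, dpi_tolerance)


def bootstrap_consensus(
    expr: ExpressionMatrix,
    tfs: list[str],
    targets: list[str],
    B: int = 1000,
    p_threshold: float = 1e-4,
    seed: int = 0,
    dpi_tolerance: float = 0.0,
    bins: int | None = None,
    mi_alpha: float = 1e-3,
    n_null: int = 1000,
) -> Network:
    """Bootstrap-consensus network: keep edges seen improbably often.

    Each of B replicates resamples samples with replacement, keeps edges
    whose MI exceeds a permutation-null significance threshold (the
    1 - ``mi_alpha`` quantile of MI between permuted pairs, estimated once
    from ``n_null`` draws), and prunes the rest by DPI.  With c the
    per-edge count and p-hat the mean edge density across replicates,
    consensus_p = P(Binomial(B, p-hat) >= c); edges with consensus_p <
    ``p_threshold`` survive.
    """
    if B < 10:
        raise ValueError("B must be >= 10")
    present_tfs = [g for g in tfs if g in expr.values.index]
    if not present_tfs:
        raise ValueError("no TF present in the expression matrix")
    present_targets = [g for g in targets if g in expr.values.index]
    tfset, tgset = set(present_tfs), set(present_targets)
    pair_list = sorted({_pair_key(a, b) for a in tfset for b in tgset if a != b})
    n_possible = len(pair_list)

    rng = np.random.default_rng(seed)
    arr = expr.values.to_numpy()
    genes = list(expr.values.index)
    gi = {g: i for i, g in enumerate(genes)}
    n_samples = arr.shape[1]

    # Null MI threshold under the bootstrap process itself: permute the
    # pairing (destroying dependence), then resample jointly — joint
    # duplication of resampled pairs inflates rank-binned MI and must be
    # part of the null.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        null_mi = np.empty(n_null)
        for k in range(n_null):
            a, b = pair_list[int(rng.integers(n_possible))]
            xp = arr[gi[a]]
            yp = rng.permutation(arr[gi[b]])
            idx = rng.integers(0, n_samples, size=n_samples)
            null_mi[k] = mutual_information(xp[idx], yp[idx], bins=bins)
    mi_threshold = float(np.quantile(null_mi, 1.0 - mi_alpha))

    counts: dict[tuple[str, str], int] = {}
    mi_sums: dict[tuple[str, str], float] = {}
    density = np.empty(B)
    for rep in range(B):
        idx = rng.integers(0, n_samples, size=n_samples)
        kept = _infer_edges(arr[:, idx], genes, tfset, tgset, dpi_tolerance, bins,
                            mi_threshold=mi_threshold)
        density[rep] = len(kept) / n_possible if n_possible else 0.0
        for e, v in kept.items():
            counts[e] = counts.get(e, 0) + 1
            mi_sums[e] = mi_sums.get(e, 0.0) + v

    p_hat = float(density.mean())
    rows = []
    for e in sorted(counts):
        c = counts[e]
        consensus_p = float(stats.binom.sf(c - 1, B, p_hat))
        if consensus_p < p_threshold:
            tf, tg = _orient(e, tfset)
            rows.append({"tf": tf, "target": tg, "mi": mi_sums[e] / c,
                         "bootstrap_count": c, "consensus_p": consensus_p})
    edges = pd.DataFrame(rows, columns=["tf", "target", "mi", "bootstrap_count", "consensus_p"])
    return Network(edges, present_tfs, present_targets, dpi_tolerance, B, p_threshold)
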
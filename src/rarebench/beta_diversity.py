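"""Between-sample (beta) dissimilarities under every depth-handling strategy.

Vector-level Jaccard / Bray-Curtis / Euclidean definitions, plus
``distance_matrix`` which assembles the full pairwise matrix for a table
under one strategy.  The rarefaction strategy implements average-distance
semantics: subsample every retained sample to a common depth, compute the
full pairwise matrix, repeat (100 draws by default), and average the
matrices elementwise.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform

from . import _engine
from .normalization import (
    DEFAULT_BETA_ITERS,
    ClrScheme,
    clr_transform,
    css_normalize,
    relative_abundance,
    srs_normalize,
)
from .otu_io import DistanceMatrix, OtuTable

__all__ = [
    "jaccard",
    "bray_curtis",
    "euclidean",
    "distance_matrix",
    "rarefied_distance_matrices",
    "BETA_METRICS",
    "BETA_STRATEGIES",
]

BETA_METRICS = ("jaccard", "braycurtis", "euclidean")
BETA_STRATEGIES = ("raw", "relabund", "srs", "css", "clr-one", "clr-nudge", "rarefaction")


def jaccard(a, b) -> float:
    """Presence/absence dissimilarity: 1 − shared / union of observed OTUs."""
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    union = int((a | b).sum())
    if union == 0:
        raise ValueError("Jaccard undefined for two empty samples")
    return float(1.0 - (a & b).sum() / union)


def bray_curtis(a, b) -> float:
    """Σ|n_A,i − n_B,i| / (N_A + N_B); 0 for identical, 1 for disjoint samples."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two empty samples")
    return float(np.abs(a - b).sum() / denom)


def euclidean(a, b) -> float:
    """√Σ(a_i − b_i)²; applicable to counts, abundances, or CLR values."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    return float(np.sqrt(((a - b) ** 2).sum()))


def _pairwise(values: np.ndarray, metric: str) -> np.ndarray:
    if metric == "jaccard":
        return pdist(values > 0, "jaccard")
    if metric == "braycurtis":
        return pdist(values.astype(np.float64), "braycurtis")
    if metric == "euclidean":
        return pdist(values.astype(np.float64), "euclidean")
    raise ValueError(f"unknown beta metric {metric!r}")


def _retain(table: OtuTable, depth: int) -> OtuTable:
    keep = table.depths >= depth
    if keep.sum() < 2:
        raise ValueError(f"fewer than 2 samples reach depth {depth}")
    if not keep.all():
        dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below rarefaction depth {depth}: "
            f"{dropped[:5]}",
            UserWarning,
            stacklevel=3,
        )
        table = table.select_samples(keep)
    return table


def rarefied_distance_matrices(
    table: OtuTable,
    metrics: tuple[str, ...] = ("braycurtis",),
    depth: int | None = None,
    n_iter: int = DEFAULT_BETA_ITERS,
    seed=None,
) -> dict[str, DistanceMatrix]:
    """Average-distance rarefaction for one or more metrics at once.

    Samples below ``depth`` (dataset minimum by default) are dropped once,
    before iterating.  Each iteration subsamples every retained sample to
    ``depth`` and computes the pairwise matrix for every requested metric
    from the same subsampled table; the per-iteration matrices are averaged
    elementwise.
    """
    for m in metrics:
        if m not in BETA_METRICS:
            raise ValueError(f"unknown beta metric {m!r}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if depth is None:
        depth = int(table.depths.min())
    table = _retain(table, depth)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(table.n_samples)
    draws = [
        _engine.subsample_draws(row, depth, n_iter, streams[i])
        for i, row in enumerate(table.counts)
    ]
    acc = {m: np.zeros(table.n_samples * (table.n_samples - 1) // 2) for m in metrics}
    for it in range(n_iter):
        matrix = np.vstack([d[it] for d in draws])
        for m in metrics:
            acc[m] += _pairwise(matrix, m)
    return {
        m: DistanceMatrix(table.sample_ids, squareform(acc[m] / n_iter), metric=m)
        for m in metrics
    }


def distance_matrix(
    table: OtuTable,
    metric: str,
    strategy: str = "raw",
    depth: int | None = None,
    n_iter: int = DEFAULT_BETA_ITERS,
    seed=None,
    css_quantile: float = 0.5,
) -> DistanceMatrix:
    """Pairwise dissimilarity matrix under one depth-handling strategy.

    CLR strategies pair only with the Euclidean metric (the Aitchison
    distance); every other combination is allowed.  ``srs`` normalizes to
    ``depth`` (dataset minimum by default) before measuring.
    """
    if metric not in BETA_METRICS:
        raise ValueError(f"unknown beta metric {metric!r}")
    if strategy not in BETA_STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy.startswith("clr") and metric != "euclidean":
        raise ValueError("CLR strategies pair only with the euclidean metric")
    if strategy == "rarefaction":
        return rarefied_distance_matrices(table, (metric,), depth, n_iter, seed)[metric]
    if strategy == "raw":
        values, ids = table.counts, table.sample_ids
    elif strategy == "relabund":
        at = relative_abundance(table)
        values, ids = at.values, at.sample_ids
    elif strategy == "srs":
        target = int(depth) if depth is not None else int(table.depths.min())
        st = srs_normalize(table, target)
        values, ids = st.counts, st.sample_ids
    elif strategy == "css":
        at = css_normalize(table, quantile=css_quantile)
        values, ids = at.values, at.sample_ids
    else:  # clr-one / clr-nudge
        scheme = ClrScheme("one" if strategy == "clr-one" else "nudge")
        at = clr_transform(table, scheme)
        values, ids = at.values, at.sample_ids
    return DistanceMatrix(ids, squareform(_pairwise(np.asarray(values), metric)), metric=metric)
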
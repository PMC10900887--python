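"""Within-sample (alpha) diversity metrics, estimators, and strategies.

All metrics operate on one sample's count vector.  ``alpha_with_strategy``
computes a metric for every sample of a table under one of four ways of
handling uneven depth: raw counts, SRS-normalized counts, rarefaction
(mean over 1,000 subsamples by default), or a nonparametric richness
estimator on raw counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _engine
from .normalization import DEFAULT_ALPHA_ITERS, srs_normalize
from .otu_io import OtuTable

__all__ = [
    "AlphaResult",
    "richness",
    "shannon",
    "inverse_simpson",
    "chao1",
    "ace",
    "goods_coverage",
    "alpha_with_strategy",
    "rarefied_alpha_table",
]

ALPHA_METRICS = ("richness", "shannon", "invsimpson", "chao1", "ace", "coverage")
ALPHA_STRATEGIES = ("raw", "srs", "rarefaction", "estimator")

_ALIASES = {"sobs": "richness", "inverse_simpson": "invsimpson"}


def _canon_metric(metric: str) -> str:
    m = _ALIASES.get(metric.lower(), metric.lower())
    if m not in ALPHA_METRICS:
        raise ValueError(f"unknown alpha metric {metric!r}")
    return m


def _counts1d(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=np.int64)
    if c.ndim != 1:
        raise ValueError("expected a single sample's count vector")
    if c.size and c.min() < 0:
        raise ValueError("counts must be nonnegative")
    return c


def richness(counts) -> int:
    """Number of OTUs observed at least once (S_obs)."""
    return int(np.count_nonzero(_counts1d(counts)))


def shannon(counts) -> float:
    """Shannon diversity, −Σ (n_i/N) ln(n_i/N) over observed OTUs."""
    c = _counts1d(counts)
    n = c[c > 0]
    total = n.sum()
    if total == 0:
        raise ValueError("Shannon diversity undefined for an empty sample")
    p = n / total
    return float(-(p * np.log(p)).sum())


def simpson(counts) -> float:
    """Simpson concentration D = Σ n_i(n_i−1) / (N(N−1))."""
    c = _counts1d(counts)
    total = c.sum()
    if total < 2:
        raise ValueError("Simpson concentration needs at least 2 sequences")
    return float((c * (c - 1)).sum() / (total * (total - 1)))


def inverse_simpson(counts) -> float:
    """1/D; undefined (error) when every observed OTU is a singleton."""
    d = simpson(counts)
    if d == 0:
        raise ValueError("inverse Simpson undefined: all OTUs are singletons")
    return 1.0 / d


def chao1(counts) -> float:
    """Bias-corrected Chao1: S_obs + n1(n1−1) / (2(n2+1))."""
    c = _counts1d(counts)
    n1 = int((c == 1).sum())
    n2 = int((c == 2).sum())
    return float(np.count_nonzero(c) + n1 * (n1 - 1) / (2.0 * (n2 + 1)))


def ace(counts, rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator with the standard rare cutoff of 10.

    Falls back to bias-corrected Chao1 when the sample coverage of the rare
    group is zero (all rare OTUs are singletons), the usual convention.
    """
    c = _counts1d(counts)
    c = c[c > 0]
    rare = c[c <= rare_threshold]
    s_abund = int((c > rare_threshold).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        return chao1(counts)
    i = np.arange(1, rare_threshold + 1)
    f = np.array([(rare == v).sum() for v in i])
    if n_rare > 1:
        gamma2 = max(
            (s_rare / c_ace) * (i * (i - 1) * f).sum() / (n_rare * (n_rare - 1)) - 1.0,
            0.0,
        )
    else:
        gamma2 = 0.0
    return float(s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2)


def goods_coverage(counts) -> float:
    """Good's coverage as a percentage: 100 × (1 − n1/N_T)."""
    c = _counts1d(counts)
    total = c.sum()
    if total == 0:
        raise ValueError("coverage undefined for an empty sample")
    n1 = int((c == 1).sum())
    return float(100.0 * (1.0 - n1 / total))


_PLUGIN = {
    "richness": lambda c: float(richness(c)),
    "shannon": shannon,
    "invsimpson": inverse_simpson,
    "chao1": chao1,
    "ace": ace,
    "coverage": goods_coverage,
}


@dataclass(frozen=True)
class AlphaResult:
    """Per-sample values of one alpha metric under one strategy."""

    sample_ids: tuple[str, ...]
    values: np.ndarray
    metric: str
    strategy: str
    params: dict = field(default_factory=dict)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.sample_ids), name=self.metric)


def _retain_at_depth(table: OtuTable, depth: int) -> OtuTable:
    keep = table.depths >= depth
    if not keep.any():
        raise ValueError(f"no sample reaches depth {depth}")
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


def rarefied_alpha_table(
    table: OtuTable,
    depth: int | None = None,
    metrics: tuple[str, ...] = ("richness", "shannon", "invsimpson"),
    n_iter: int = DEFAULT_ALPHA_ITERS,
    seed=None,
) -> pd.DataFrame:
    """Rarefied alpha metrics for every sample, sharing one set of draws.

    For each retained sample, ``n_iter`` subsamples at ``depth`` (dataset
    minimum by default) are drawn once and every requested metric is
    averaged over them — the draws are shared across metrics, mirroring how
    one subsampled table yields all its summary statistics.  Samples below
    the depth are dropped with a warning.  Draws where the Simpson
    concentration is zero contribute nothing to the inverse-Simpson mean
    (they are excluded); at realistic depths they do not occur.
    """
    metrics = tuple(_canon_metric(m) for m in metrics)
    unsupported = set(metrics) - {"richness", "shannon", "invsimpson", "coverage"}
    if unsupported:
        raise ValueError(f"metrics {sorted(unsupported)} cannot be rarefied here")
    if depth is None:
        depth = int(table.depths.min())
    table = _retain_at_depth(table, depth)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(table.n_samples)
    out = {m: np.empty(table.n_samples) for m in metrics}
    for i, row in enumerate(table.counts):
        draws = _engine.rarefied_alpha_draws(row, depth, n_iter, streams[i])
        if "richness" in out:
            out["richness"][i] = draws["richness"].mean()
        if "shannon" in out:
            out["shannon"][i] = draws["shannon"].mean()
        if "invsimpson" in out:
            d = draws["simpson_d"]
            with np.errstate(divide="ignore"):
                inv = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), np.nan)
            out["invsimpson"][i] = np.nanmean(inv)
        if "coverage" in out:
            out["coverage"][i] = 100.0 * (1.0 - draws["singletons"] / depth).mean()
    return pd.DataFrame(out, index=list(table.sample_ids))


def alpha_with_strategy(
    table: OtuTable,
    metric: str,
    strategy: str,
    depth: int | None = None,
    n_iter: int = DEFAULT_ALPHA_ITERS,
    seed=None,
) -> AlphaResult:
    """One alpha metric per sample under a depth-handling strategy.

    - ``raw``: plug-in metric on the observed counts,
    - ``srs``: metric on SRS-normalized counts (target = ``depth`` or the
      dataset minimum),
    - ``rarefaction``: mean over ``n_iter`` subsamples at ``depth``,
    - ``estimator``: ``chao1``/``ace`` on raw counts.
    """
    metric = _canon_metric(metric)
    if strategy not in ALPHA_STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    params = {"depth": depth, "n_iter": n_iter}
    if strategy == "raw":
        values = np.array([_PLUGIN[metric](row) for row in table.counts])
        ids = table.sample_ids
    elif strategy == "estimator":
        if metric not in ("chao1", "ace"):
            raise ValueError("strategy 'estimator' applies to chao1/ace")
        values = np.array([_PLUGIN[metric](row) for row in table.counts])
        ids = table.sample_ids
    elif strategy == "srs":
        target = int(depth) if depth is not None else int(table.depths.min())
        normalized = srs_normalize(table, target)
        values = np.array([_PLUGIN[metric](row) for row in normalized.counts])
        ids = normalized.sample_ids
    else:  # rarefaction
        df = rarefied_alpha_table(table, depth, (metric,), n_iter, seed)
        values = df[metric].to_numpy()
        ids = tuple(df.index)
    return AlphaResult(tuple(ids), values, metric, strategy, params)
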
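"""Significance tests: two-sample Wilcoxon rank-sum and two-group PERMANOVA.

Both are implemented here rather than delegated: the Wilcoxon test switches
between complete enumeration of the rank-sum null (small samples, no ties)
and the tie-corrected, continuity-corrected normal approximation; PERMANOVA
computes Anderson's pseudo-F from squared distances and obtains its p-value
by uniformly permuting group labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .community_models import TreatmentDesign
from .otu_io import DistanceMatrix

__all__ = ["TestResult", "wilcoxon_rank_sum", "permanova"]

EXACT_WILCOXON_MAX_N = 20


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_permutations: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1 or np.isnan(self.p_value)):
            raise ValueError("p-value must lie in (0, 1]")


def _rank_sum_distribution(n: int, n_a: int) -> np.ndarray:
    """Counts of subsets of {1..n} of size n_a by rank sum (index = sum).

    Standard dynamic program over the ranks; the table is tiny for the
    n ≤ 20 regime where exact enumeration is used.
    """
    max_sum = n_a * n
    dp = np.zeros((n_a + 1, max_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for rank in range(1, n + 1):
        for chosen in range(min(rank, n_a), 0, -1):
            dp[chosen, rank:] += dp[chosen - 1, : max_sum + 1 - rank]
    return dp[n_a]


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided two-sample Wilcoxon (Mann-Whitney) rank-sum test.

    The statistic is the rank sum of ``x`` using midranks.  With combined
    n ≤ 20 and no ties the p-value is exact (complete enumeration via the
    rank-sum distribution); otherwise the normal approximation with tie
    correction and continuity correction is used.  Identical constant data
    yield p = 1.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups need at least one value")
    combined = np.concatenate([x, y])
    n, n_a = combined.size, x.size
    ranks = rankdata(combined)
    w = float(ranks[:n_a].sum())
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    if n <= EXACT_WILCOXON_MAX_N and not has_ties:
        dist = _rank_sum_distribution(n, n_a)
        total = dist.sum()
        wi = int(round(w))
        p_low = dist[: wi + 1].sum() / total
        p_high = dist[wi:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return TestResult(w, p, "wilcoxon-exact")
    mean_w = n_a * (n + 1) / 2.0
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1.0)) if n > 1 else 0.0
    var_w = n_a * (n - n_a) / 12.0 * ((n + 1.0) - tie_term)
    if var_w <= 0:
        return TestResult(w, 1.0, "wilcoxon-normal")
    z = w - mean_w
    z = (z - 0.5 * np.sign(z)) / np.sqrt(var_w)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return TestResult(w, max(p, np.finfo(float).tiny), "wilcoxon-normal")


def _labels_from(grouping, n: int) -> np.ndarray:
    if isinstance(grouping, TreatmentDesign):
        labels = np.asarray(grouping.labels)
    else:
        labels = np.asarray(grouping)
    if labels.size != n:
        raise ValueError("grouping length must match the distance matrix")
    return labels


def _pseudo_f(d2: np.ndarray, group_masks: list[np.ndarray]) -> float:
    n = d2.shape[0]
    g = len(group_masks)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for mask in group_masks:
        m = int(mask.sum())
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(m, k=1)].sum() / m
    ss_between = ss_total - ss_within
    denom = ss_within / (n - g)
    if denom == 0:
        return np.inf if ss_between > 0 else np.nan
    return (ss_between / (g - 1)) / denom


def permanova(
    dm: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed=None,
) -> TestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    pseudo-F = (SS_between/(g−1)) / (SS_within/(n−g)) with sums of squared
    distances; p = (1 + #{F_perm ≥ F_obs}) / (1 + n_permutations) under
    uniform random label permutations.  A degenerate all-zero matrix gives
    p = 1.
    """
    labels = _labels_from(grouping, dm.n_samples)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least two groups")
    for gname in groups:
        if (labels == gname).sum() < 2:
            raise ValueError(f"group {gname!r} has fewer than 2 samples")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    d2 = dm.values**2
    n = dm.n_samples
    if not d2.any():
        return TestResult(np.nan, 1.0, "permanova", n_permutations)
    masks = [labels == gname for gname in groups]
    f_obs = _pseudo_f(d2, masks)

    # vectorized permutations: group-indicator matrices Z_g of shape (P, n)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = groups.size
    perm_idx = np.argsort(rng.random((n_permutations, n)), axis=1)
    sizes = [int(m.sum()) for m in masks]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = np.zeros(n_permutations)
    for gi in range(g):
        cols = perm_idx[:, offsets[gi] : offsets[gi + 1]]
        z = np.zeros((n_permutations, n))
        np.put_along_axis(z, cols, 1.0, axis=1)
        ss_within += np.einsum("pi,ij,pj->p", z, d2, z) / (2.0 * sizes[gi])
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ss_between / (g - 1)) / (ss_within / (n - g))
    if np.isinf(f_obs):
        exceed = np.isinf(f_perm).sum()
    else:
        exceed = int((f_perm >= f_obs - 1e-12).sum())
    p = (1 + exceed) / (1 + n_permutations)
    return TestResult(float(f_obs), float(p), "permanova", n_permutations)
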
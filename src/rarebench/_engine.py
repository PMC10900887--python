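"""Fast repeated subsampling (rarefaction) kernels.

Rarefying one sample means drawing ``depth`` sequences without replacement
from its pool of ``N`` sequences — a multivariate hypergeometric draw over
the OTU counts.  The experiments in this package need on the order of
10^8–10^9 individually subsampled sequences (hundreds of null replicates ×
dozens of samples × 1,000 draws each), which rules out per-draw calls into
numpy's generic samplers.

The kernels below expand a sample's counts into a pool of OTU labels once
and then run a partial Fisher–Yates shuffle per draw: ``depth`` swap steps
select a uniform random subset, and because a permuted pool is still the
same pool, the array is simply left in place between draws — no restore
pass, no hash set.  Per-draw cost is O(depth) with a small constant.

Randomness comes from a splitmix64 stream (seeded per call), with the
64→range reduction done in double precision; the bias of that reduction is
O(range/2^53), irrelevant at these pool sizes.  Everything is deterministic
given the seed and independent of numpy's global state.

``normalization.subsample`` deliberately does *not* use these kernels: it
wraps numpy's ``multivariate_hypergeometric``, which the test suite uses as
an independent oracle for the distributions produced here.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["pot_labels", "rarefied_alpha_draws", "subsample_draws"]

_C1 = np.uint64(0x9E3779B97F4A7C15)
_C2 = np.uint64(0xBF58476D1CE4E5B9)
_C3 = np.uint64(0x94D049BB133111EB)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True)
def _alpha_kernel(labels, k, d, B, seed, lntab):  # pragma: no cover - jitted
    N = labels.shape[0]
    state = np.uint64(seed)
    cnt = np.zeros(k, np.int64)
    touched = np.empty(d, np.int64)
    rich = np.empty(B, np.float64)
    shan = np.empty(B, np.float64)
    simpson = np.empty(B, np.float64)
    singles = np.empty(B, np.float64)
    lnd = lntab[d]
    for b in range(B):
        nt = 0
        for j in range(d):
            state = state + _C1
            z = state
            z = (z ^ (z >> np.uint64(30))) * _C2
            z = (z ^ (z >> np.uint64(27))) * _C3
            z = z ^ (z >> np.uint64(31))
            u = np.float64(z >> np.uint64(11)) * _INV53
            i = np.int64(u * (N - j))
            otu = labels[i]
            labels[i] = labels[N - 1 - j]
            labels[N - 1 - j] = otu
            if cnt[otu] == 0:
                touched[nt] = otu
                nt += 1
            cnt[otu] += 1
        r = 0.0
        h = 0.0
        s = 0.0
        s1 = 0.0
        for t in range(nt):
            n = cnt[touched[t]]
            r += 1.0
            h -= (n / d) * (lntab[n] - lnd)
            s += n * (n - 1.0)
            if n == 1:
                s1 += 1.0
            cnt[touched[t]] = 0
        rich[b] = r
        shan[b] = h
        simpson[b] = s / (d * (d - 1.0)) if d > 1 else 0.0
        singles[b] = s1
    return rich, shan, simpson, singles


@njit(cache=True)
def _dense_kernel(labels, k, d, B, seed):  # pragma: no cover - jitted
    N = labels.shape[0]
    state = np.uint64(seed)
    out = np.zeros((B, k), np.int64)
    for b in range(B):
        for j in range(d):
            state = state + _C1
            z = state
            z = (z ^ (z >> np.uint64(30))) * _C2
            z = (z ^ (z >> np.uint64(27))) * _C3
            z = z ^ (z >> np.uint64(31))
            u = np.float64(z >> np.uint64(11)) * _INV53
            i = np.int64(u * (N - j))
            otu = labels[i]
            labels[i] = labels[N - 1 - j]
            labels[N - 1 - j] = otu
            out[b, otu] += 1
    return out


def pot_labels(counts: np.ndarray) -> np.ndarray:
    """Expand a count vector into its pool of OTU labels (int32)."""
    counts = np.asarray(counts, dtype=np.int64)
    return np.repeat(np.arange(counts.size, dtype=np.int32), counts)


def _seed_u64(seed) -> np.uint64:
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    return np.uint64(ss.generate_state(1, np.uint64)[0])


def rarefied_alpha_draws(
    counts: np.ndarray, depth: int, n_iter: int, seed
) -> dict[str, np.ndarray]:
    """Per-draw alpha statistics over ``n_iter`` subsamples of one sample.

    Returns arrays of length ``n_iter`` for observed richness, Shannon
    diversity, the Simpson concentration D (not its inverse — D can be 0 on
    pathological draws and the caller decides how to invert), and the number
    of singleton OTUs (for Good's coverage).
    """
    counts = np.asarray(counts, dtype=np.int64)
    N = int(counts.sum())
    depth = int(depth)
    if not 1 <= depth <= N:
        raise ValueError(f"depth {depth} outside [1, {N}]")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    labels = pot_labels(counts)
    lntab = np.log(np.maximum(np.arange(depth + 1, dtype=np.float64), 1.0))
    rich, shan, simpson, singles = _alpha_kernel(
        labels, counts.size, depth, int(n_iter), _seed_u64(seed), lntab
    )
    return {
        "richness": rich,
        "shannon": shan,
        "simpson_d": simpson,
        "singletons": singles,
    }


def subsample_draws(counts: np.ndarray, depth: int, n_iter: int, seed) -> np.ndarray:
    """``(n_iter, n_otus)`` matrix of independent subsamples of one sample."""
    counts = np.asarray(counts, dtype=np.int64)
    N = int(counts.sum())
    depth = int(depth)
    if not 1 <= depth <= N:
        raise ValueError(f"depth {depth} outside [1, {N}]")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    labels = pot_labels(counts)
    return _dense_kernel(labels, counts.size, depth, int(n_iter), _seed_u64(seed))
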
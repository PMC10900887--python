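"""Strategies for handling uneven sequencing depth.

Covers single subsampling (the building block of rarefaction), relative
abundance, scaled ranked subsampling (SRS), cumulative sum scaling (CSS),
and centered log-ratio transforms under two pseudo-count schemes.  The
``rarefaction_mean`` engine repeats subsampling and averages an arbitrary
statistic; the same semantics back both alpha rarefaction (1,000 draws) and
average-distance beta rarefaction (100 draws) elsewhere in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .otu_io import AbundanceTable, OtuTable

__all__ = [
    "ClrScheme",
    "subsample",
    "relative_abundance",
    "srs_normalize",
    "css_normalize",
    "clr_transform",
    "rarefaction_mean",
]

DEFAULT_ALPHA_ITERS = 1000
DEFAULT_BETA_ITERS = 100


@dataclass(frozen=True)
class ClrScheme:
    """Pseudo-count rule that makes the CLR defined on sparse counts.

    ``one`` adds 1 to every count; ``nudge`` adds 1/N_j (one over the
    sample's depth) to every count of sample j.
    """

    kind: str = "one"

    def __post_init__(self) -> None:
        if self.kind not in ("one", "nudge"):
            raise ValueError("ClrScheme kind must be 'one' or 'nudge'")

    def pseudo_counted(self, row: np.ndarray) -> np.ndarray:
        row = np.asarray(row, dtype=np.float64)
        if self.kind == "one":
            return row + 1.0
        depth = row.sum()
        if depth <= 0:
            raise ValueError("nudge CLR undefined for a zero-depth sample")
        return row + 1.0 / depth


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def subsample(counts: Sequence[int], depth: int, seed=None) -> np.ndarray:
    """One draw of ``depth`` sequences without replacement from a sample.

    A multivariate hypergeometric draw over the OTU counts (numpy's
    implementation).  Callers wanting a common depth across a dataset must
    drop samples whose total is below ``depth``; asking for more sequences
    than the sample has is an error here.
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    depth = int(depth)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if depth > total:
        raise ValueError(f"depth {depth} exceeds sample total {total}")
    if depth == total:
        return counts.copy()
    rng = _as_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth).astype(np.int64)


def relative_abundance(table: OtuTable) -> AbundanceTable:
    """Divide each count by its sample's depth; rows sum to 1."""
    depths = table.depths
    if np.any(depths == 0):
        bad = [s for s, d in zip(table.sample_ids, depths) if d == 0]
        raise ValueError(f"zero-depth samples have no relative abundances: {bad[:5]}")
    values = table.counts / depths[:, None]
    return AbundanceTable(table.sample_ids, table.otu_ids, values, tag="relabund")


def _srs_row(counts: np.ndarray, target: int, rng: np.random.Generator | None) -> np.ndarray:
    scaled = counts * (target / counts.sum())
    ipart = np.floor(scaled).astype(np.int64)
    remaining = target - int(ipart.sum())
    if remaining == 0:
        return ipart
    frac = scaled - ipart
    if rng is None:
        # descending fractional part; ties by descending scaled value, then
        # by OTU index (lexsort is stable, so original order breaks the rest)
        order = np.lexsort((-scaled, -frac))
    else:
        order = np.lexsort((rng.random(counts.size), -frac))
    ipart[order[:remaining]] += 1
    return ipart


def srs_normalize(
    table: OtuTable, target_depth: int, random_ties: bool = False, seed=None
) -> OtuTable:
    """Scaled ranked subsampling: integer counts summing exactly to the target.

    Counts are scaled by ``target/N``; integer parts are kept and the
    leftover units go to the OTUs with the largest fractional parts.  The
    reference algorithm breaks fractional-part ties at random; the default
    here is deterministic (descending scaled value, then OTU index), with
    ``random_ties=True`` restoring randomized ties.

    Samples with depth below ``target_depth`` are dropped with a warning.
    """
    target_depth = int(target_depth)
    if target_depth < 1:
        raise ValueError("target_depth must be >= 1")
    depths = table.depths
    keep = depths >= target_depth
    if not keep.any():
        raise ValueError("no sample reaches the target depth")
    if not keep.all():
        dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {target_depth}: "
            f"{dropped[:5]}",
            UserWarning,
            stacklevel=2,
        )
        table = table.select_samples(keep)
    rng = _as_rng(seed) if random_ties else None
    rows = np.vstack([_srs_row(row, target_depth, rng) for row in table.counts])
    return OtuTable(table.sample_ids, table.otu_ids, rows)


def css_normalize(table: OtuTable, quantile: float = 0.5, scale: float = 1000.0) -> AbundanceTable:
    """Cumulative sum scaling.

    Per sample, the scaling factor is the sum of counts at or below the
    ``quantile``-th quantile of the sample's *nonzero* counts; normalized
    values are ``count / factor × scale``.
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    depths = table.depths
    if np.any(depths == 0):
        bad = [s for s, d in zip(table.sample_ids, depths) if d == 0]
        raise ValueError(f"CSS undefined for zero-depth samples: {bad[:5]}")
    values = np.empty(table.counts.shape, dtype=np.float64)
    for i, row in enumerate(table.counts):
        nonzero = row[row > 0]
        q = np.quantile(nonzero, quantile)
        s = row[row <= q].sum()
        if s == 0:
            raise ValueError(
                f"CSS scaling factor is zero for sample {table.sample_ids[i]!r}"
            )
        values[i] = row / s * scale
    return AbundanceTable(table.sample_ids, table.otu_ids, values, tag="css")


def clr_transform(table: OtuTable, scheme: ClrScheme | str = "one") -> AbundanceTable:
    """Centered log-ratio of pseudo-counted counts; rows sum to 0."""
    if isinstance(scheme, str):
        scheme = ClrScheme(scheme)
    values = np.empty(table.counts.shape, dtype=np.float64)
    for i, row in enumerate(table.counts):
        x = scheme.pseudo_counted(row)
        logs = np.log(x)
        values[i] = logs - logs.mean()
    return AbundanceTable(table.sample_ids, table.otu_ids, values, tag="clr")


def rarefaction_mean(
    sample_or_pair,
    statistic: Callable[..., float],
    depth: int,
    n_iter: int,
    seed=None,
) -> float:
    """Mean of ``statistic`` over repeated independent subsamplings.

    ``sample_or_pair`` is one count vector (the statistic receives one
    subsampled vector) or a pair of count vectors (the statistic receives
    two, subsampled independently each iteration — the semantics of
    average-distance rarefaction).  Each iteration uses its own derived RNG
    stream so results do not depend on evaluation order.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if isinstance(sample_or_pair, tuple) and len(sample_or_pair) == 2:
        a, b = (np.asarray(v, dtype=np.int64) for v in sample_or_pair)
        pair = True
    else:
        a = np.asarray(sample_or_pair, dtype=np.int64)
        b = None
        pair = False
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(n_iter)
    total = 0.0
    for child in streams:
        rng = np.random.default_rng(child)
        if pair:
            total += statistic(subsample(a, depth, rng), subsample(b, depth, rng))
        else:
            total += statistic(subsample(a, depth, rng))
    return total / n_iter
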
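"""Simulation models: fixed-margin null tables, treatment assignments, effects.

The null community model regenerates a table by randomly reassigning every
sequence to a (sample, OTU) cell while conserving *both* margins exactly:
each sample keeps its depth and each OTU keeps its dataset-wide total.  All
samples then are statistical draws of one community, so any detected
difference between treatment groups is a false positive.

Treatment assignments come in three flavors: unbiased random splits, a
median split fully confounding group with depth, and a 5th/95th-percentile
model pinning only the extreme-depth samples to opposite groups.

The two effect models build a two-group dataset with a known difference:
``skewed_abundance_pair`` inflates the relative abundance of a random 10%
of OTUs by 5% in one group's generating profile; ``richness_adjusted_pair``
removes a random 3% of OTUs from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .otu_io import OtuTable

__all__ = [
    "TreatmentDesign",
    "EffectModel",
    "null_community",
    "assign_treatments",
    "skewed_abundance_pair",
    "richness_adjusted_pair",
    "BIAS_MODES",
]

BIAS_MODES = ("unbiased", "median_split", "tail_5_95")


@dataclass(frozen=True)
class TreatmentDesign:
    """Two-group assignment of samples, with the bias that produced it."""

    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]  # 'A' or 'B' per sample
    bias_mode: str

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("one label per sample required")
        groups = set(self.labels)
        if groups != {"A", "B"}:
            raise ValueError("design must contain exactly two nonempty groups A and B")
        if self.bias_mode not in BIAS_MODES:
            raise ValueError(f"unknown bias mode {self.bias_mode!r}")
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def assignment(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.labels))

    def mask(self, group: str = "A") -> np.ndarray:
        return np.array([lab == group for lab in self.labels])

    def group_sizes(self) -> tuple[int, int]:
        m = self.mask("A")
        return int(m.sum()), int((~m).sum())


@dataclass(frozen=True)
class EffectModel:
    """Parameters of a simulated treatment effect.

    For ``skewed_abundance``, a fraction ``frac_otus_perturbed`` of OTUs has
    its profile probability multiplied by ``1 + effect_size`` before
    renormalization.  For ``richness_adjusted``, a fraction
    ``frac_otus_removed`` of OTUs is zeroed out of the profile.
    """

    kind: str
    frac_otus_perturbed: float = 0.10
    effect_size: float = 0.05
    frac_otus_removed: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("skewed_abundance", "richness_adjusted"):
            raise ValueError(f"unknown effect model {self.kind!r}")
        for name in ("frac_otus_perturbed", "frac_otus_removed"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


def null_community(observed: OtuTable, seed=None) -> OtuTable:
    """Fixed-margin shuffle: exact row (depth) and column (OTU total) sums.

    Builds the pool of all ΣN sequence labels (each OTU id repeated by its
    dataset total), shuffles it uniformly, and partitions it sequentially
    into samples by their observed depths.  Each sample's counts are then a
    multivariate hypergeometric draw from the pooled community, conditional
    on all the other samples — the uniform distribution over tables with
    both margins fixed that sequential assignment of a uniformly shuffled
    label vector induces.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    col_totals = observed.counts.sum(axis=0)
    depths = observed.depths
    labels = np.repeat(np.arange(observed.n_otus, dtype=np.int32), col_totals)
    rng.shuffle(labels)
    edges = np.concatenate([[0], np.cumsum(depths)])
    counts = np.vstack(
        [
            np.bincount(labels[edges[i] : edges[i + 1]], minlength=observed.n_otus)
            for i in range(observed.n_samples)
        ]
    ).astype(np.int64)
    return OtuTable(observed.sample_ids, observed.otu_ids, counts)


def assign_treatments(
    depths,
    mode: str = "unbiased",
    seed=None,
    sample_ids: tuple[str, ...] | None = None,
) -> TreatmentDesign:
    """Split samples into groups A/B, optionally biased by sequencing depth.

    - ``unbiased``: uniform random split into ⌈n/2⌉ / ⌊n/2⌋,
    - ``median_split``: samples with depth above the median → A, rest → B,
    - ``tail_5_95``: samples at or below the 5th depth percentile → B, at or
      above the 95th → A, the middle 90% assigned at random.

    Depth ties are broken by sample order so the tail assignment is
    deterministic.
    """
    depths = np.asarray(depths)
    n = depths.size
    if n < 4:
        raise ValueError("need at least 4 samples to form two groups")
    if sample_ids is None:
        sample_ids = tuple(f"S{i + 1}" for i in range(n))
    if len(sample_ids) != n:
        raise ValueError("sample_ids must match depths")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.empty(n, dtype="<U1")
    if mode == "unbiased":
        order = rng.permutation(n)
        labels[:] = "B"
        labels[order[: (n + 1) // 2]] = "A"
    elif mode == "median_split":
        med = np.median(depths)
        above = depths > med
        if not above.any() or above.all():
            raise ValueError("median split impossible: all depths on one side")
        labels[:] = "B"
        labels[above] = "A"
    elif mode == "tail_5_95":
        n_tail = max(1, int(np.ceil(0.05 * n)))
        order = np.lexsort((np.arange(n), depths))  # depth, then sample order
        labels[:] = ""
        labels[order[:n_tail]] = "B"
        labels[order[n - n_tail :]] = "A"
        middle = order[n_tail : n - n_tail]
        labels[middle] = np.where(rng.random(middle.size) < 0.5, "A", "B")
    else:
        raise ValueError(f"unknown bias mode {mode!r}")
    return TreatmentDesign(tuple(sample_ids), tuple(labels), mode)


def pooled_profile(observed: OtuTable) -> np.ndarray:
    """Dataset-wide relative abundance: OTU totals over the grand total."""
    totals = observed.counts.sum(axis=0).astype(np.float64)
    return totals / totals.sum()


def _sample_pair(
    observed: OtuTable,
    design: TreatmentDesign,
    p_a: np.ndarray,
    p_b: np.ndarray,
    rng: np.random.Generator,
) -> OtuTable:
    if tuple(design.sample_ids) != tuple(observed.sample_ids):
        raise ValueError("design sample ids must match the table")
    sizes = design.group_sizes()
    if 0 in sizes:
        raise ValueError("both treatment groups must be nonempty")
    counts = np.empty_like(observed.counts)
    mask_a = design.mask("A")
    for i, depth in enumerate(observed.depths):
        p = p_a if mask_a[i] else p_b
        counts[i] = rng.multinomial(int(depth), p)
    return OtuTable(observed.sample_ids, observed.otu_ids, counts)


def skewed_abundance_pair(
    observed: OtuTable, design: TreatmentDesign, model: EffectModel, seed=None
) -> OtuTable:
    """Two groups drawn (with replacement) from a profile and a skewed copy.

    Group A samples are multinomial draws at their observed depths from the
    pooled profile p; group B samples come from p with a random
    ``frac_otus_perturbed`` of OTUs multiplied by ``1 + effect_size`` and
    the whole vector renormalized.  Row sums equal the observed depths
    exactly.
    """
    if model.kind != "skewed_abundance":
        raise ValueError("model.kind must be 'skewed_abundance'")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    p = pooled_profile(observed)
    n_perturb = max(1, round(model.frac_otus_perturbed * observed.n_otus))
    chosen = rng.choice(observed.n_otus, size=n_perturb, replace=False)
    p_b = p.copy()
    p_b[chosen] *= 1.0 + model.effect_size
    p_b /= p_b.sum()
    return _sample_pair(observed, design, p, p_b, rng)


def richness_adjusted_pair(
    observed: OtuTable, design: TreatmentDesign, model: EffectModel, seed=None
) -> OtuTable:
    """Two groups where group B's profile lost a random 3% of the OTUs."""
    if model.kind != "richness_adjusted":
        raise ValueError("model.kind must be 'richness_adjusted'")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    p = pooled_profile(observed)
    n_remove = max(1, round(model.frac_otus_removed * observed.n_otus))
    if n_remove >= observed.n_otus:
        raise ValueError("removal would empty the profile")
    chosen = rng.choice(observed.n_otus, size=n_remove, replace=False)
    p_b = p.copy()
    p_b[chosen] = 0.0
    total = p_b.sum()
    if total == 0:
        raise ValueError("removal emptied the profile")
    p_b /= total
    return _sample_pair(observed, design, p, p_b, rng)
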
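"""Synthetic OTU tables with the size/depth structure of published 16S surveys.

Real amplicon surveys combine a long-tailed species-abundance distribution
with sample depths that can span two orders of magnitude within one study.
The generator here draws per-sample depths from a truncated lognormal, a
community profile from a lognormal species-abundance distribution, and each
sample multinomially from that profile at its depth.  ``panel_specs``
provides twelve ready-made specs whose sample counts and depth ranges match
a panel of published BioProjects spanning host-associated, aquatic, soil,
and engineered environments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .otu_io import OtuTable

__all__ = ["DatasetSpec", "generate_dataset", "panel_specs"]


@dataclass(frozen=True)
class DatasetSpec:
    """Parameters of one synthetic dataset.

    ``depth_log_mean``/``depth_log_sd`` parameterize a lognormal for sample
    depths, truncated to ``[min_depth, max_depth]`` by rejection so the
    stated bounds are respected exactly.  ``abundance_log_sd`` is the log-sd
    of the lognormal species-abundance distribution; 2.0 gives the heavy
    tail typical of 16S OTU data (a few dominant OTUs, a long tail of rare
    ones).
    """

    name: str = "synthetic"
    n_samples: int = 50
    n_otus: int = 2000
    depth_log_mean: float = np.log(16014.0)
    depth_log_sd: float = 1.0
    min_depth: int = 2000
    max_depth: int = 200000
    abundance_log_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_otus < 2:
            raise ValueError("need at least 2 samples and 2 OTUs")
        if self.min_depth < 1 or self.max_depth < self.min_depth:
            raise ValueError("require 1 <= min_depth <= max_depth")
        if self.depth_log_sd <= 0 or self.abundance_log_sd <= 0:
            raise ValueError("lognormal sd parameters must be positive")


def _truncated_lognormal(
    rng: np.random.Generator, n: int, mu: float, sigma: float, lo: int, hi: int
) -> np.ndarray:
    """Integer draws from a lognormal conditioned on [lo, hi]."""
    out = np.empty(n, dtype=np.int64)
    filled = 0
    for _ in range(1000):
        need = n - filled
        draw = np.floor(rng.lognormal(mu, sigma, size=2 * need + 16)).astype(np.int64)
        keep = draw[(draw >= lo) & (draw <= hi)][:need]
        out[filled : filled + keep.size] = keep
        filled += keep.size
        if filled == n:
            return out
    raise ValueError(
        "depth law rejects almost all draws; widen [min_depth, max_depth] "
        "or move depth_log_mean"
    )


def community_profile(spec: DatasetSpec, rng: np.random.Generator) -> np.ndarray:
    """Lognormal species-abundance profile, normalized to sum to 1."""
    w = rng.lognormal(0.0, spec.abundance_log_sd, size=spec.n_otus)
    return w / w.sum()


def generate_dataset(spec: DatasetSpec) -> OtuTable:
    """Draw one OTU table: truncated-lognormal depths, multinomial samples.

    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    depths = _truncated_lognormal(
        rng,
        spec.n_samples,
        spec.depth_log_mean,
        spec.depth_log_sd,
        spec.min_depth,
        spec.max_depth,
    )
    profile = community_profile(spec, rng)
    counts = np.vstack([rng.multinomial(d, profile) for d in depths])
    width = len(str(spec.n_samples))
    sample_ids = tuple(f"{spec.name}_{i + 1:0{width}d}" for i in range(spec.n_samples))
    otu_ids = tuple(f"Otu{j + 1:05d}" for j in range(spec.n_otus))
    return OtuTable(sample_ids, otu_ids, counts)


# (n_samples, median depth, min depth, max depth) for the twelve published
# surveys the generator emulates; only size and depth structure are mimicked,
# not taxonomy or the real abundance distributions.
_PANEL_ROWS: dict[str, tuple[int, int, int, int]] = {
    "Bioethanol": (95, 16014, 3690, 356027),
    "Human": (490, 32452, 10439, 422904),
    "Lake": (52, 69205, 15135, 110993),
    "Marine": (7, 213091, 132895, 256758),
    "Mice": (348, 6426, 1804, 30311),
    "Peromyscus": (111, 12393, 4454, 33502),
    "Rainforest": (69, 11464, 4880, 37403),
    "Rice": (490, 43399, 2777, 192200),
    "Seagrass": (286, 13538, 1830, 45076),
    "Sediment": (58, 17606, 7686, 67763),
    "Soil": (18, 50487, 46622, 58935),
    "Stream": (201, 90621, 8931, 394419),
}


def panel_specs(
    n_otus: int = 2000, abundance_log_sd: float = 2.0, seed: int = 0
) -> list[DatasetSpec]:
    """Twelve specs matching the sample counts and depth ranges of the panel.

    The depth law centers on the published median depth; its log-sd is set to
    a quarter of the log range so the truncated lognormal covers the stated
    bounds without being dominated by rejection.
    """
    specs = []
    for i, (name, (n, med, lo, hi)) in enumerate(sorted(_PANEL_ROWS.items())):
        sigma = max((np.log(hi) - np.log(lo)) / 4.0, 0.05)
        specs.append(
            DatasetSpec(
                name=name,
                n_samples=n,
                n_otus=n_otus,
                depth_log_mean=float(np.log(med)),
                depth_log_sd=float(sigma),
                min_depth=lo,
                max_depth=hi,
                abundance_log_sd=abundance_log_sd,
                seed=seed + i,
            )
        )
    return specs


def spec_by_name(name: str, **overrides) -> DatasetSpec:
    """Look up one of the named panel specs, optionally overriding fields."""
    for spec in panel_specs():
        if spec.name == name:
            return replace(spec, **overrides) if overrides else spec
    raise KeyError(f"no panel dataset named {name!r}")
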
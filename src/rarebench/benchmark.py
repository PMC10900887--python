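"""Canonical benchmark configurations reused by drivers, tests, and scripts.

Two study setups are fixed here so that every entry point reproduces the
same experiment:

- the *calibration* dataset (50 samples × 2,000 OTUs, truncated-lognormal
  depths spanning 2,000–200,000, i.e. a 100-fold spread centered on a
  typical published median depth) used for type-I-error studies under
  unbiased and depth-confounded treatment assignment;
- the *power* dataset, a smaller table (40 samples × 500 OTUs, 10-fold
  depth spread) on which the two effect models are compared across
  normalization strategies at affordable cost.
"""

from __future__ import annotations

import numpy as np

from .community_models import EffectModel
from .experiments import ExperimentResult, fpr_experiment, power_experiment
from .otu_io import OtuTable
from .synthetic_data import DatasetSpec, generate_dataset

__all__ = [
    "calibration_spec",
    "power_spec",
    "calibration_study",
    "mean_rejection_percent",
]

CALIBRATION_ALPHA_METRICS = ("richness", "shannon", "invsimpson")
CALIBRATION_BETA_METRICS = ("jaccard", "braycurtis")


def calibration_spec(seed: int = 0) -> DatasetSpec:
    """50 samples × 2,000 OTUs with a 100-fold depth spread."""
    return DatasetSpec(
        name="calibration",
        n_samples=50,
        n_otus=2000,
        depth_log_mean=float(np.log(16014.0)),
        depth_log_sd=1.0,
        min_depth=2000,
        max_depth=200000,
        abundance_log_sd=2.0,
        seed=seed,
    )


def power_spec(seed: int = 0) -> DatasetSpec:
    """40 samples × 500 OTUs with a 10-fold depth spread.

    Sized by pilot simulation so the subtle skewed-abundance effect (5% on
    10% of OTUs) is detectable (≈25% Bray-Curtis power) while remaining far
    from saturation, giving the power orderings room to show.
    """
    return DatasetSpec(
        name="power",
        n_samples=40,
        n_otus=500,
        depth_log_mean=float(np.log(6000.0)),
        depth_log_sd=0.5,
        min_depth=2000,
        max_depth=20000,
        abundance_log_sd=2.0,
        seed=seed,
    )


def calibration_study(
    bias_mode: str,
    seed: int = 0,
    n_replicates: int = 100,
    strategies: tuple[str, ...] = ("rarefaction",),
    table: OtuTable | None = None,
    progress: bool = False,
) -> ExperimentResult:
    """Type-I-error study on the calibration dataset.

    100 replicates of: fixed-margin null community, treatment assignment
    under ``bias_mode``, rarefied alpha metrics (1,000 draws at the minimum
    depth) tested with Wilcoxon, and 100-draw average Jaccard/Bray-Curtis
    distances tested with PERMANOVA (999 permutations), all at α = 0.05.
    """
    if table is None:
        table = generate_dataset(calibration_spec(seed))
    return fpr_experiment(
        table,
        bias_mode,
        n_replicates=n_replicates,
        seed=seed,
        strategies=strategies,
        alpha_metrics=CALIBRATION_ALPHA_METRICS,
        beta_metrics=CALIBRATION_BETA_METRICS,
        progress=progress,
    )


def mean_rejection_percent(result: ExperimentResult, strategy: str = "rarefaction") -> float:
    """Mean rejection rate across the five (metric, test) cells, in percent."""
    sub = result.aggregates[result.aggregates["strategy"] == strategy]
    if sub.empty:
        raise KeyError(f"no cells for strategy {strategy!r}")
    return float(sub["rate"].mean() * 100.0)


def power_ordering_study(
    seed: int = 0,
    n_replicates: int = 100,
    effect_sizes: tuple[float, ...] = (0.0, 0.05, 0.20),
    progress: bool = False,
) -> dict:
    """Power comparisons on the power dataset.

    Returns a dict with (i) rarefied vs SRS richness power under the
    richness-adjusted model (same replicates for both strategies, a paired
    comparison) and (ii) rarefied Bray-Curtis + PERMANOVA power across
    skewed-model effect sizes, computed with common random numbers across
    effect sizes.
    """
    table = generate_dataset(power_spec(seed))
    richness_result = power_experiment(
        table,
        EffectModel("richness_adjusted"),
        n_replicates=n_replicates,
        seed=seed,
        strategies=("rarefaction", "srs"),
        alpha_metrics=("richness",),
        beta_metrics=(),
        progress=progress,
    )
    skewed_power = {}
    for es in effect_sizes:
        result = power_experiment(
            table,
            EffectModel("skewed_abundance", effect_size=es),
            n_replicates=n_replicates,
            seed=seed,
            strategies=("rarefaction",),
            alpha_metrics=(),
            beta_metrics=("braycurtis",),
            progress=progress,
        )
        skewed_power[es] = result.rate("braycurtis", "rarefaction")
    return {
        "richness_power_rarefaction": richness_result.rate("richness", "rarefaction"),
        "richness_power_srs": richness_result.rate("richness", "srs"),
        "richness_records": richness_result.records,
        "skewed_braycurtis_power": skewed_power,
    }
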
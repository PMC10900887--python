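"""Experiment drivers: sensitivity, false-positive rate, power, depth sweep, coverage.

Each driver is a pure function of (dataset, configuration, seed) and returns
an :class:`ExperimentResult` holding the per-replicate records, the
aggregated summary, and the configuration that produced them, so every
aggregate is traceable to its records.

The designs mirror a common benchmarking protocol: regenerate a null (or
effect) community many times, run every (metric × strategy) cell through
its significance test at α = 0.05, and summarize rejection fractions,
depth correlations, or dispersion across depths.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .alpha_diversity import alpha_with_strategy, rarefied_alpha_table
from .beta_diversity import distance_matrix, rarefied_distance_matrices
from .community_models import (
    EffectModel,
    TreatmentDesign,
    assign_treatments,
    null_community,
    richness_adjusted_pair,
    skewed_abundance_pair,
)
from .inference import permanova, wilcoxon_rank_sum
from .normalization import DEFAULT_ALPHA_ITERS, DEFAULT_BETA_ITERS
from .otu_io import OtuTable

__all__ = [
    "ExperimentResult",
    "sensitivity_experiment",
    "fpr_experiment",
    "power_experiment",
    "depth_sweep",
    "coverage_experiment",
]

DEFAULT_ALPHA_METRICS = ("richness", "shannon", "invsimpson")
DEFAULT_BETA_METRICS = ("jaccard", "braycurtis")


@dataclass(frozen=True)
class ExperimentResult:
    """Per-replicate records plus the summary derived from them."""

    records: pd.DataFrame
    aggregates: pd.DataFrame
    config: dict = field(default_factory=dict)

    def rate(self, metric: str, strategy: str) -> float:
        """Rejection rate (FPR or power) for one (metric, strategy) cell."""
        sub = self.aggregates
        row = sub[(sub["metric"] == metric) & (sub["strategy"] == strategy)]
        if row.empty:
            raise KeyError(f"no cell ({metric!r}, {strategy!r})")
        return float(row["rate"].iloc[0])


def _log(progress: bool, msg: str) -> None:
    if progress:
        print(msg, file=sys.stderr, flush=True)


def _seeds(master: int, replicate: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence([int(master), int(replicate)]).spawn(n)


def _alpha_values(
    table: OtuTable,
    metrics: tuple[str, ...],
    strategy: str,
    depth: int | None,
    n_iter: int,
    seed,
) -> pd.DataFrame:
    """Per-sample values for several alpha metrics under one strategy."""
    if strategy == "rarefaction":
        return rarefied_alpha_table(table, depth, metrics, n_iter, seed)
    frames = {}
    for m in metrics:
        res = alpha_with_strategy(table, m, strategy, depth=depth)
        frames[m] = res.to_series()
    return pd.DataFrame(frames)


def _test_battery(
    table: OtuTable,
    design: TreatmentDesign,
    strategies: tuple[str, ...],
    alpha_metrics: tuple[str, ...],
    beta_metrics: tuple[str, ...],
    depth: int | None,
    n_alpha_iters: int,
    n_beta_iters: int,
    n_permutations: int,
    seeds: list[np.random.SeedSequence],
) -> list[dict]:
    """p-values for every (metric × strategy) cell on one simulated dataset."""
    alpha_seed, beta_seed, perm_seed = seeds
    perm_rng = np.random.default_rng(perm_seed)
    group_a = design.mask("A")
    rows: list[dict] = []
    for strategy in strategies:
        if alpha_metrics:
            values = _alpha_values(
                table, alpha_metrics, strategy, depth, n_alpha_iters, alpha_seed
            )
            for m in alpha_metrics:
                v = values[m].to_numpy()
                res = wilcoxon_rank_sum(v[group_a], v[~group_a])
                rows.append(
                    {"family": "alpha", "metric": m, "strategy": strategy,
                     "p_value": res.p_value, "statistic": res.statistic}
                )
        if beta_metrics:
            if strategy == "rarefaction":
                dms = rarefied_distance_matrices(
                    table, tuple(beta_metrics), depth, n_beta_iters, beta_seed
                )
            else:
                dms = {
                    m: distance_matrix(table, m, strategy, depth=depth)
                    for m in beta_metrics
                }
            for m in beta_metrics:
                res = permanova(dms[m], design, n_permutations, perm_rng)
                rows.append(
                    {"family": "beta", "metric": m, "strategy": strategy,
                     "p_value": res.p_value, "statistic": res.statistic}
                )
    return rows


def _rates(records: pd.DataFrame, alpha: float) -> pd.DataFrame:
    agg = (
        records.assign(significant=records["p_value"] < alpha)
        .groupby(["family", "metric", "strategy"], as_index=False)
        .agg(rate=("significant", "mean"), n=("significant", "size"))
    )
    return agg


def fpr_experiment(
    table: OtuTable,
    bias_mode: str = "unbiased",
    n_replicates: int = 100,
    seed: int = 0,
    strategies: tuple[str, ...] = ("rarefaction",),
    alpha_metrics: tuple[str, ...] = DEFAULT_ALPHA_METRICS,
    beta_metrics: tuple[str, ...] = DEFAULT_BETA_METRICS,
    depth: int | None = None,
    n_alpha_iters: int = DEFAULT_ALPHA_ITERS,
    n_beta_iters: int = DEFAULT_BETA_ITERS,
    n_permutations: int = 999,
    alpha: float = 0.05,
    progress: bool = False,
) -> ExperimentResult:
    """Type-I-error study: null communities, possibly depth-biased grouping.

    Per replicate: regenerate the fixed-margin null table, assign treatment
    groups under ``bias_mode``, compute every (metric × strategy) cell, and
    test alpha metrics with Wilcoxon and beta metrics with PERMANOVA.  The
    false-positive rate of a cell is the fraction of replicates with
    p < ``alpha``.
    """
    rows = []
    for rep in range(n_replicates):
        null_s, design_s, *battery = _seeds(seed, rep, 5)
        null = null_community(table, np.random.default_rng(null_s))
        design = assign_treatments(
            null.depths, bias_mode, np.random.default_rng(design_s), null.sample_ids
        )
        for row in _test_battery(
            null, design, strategies, alpha_metrics, beta_metrics,
            depth, n_alpha_iters, n_beta_iters, n_permutations, battery,
        ):
            rows.append({"replicate": rep, **row})
        if (rep + 1) % 10 == 0:
            _log(progress, f"fpr[{bias_mode}] replicate {rep + 1}/{n_replicates}")
    records = pd.DataFrame(rows)
    config = {
        "experiment": "fpr", "bias_mode": bias_mode, "n_replicates": n_replicates,
        "seed": seed, "strategies": strategies, "alpha": alpha,
        "n_alpha_iters": n_alpha_iters, "n_beta_iters": n_beta_iters,
        "n_permutations": n_permutations,
    }
    return ExperimentResult(records, _rates(records, alpha), config)


def power_experiment(
    table: OtuTable,
    effect: EffectModel,
    n_replicates: int = 100,
    seed: int = 0,
    strategies: tuple[str, ...] = ("rarefaction",),
    alpha_metrics: tuple[str, ...] = DEFAULT_ALPHA_METRICS,
    beta_metrics: tuple[str, ...] = DEFAULT_BETA_METRICS,
    depth: int | None = None,
    n_alpha_iters: int = DEFAULT_ALPHA_ITERS,
    n_beta_iters: int = DEFAULT_BETA_ITERS,
    n_permutations: int = 999,
    alpha: float = 0.05,
    progress: bool = False,
) -> ExperimentResult:
    """Power study: paired communities with a known simulated effect.

    Group assignment is unbiased; group B's generating profile carries the
    effect (skewed abundances or removed OTUs).  Power of a cell is the
    fraction of replicates with p < ``alpha``.  With ``effect_size = 0``
    (skewed model) the two profiles coincide and power reduces to the
    false-positive rate.
    """
    builder = (
        skewed_abundance_pair
        if effect.kind == "skewed_abundance"
        else richness_adjusted_pair
    )
    rows = []
    for rep in range(n_replicates):
        design_s, effect_s, *battery = _seeds(seed, rep, 5)
        design = assign_treatments(
            table.depths, "unbiased", np.random.default_rng(design_s), table.sample_ids
        )
        pair = builder(table, design, effect, seed=effect_s)
        for row in _test_battery(
            pair, design, strategies, alpha_metrics, beta_metrics,
            depth, n_alpha_iters, n_beta_iters, n_permutations, battery,
        ):
            rows.append({"replicate": rep, **row})
        if (rep + 1) % 10 == 0:
            _log(progress, f"power[{effect.kind}] replicate {rep + 1}/{n_replicates}")
    records = pd.DataFrame(rows)
    config = {
        "experiment": "power", "effect": effect.kind,
        "effect_size": effect.effect_size, "n_replicates": n_replicates,
        "seed": seed, "strategies": strategies, "alpha": alpha,
    }
    return ExperimentResult(records, _rates(records, alpha), config)


DEFAULT_ALPHA_SENSITIVITY = (
    ("richness", "raw"), ("richness", "srs"), ("richness", "rarefaction"),
    ("chao1", "estimator"), ("ace", "estimator"),
    ("shannon", "raw"), ("shannon", "srs"), ("shannon", "rarefaction"),
    ("invsimpson", "raw"), ("invsimpson", "srs"), ("invsimpson", "rarefaction"),
)
DEFAULT_BETA_SENSITIVITY = tuple(
    [(m, s) for m in ("jaccard", "braycurtis")
     for s in ("raw", "relabund", "srs", "css", "rarefaction")]
    + [("euclidean", s)
       for s in ("raw", "relabund", "clr-one", "clr-nudge", "rarefaction")]
)


def sensitivity_experiment(
    table: OtuTable,
    n_replicates: int = 100,
    seed: int = 0,
    alpha_specs: tuple[tuple[str, str], ...] = DEFAULT_ALPHA_SENSITIVITY,
    beta_specs: tuple[tuple[str, str], ...] = DEFAULT_BETA_SENSITIVITY,
    depth: int | None = None,
    n_alpha_iters: int = DEFAULT_ALPHA_ITERS,
    n_beta_iters: int = DEFAULT_BETA_ITERS,
    progress: bool = False,
) -> ExperimentResult:
    """Correlation between sequencing effort and each diversity measure.

    Per replicate, on a fresh null table: for every alpha (metric, strategy)
    the Spearman correlation between sample depth and the per-sample value;
    for every beta pair the Spearman correlation between the pairwise
    absolute depth difference and the pairwise distance.  Correlations are
    computed per replicate and averaged.  Under the null every sample is a
    draw of one community, so any nonzero correlation is depth sensitivity.
    """
    rows = []
    iu = np.triu_indices(table.n_samples, k=1)
    for rep in range(n_replicates):
        null_s, alpha_s, beta_s = _seeds(seed, rep, 3)
        null = null_community(table, np.random.default_rng(null_s))
        depths = null.depths.astype(float)
        ddiff = np.abs(depths[iu[0]] - depths[iu[1]])
        by_strategy: dict[str, pd.DataFrame] = {}
        for metric, strategy in alpha_specs:
            key = strategy
            metrics_here = tuple(m for m, s in alpha_specs if s == strategy)
            if key not in by_strategy:
                by_strategy[key] = _alpha_values(
                    null, metrics_here, strategy, depth, n_alpha_iters, alpha_s
                )
            values = by_strategy[key][metric]
            kept = values.index
            d_kept = depths[[null.sample_ids.index(s) for s in kept]]
            rho = spearmanr(d_kept, values.to_numpy()).statistic
            rows.append(
                {"replicate": rep, "family": "alpha", "metric": metric,
                 "strategy": strategy, "spearman": rho}
            )
        raref_metrics = tuple(m for m, s in beta_specs if s == "rarefaction")
        raref_dms = (
            rarefied_distance_matrices(null, raref_metrics, depth, n_beta_iters, beta_s)
            if raref_metrics
            else {}
        )
        for metric, strategy in beta_specs:
            dm = (
                raref_dms[metric]
                if strategy == "rarefaction"
                else distance_matrix(null, metric, strategy, depth=depth)
            )
            if dm.n_samples == table.n_samples:
                dd = ddiff
            else:
                idx = [null.sample_ids.index(s) for s in dm.sample_ids]
                sub = depths[idx]
                sub_iu = np.triu_indices(len(idx), k=1)
                dd = np.abs(sub[sub_iu[0]] - sub[sub_iu[1]])
            rho = spearmanr(dd, dm.condensed()).statistic
            rows.append(
                {"replicate": rep, "family": "beta", "metric": metric,
                 "strategy": strategy, "spearman": rho}
            )
        if (rep + 1) % 10 == 0:
            _log(progress, f"sensitivity replicate {rep + 1}/{n_replicates}")
    records = pd.DataFrame(rows)
    agg = records.groupby(["family", "metric", "strategy"], as_index=False).agg(
        mean_spearman=("spearman", "mean"), n=("spearman", "size")
    )
    config = {"experiment": "sensitivity", "n_replicates": n_replicates, "seed": seed}
    return ExperimentResult(records, agg, config)


def depth_sweep(
    table: OtuTable,
    depths: list[int],
    n_replicates: int = 10,
    seed: int = 0,
    n_alpha_iters: int = DEFAULT_ALPHA_ITERS,
    n_beta_iters: int = DEFAULT_BETA_ITERS,
    min_samples: int = 5,
    progress: bool = False,
) -> ExperimentResult:
    """Mean and CV of rarefied metrics as the rarefaction depth varies.

    For each replicate null table and each depth (ascending), samples below
    the depth are dropped; depths retaining fewer than ``min_samples``
    samples are skipped.  Rarefied richness and Shannon are summarized
    across samples, rarefied Bray-Curtis across pairs; CV = sd/mean.
    """
    depths = sorted(int(d) for d in depths)
    rows = []
    any_kept = False
    for rep in range(n_replicates):
        null_s, alpha_s, beta_s = _seeds(seed, rep, 3)
        null = null_community(table, np.random.default_rng(null_s))
        for depth in depths:
            retained = int((null.depths >= depth).sum())
            if retained < min_samples:
                continue
            any_kept = True
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore", UserWarning)
                values = rarefied_alpha_table(
                    null, depth, ("richness", "shannon"), n_alpha_iters, alpha_s
                )
                dm = rarefied_distance_matrices(
                    null, ("braycurtis",), depth, n_beta_iters, beta_s
                )["braycurtis"]
            summaries = {
                "richness": values["richness"].to_numpy(),
                "shannon": values["shannon"].to_numpy(),
                "braycurtis": dm.condensed(),
            }
            for metric, v in summaries.items():
                mean = float(np.mean(v))
                sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
                rows.append(
                    {"replicate": rep, "depth": depth, "metric": metric,
                     "n_samples": retained, "mean": mean,
                     "cv": sd / mean if mean != 0 else np.nan}
                )
        if (rep + 1) % 5 == 0:
            _log(progress, f"depth sweep replicate {rep + 1}/{n_replicates}")
    if not any_kept:
        raise ValueError("every requested depth retains fewer than "
                         f"{min_samples} samples")
    records = pd.DataFrame(rows)
    agg = records.groupby(["depth", "metric"], as_index=False).agg(
        mean=("mean", "mean"), cv=("cv", "mean"), n_samples=("n_samples", "first")
    )
    config = {"experiment": "depth_sweep", "depths": depths, "seed": seed,
              "n_replicates": n_replicates}
    return ExperimentResult(records, agg, config)


def coverage_experiment(
    table: OtuTable,
    depths: list[int] | None = None,
    seed: int = 0,
    n_iter: int = DEFAULT_ALPHA_ITERS,
    progress: bool = False,
) -> ExperimentResult:
    """Good's coverage three ways: observed, rarefied, simulated-vs-depth.

    (i) plug-in coverage of each observed sample; (ii) mean coverage over
    ``n_iter`` subsamples at the dataset minimum depth; (iii) a coverage-
    versus-depth curve computed on one null-community table (mean rarefied
    coverage across the samples retained at each depth).
    """
    from .alpha_diversity import goods_coverage, rarefied_alpha_table  # local reuse

    min_depth = int(table.depths.min())
    if depths is None:
        hi = int(table.depths.max())
        depths = sorted(
            {int(d) for d in np.geomspace(min_depth, hi, num=10).round()}
        )
    rows = [
        {"mode": "observed", "sample": s, "depth": int(d), "coverage": goods_coverage(c)}
        for s, d, c in zip(table.sample_ids, table.depths, table.counts)
    ]
    obs_raref = rarefied_alpha_table(table, min_depth, ("coverage",), n_iter,
                                     np.random.SeedSequence([seed, 0]))
    rows += [
        {"mode": "rarefied", "sample": s, "depth": min_depth,
         "coverage": float(v)}
        for s, v in obs_raref["coverage"].items()
    ]
    null = null_community(table, np.random.default_rng(np.random.SeedSequence([seed, 1])))
    import warnings as _w

    for j, depth in enumerate(sorted(depths)):
        keep = null.depths >= depth
        if keep.sum() < 1:
            continue
        with _w.catch_warnings():
            _w.simplefilter("ignore", UserWarning)
            values = rarefied_alpha_table(
                null, depth, ("coverage",), n_iter, np.random.SeedSequence([seed, 2, j])
            )
        rows.append(
            {"mode": "null_curve", "sample": "(mean)", "depth": int(depth),
             "coverage": float(values["coverage"].mean())}
        )
        _log(progress, f"coverage curve depth {depth}")
    records = pd.DataFrame(rows)
    agg = records.groupby(["mode", "depth"], as_index=False).agg(
        coverage=("coverage", "mean"), n=("coverage", "size")
    )
    config = {"experiment": "coverage", "seed": seed, "n_iter": n_iter}
    return ExperimentResult(records, agg, config)
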
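"""How the rarefaction depth shapes rarefied metrics and their dispersion.

Sweeps the rarefaction depth across a log-spaced grid on null replicates of
the power dataset and records the across-sample mean and coefficient of
variation (sd/mean) of rarefied richness, Shannon diversity, and Bray-
Curtis distances.  Richness keeps climbing with depth as rare OTUs continue
to appear; Shannon plateaus and its CV shrinks toward zero; depths
retaining fewer than five samples are skipped.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from rarebench import depth_sweep, generate_dataset
from rarebench.benchmark import power_spec

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

SEED = 1


def main() -> None:
    table = generate_dataset(power_spec(SEED))
    lo, hi = int(table.depths.min()), int(table.depths.max())
    depths = sorted({int(d) for d in np.geomspace(lo // 4, hi, num=8).round()})
    result = depth_sweep(
        table,
        depths,
        n_replicates=5,
        seed=SEED,
        n_alpha_iters=200,
        n_beta_iters=25,
        progress=True,
    )
    agg = result.aggregates
    agg.to_csv(RESULTS / "depth_sweep_summary.tsv", sep="\t", index=False)
    print(agg.to_string(index=False))

    rich = agg[agg["metric"] == "richness"].sort_values("depth")
    sh = agg[agg["metric"] == "shannon"].sort_values("depth")
    print(
        f"\nRarefied richness grows {rich['mean'].iloc[0]:.0f} → "
        f"{rich['mean'].iloc[-1]:.0f} across the sweep while Shannon moves "
        f"only {sh['mean'].iloc[0]:.2f} → {sh['mean'].iloc[-1]:.2f} and its "
        f"CV falls {sh['cv'].iloc[0]:.3f} → {sh['cv'].iloc[-1]:.3f}: depth "
        "buys precision for evenness-weighted metrics, not stability for "
        "richness."
    )


if __name__ == "__main__":
    main()
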
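# Methods

## Models

**Fixed-margin null community.**  For an observed samples × OTUs count
table, the pool of all ΣN sequence labels (each OTU id repeated by its
dataset-wide total) is shuffled uniformly and partitioned sequentially into
samples by their observed depths.  Both margins are conserved exactly by
construction, and each sample's counts are a multivariate hypergeometric
draw from the pooled community conditional on the others.  A useful exact
consequence: subsampling any null-model sample to a common depth d yields,
by exchangeability, the same distribution as a direct d-draw from the pool
— so rarefied metrics are *exactly* exchangeable across samples regardless
of original depth.  That is the mechanism behind the calibration results,
not an approximation.

**Treatment models.**  `unbiased` splits samples uniformly into groups of
⌈n/2⌉ and ⌊n/2⌋ (group sizes are not stated more precisely anywhere, and a
balanced split maximizes test power, so it is the natural reading).
`median_split` puts every sample with depth strictly above the median in
one group.  `tail_5_95` pins the ⌈0.05 n⌉ shallowest samples to one group
and the ⌈0.05 n⌉ deepest to the other, assigning the middle 90% by fair
coin; depth ties are broken by sample order so the assignment is
deterministic given the seed.

**Effect models.**  Both build a two-group dataset from the pooled
relative-abundance profile p (OTU totals over the grand total), drawing
every sample multinomially (with replacement) at its observed depth.  The
*skewed-abundance* model multiplies a seeded random 10% of OTUs' p_i by
1.05 and renormalizes — the only reading of "increase relative abundance
by 5%" under which the profile remains a distribution.  The
*richness-adjusted* model zeroes a seeded random 3% of OTUs and
renormalizes.  The number of OTUs perturbed/removed is round(fraction · K),
minimum 1.  The perturbation is applied at the pooled-profile level (not
per sample), which is what makes the two groups exchangeable within group.

## Normalizations

- **Subsampling / rarefaction.**  A single subsample is a multivariate
  hypergeometric draw.  Rarefaction averages a statistic over repeated
  subsamples: 1,000 draws for alpha metrics, 100 for average-distance
  (avgdist-style) beta matrices, at the dataset's minimum depth by default;
  samples below the depth are dropped once, before iterating.
- **SRS.**  Counts are scaled by target/N; integer parts are kept and the
  leftover units go to the OTUs with the largest fractional parts.  The
  reference algorithm randomizes fractional-part ties; the default here is
  deterministic (descending scaled value, then OTU index) with
  `random_ties=True` restoring randomization.  Determinism was preferred
  because tie noise is irrelevant to the benchmark but poisons
  reproducibility.
- **CSS.**  Per sample, the scaling factor is the sum of counts at or below
  the 0.5 quantile of the sample's nonzero counts, with output scale ×1000.
  The reference implementation searches for a dataset-adaptive quantile;
  that search is out of scope here because CSS serves as a comparison
  baseline, not the object of study.
- **CLR.**  y_i = ln((x_i + c)/g(x + c)) with c = 1 ("one") or c = 1/N_j
  ("nudge").  Rows sum to zero by the CLR identity.  Euclidean distance on
  CLR values is the Aitchison distance.

## Tests

**Wilcoxon rank-sum** (two-sided, midranks): exact by complete enumeration
of the rank-sum distribution when the combined n ≤ 20 and there are no
ties — enumeration is cheap there and removes any approximation concern at
the panel's smallest sample sizes — otherwise the normal approximation
with tie correction and continuity correction.  **PERMANOVA**: pseudo-F
from squared distances, p = (1 + #{F_perm ≥ F_obs})/(1 + P) over P = 999
uniform label permutations (the permutation count is the convention of the
standard implementations; the +1 correction keeps p > 0 and the test
exact-level).  On Euclidean distances of 1-D points the pseudo-F equals the
one-way ANOVA F; the suite checks this identity numerically, along with
complete-enumeration oracles at n = 8.

## Synthetic data

Each dataset draws per-sample depths from a lognormal truncated (by
rejection, so bounds are respected exactly) to a stated [min, max], a
community profile from a lognormal species-abundance distribution
(log-sd 2.0 — heavy-tailed, a few dominant OTUs and a long rare tail), and
each sample multinomially from that profile.  Twelve ready-made specs match
the sample counts and depth ranges of a published 12-study panel
(3,690–356,027 at the widest); only size and depth structure are emulated —
taxonomy, per-dataset abundance shapes, and any real covariance between
depth and composition are not, so passing benchmarks here demonstrate
behavior under uneven *effort*, not robustness to every artifact of real
libraries.  OTU richness is fixed at 2,000 per dataset (the panel's real
richnesses are unknown to the generator and do not affect the
depth-confounding mechanism being studied).

Benchmark datasets, fixed once: *calibration* — 50 samples × 2,000 OTUs,
depths on [2,000, 200,000] (log-mean ln 16,014, log-sd 1.0), reproducing
the ~100-fold worst-case spread; *power* — 40 samples × 500 OTUs, depths
on [2,000, 20,000].  The power dataset was sized by pilot simulation so the
subtle skewed-abundance effect is detectable but unsaturated
(Bray-Curtis/PERMANOVA power ≈ 0.05/0.25/1.0 at effect sizes 0/0.05/0.20);
power comparisons across strategies and effect sizes reuse the same
replicate seeds (common random numbers) so orderings are paired rather
than noise-dominated.

## Numerical choices

- **Subsampling engine.**  Repeated subsampling dominates the benchmark's
  cost (~10^9 sequence draws per study), so it runs as a numba kernel: the
  sample's label pool is shuffled by a partial Fisher–Yates pass per draw
  (a permuted pool is still the same pool, so no restore is needed), with a
  splitmix64 PRNG and double-precision range reduction (bias O(range/2^53),
  negligible).  numpy's `multivariate_hypergeometric` is kept as the
  independent oracle in the test suite, which checks the kernel against
  closed-form expected richness, hypergeometric marginals, and subset
  uniformity by enumeration.
- **RNG discipline.**  One master seed per experiment; per-replicate and
  per-sample streams derived through `SeedSequence` spawning, so results do
  not depend on evaluation order and are bitwise reproducible.
- **Degenerate inputs.**  Zero-depth samples are readable but rejected by
  any operation dividing by N.  All-singleton samples have no inverse
  Simpson (D = 0) — an error for the scalar function; excluded draws in the
  rarefied mean (they do not occur at realistic depths).  All-zero distance
  matrices give PERMANOVA p = 1.  ACE uses the standard rare cutoff of 10
  and falls back to bias-corrected Chao1 when the rare group's coverage is
  zero.
- **CV** is sd/mean throughout.
- **Dissimilarity forms.**  Bray-Curtis = Σ|n_A − n_B|/(N_A + N_B) and
  Euclidean = √Σ(n_A − n_B)², i.e. the standard dissimilarities where
  identical samples give 0; Jaccard = 1 − S_AB/(S_A + S_B − S_AB).

## Scale of the shipped runs

Full-scale studies (100 replicates, 1,000/100 rarefaction draws, 999
permutations) run in `scripts/acceptance.py` and the end-to-end test
module, about ten minutes total on one CPU.  The `analysis/` drivers use
20–40 replicates and 200/25 draws to stay in the minutes range while
showing the same orderings; replicate counts are parameters everywhere.

## Known limitations

- The generator shares one abundance profile across samples; real studies
  have between-sample heterogeneity beyond depth, which the null model
  deliberately removes and the benchmark therefore does not probe.
- Only two-group designs; no multi-factor PERMANOVA, strata, or dispersion
  (PERMDISP) tests.
- CLR variants with zero-imputation or matrix completion, variance-
  stabilizing transforms, parametric richness models, and
  rarefaction/extrapolation estimators are outside the implemented scope.
- The exact Wilcoxon cutoff (n ≤ 20, no ties) means studies of ≥ 21
  samples always use the corrected normal approximation, as standard
  software does.
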
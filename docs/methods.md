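# Methods

This note records the statistical conventions, defaults and open design
choices behind the package. It documents procedures only; every number
quoted as a result is one the test suite or the analysis drivers
recompute.

## Calibration model

Detector response is modelled as linear in concentration,
`Y = a·x + b`, fitted by unweighted ordinary least squares to the
*per-level mean* responses (replicates are averaged before fitting, the
standard external-calibration construction). r² is the squared Pearson
correlation of observed and fitted level means. Weighted regression is
deliberately not offered: the validated working ranges (1–10 mg L⁻¹ in
solvent, 3–10 mg kg⁻¹ matrix-matched) span one decade, where
heteroscedasticity distorts unweighted fits only mildly; the synthetic
generator produces CV-proportional noise precisely so this choice can be
stress-tested.

Degenerate inputs: fewer than three distinct levels raises an
insufficient-data error; identical levels a degenerate-design error.
With a single replicate per level the mean-aggregation path reduces to
the raw fit.

## Detection and quantification limits

`LOD = k₃·σ/a` and `LOQ = k₁₀·σ/a` with k₃ = 3, k₁₀ = 10. Two σ
estimators are available as a policy:

* `residual_sd` (default): residual standard deviation of the level
  means about the fitted line;
* `intercept_sd`: standard error of the fitted intercept
  (`σ_resid·√(1/n + x̄²/Sxx)`), the ISO 11843-flavoured variant.

The source method statement cites both a signal-to-noise convention and
ISO 11843 without the raw data needed to disambiguate, so the estimator
is a policy rather than a constant. Under either estimator
LOQ/LOD = 10/3 exactly; the bundled regression-summary fixture contains
two printed pairs violating that ratio (compound 8/porridge 0.9/0.4,
compound 2/teabag 1.5/2.9), presumed typos and stored verbatim — the
ratio invariant is asserted only on curves this package fits.

Boundary convention for coding a measured concentration c: c < LOD →
not detected (0.0); LOD ≤ c < LOQ → below LOQ (0.1); c ≥ LOQ →
quantified. Lower-inclusive throughout.

## Matrix effect

`%ME = 100·(S_matrix − S_solvent)/S_solvent`, direction from the sign of
the unrounded value (exact zero → "none"). Severity bands on |%ME| are
mild < 20 ≤ medium < 50 ≤ strong, lower edges inclusive, so the classes
partition the line and are symmetric under sign flip.

Reported integer percentages are rounded in two stages — to one decimal,
then to the integer, halves away from zero — because the summary values
were evidently presented that way (the largest enhancement is 44.499%,
printed as 45%). Full precision is kept internally.

The slope-sign recount over all 50 pairs gives 31 enhanced / 19
suppressed (62%/38%); the source text asserts 60%/40%. The summary
reports the recount and leaves the discrepancy visible rather than
reconciling it.

## Recovery and precision

`%R = 100·(C_found − C_original)/C_spiked`, computed on the mean of
replicate inverse-predicted concentrations (per-replicate recoveries are
kept for audit). Intra-day precision is the %RSD (sample SD, n−1) of
replicates within the reference day; inter-day precision is the %RSD of
per-day means across days — the aggregation is not stated in the source,
and day-mean RSD is standard intermediate-precision practice; it is
configurable via `precision_summary`'s inputs. A single-day table
reports inter-day precision as unavailable, never as zero. Threshold
comparisons are strict (<10% intra, <20% inter).

## Top-down uncertainty

The printed defining equations are typographically corrupted (radicals
and grouping lost). The adopted reading is

    U_x = √(RSD² + ((100 − R)/d)²),  U_c = √(U₃² + U₁₀²),  U = K·U_c

with bias divisor d = √3 by default (rectangular-distribution
convention for converting a bias bound into a standard uncertainty;
d = 1 and d = √(3n) are selectable) and coverage factor K = 2. The RSD
feeding U_x defaults to the inter-day value at that level, since
reproducibility dominates top-down budgets; intra-day is selectable.

The published expanded-uncertainty row is **not reproducible** from the
printed recovery/RSD summaries under any reading of the corrupted
equations explored here (the recomputed budget for compound 1 in seeds
is ≈40% against a printed 10.7%); it ships as fixture metadata for
side-by-side display and is never asserted against.

## Product quantification summaries

Per-sample counts treat a cell as detected when its status is below-LOQ
or quantified, so `n_detected = n_below_loq + n_quantified` by
construction. Per-compound extremes use quantified cells only — 0.1 is a
code, not a measurement. Ties at a compound's maximum report all argmax
samples in table order (compound 7 peaks at 9.6 mg kg⁻¹ in both PRD1
and S1; the source names only PRD1). A further printed-table
discrepancy: sample L7 also contains exactly five detected compounds,
although the source names only L5/TB1/TB2/TB3 as the five-compound
minimum set.

## PCA and clustering

PCA is an eigendecomposition (`numpy.linalg.eigh`) of the covariance or
correlation matrix of column-centred (and, in correlation mode,
column-standardised with n−1 SDs) data. Components are ordered by
eigenvalue; negative eigenvalues from floating-point round-off are
clipped to zero; signs are fixed by making the largest-magnitude loading
of each component positive, so scores are reproducible run to run.
Coded cells (0.0/0.1) enter as numbers — the source applies no
imputation. Variance fractions are eigenvalues over their total and sum
to one; all-constant data yields an all-zero fraction vector, flagged
degenerate.

The library default is correlation mode (shared units, unequal spreads
argue for standardising), but the product-comparison driver runs both
modes because the software used for the original analysis does not state
its mode. Empirically the covariance mode matches the reported variance
partition (30.4%/25.2% recomputed vs 30.3%/25.1% reported, within 0.5
percentage points) while correlation mode does not (29.5%/19.3%), so the
reported figures are identified with the unstandardised analysis; the
residual 0.1-point differences are presentation rounding and are left as
is.

Biplot coordinates follow the standard α-split: sites `U·S^α`, arrows
`V·S^(1−α)` (α = 1 distance biplot, α = 0 correlation biplot); the
inner products of the α-split coordinates reconstruct the rank-k
approximation of the preprocessed data.

Clustering is agglomerative with Euclidean distances and Lance–Williams
updates (average default; single, complete, Ward selectable; Ward
updates run on squared distances and heights are un-squared). Ties on
the minimum inter-cluster distance break on the smallest cluster-index
pair, making the merge tree deterministic. The tree serialises to Newick
with branch lengths equal to merge-height differences. Merge heights are
verified against an independent implementation in the tests
(and single linkage against a minimum-spanning-tree construction).

## Synthetic-data generator

The generators mirror the validated study design: a seven-point solvent
curve over 1–10 mg L⁻¹ and five-point matrix curves over 3–10 mg kg⁻¹,
seven replicate injections per level, five consecutive days, spikes at
3/6/10 mg kg⁻¹. Noise is multiplicative lognormal with unit mean —
per-injection CV 1% and between-day SD 2% by default, inside the
reported intra-day (0.1–4.7%) and inter-day (0.02–6.3%) RSD ranges for
the matrices — because peak-area scatter scales with signal and
lognormal factors keep responses positive. The default recovery-bias
profile (76/95/100% at 3/6/10 mg kg⁻¹) echoes the reported
level-dependent recovery pattern. Default product groups are three
clusters (leafy, seed-like, heterogeneous commercial) with disjoint
dominant compounds.

What the generator does **not** emulate: chromatographic peak shape,
drift and carryover, co-elution, matrix-dependent *noise* (only
matrix-dependent slopes), and non-normal between-sample variation in
product profiles. Passing parameter-recovery tests therefore shows the
estimators are correctly implemented and unbiased under the stated noise
model, not that the method is robust to every real-data pathology.

## Problem sizes

Monte-Carlo checks use 200–500 repeats of the study-sized designs
(7 × 7 or 5 × 7 level/replicate grids, 5 days), enough to pin the mean
fitted slope within ±0.5% and mean recoveries within ±2% relative;
multivariate checks run on the full 32 × 10 product matrix and small
random matrices against brute-force eigen/MST oracles.
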
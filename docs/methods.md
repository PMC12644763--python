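# Methods

`sepstrat` re-implements, at desk scale, a toolkit for quantifying
sepsis heterogeneity from eight routine predictors: seven
coagulation-inflammatory markers (APTT, INR, WBC, neutrophil,
lymphocyte, monocyte and platelet counts) and patient age. This note
records the models, the numerical choices, and what the bundled
synthetic cohorts do and do not establish.

## Synthetic cohort model

The generator is the package's substitute for access-controlled ICU
cohorts. It reproduces the *structure* those cohorts are reported to
have — a minority mortality class, multi-center covariate shift, a
latent marker-driven risk, two marker subpopulations, and
stratum-dependent treatment effects — without attempting to match any
real marginal distribution numerically.

Marker marginals. Count-type markers (WBC, NEUT, LYM, MON, PLT) are
log-normal; APTT, INR and age are truncated normal. These families
were chosen once for positivity and the right skew typical of routine
labs. Defaults (natural-scale median / log-sd for the log-normals;
mean / sd / truncation for the rest) describe a plausibly severe ICU
population: age 64 ± 16 y (≥ 18), APTT 38 ± 12 s, INR 1.4 ± 0.4,
WBC 12 ·e0.50, NEUT 9 ·e0.55, LYM 1.0 ·e0.60, MON 0.5 ·e0.60,
PLT 180 ·e0.50 (all counts ×10⁹/L).

Outcome model. Markers are z-standardized within the cohort and a
logistic linear predictor `eta = b0 + Σ beta_j z_j` defines the death
probability; the intercept is solved by root finding so the mean death
probability equals the configured mortality rate (default 0.25, in the
range of the reported retrospective cohorts). Default coefficients
point in the clinically expected directions (positive for APTT, INR,
WBC, NEUT, MON, age; negative for LYM and PLT) with magnitudes 0.3–0.8
so that a logistic refit on n ≥ 20,000 recovers them within ±15 %.

Survival. The 28-day survival time is exponential with the per-patient
rate chosen so that `P(T ≤ 28) = p_i` exactly; this makes the binary
28-day outcome and the survival time mutually consistent by
construction (the simplest coherent joint model). Administrative
censoring at 28 days. Treated patients have their rate multiplied by a
stratum's hazard multiplier; with several multipliers, strata are
equal-sized quantile bins of `eta`, i.e. latent risk levels. Treatment
assignment is Bernoulli(0.5) independent of markers by default
(randomized-like), with an optional confounding knob that tilts the
assignment log-odds along `eta`.

Subpopulations. `make_two_subpopulations(separation)` shifts the
high-severity component's location by `separation` *scale parameters
per marker* along the severity profile (up for APTT, INR and the
leukocyte lineages, down for PLT), in each family's sampling space (log
space for log-normal markers, preserving positivity). We deliberately
parameterize the shift per marker rather than as a total Mahalanobis
distance: a total distance of 3 would cap the achievable adjusted Rand
index near 0.75 (Bayes error Φ(−1.5) ≈ 6.7 %), whereas per-marker
separation 3 across seven markers yields an essentially recoverable
mixture, which is the regime the recovery checks are designed for.

What passing tests do *not* show: the generator has Gaussian-family
marginals, a correctly specified logistic risk, exponential hazards
and no missing data. Real cohorts violate all four; results here
establish correctness of the algorithms, not clinical performance.

## Scorecard

The frozen card ships as data and is never re-fit (its published
points were hand-adjusted with medical knowledge). Boundary semantics
are exact: APTT, counts and age bins are lower-inclusive /
upper-exclusive; INR bins are lower-exclusive / upper-inclusive.
Minimum/maximum achievable totals are 4.0 / 20.0.

Risk-level cutoffs are not published; the shipped defaults
(mild ≤ 7 < moderate ≤ 11 < severe ≤ 15 < dangerous) are repository
defaults chosen once on synthetic cohorts to produce a steep monotone
mortality gradient, and are overridable in the spec JSON.

Construction pipeline. ChiMerge uses quantile pre-binning (20 bins)
followed by bottom-up merging of the adjacent pair with the smallest
2×2 Pearson chi-square, while that minimum is below the threshold
(default 3.841 = χ² at df 1, α 0.05) and more than `max_bins` intervals
remain; `max_bins` is therefore the merging floor, so an infinite
threshold merges exactly down to `max_bins`. Undersized bins
(< `min_bin_frac`) are always merged into the less-associated
neighbor. Weight of evidence is `ln((e_b/E)/(n_b/N))` with a 0.5
continuity correction on zero cells; information value is the
WOE-weighted sum of distribution gaps (non-negative by construction).
The L1-penalized logistic fit runs on WOE-encoded features; bin points
are `round(sign · coef · WOE · pdo/ln2 + offset/m)` with
half-away-from-zero rounding to one decimal (the frozen card prints
one decimal). With events-over-non-events WOE this formula natively
produces credit-convention scores (higher = safer); the default
`orientation="risk"` flips the sign so higher points mean higher
mortality risk, matching the frozen card. Scaling defaults
(base_points 12, base_odds 1/9, pdo 4) put fitted points on the frozen
card's single-digit scale; the original authors' scaling constants are
unpublished, so all three are exposed.

## Subphenotyping

Full-covariance Gaussian mixture fitted by EM on the z-standardized
eight markers: k-means initialization, 10 random restarts (best
log-likelihood kept), ridge 1e-6 on covariance diagonals (escalated
×1000 on a singularity), convergence at 1e-7 mean log-likelihood gain,
trace stored (non-decreasing by EM theory; asserted to 1e-8).
Standardization is our documented choice — the markers mix seconds,
ratios and counts, so clustering raw values would be dominated by PLT.

The cluster count is a majority vote of silhouette (max),
Calinski–Harabasz (max) and Davies–Bouldin (min) over mixture
labelings; ties break toward smaller k for parsimony.

Canonical labeling uses only marker means: components are ordered by
the severity composite mean-z(APTT) + z(INR) + z(WBC) − z(PLT), and the
highest composite becomes CIS2. This makes deployment labeling
outcome-free (the original subphenotypes were identified post hoc by
mortality, which is unusable at inference time). SIRI is
NEUT × MON / LYM — the standard literature definition; rows with zero
lymphocytes are excluded and counted.

## Rebalancing and domain adaptation

SMOTE interpolates between a uniformly drawn minority parent and one
of its k nearest minority neighbors (Euclidean metric on z-standardized
features to avoid unit dominance; ties broken by index order), with
λ ~ U(0,1); every synthetic row therefore lies on its parent segment.

The MMID metric is a reconstruction from its expanded name (max–min
interval discrepancy): per feature,
`(|min_s − min_t| + |max_s − max_t|) / range_t` with a 1e-9 range
floor, averaged over features. Normalizing by the target range makes
it scale-free but asymmetric; the direction (source → target) is
always stated. MMID-SMOTE clips SMOTE candidates into the target
per-feature interval, moves their mean/sd toward the target's by
`moment_weight`, and re-clips — clip-then-adjust-then-re-clip so the
interval constraint is never violated by the final output. A
consequence worth noting: because synthetic rows are confined to the
target interval, augmenting the source can never increase its MMID to
the target. The moment-matching baseline is the per-feature affine
map aligning source mean/sd to target mean/sd.

## Prognostic model

Feature-tokenized transformer encoder: each scalar predictor becomes a
learned d-vector (per-feature scale vector + bias, d = 16 by default),
a classification token is prepended, and the sequence passes through L
pre-norm encoder layers (multi-head self-attention with H heads,
dropout, residual; then a position-wise feed-forward block of three
linear maps d → 2d → 2d → d with GELU activations, dropout, residual).
The decision head applies layer norm to the classification token and
an MLP with 64 and 128 hidden units into a 2-way softmax. The
published depth/width reading — 8 stacked encoder layers with 8 heads
each, rather than an 8-model ensemble — is adopted and both counts are
configurable; "three dense layers" is folded into the feed-forward
width schedule, as the exact wiring is unspecified.

The network and Adam (β 0.9/0.999, ε 1e-8) are implemented in NumPy;
the backward pass is verified against central finite differences in
the test suite. Published training hyperparameters (learning rate
1e-3, batch 5000 capped at n, dropout 0.1, 1400 epochs) are available
via `published_config()`; the desk-scale default is 200 epochs with
optional early stopping on a validation split, and the bundled checks
use 2-layer/2-head models at n = 2,000, which train in seconds while
exercising every code path of the full architecture. Training is
bit-deterministic given the seed (pure NumPy, no threading
nondeterminism); inference is batch- and order-invariant because every
operation is per-row.

Metrics and statistics. AUC is the Mann–Whitney rank statistic with
half credit for ties (exactly the all-pairs count). The default
operating point is Youden's J over observed scores; the original
operating-point rule is unstated. DeLong's test uses per-positive and
per-negative placement values with the usual covariance combination;
identical scores return z = 0, p = 1 with a degeneracy flag.

Attribution is model-agnostic permutation-sampling Shapley: per
explained row, K feature permutations each with one background draw;
features switch from background to explained values one at a time and
the marginal prediction changes are averaged. The estimator satisfies
local accuracy *exactly* against the mean prediction of its own
background draws, and gives exactly zero to features the model never
reads; Monte-Carlo standard errors per feature are returned.

## Survival statistics

Kaplan–Meier is the product-limit estimator (equal to 1 − ECDF under
no censoring — used as an exact oracle). The two-group log-rank test
uses the aggregate hypergeometric variance at tied event times. The
hazard ratio is the closed-form log-rank O/E (Pike) estimator with
log-HR variance 1/E_a + 1/E_b and a Wald 95 % interval — deterministic
and testable without iterative fitting; a Cox partial-likelihood HR
can be substituted behind the same result type. Strata without
treated patients, control patients or events are flagged and their
statistics omitted.

The treatment-effect recovery check stratifies a single cohort by
latent-risk quartiles (1,000 patients per stratum) with hazard
multipliers 1.0 / 0.6 / 0.6 / 0.33, mirroring the reported
mild-to-dangerous benefit pattern. Stratifying one cohort — rather
than simulating each stratum as an independent heterogeneous cohort —
matters: within-stratum frailty attenuates the marginal O/E hazard
ratio, and risk-level strata are nearly homogeneous by construction.

## Known limitations

- The exact MMID-SMOTE algorithm and the MMID formula are
  reconstructions from the stated ingredients (interval constraints,
  moment alignment); step order is our choice.
- The O/E hazard ratio is unadjusted, matching the two-group contrasts
  reported; no covariate adjustment or propensity matching.
- The extended 36-predictor mode is schematic (correlated positive
  noise in four organ-system blocks) because the full laboratory list
  is not enumerated in the source text.
- Real-data headline numbers (e.g. transformer AUC ≈ 0.93 on
  multi-center ICU cohorts) require access-controlled data and are out
  of scope; nothing in this repository estimates them.
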
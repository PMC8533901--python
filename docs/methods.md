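# Methods

This note documents the models and procedures implemented in `vigicorr`, the
design choices made where the underlying methodology is not fully public, and
what the synthetic cohort generator does and does not emulate.

## Stage classification

Each one-second segment carries alpha and delta+theta band current densities
for four regions of interest (occipital, parietal, temporal, frontal), an EOG
slow-eye-movement (SEM) flag, a graph-element flag (sleep spindle or
K-complex), and an artifact flag. Artifact segments are missing data
throughout: they receive no stage, enter no numerator or denominator, and are
never interpolated. A recording with ≥ 15% artifact segments fails QC
(inclusive bound).

The classifier is a first-match cascade:

1. **C** if a graph element is present.
2. **A-candidate** if the maximal ROI alpha density exceeds the individual
   absolute threshold θ_A *and* exceeds the same ROI's delta+theta density by
   a factor `a_ratio` (default 2). Among A-candidates: **A1** if occipital
   alpha is strictly the greatest, **A3** if frontal alpha ≥ occipital
   (anteriorization; the tie goes to A3 to keep severity monotone), else
   **A2**.
3. **B2/3** if mean delta+theta ≥ `dt_dominance_factor` (default 2) × mean
   alpha.
4. **B1** if the SEM flag is set or any sub-wake stage (A/B/C) occurred within
   the preceding `b1_context_window` seconds (default 60, causal), else **0**.

Two consequences worth knowing. First, classification is scale-invariant:
multiplying all densities and θ_A by a positive constant changes no label.
Second, the 0-vs-B1 decision is made by EOG and context, not by band
densities; raising delta+theta is guaranteed not to raise the assigned arousal
only when drowsiness markers are present. A wake-like segment occurring
shortly after sub-wake stages is read as B1 by design.

**Adaptive threshold.** The reference tool derives θ_A per individual by an
adaptive procedure whose details live in its manual; no published formula
exists. We use a documented approximation: θ_A = `threshold_scale` (0.25) ×
the mean occipital alpha over the top `threshold_quantile` (top decile) of
artifact-free segments. It is order-invariant, homogeneous of degree one in
the densities, and configurable; fidelity to the original procedure is not
claimed.

## Summary metrics

* **Mean vigilance**: arithmetic mean of numeric stages (7..1) over
  artifact-free segments; range [1, 7].
* **Slope index**: OLS slope of per-minute mean vigilance against block
  midpoint time, reported per 10 minutes. A minute contributes only if ≥ 30
  of its seconds are artifact-free (robustness without imputation); at least
  two usable blocks are required.
* **Stability score**: the published 14-level rubric is not in the open
  literature, so the score is a reconstruction preserving its ordinal intent
  — deeper and earlier decline ⇒ lower score. Fourteen first-match rows over
  the stage-class proportions P(C), P(B2/3), P(B1), P(A2∪A3) and the
  first-occurrence minute of each class (rows distinguish ≥ 10% burden vs any
  presence, and first occurrence within vs after minute 10; row 14 = only
  stages 0/A1 throughout). The rubric ships as
  `vigicorr/data/stability_rubric.csv` and can be replaced wholesale. The
  score is monotone: deepening or advancing the decline never raises it. No
  numeric equality with the proprietary implementation is claimed.
* **Moving-average course**: centered 61-s simple moving average over
  artifact-free segments (window truncated at the edges), used for group
  time-course figures.

## Association testing

Spearman correlation is computed as the Pearson correlation of mean-ranked
data; two-sided p-values use the t approximation t = r_S √((n−2)/(1−r_S²)) on
n−2 df, which is standard at cohort sizes in the hundreds (an exact
permutation p is available for small n). Covariate adjustment rank-transforms
the two variables *and* each covariate (sex 0/1, age in years, daytime slot
hour), residualizes the ranked variables on the ranked covariates with
intercept, and correlates the residuals, with n−2−k df. BH-FDR adjustment is
step-up over the full test family of the scope (15 dimension tests or 90
facet tests). Median splits assign the lower ⌈n/2⌉ order statistics
(median-tied values first) to the "low" group.

## Correlation Bayes factor

BF₁₀ integrates the exact sampling density of the sample correlation of a
bivariate normal sample (Hotelling's hypergeometric form, evaluated in log
space) against the stretched beta prior Beta(1/κ, 1/κ) rescaled to (−1, 1),
by adaptive quadrature with relative tolerance 10⁻⁶. With the default
κ = 1/3 the prior places 79.3% of its mass on |ρ| < 0.5. The BF is symmetric
in the sign of r and strictly increasing in |r|.

Reference analyses in this field typically feed *Spearman* coefficients into
a Pearson-model Bayes factor; we adopt the same convention, computing BF₁₀
from the reported coefficient and n under the bivariate-normal model.
Together with the 3-decimal rounding of published coefficients (sensitivity
≈ n·r per unit r in log BF, i.e. ≈ 4% at r = 0.17, n = 468), this motivates
the ±5% reproduction tolerance used in the tests. A Fisher-z approximate
likelihood is available (`method="fisher"`) for cross-checking only.

## Structured permutation null

To judge a family of m cross-domain tests jointly, the subject rows of the
vigilance block are permuted as a unit: within-block correlation matrices are
preserved *exactly* (the same rows travel together), while all cross-domain
correlations are destroyed. Permuting the trait block instead would be
equivalent by symmetry. Each of B permutations yields m Spearman p-values
(same tie policy and t approximation as the observed analysis, so observed
and null are comparable); per-rank means and 5th/95th percentiles on the
−log₁₀ scale form the qq envelope, and exceedance summaries report the
fraction of null sets with ≥ k p-values below α and the fraction whose
minimum falls below a reference p₀. The default B = 10⁴ is a desk scale —
B is configurable upward; envelope percentiles stabilize long before 10⁶.
Null p-values are computed without covariate adjustment by default.

## Power analysis

Power mirrors the classic Fisher-z algorithm with small-sample bias
correction: critical correlation r_c from the two-sided t criterion on n−2
df, z = arctanh r + r/(2(n−1)), power = Φ((z−z_c)√(n−3)) + Φ((−z−z_c)√(n−3)).
The bias term and the t-based critical value are included deliberately; plain
Fisher-z differs only in the fourth decimal at n = 468, but the mirrored form
removes ambiguity against the standard implementation. `detectable_r` inverts
the power function by bisection on (0, 0.999) to 10⁻⁶. At r → 0 the computed
power equals the level only up to the Fisher-z approximation of the critical
value (≈ 5 × 10⁻⁵ at n = 468).

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated; its defaults emulate a cohort of 468 adults aged 40–79 assessed in
three daytime slots (8:30, 11:00, 13:30) with 20-minute recordings.

**Traits.** Latent multivariate normal dimensions (default correlation:
identity except extraversion–openness 0.477) mapped affinely to T-scores
(mean 50, SD 10, no integer rounding — preserves rank statistics; rounding
would only coarsen ties). Six facets per dimension load on their parent with
loading 0.7 plus independent noise.

**Effect calibration on the Spearman scale.** All configured correlations
(trait matrix, effect vector, covariate effects) are interpreted as *Spearman*
correlations — the scale on which such analyses report effects — and mapped
to the latent Pearson scale by Greiner's relation ρ_P = 2 sin(πρ_S/6) before
being imposed on the latent normals. The mapping is elementwise,
PSD-preserving, and makes sample Spearman correlations recover the configured
values; specifying effects directly on the Pearson scale would lose ≈ 4% of
the effect (population Spearman of a latent-Pearson-0.17 pair is 0.1625),
which matters when validating recovery to ±0.02. For the uniform age variable
and the three-point daytime variable the relation is an approximation; the
daytime effect is additionally attenuated slightly by ties.

**Arousal propensity.** A standard-normal latent g with corr(trait_k, g) =
effect_k (defaults: the slope-index column of the reference association
table: −0.002, −0.137, −0.173, −0.032, −0.039), corr(age, g) = +0.168
(younger subjects decline more), corr(daytime, g) = −0.155 (later assessment,
lower vigilance), remainder independent noise; weights come from solving the
latent correlation system, and a configuration error is raised if the implied
multiple correlation reaches 1.

**Stage courses.** Decline propensity d = −g sets a per-minute decline rate
`drift_mean + drift_sd·d` (defaults 0.152 and 0.092 stages·min⁻¹, chosen so
the realized slope-index distribution matches reference descriptives: mean
≈ −1.5, SD ≈ 0.9 per 10 min, range ≈ −3..0.5). The target level starts at
6.7 (subjects begin in active/relaxed wakefulness after an activating task)
and declines linearly, clipped to [1, start]; the cap at the onset level
reflects that arousal does not rise above where the pre-task left it without
stimulation. The per-second chain is single-step with stickiness 0.70
(P(no move) per second) and steps down when above target, up with probability
`recovery` = 0.5 when below. This is the simplest mechanism producing
monotone-in-expectation decline with realistic-looking fluctuation;
stickiness/recovery defaults were chosen by direct measurement so that chain
realization noise keeps corr(d, realized slope) ≈ 0.996 — the generator's
effect sizes survive the full pipeline essentially unattenuated (200-cohort
recovery of a configured −0.17: mean −0.164, SD 0.043 ≈ 1/√465). The chain is
a calibration device, not a claim about arousal dynamics: real stage courses
show abrupt state switches, spindle-driven C episodes, and non-monotone
recoveries that this chain does not model.

**Features.** Optional per-segment ROI densities are drawn from per-stage
templates constructed to satisfy the classifier rules exactly at zero noise
(occipital-dominant alpha for A1, parietal for A2, frontal for A3, diffuse
delta-theta for B2/3, SEM flag for B1, graph flag for C), with multiplicative
Gaussian noise of configurable SD (default 20% of the template value,
truncated at zero). At 20% noise the classifier recovers ≥ 95% of labels;
errors concentrate where templates are adjacent (A1/A2 topography). Artifacts
are iid per second with a per-subject Beta-distributed rate (mean 2%), so a
small fraction of subjects fail the 15% QC rule.

**What passing tests do not show.** The generator produces normal margins,
linear latent links, exchangeable seconds within a minute, and noise-free
trait measurement. Real cohorts have skewed summary distributions, age- and
time-structured artifact patterns, measurement unreliability, and stage
dynamics far richer than a drifting two-state neighborhood. Pipeline
validation on this generator demonstrates statistical correctness of the
implementations, not empirical claims about any cohort.

## Problem sizes and numerical choices

Monte-Carlo checks use 10⁶ draws for the sampling-density KS comparison
(n = 20, ρ = 0.3), 2 × 10⁵ replicates for the power rejection-rate comparison
(±0.005), 200 replicate cohorts at n = 468 for parameter recovery, and
B = 10³–10⁴ permutation sets for null calibration; these sizes give the
stated tolerances comfortable margins while keeping the default test run
short. BF quadrature raises rather than returns on non-convergence; the
sampling density raises on hypergeometric overflow. Degenerate inputs
(constant vectors, all-artifact recordings, rank-deficient covariates,
non-PSD trait matrices, over-determined effect vectors) raise typed errors
naming the offending object. All randomness flows through explicit
`numpy.random.Generator` instances; cohort products embed the seed and a
configuration hash in their manifest, and identical seeds reproduce tables
byte-identically.
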
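# Methods

`boneage-calib` implements a population-specific validation and calibration
workflow for automated bone age (BA) assessment: a multi-rater consensus
reference, a sex-specific linear recalibration of a black-box AI predictor,
a battery of agreement statistics with their exact confidence-interval
constructions, and a re-partitioning stability analysis. All ages and bone
ages are real-valued months; the cohort model covers the pediatric range
0–216 months (0–18 years), during which hand/wrist ossification progresses
until the growth plates fuse.

## Consensus reference rating

The reference BA for each image is built from a panel of k raters (k ≥ 2;
k = 7 in the study-scale default) in one pass:

1. *Initial consensus* m_i: the unweighted mean of the available ratings of
   image i.
2. *Exclusions*: images with any missing rating are dropped, as are images
   in which any single rating deviates **strictly** more than 30 months
   from m_i (both thresholds configurable; reasons are recorded per image).
3. *Rater profiles*, anchored to the initial mean:
   - signed mean difference (bias): `smd_j = mean_i(r_ij − m_i)`,
   - precision: `mad_j = mean_i |r_ij − smd_j − m_i|`,
   - weight: `w_j = (1/mad_j) / Σ_l (1/mad_l)`.
4. *Weighted consensus*: `c_i = Σ_j w_j (r_ij − smd_j)`.

Both rater statistics are computed against the initial, uncorrected mean in
a single pass. An iterative variant that re-anchors the profiles to the
weighted consensus until convergence is available (`iterate=True`) but off
by default; on realistic panels it perturbs the consensus by well under a
month.

Two properties of this construction are worth stating explicitly:

- A constant offset added to one rater changes no weight and no MAD, but
  shifts the consensus by exactly offset/k. This is unavoidable: the
  consensus is equivariant under a common shift of all raters, and k
  single-rater shifts compose to a common shift. The panel's mean bias is
  therefore *retained* in the reference — the panel defines the scale.
- With equal MADs the consensus reduces to the unweighted mean of the
  bias-corrected ratings, and it is invariant to rater order.

A rater in perfect agreement with the initial mean (MAD = 0) would receive
infinite weight; the MAD is floored at a configurable epsilon (default
1e-6 months) and a warning is emitted.

Leave-one-rater-out consensus re-runs the entire pipeline (initial mean,
exclusions, profiles, weights) on the reduced panel, so the held-out rater
and the AI can be benchmarked against an independent reference. The
Table-2-style benchmark in the study report evaluates the held-out rater,
the raw AI, and the calibrated AI on the *test split* (intersected with
each reduced panel's included images), so the AI columns reflect held-out
performance.

## Calibration

The calibrated bone age is `BA_cal = slope_sex · BA_raw + intercept_sex`,
with parameters from ordinary least squares of the *reference* (response)
on the *raw AI prediction* (predictor), fitted separately per sex — the
direction is forced by the form of the calibration equation. 95% CIs come
from the t distribution on the coefficient standard errors; `residual_sd`
is √(SSR/(n−2)). The fit is the closed-form normal-equations solution
(validated against statsmodels OLS in the test suite), which keeps the
1000-replicate bootstrap fast. Requirements: ≥ 3 images per sex stratum and
non-zero predictor variance. Calibrated outputs are *not* clamped to
[0, 216]; clamping would distort signed-difference analyses near the range
edges, so negative outputs only raise a warning.

Because the synthetic generator distorts in the forward direction
(`ai_raw = a·BA_true + c + ε`), the ideal recalibration is analytically
known: slope 1/a, intercept −c/a. One caveat matters when checking
parameter recovery: OLS on a noise-carrying predictor is attenuated
(regression dilution) by the factor `V/(V + σ²_ai/a²)` where V is the
variance of true bone age. With V ≈ 3 600 month² and σ_ai = 4 months the
expected slope is ≈ 0.5% below 1/a — negligible for any practical
calibration (well inside the ±0.03 design tolerance), but systematic, so
averaging over many replicates does not remove it, and nominal CI coverage
of the *noise-free inverse* parameters falls below 95%. Deming-style
errors-in-variables fitting would remove the attenuation but is
deliberately out of scope: the method under study is plain linear
recalibration.

## Agreement statistics

For a predictor vs. reference comparison on n images (differences
d = pred − ref):

- **MAD** `mean|d|` and **RMSE** `√(mean d²)`, months.
- **RMSE CI**: χ²-based, assuming normal residuals, with quantiles at *n*
  degrees of freedom:
  `(√(n·RMSE²/χ²_{0.975,n}), √(n·RMSE²/χ²_{0.025,n}))`. The interval is a
  function of (RMSE, n) alone, so it can be reproduced exactly from a
  reported summary pair (`rmse_ci_from_point`).
- **SMD** `mean(d)` with the t interval `d̄ ± t_{0.975,n−1}·σ_d/√n`, σ_d the
  n−1 sample SD.
- **1-year accuracy**: percent of |d| ≤ 12 months, *inclusive* boundary.
- **ICC(2,k)**: two-way random effects, absolute agreement, average of k
  measurements (McGraw & Wong's ICC(A,k)), from the two-way ANOVA mean
  squares, with the F-based CI using the Satterthwaite-approximated
  denominator df of the absolute-agreement case. By default the matrix is
  the (predictor, reference) pair (k = 2); a "panel" mode stacks the
  predictor next to the individual raters instead, and every report labels
  which mode was used.
- **Bland–Altman**: μ = mean(d), limits μ ± 1.96·σ_d, and the percentage of
  differences inside the closed limits (→ ≈ 95% for normal differences).
- **Normality of d**: Kolmogorov–Smirnov with parameters estimated from the
  sample, i.e. the Lilliefors test (statsmodels). The Lilliefors null is
  used because the plain KS p-value is badly miscalibrated (conservative)
  when mean and SD are estimated; a zero-variance sample returns p = 0 with
  a warning.
- **BA − CA summaries**: per-sex n, mean, SD and quartiles of bone age
  minus chronological age, computable for any BA source (consensus, raw
  AI, calibrated AI).

## Partitioning and the re-partitioning "bootstrap"

The calibration/test split stratifies on age-bin × sex cells (24-month bins
by default — fine enough to balance the age distribution, coarse enough to
keep cells occupied at n ≈ 381) with largest-remainder rounding of the
per-stratum train counts, and assigns every disorder-flagged image to the
test set before sampling. Splits are deterministic under a fixed seed.

The stability analysis repeatedly re-partitions the *same* cohort (no
resampling with replacement), refits the calibration on each ⅓ calibration
set and re-evaluates MAD, RMSE and 1-year accuracy of the calibrated AI on
each ⅔ test set. Replicate seeds derive from the master seed through
counter-keyed `SeedSequence`s, so any replicate is reproducible in
isolation. Summaries are 2.5/50/97.5 percentiles (NumPy linear-interpolation
convention). Correction curves `(slope − 1)·raw + intercept` are evaluated
per replicate on a raw-BA grid (0–216 by 12 months) and summarized
pointwise; `correction_within_band` reports, per sex, whether a given
model's correction lies inside the 95% band at every grid point and the
fraction of grid points covered.

One statistical caveat: a primary split drawn the same way as the
replicates is *exchangeable* with them, so each grid point covers it with
probability ≈ 0.95. A straight line lying inside a pointwise band is
roughly two independent 95% events per sex (the binding grid points are
the ends, whose deviations are anticorrelated through the slope–intercept
covariance), and the two sexes are fitted independently — so "fully inside
for both sexes" holds in only ≈ 0.95⁴ ≈ 80% of runs, not ≈ 95%. A single
observed study will typically find its calibration inside the band, but
that outcome should not be expected in nearly all replications.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
with a known ground truth per image:

- chronological age CA ~ Uniform(12, 216) months by default (a truncated
  normal sampler is available); true bone age `BA_true = CA + N(0, 12)`
  months, floored at 0 — a biological dispersion of skeletal age around
  calendar age;
- rater j reports `BA_true + bias_j + N(0, sd_j)`, floored at 0;
- the AI reports `a_sex·BA_true + c_sex + N(0, σ_ai)`, floored at 0;
- disorder flags are independent Bernoulli draws.

The study-scale default (`default_gbad_like_config`) fixes n = 381 images
(184 female), 7 raters with biases spanning [−3.07, +1.55] months, a
disorder prevalence of 19/381, and per-sex forward slopes 1/1.032 and
1/1.040 (the inverses of the recalibration slopes the method should
recover). The offsets c_sex are derived analytically so that the expected
raw-AI-vs-consensus SMD equals +2.85 months (female) and +5.35 months
(male): since the consensus retains the panel's mean bias b̄,
`E[ai_raw − consensus] = (a−1)·E[BA_true] + c − b̄`, solved for c at
E[BA_true] = 114 months.

Noise levels are design choices, not estimates of any real cohort's
dispersion: rater SDs rise from 3.2 to 5.0 months across the panel (giving
1/MAD weights spread over ≈ [0.12, 0.18], like a genuinely unequal expert
panel) and σ_ai = 2.0 months. The AI term is kept small deliberately — the
emulated predictor is an ensemble with high test-retest precision, so its
error against truth is dominated by the *systematic* linear distortion that
calibration targets — and small enough that, at study scale (~60 training
and ~130 test images per sex), the sampling SD of a per-sex test SMD is
≈ 0.4 months and systematic effects dominate split-to-split noise. What
passing tests on these cohorts show is that the *method* recovers and
removes a systematic linear miscalibration under realistic panel structure;
they do not certify absolute error levels on real radiographs, where rater
disagreement and AI errors are larger and age-dependent, rating is
atlas-discretized, and the age distribution is not uniform.

## Numerical and degenerate-input conventions

- Sample SDs use the n−1 denominator throughout; percentiles use NumPy's
  linear interpolation.
- Exclusion threshold comparison is strict (> 30 months); the 1-year
  accuracy boundary is inclusive (≤ 12 months).
- Zero-MAD raters: epsilon-floored weight plus warning. Zero-variance
  difference samples: Bland–Altman limits collapse (100% within); the
  normality test returns p = 0 with a warning.
- A singular calibration fit (zero predictor variance or < 3 images per
  sex) raises; inside the bootstrap a singular replicate is recorded as
  failed, and more than 1% failures aborts the summary.
- Missing ratings are first-class (NaN) in the cohort model; exclusion
  policy belongs to the consensus stage, never to the CSV reader. The
  reader parses floats through the exact strtod path so that
  write → read → write is byte-identical.

## Known limitations

- The consensus inherits the rater panel's mean bias; all "accuracy" is
  relative to this local panel, not to an external gold standard.
- Plain OLS calibration carries the (small) regression-dilution attenuation
  discussed above.
- Rater noise is homoscedastic per rater by default; an optional
  age-proportional mode exists but no data constrain it.
- Ratings are continuous months; atlas-stage discreteness is not modeled.
- The data model records no hand laterality and no image-level covariates.
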
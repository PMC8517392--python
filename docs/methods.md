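# Methods

This note documents the models, parameter choices, numerical details and
known limitations of `pslwork`. It records design rationale only; every
empirical number cited here is computed by the test suite or by
`scripts/acceptance.py`.

## Non-invasive LV pressure curve

The instantaneous left-ventricular pressure over one cycle is estimated by
scaling a fixed normalized reference shape. The shape lives on
phase-normalized time `u ∈ [0, 1]` with canonical phase boundaries at
`u = 0.15` (end of isovolumic contraction) and `u = 0.75` (end of
ejection), and is a piecewise raised cosine:

- isovolumic contraction: half-cosine rise from 0 at mitral valve closure
  to 0.90 at aortic valve opening;
- ejection: raised-cosine arch from 0.90 up to 1.00 (peak at 30% of the
  ejection phase) down to 0.55 at aortic valve closure;
- isovolumic relaxation: half-cosine fall from 0.55 to 0.10 at mitral
  valve opening.

The exact reference profile used by clinical workstations is proprietary
and not published; this template reproduces the qualitative LV pressure
morphology (steep isovolumic rise, early-ejection peak, isovolumic fall)
while making every anchor value testable, and it is a named constant
(`RAISED_COSINE_TEMPLATE`) so an alternative shape can be swapped in
without touching the scaling machinery.

Scaling maps each phase segment affinely onto the subject's own valve
events and multiplies by cuff systolic pressure, implementing the
assumption that peak LV pressure equals peak brachial arterial pressure.
Consequences that the tests rely on: the curve peak equals cuff SBP, the
values at AVO/AVC/MVO are 90%/55%/10% of SBP, and stretching all phase
durations by a common factor leaves the pressure-versus-phase-fraction
profile unchanged. The curve is anchored to 0 mmHg at MVC; diastolic cuff
pressure is carried in the covariate table but deliberately does not
offset the curve — only the peak is pinned by measurement, and an
explicit zero baseline is preferable to a hidden offset.

Numerics: the sampling grid is uniform with step `dt` (default cycle
length / 2000, far below echocardiographic frame intervals of ~15 ms)
*plus* the valve-event and peak times, so the peak and phase anchors are
represented exactly at any resolution. Curves built from the template
carry it and are evaluated through the closed form (grid refinement then
changes nothing); curves built from raw samples fall back to
piecewise-linear interpolation.

## Segmental and global myocardial work

Strain is longitudinal, in percent, negative for shortening, referenced
to zero at mitral valve closure. Instantaneous power is
`w(t) = −(dε/dt)·P(t)` so physiologic systolic shortening counts
positive, in mmHg·%/s.

The work window is MVC → MVO. Constructive and wasted work partition the
power by phase: during systole (MVC → AVC) shortening is constructive
and lengthening wasted; during isovolumic relaxation (AVC → MVO) the
roles invert (relengthening is constructive, post-systolic shortening is
wasted). The segmental work index is defined as
`constructive − wasted`, making the decomposition identity exact by
construction and bounding efficiency `GWE = 100·GCW/(GCW+GWW)` in
[0, 100] with `GWE = 100` exactly when nothing is wasted.

A consequence worth stating plainly: a clinical work index computed as a
net pressure–strain loop area can sit well below `GCW − GWW` (published
cohorts show GCW − GWI ≈ 250 mmHg·% against GWW ≈ 35 mmHg·%, because the
loop nets out IVR contributions differently). Under the exact identity
chosen here, the synthetic cohort's GWI is necessarily ≈ GCW − GWW
(≈ 2040 mmHg·% in controls rather than ≈ 1900). Group *contrasts* and
effect structure are unaffected; absolute GWI levels are systematically
above the loop-area convention.

Numerics: strain traces and the pressure curve are resampled onto a
common uniform grid (default 2000 points per cycle) by linear
interpolation; the valve events are inserted into the grid and the
derivative is computed independently within each phase (second-order
central differences inside, one-sided at phase boundaries), because the
valve events are genuine breakpoints of the deformation — smearing the
derivative across them turns a clean phase transition into spurious
wasted work. Integrals are trapezoidal per phase. With constant pressure
and linear strain the result is exact; on smooth traces the default grid
agrees with 16×-refined quadrature to well under 0.5% (tested). Global
indices are unweighted segment means over the 17-segment model (the
mass-weighted alternative is not published for this method; weights for
GLS are an exposed parameter, equal by default with the apex counted
once). Peak systolic strain per segment is the minimum of ε over
systole.

## Synthetic cohort generator

The generator emulates a 50-vs-50 normal-control / type-2-diabetes
echocardiographic study so the full pipeline is testable without patient
data.

**Covariates.** Rows summarized as mean ± SD are sampled from normals
truncated to physiologic bounds by resampling (e.g. HbA1c 4–15%, SBP
90–140 mmHg — the emulated study excluded arterial hypertension); rows
summarized as median (IQR) use a log-normal matched exactly to both
numbers (`μ = ln median`, `IQR = 2·median·sinh(z₇₅σ)`); sex and smoking
are Bernoulli with the published proportions. Diabetes-only fields
(fasting glucose, post-prandial glucose, duration) are absent from
control records. Covariates are sampled independently of one another;
real cohorts correlate BMI/BSA/lipids, so covariance-sensitive analyses
should not lean on this generator.

**Strain phenotype.** Each subject receives 17 raised-cosine contraction
profiles: flat through isovolumic contraction, half-cosine shortening to
the segmental peak at AVC, partial relengthening (15 ± 3% of peak)
during IVR, sampled at 150 Hz. Segments carry multiplicative
heterogeneity (CV 10%). A random subset of segments (probability 0.50
controls / 0.65 diabetics) shows a post-systolic-shortening bump
(depth 2.15% / 2.2% strain), the substrate of wasted work. Group peak
strain targets are 19.5% (controls) and 17.0% (diabetics); with the
template pressures this calibration lands GWW/GWE medians near 33/46
mmHg·% and 98.4/97.6%, and constructive work near 2080/1870 mmHg·%.

**Severity structure.** A unit-variance latent severity score combines
z-scored HbA1c and z-scored log(1 + duration) with residual noise and
scales the subject's peak strain by `1 − 0.12·u`. The configured effects
(standardized −0.45 for HbA1c, −0.30 for duration, acting on the
constructive-work channel) are specified on the *outcome* scale: because
work also varies with cuff pressure, segment heterogeneity and minor
shape channels, a loading equal to the target would be attenuated by
roughly 12%; the generator divides the loadings by its analytically
estimated attenuation (`strain_rel_sd / total relative SD`, with the
extra variance taken from the SBP coefficient of variation, the segment
CV over 17 segments, and a small constant for the remaining channels) so
that large-sample regression recovers the configured values. The
z-scoring of log(1 + duration) uses the log-normal's population moments
computed by Gauss–Hermite quadrature. Control subjects have no severity
loadings; their score is pure noise, giving the control GLS its spread.

Because GWI = GCW − GWW shares the strain channel with GCW, both
outcomes carry both covariate effects — the generator cannot give HbA1c
and duration disjoint work channels while the exact decomposition
identity holds.

**Reproducibility.** One master seed; every subject draws covariates and
traces from its own substreams keyed by a stable hash (CRC-32) of its
subject id, so output does not depend on generation order, and covariates
are drawn in sorted name order so equivalent specifications built in any
dict order sample identically. Identical seeds give byte-identical
cohort tables.

**What passing tests do not show.** The generator's traces are smooth
closed forms without speckle noise, drift, drop-out or inter-vendor
tracking differences; covariates are uncorrelated; valve timings are
independent of heart rate. Passing direction and recovery tests
demonstrate the pipeline's correctness on data with the assumed
structure, not robustness to real measurement artifacts.

## Statistics layer

- Student's t: pooled-variance (not Welch), `df = n₁+n₂−2`, group 1 is
  the control group so signs match a control-first table. The pooled
  form is the variant that reproduces the internally consistent
  published rows from their printed summaries.
- Mann-Whitney: midrank U; Z by normal approximation with tie-corrected
  variance and 0.5 continuity correction toward the null (matching
  common statistics-package defaults); exhaustive pair-count enumeration
  is the test oracle up to 8×8.
- Chi-square: closed-form Pearson statistic on 2×2 counts without
  continuity correction — the uncorrected form is the one consistent
  with the published categorical rows.
- Regression: OLS with intercept via statsmodels; standardized β =
  raw coefficient × sd(x)/sd(y), so a univariable standardized β equals
  the Pearson correlation (tested to 1e-9). Rank-deficient designs raise
  a collinearity error.
- Stepwise: bidirectional, forward entry at p < 0.05 and backward
  removal at p > 0.10 (conventional defaults; both exposed), ties broken
  by input column order for determinism. The pipeline pre-filters
  candidates to univariable p < 0.05. Diabetes duration enters as
  log(1 + duration) because the median/IQR-matched log-normal is far too
  heavy-tailed for raw-scale linear correlation.
- Bland-Altman: bias = mean(m₂ − m₁), limits of agreement
  bias ± 1.96·sd (ddof = 1). Replicate measurements for the agreement
  table are simulated as additive Gaussian re-measurement noise on the
  computed work parameters of 20 randomly chosen subjects, with separate
  intra-/inter-observer difference SDs chosen to match published
  repeatability magnitudes.
- All p-values two-sided; the comparison table routes each variable to
  t / Z / χ² by a declared configuration (defaulting to the
  mean±SD-vs-median(IQR) layout of the emulated study) rather than by
  normality testing.

## Pipeline

`run_full_study` is deterministic given the seed: every output CSV
carries the seed and a configuration hash (over the parameters that
affect values, excluding file locations) in `#` metadata lines, the run
log records versions and per-subject exclusions, and input row count
always equals output rows plus logged exclusions. Problem sizes used by
the shipped analyses: integration grid of 1000 points per cycle for
cohort generation (work integrals change by < 0.1% on refinement),
100-replicate direction studies at the 50-vs-50 scale, and n = 1000
diabetic arms for effect-recovery checks.

## Known limitations

- The reference pressure template is a documented stand-in, not the
  proprietary clinical profile; absolute work values depend on its shape
  (they scale linearly with pressure, so contrasts are stable).
- The work window ends at MVO; diastolic strain after mitral opening
  contributes to no index.
- GWI follows the exact decomposition convention discussed above, not
  the net loop-area convention; absolute GWI levels differ between the
  two.
- 17-segment model only; 16- and 18-segment variants are out of scope.
- The generator does not simulate images, longitudinal follow-up or
  treatment effects; medication columns are labels only.
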
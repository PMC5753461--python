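# Methods

This note documents the models implemented in `hccscreen`, the assumptions
behind them, the synthetic cohort used to validate them, and the numerical
and design choices that were genuinely open.

## Data model and preprocessing

A cohort is a patients table (case indicator δ, endpoint `d` in months
from the HCV index date — diagnosis for cases, end of follow-up for
controls) and a visits table of AFP tests, optionally with an ALT/PLT lab
stream. Preprocessing:

- **Concurrent labs.** Each AFP test at time `t` receives the most recent
  ALT and PLT drawn in the closed window `[t − 6, t]` months. A lab drawn
  the same day counts (offset 0). Visits lacking either lab are ineligible
  for the full risk model but remain usable by the AFP-only and PEB
  algorithms.
- **Same-day collapsing.** Repeat measurements on one day are collapsed to
  the anti-log2 of the mean of their log2 values (a geometric mean); the
  operation is idempotent.
- **AFP rate of change.** `ΔAFP_rate = [log2 AFP_j − log2 AFP_{j−1}] /
  [(t_j − t_{j−1})/12]`, defined only when the previous test is at most 12
  months old; the first visit has no rate.
- **Six-month outcome.** `D_ij = 1` iff the patient is a case and
  `d < t_ij + 6` (strict inequality).
- **Truncation.** Risk-model covariates (AFP, ALT, PLT) are floored at 1
  before log2. The PEB standardisation deliberately does **not** floor
  AFP: censoring the lower tail of log2(AFP) at 0 shrinks both variance
  components by ~7% at the reference parameters, which would corrupt the
  shrinkage weights. Cohort inclusion already guarantees AFP > 0.

## PEB screening rule

Hierarchy `Y_ij | θ_i ~ N(θ_i, σ²)`, `θ_i ~ N(θ̄, τ²)` for controls, with
`Y = log2(AFP)`. The marginal of `Z_ij = (Y_ij − θ̄)/√(σ²+τ²)` is standard
normal. At screen `j` the patient-specific mean is estimated by shrinking
the running mean of the `j−1` prior standardised values toward 0:
`μ̂_ij = B_j Z̄_ij`, `B_j = τ²/(σ²/(j−1) + τ²)` (so `B_1 = 0`), and the
screen is positive when `Z_ij > μ̂_ij + z_{1−f0}√(1 − B₁B_j)`. The
continuous score `Φ((Z_ij − μ̂_ij)/√(1 − B₁B_j))` is uniform per screen
under the null model, which makes the rule equivalent to `score > 1 − f0`
and gives all algorithms a common (0, 1) score scale for percentile
curves and calibration.

Parameters `(θ̄, σ², τ²)` are estimated once on training-cohort controls
(screens with AFP < 400 ng/ml) by a random-intercept linear mixed model
(statsmodels `MixedLM`, REML) and frozen for validation. At least two
patients with two or more visits are required; a zero boundary estimate of
τ² is flagged and yields `B₁ = 0` (the rule degenerates to the fixed
threshold, as it should). Screens triggering the AFP ≥ 400 OR rule remain
in the shrinkage history by default (the history is defined over all prior
screens); a switch drops them.

Key parameter: `f0`, the per-screen false-positive level (default 0.10).
`B₁ = τ²/(σ²+τ²)` equals the intra-class correlation of log2(AFP) —
0.73 at the reference control variances (1.90 between, 0.71 within) —
and governs how much a patient's history can move their threshold.

## Six-month risk model

A logistic model of `D_ij` on continuous piecewise-linear bases (hinge
terms `(x − k)·I(x > k)`, strict indicators): log2 AFP (knots 2, 7, 9),
log2 ALT (knots log2 20/50/100/200), PLT (knot 35), age (knot 50), and the
AFP rate of change (knots −8, 0, 2, 9) zeroed when unobserved, plus an
indicator that it is unobserved. Covariate sets: `afp_only` (the 4-term
AFP basis) and `full`.

Design choices:

- **Interactions.** The AFP×ALT and AFP×PLT blocks are the full outer
  products of the basis vectors (20 + 8 columns); a `linear` mode keeps
  only the product of the leading (untransformed log2) terms. The outer
  product is the standard spline-interaction expansion; the switch keeps
  both readings testable.
- **Intercept.** Always included; a no-intercept logistic on these bases
  would force the baseline risk through zero covariates and is degenerate.
- **Resampling fit.** Within-patient correlation is handled by drawing one
  visit per training patient uniformly at random and fitting an ordinary
  maximum-likelihood logistic regression, repeated K = 100 times;
  predictions average the K per-fit probabilities. Iteration k draws from
  an independent child stream of the fit seed, so increasing K never
  reshuffles earlier iterations. Training is restricted to screens with
  AFP < 400 ng/ml (the OR rule owns the rest) and, for the full set, to
  lab-eligible visits.
- **Separation fallback.** Rare-event draws can separate or fail to
  converge; such iterations are refit with a small ridge penalty
  (scikit-learn logistic, α = 0.01) and counted in the diagnostics. A draw
  with no events at all gets an intercept-only fit at the smoothed
  empirical log-odds. Fallback rates are visible in `summary()`.

## OR rule, calibration, percentiles

A screen is positive when AFP ≥ 400 ng/ml (inclusive) or the algorithm
score strictly exceeds its threshold. Calibration returns the smallest
threshold whose achieved screening-level FPR (over controls' screens plus
case screens earlier than `τ1` before diagnosis) does not exceed the
target; ties can leave the achieved rate strictly below the target, which
is reported. If AFP ≥ 400 screens alone exceed the target the calibration
fails with the floor rate. Thresholds are calibrated on the training split
by default — the honest prospective protocol — with a validation-split
mode for exactly matched validation FPR. Risk percentiles use mid-ranks
(fraction strictly below plus half the ties), which keeps the control-only
FPR-versus-percentile relationship linear with slope −1 in expectation.

## Longitudinal evaluation

For a window `(τ1, τ2)` and a case diagnosed at `d`: screens in
`[d − τ1, d − τ2]` (closed both ends) are true-positive-eligible, screens
strictly earlier are false-positive-eligible, screens after `d − τ2` are
excluded; control screens are always false-positive-eligible. The eight
standard windows are A1 (6, 0), B1 (12, 0), C1 (24, 0), D1 (max
follow-up, 0) and A2–D2 with `τ2 = 3` months.

All four measures are natural plug-in (empirical proportion) estimators of
their defining conditional probabilities, verified against brute-force
counting on enumerable cohorts. Patient-level TPR divides by cases with at
least one in-window screen (cases never screened inside the window are not
evaluable). PPV and NPV condition on the screen result only, so
excluded-region screens of cases stay in their denominators by default;
`include_excluded=False` drops them — the definitions are silent on this
point, so both modes exist and the default follows the literal
conditional. First-positive timing compares algorithms on cases flagged by
at least one of them, assigning the diagnosis time to an algorithm that
never flags inside the window. The false-positive burden is the fraction
of patients with more than two false-positive screens.

Performance curves evaluate all measures at every unique score threshold
(thinned to a grid for large cohorts) against the risk percentile;
per-decile risk of diagnosis within `τ1` months is smoothed with a natural
cubic spline through decile midpoints, omitting empty deciles.

## Synthetic cohort generator

The generator exists so every stage is testable without registry access.
Defaults emulate the reported HCV-cirrhosis control population:

| parameter | default | meaning |
| --- | --- | --- |
| θ̄, τ², σ² | 2.92, 1.90, 0.71 | control log2(AFP) hierarchy (ICC 0.73) |
| visit-count categories {1, 2, 3–4, >4} | 0.285/0.231/0.264/0.220 | tests per patient |
| gap mean, SD | 11.67, 11.00 months | gamma inter-visit gaps |
| log2 ALT mean; between/within SD | 6.14; 0.80/0.65 | lognormal-type ALT |
| PLT mean; between/within SD | 147.97; 75/25 | truncated-normal PLT (≥ 10) |
| age mean, SD | 52.87, 7.28 years | baseline age, clipped to [25, 90] |
| lab missingness | 0.05 per analyte per visit | drives lab-eligibility |
| case slope | 0.15 (SD 0.05) log2/month | post-onset drift |
| onset lead | U(0, 24) months before diagnosis | latent onset |
| AFP assay floor | 0.25 ng/ml | reporting floor (censoring mass ~10⁻³) |

Cases follow the control model until the latent onset `d − lead`, then the
log2 mean drifts upward linearly; a slope of 0.15/month (AFP doubling time
≈ 7 months) yields ≈ 1.8 log2 units of elevation over the mean 12-month
lead, consistent with the observed case-versus-control baseline AFP gap.
Control follow-up ends shortly (0.5–12 months) after the last test so the
observed gap distribution is not length-biased by end-of-study truncation;
case schedules are truncated at diagnosis, which reproduces the slightly
shorter gaps seen in cases. A truth sidecar records each patient's latent
mean, onset time and slope for oracle tests.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: assay/platform drift and batch effects,
non-normal AFP tails, dependence of ALT/PLT on disease progression (labs
are generated independently of AFP by default, so in synthetic cohorts
the lab covariates carry no case signal and the full risk model mostly
adds noise over AFP alone), informative visit scheduling near symptoms,
death and competing risks, and any dependence between visit frequency and
risk. Directional conclusions (e.g. the PEB advantage at high ICC) are
properties of the model class exercised at realistic parameters, not
estimates of field performance.

## Experiments and reproducibility

Split-sample validation divides cases and controls separately into random
halves (odd patient to training). Out-of-bag bootstrap validation draws n
patients with replacement (duplicates relabelled) for training and
evaluates on the ~1/e of patients left out, averaging over B = 300
replicates by default; replicates whose out-of-bag set lacks a case or a
control are skipped and counted. All randomness derives from one root seed
via named SHA-256 substreams (split / fit / bootstrap / synthetic), and a
run manifest (config, seeds, split hash, thresholds, outputs) suffices to
reproduce a run bit-for-bit.

## Numerical choices

- Normal quantiles/CDFs from scipy to double precision; no tables.
- `√(1 − B₁B_j)` cannot vanish (B₁ < 1, B_j ≤ 1); asserted.
- Positivity is strict (`score > c`) everywhere, matching the rule
  displays; the AFP ≥ 400 comparison is inclusive.
- Predicted risks are clipped away from {0, 1} by 10⁻¹⁵ for downstream
  logs; logistic evaluation uses `expit` to avoid overflow.
- Zero-variance boundary estimates (σ̂² or τ̂² ≈ 0) emit warnings rather
  than errors; single-visit-only cohorts raise an identifiability error.
- Validation problem sizes in the test suite (cohorts of 10³–10⁴ patients,
  2000×6 null simulations, 5000-control recovery runs) were chosen to make
  Monte-Carlo error small relative to the tolerances being checked while
  keeping the suite quick to run end-to-end.

## Known limitations

- The evaluation treats the diagnosis date as exact; date uncertainty in
  registry data would blur window boundaries.
- The resampling fit uses one visit per patient per iteration regardless
  of visit count, so patients with many visits contribute the same weight
  as single-visit patients.
- The PEB rule assumes normality of log2(AFP) in controls; the score is a
  monotone transform, so ranking is robust, but the per-screen level `f0`
  is exact only under the assumed hierarchy.
- Bootstrap training multisets duplicate patients by relabelling; variance
  components estimated on multisets are slightly anti-conservative.
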
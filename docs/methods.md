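# Methods

This note documents the generative model behind the synthetic cohorts, the
analysis procedures, the numerical choices, and what passing tests do and do
not establish about real data.

## Study design being emulated

Two groups — 63 patients with a PTSD diagnosis and 64 trauma-exposed
controls — each view six videos of everyday activities (breakfast 329 s,
party preparation 376 s, planting 354 s, library walk 249 s, sweeping
263 s, dishes 327 s) across two sessions.  Before each session's tasks the
participant hears a recording of their own traumatic or positive life
narrative (narrative priming); which narrative comes first alternates
deterministically across participants, and each video is seen exactly once,
so the first three videos fall in one priming condition and the last three
in the other.  Per session, 11 anxiety probes are rated on a 1–10 scale.
Symptom severity is the 17-item PCL total (range 17–85).

## Generative model

All randomness descends from a single root seed; each subject / video /
data stream uses a substream keyed by stable CRC32 hashes of its
identifiers, so any subset of a cohort regenerates identically.

**PCL totals.** Group-specific truncated normals on [17, 85], rounded to
integers.  The latent (mu, sigma) are solved so the *post-truncation*
mean/SD match the target sample statistics: PTSD mu=55.179, sigma=14.798
(mean 54.60, SD 13.66).  For controls the target SD is unattainable: a
normal truncated at 17 with mean 20.81 cannot have SD above ~3.8 (the
exponential-tail limit), so the calibration matches the mean exactly
(mu=6.880, sigma=8.0, giving SD 3.31).  Real control samples are
right-skewed in a way a truncated normal is not; this is a known
limitation.

**Latent segmentation ability.** ability_i = logistic(0.98 − 0.30·z_i + u_i),
u_i ~ N(0, 1.2²), where z_i standardises PCL against fixed reference
constants (pooled mean 37.6, SD 19.6 of the default cohort) so ability does
not depend on cohort composition.  The negative severity slope is the sole
channel through which diagnosis degrades segmentation.

**Video boundary structure.** Latent normative boundaries follow a gamma
renewal process (shape 4, mean gap 8.48 s → ≈ 37 boundaries for a 316-s
video); per-boundary salience ~ Beta(4, 2).  Empty boundary lists are
permitted (and logged) if the mean gap exceeds the duration.

**Button presses.** A boundary of salience s is detected with probability
`clip(base + slope·ability, 0, 1)^(1/s)` (defaults base 0, slope 1: the
probability is exactly ability^(1/s), increasing in both arguments, 1 in
the perfect-ability limit, 0 at zero ability).  Detected boundaries are
reported with N(0, 0.9²) s timing jitter, clipped to the video; false
alarms are a homogeneous Poisson process at 0.075·(1 − ability) presses/s.
These defaults land the observed mean of ≈ 28.7 presses per video and
group means of scaled agreement of ≈ 0.63 (control) and ≈ 0.59 (PTSD).
The press-count dispersion of real samples (SD ≈ 20, range up to ~140) is
*not* reproduced — that would need a heavy-tailed press-propensity trait —
so analyses sensitive to count extremes should not rely on this generator.

**Recall.** Each of 40 A1 units per video is recalled independently with
probability logistic(−2.65 + 2.21·scaled_agreement − 0.005·1[PTSD]
− 0.044·z(PCL) − 0.06·1[TRAUMATIC] + e_i), e_i ~ N(0, 0.33²) per subject.
The agreement term uses the *measured* scaled agreement, which is what
makes segmentation a genuine mediator rather than a correlate.  The direct
(non-mediated) deficit is deliberately carried almost entirely by the
continuous severity term: a purely binary group offset would be absorbed
differently by the group and severity mediation regressions (within-group
PCL variation identifies a near-zero direct severity effect), pushing the
two proportion-mediated figures ~9 points apart, which no single direct
path can reconcile with the calibration targets (45% and 46%).

**Anxiety.** rating = baseline + 1.4232·1[PTSD] + 1.1682·1[TRAUMATIC] +
0.7479·both + u_i + e, u_i ~ N(0, 0.8²), e ~ N(0, 1.1²), clipped to
[1, 10], 11 trials per session.  Because clipping at the scale floor
shifts observed means, the latent coefficients are solved (inverse
clipped-normal) so the large-n *observed* cell contrasts equal the target
fixed effects: group 1.05, condition 0.83, interaction 1.01, with the
control grand mean at 2.06.  The printed target means and coefficients are
mutually inconsistent at rounding level (they imply group gaps of 1.65 vs
1.56); the coefficients were taken as truth, leaving the PTSD grand mean at
3.62 rather than 3.71.

## Analysis procedures

**Binning and norms.** Presses fall into 1-s half-open bins [b, b+1); a
press at exactly the video end is clamped into the final bin.  The norm
profile is the per-bin marking proportion over the whole sample for that
video, pooling both priming conditions (each video is seen in only one
condition per participant); the index participant is included, with
leave-one-out available as a flag.

**Agreement.** raw_r is the Pearson correlation of the participant's
binary vector with the norm; scaled = (raw_r − r_min)/(r_max − r_min),
where r_max/r_min are the correlations of the best/worst vectors with the
same number of marked bins k (ones in the k highest-/lowest-norm bins,
ties broken toward the lowest bin index — the tie-break cannot change the
value, since for fixed k the correlation depends only on the sum of norm
values over marked bins).  Scaled is clamped to [0, 1] against
floating-point spill.  Degenerate cases (k = 0, k = n_bins, constant
norms) yield missing scores, are counted in the log, and are dropped
listwise downstream.

**Mixed models.** statsmodels MixedLM with a single all-encompassing group
and one variance component per crossed factor, REML, Wald z tests,
treatment coding with CONTROL / POSITIVE reference levels.  Severity
models mean-centre PCL over the full analysis table before forming the
interaction.  The anxiety model is trial-level with subject and trial
(1–11) random intercepts; a session-averaged variant can be obtained by
aggregating the table before fitting.  Non-convergence is flagged on the
returned fit, never silent; on tiny cohorts the trial or video variance
component frequently converges to the boundary, which is expected.

**Mediation.** Per-subject means over all non-missing videos (both
conditions pooled), then OLS mediator and outcome regressions and the
quasi-Bayesian decomposition: 1000 draws from each fit's asymptotic normal,
ACME = a·b, ADE = c′, total = ACME + ADE exactly per draw.  Intervals are
2.5/97.5 percentiles; p-values are two-sided MC tail proportions (floored
at 1/n_draws).  The proportion mediated is reported as the *median* of
per-draw ACME/total ratios, truncated to [0, 1]: draws with near-zero
totals make the per-draw ratio heavy-tailed, and the winsorised mean
(kept in metadata as `prop_mediated_raw`) carries a noticeable upward
Jensen-type bias at these effect sizes (total ≈ −0.03, SE ≈ 0.01).  When
the total-effect interval covers zero the proportion is flagged unstable
but still reported.  A nonparametric bootstrap over subjects is available
as an alternative (`bootstrap=True`).

## Calibration targets and what recovery shows

The defaults were solved once against these large-sample targets and then
frozen: agreement group means 0.63/0.59 (group coefficient −0.04), recall
means 0.23/0.20 (group coefficient −0.03), proportion mediated 45%
(group) and 46% (severity), outcome-regression R² 27%, 28.68 boundaries
per video, PCL means 54.60/20.81, anxiety contrasts 1.05/0.83/1.01.
Across 100 default cohorts the pipeline recovers: recall means
0.229/0.200, proportion mediated 43.9% / 48.4%, R² 27.6%, agreement
coefficient −0.040.  At the study's n = 127 the per-cohort proportion
mediated has an MC SD of ≈ 22 points, so a 25-seed average still moves
± 4–5 points between seed windows; this dispersion is a property of the
design size, not of the estimator.

Passing recovery tests shows the chain is internally consistent — the
estimators recover what the generator encodes.  It does not validate the
generator against real behaviour: real press logs have far larger
between-subject count dispersion, recall coding involves human raters
(only their agreement statistic, Cohen's kappa, is implemented), and the
condition effect on pressing is set to zero by default (exposed as
`condition_hit_offset`).

## Numerical choices and edge cases

- REML via L-BFGS, falling back to Powell on linear-algebra failure.
- Recall for a subject-video whose agreement is degenerate substitutes the
  scale midpoint 0.5 so the record remains generable; such viewings are
  rare under defaults (none in 100 cohorts) and excluded from models anyway.
- Ability is clipped to (1e-9, 1 − 1e-9) against logistic saturation.
- Kappa raises on the undefined p_e = 1 case (both coders constant and
  identical) rather than returning a sentinel.
- Mediation requires ≥ 20 subjects and a non-constant predictor.
- Seeds are masked to 31 bits before deriving substreams.

## Problem sizes used in the shipped checks

Recovery suites run 25 cohorts of 127 subjects × 6 videos with 1000
mediation draws (≈ 40 s total); the exhaustive-enumeration oracle for the
agreement statistic covers all k-subsets of vectors up to length 12; the
closed-form mediation oracle uses one n = 5000 linear-Gaussian cohort.
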
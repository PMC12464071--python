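# Methods

This note documents the models, estimators, and numerical choices behind
`vplearn`, and what its synthetic-data validation does and does not show.

## Stimulus model

A Gabor patch is rendered as
`L(x,y) = L_bg · (1 + c · exp(−(x²+y²)/(2σ²)) · cos(2πf(x·cosθ + y·sinθ) + φ))`
with defaults σ = 0.28 dva, f = 2.5 cpd, 2-dva aperture, L_bg = 52.42 cd/m²,
reference orientation 45°.  Conventions fixed here: orientation 0° means
vertical stripes and increases clockwise; phase is measured at the envelope
center; phase randomization samples the half-open interval [0°, 180°);
luminance is clipped at zero and no display gamma is modeled.  `contrast` is
the *nominal carrier* contrast: because the Gaussian envelope attenuates the
nearest carrier trough (0.2 dva off-center for these parameters, envelope
≈ 0.775), the measured Michelson contrast of a rendered 45%-contrast patch
is ≈ 0.38, always at or below nominal.  The rendering grid uses an odd
sample count so the envelope center is an exact pixel, and requires at least
4 samples per carrier cycle (twice Nyquist).

## Staircase procedure

Each track multiplies the orientation-offset level by 10^±0.05 (up on any
error, down after 3 consecutive correct responses), which converges on the
level with P(correct) = 0.5^(1/3) ≈ 0.794.  A block runs two tracks
starting at 1° and 3°, interleaved by seeded uniform random choice among
unfinished tracks (random interleaving rather than strict alternation keeps
the schedule unpredictable and testable under a seed); the CW/CCW offset
sign is uniform per trial.  A block ends when both tracks have 10 reversals
or at 200 trials total.  A reversal is logged at the level of the trial
that triggered the direction change.  Thresholds: per track with ≥ 10
reversals, the mean of reversals 5–10 (reversals beyond 10 are ignored so
the estimator is identical across blocks); the block estimate averages the
valid per-track thresholds, and a block with no valid track is flagged
invalid, not raised.  A config switch (`pool_staircases`) instead pools the
reversals of both tracks in trial order before the discard/average rule.

Measured properties (asserted in the tests): long-run accuracy at visited
levels 0.794 ± 0.03; block thresholds recover a known observer threshold to
within 25% (median) across 0.5–4°.  The reversal-mean estimator carries a
small threshold-dependent bias (under-estimation when the true threshold is
far above the start levels) — this is a property of the procedure itself
and is inherited by anything computed from measured thresholds.

## Learning statistics

`LI = (T_post − T_pre)/T_pre` (negative = improvement; exactly
scale-invariant).  Subjects whose *training-location* LI exceeds the
criterion (−0.20 by default, i.e. improvement weaker than 20%) are
excluded; the criterion is configurable (−0.30 reproduces the robustness
variant).  Subject-level thresholds are means over valid blocks; both the
block layer and the subject layer are retained.  Learning curves are fit by
constrained least squares to `T(b) = a·b^(−β) + c`, `a, β, c ≥ 0`
(`scipy.optimize.curve_fit`; non-convergence is flagged in the result, not
raised; a two-parameter `c = 0` variant is selectable).  Welch's t-test
reports the Welch–Satterthwaite df and a pooled-SD Cohen's d (the
conventional effect-size default; a Welch-adjusted d is not used).  The
Pearson test uses `t = r√(n−2)/√(1−r²)`; `r = ±1` yields an infinite t
flagged with p = 0.  Two independent correlations are compared with
Fisher's z: `z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))`, one-sided
by default, with `Cohen's q = |atanh r₁ − atanh r₂|`.  Under a
bivariate-normal null this test's type-I error is nominal to ±0.02 (checked
by simulation).  From the printed inputs r₁ = 0.71 (n = 13), r₂ = 0.09
(n = 16) the package computes z = 1.895, one-sided p = 0.029, q = 0.797.

## Aligned rank transform mixed ANOVA

The design is split-plot: Randomization (phase/contrast) and
TrainingLocation (UVF/LVF) vary between subjects; Time (pre/post) and
Location (training/C-transfer/F-transfer) within; blocks replicate within
cells.  For each of the 15 factorial terms the response is aligned —
full-factorial cell means subtracted, the target term's effect
(inclusion–exclusion over unweighted marginal means of cell means) added
back — and midranked (ties get midranks).  Alignment deliberately leaves
the subject deviations in the residual: they are the error term for
between-subject effects, and stripping them would invalidate those tests.

The mixed model with a random subject intercept is then fit on the ranks by
exact variance-stratum decomposition instead of iterative REML: terms
composed only of between-subject factors are tested on subject means
(denominator = subjects-within-groups, df = n_subj − #between-cells); terms
involving a within-subject factor are tested with subject indicators
absorbed (denominator = within-subject residual).  For balanced
compound-symmetric data these F statistics and denominator df are exactly
the Satterthwaite values of the random-intercept mixed model — verified
against an independent mixed-model implementation on a pinned fixture
(tests/test_art.py) — and the stratified form is closed-form, which keeps
thousand-replicate calibration studies cheap.  Fixed effects use
sum-to-zero (center) coding and type-III (drop-term) sums of squares, so
the analysis tolerates the unbalanced group sizes.  No multiplicity
correction is applied across terms.  Per-term effect size is
η²p = F·df₁/(F·df₁ + df₂).

Calibration: under a true null with subject intercepts (n = 24, 1000
replicates) every term's type-I error is within 0.05 ± 0.02.  One caveat
found during development: with a *strongly* skewed response (log-normal,
σ = 1) the aligned-rank F is anticalibrated (error rates up to ~0.2);
with normal errors, or the mild skew the threshold generator produces, it
is nominal.  Severely skewed responses should be transformed first.

Post hoc contrasts use ART-C: the response is re-aligned to the cell means
of the factor combination of interest, midranked, and the weighted
combination of estimated cell means tested with subject indicators
absorbed; Cohen's d is derived from the t statistic as 2t/√df.  The
packaged headline contrast is the pre–post difference at F-transfer, phase
minus contrast.

## Eye-movement analysis

Gaze traces are 1000-Hz samples in dva, screen-centered, x rightward,
y upward (UVF = positive y).  Blink handling keeps the raw blink channel
and derives validity from it (blink ± [−100, +150] ms), making the mask
idempotent and merging overlapping margins.  Trials are segmented from
200 ms before reference onset to 350 ms after test offset; trials with any
blink are excluded from valid-trial denominators.

Detection: velocity from a 5-sample centered difference (the standard
kernel for this detector family; 1-ms raw differences are noise-dominated
at 1000 Hz), invalid wherever the kernel touches an invalid sample.  The
default threshold is the canonical velocity-threshold detector's
median-based elliptical criterion, (vx/6σx)² + (vy/6σy)² > 1 with
σ² = median(v²) − median(v)² per component — the robust choice, since the
events themselves cannot inflate a median-based estimate.  A literal
scalar variant (trial mean speed + 6 SD) is available via
`estimator='mean'`; in simulation it loses roughly a third of true events
at realistic event rates precisely because of that self-inflation.
Candidates must last ≥ 6 ms; candidates closer than 10 ms are merged
(merging preserves event energy; a discard variant exists); events with
amplitude ≥ 1 dva are dropped.  Amplitude is the Euclidean combination of
per-axis positional ranges (onset-to-offset displacement selectable), peak
velocity the maximum speed in the event.

Summaries: microsaccade rate = total onsets / total trial time × 1000 Hz
(onsets per 1-ms bin, averaged over trials); microsaccade percentage =
events per valid trial, computed for the reference window, the test window,
and the whole trial; fixation variability = across-trial SD (ddof = 1) of
the per-trial mean gaze-to-fixation distance over the union of the
reference and test windows (each window alone is selectable); the main
sequence is the Pearson correlation of amplitude and peak velocity.

## Synthetic data

*Observer.*  `P(correct | offset) = 0.5 + (0.5 − λ)·W(|offset|)` with a
Weibull `W` whose scale is chosen so that `alpha_deg` is exactly the
79.4%-correct point at any lapse rate λ — the quantity the staircase
estimates.  Defaults: slope β = 3.5 (a steep but realistic psychometric
slope for fine orientation discrimination, which keeps the staircase's
measurement error small relative to between-subject differences), lapse
0.02.

*Cohort.*  Post-exclusion group sizes 13 (phase) and 16 (contrast), split
over UVF/LVF training.  Pre-thresholds are log-normal, median 3.0°,
log-SD 0.15 (thresholds ≈ 2–4.5°, consistent with improvements of 1.3–2.0°
at learning indices of −0.3…−0.65).  Group-mean improvements in degrees are
the reported conditions: training 1.53 (phase) / 1.40 (contrast),
far-transfer 1.99 / 1.31; the close-transfer values are not reported and
are set to 1.55 / 1.45 — a near-zero group gap, matching the reported
non-significant close-transfer group difference (d ≈ 0.09).  Improvements
are converted to mean LIs by dividing by the expected pre-threshold.
Per-subject LIs: training ~ N(mean, 0.10); the two transfer LIs are
bivariate normal with SD 0.14 — individual differences large enough that
the transfer correlation is identifiable at these group sizes yet small
relative to the group-mean improvement gaps — with group-specific
correlation ρ = 0.71 (phase) / 0.09 (contrast).  Draws are truncated to
(−0.95, 0.5) with bounded resampling.  Post thresholds are
`pre · (1 + LI)`, and every block threshold is *measured* by running the
interleaved staircases against the observer — so generated tables carry
realistic estimation noise and the procedure's own biases.  Learning is
applied between sessions only; `include_training=True` adds four 5-block
training sessions whose true threshold follows a power-law decay between
the pre and post values (for learning-curve analyses).  A `measure='direct'`
path skips the staircases for fast sampling-theory checks.  Presets:
`paper-like` (above), `null` (no improvement, ρ = 0), `high-noise`.

*Traces.*  Position = 2-D random walk (step SD 0.001 dva) + white
measurement noise (SD 0.005 dva), blinks with probability 0.1 per trial
(80–200 ms), and Poisson microsaccades (1 Hz) with log-normal amplitudes
(median 0.4 dva, truncated to (0.05, 0.95)) moved along minimum-jerk
profiles; peak velocity = 100·amplitude·(1 + 0.1·N(0,1)) s⁻¹, a linear
main sequence with realistic gain, and duration = 1.875·A/v_peak from the
minimum-jerk identity.  Events avoid each other, the trace edges, and
blink margins.  Ground truth (onset, offset, amplitude, peak velocity) is
returned alongside.

What the generators do *not* emulate: pupil-size artifacts around blinks,
saccadic overshoot/dynamic main-sequence curvature, session-level
non-stationarity (fatigue), within-block learning, response-time structure,
and any dependence of transfer on the actual stimulus geometry.  Passing
tests therefore demonstrate that the estimators recover the quantities
these generative models define — not that the models capture every property
of human data.

## Problem sizes and tolerances

The validation suite uses: 5000 trials for staircase convergence (±0.03 on
proportion correct; ±25% on the median of 200 block thresholds); 500
trials, amplitudes ≥ 0.2 dva, for detector fidelity (precision and recall
≥ 0.9); 1000 null replicates at n = 24 for ART calibration (per-term
0.05 ± 0.02); 100 paper-like cohorts for parameter recovery (phase-group
95% CI coverage of ρ = 0.71 at least 90%, contrast-group mean r within
±0.1 of zero, interaction detection ≥ 80%).  `scripts/acceptance.py`
recomputes all of these at the same sizes from a single `--seed` and writes
`{"name": {"value": ..., "n": ...}}` JSON.  Note the contrast-group band
is centered on zero while the generating correlation is 0.09, so that
check's expected value sits at ≈ +0.08: occasional seed-level excursions
just past +0.1 are sampling noise, not bias.

## Known limitations

- Denominator df are exact for balanced compound-symmetric designs and a
  very close approximation under the mild unbalance of unequal group
  sizes; Kenward–Roger small-sample adjustment is not implemented.
- The ART F is anticalibrated under strongly skewed error distributions
  (see above).
- The reversal-mean threshold estimator is biased when the true threshold
  is far from the staircase start levels; comparisons of measured LIs
  across conditions with very different threshold magnitudes inherit a
  small compression.
- Replay of logged staircases assumes logs are complete and ordered; it
  validates levels against the re-simulated track and refuses corrupted
  logs rather than guessing.
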
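# Methods

## Scope and data model

The pipeline analyzes T-maze delayed-alternation sessions recorded as (a)
timestamped 2-D head coordinates at a nominal 30 samples/s, (b) paired
mPFC and dHPC LFP with sampling-rate metadata, and (c) per-trial metadata
(chosen arm, condition ∈ {no-infusion, saline, muscimol}, epoch ∈
{baseline, testing}). All kinematic and spectral windows are anchored to
the choice point: the square region around the divergence toward the goal
arms, defined per session in the geometry config together with both
goal-arm rectangles.

## VTE detection

A choice-point pass runs from the first sample inside the choice region
(after the previous trial's commitment) to commitment — the first sample
inside a goal-arm region beyond the search-box margin (10% of region size,
configurable). Pass segmentation operates on the smoothed track so a
single noisy sample cannot end a pass early.

The IdPhi chain is: Gaussian-weighted moving average (window 30 samples,
kernel SD = window/5, truncated-renormalized at edges) → adaptive-window
velocity estimation → Phi = unwrap(atan2(dY, dX)) → adaptive-window dPhi →
IdPhi = trapezoidal ∫|dPhi| dt with per-sample time steps, so the score is
robust to rate changes. The adaptive derivative grows a window *centered*
on each sample until the best-fit line's maximum residual exceeds a
tolerance (1 cm for position, 0.1 rad for orientation) or ~15 samples
(~0.5 s at 30 Hz) are reached — short enough to track a head sweep, long
enough to suppress tracking jitter. Centering is deliberate: a trailing
(causal) window reports the slope at the window's midpoint and therefore
lags the true rate wherever the signal curves (a 30% error on a quadratic
test signal); offline tracking data has no causality constraint, and the
centered fit is exact there. These constants are package defaults (the
windowing method itself does not fix them) and are configurable.

**Kinematic window padding.** The pass window is extended by 10 samples
before entry and 20 after commitment before smoothing. With a 30-sample
smoother, the turn into the goal arm otherwise completes outside the
segment and the integral misses most of it: on a zero-noise ballistic pass
the unpadded estimate was 0.26 rad against an analytic heading change of
1.57 rad; padded, 1.58 rad. `time_spent` still measures entry→commitment
only.

zlnIdPhi is the z-score (sample SD) of ln IdPhi. The standalone
trajectory API pools per session; the *pipeline* pools across the whole
study by default (configurable: study / rat / session). The distinction
matters: the threshold is relative, so in a session that happens to
contain no genuine deliberative pass, per-session pooling puts about half
the ballistic trials above zero. Pooled across a study that does contain
deliberative passes, an all-ballistic session's trials fall in the lower
bulk and are labeled correctly. The VTE threshold is 0 — where the
ballistic component of the pooled distribution tapers.
Non-positive IdPhi (possible only for a constant-heading pass) is floored
to the smallest positive score and flagged. The head-sweep extractor runs
on the *raw* coordinates (smoothing attenuates a brief arm excursion below
the arm boundary) inside the search box, before commitment; excursions
into an arm beyond the box are rejected with a QC flag. Manual play-back
vetting is replaced by automated flags: `late_pause_suspect` when more
than half of near-zero-speed time falls in the last quarter of the pass,
and `tracking_error_suspect` when inter-sample speed exceeds 150 cm/s.
Flagged trials are reported, never silently dropped.

## Behavioral metrics

Trial 1 is a rewarded free choice and scored correct; trial t ≥ 2 is
correct iff its arm differs from trial t−1's. Perseveration counts
overlapping all-equal triples over n−2 windows (the 10L/10R worked
example: 16/18 = 89%), which pins the denominator choice. Turn bias is
|#L−#R|/n. A perseverative *event* for the overlap analysis is a maximal
run of ≥3 same-arm choices; its first error is the run's second trial, and
the VTE/non-VTE overlap percentages are each class's share of first
errors, summing to 100 when all labels are defined. Condition contrasts of
perseveration and turn bias use raw (non-normalized) testing-minus-baseline
differences, because control sessions can have zero perseveration and the
normalized score is then undefined. Accuracy by VTE class reports a rat as
missing when it contributes fewer than 2 trials of a class.

## Spectral analyses

Clipping is detected as runs of ≥2 identical consecutive values; a trial
is excluded when either region's choice-point segment is ≥1% clipped
(inclusive boundary). LFP windows start 0.33 s before choice-region entry
— the choice-point box includes data immediately preceding entry — and run
to commitment; retained segments are concatenated per VTE class.

Coherence is estimated from segment-averaged cross/auto spectra with
rectangular (untapered) segments and zero overlap — the reading under
which "no windowing or overlap" still yields a defined estimator, since
single-segment coherence is identically 1. At least 8 segments are
required. The module default segment is 2 s (0.5 Hz native resolution);
the *pipeline* uses 1-s segments so that control and muscimol cells with
very different concatenated lengths are estimated at the same resolution
bandwidth — with unequal segment lengths, the shorter condition's smeared
theta peak mimicked a coherence deficit that was never planted. Estimates
are interpolated onto the 1–20 Hz, 0.5 Hz analysis grid; normalization is
a z-score across the grid's bins (idempotent, affine-invariant); theta
summaries average the 5–10 Hz bins inclusive. Power spectra use 2-s
rectangular averaged periodograms, natural-log transformed.

## Granger prediction

Univariate and bivariate models are fit by OLS on lag-embedded design
matrices over the same sample window, so the nesting inequality (bivariate
residual variance ≤ univariate) and hence GC ≥ 0 hold exactly in-sample.
Series are de-meaned; variances are floored at 1e-12 with a warning. BIC
is the Gaussian form n·ln det Σ̂ + p·ln n with p = 4k coefficients,
minimized over k = 1..20 per session (ties to the smaller lag); the
study-wide order is the half-to-even rounded mean of per-session argmins.
In the pipeline, order selection uses the first 6000 samples of each
series (a runtime bound; the final fit uses everything), configurable.
Geweke's frequency decomposition evaluates H(f) = (I − Σ A_k e^(−i2πfk/fs))^(−1),
S = HΣH*, and per direction the log ratio of total to intrinsic power
after removing the cross-innovation term via the standard normalization;
unstable fits (companion spectral radius ≥ 1) are rejected.

## Statistics

RM-ANOVA is computed from within-subject sums of squares;
Greenhouse–Geisser epsilon uses the standard sample-covariance estimator
(bounded to [1/(k−1), 1]) and scales both degrees of freedom. t-tests are
two-sided with 95% CIs; Bonferroni conversion multiplies the raw p by the
number of comparisons in the panel (3 for condition follow-ups, 2 for the
VTE/non-VTE coherence pair) and caps at 1. Cohen's d for paired and
one-sample data is mean/SD of the (difference) scores; pooled-SD for
independent samples. Missing subjects are dropped listwise and reported.

## Synthetic sessions: what they emulate, and what they do not

Trajectories are built by integrating a prescribed heading/speed profile,
so the total absolute heading change — exactly what IdPhi estimates — is
known analytically per pass. Ballistic passes make one pivot turn into the
arm (π/2); head-sweep passes dip into each arm region `sweep_count` times
inside the search box before committing; pause passes wiggle nearly in
place with the heading sweeping back and forth, which is what makes a
pause IdPhi-detectable (the tracked head-stage moves while the body
stops). Tracking noise is isotropic Gaussian per sample (default 0 at the
module level, 0.5 cm typical in tests); there is no dropout/occlusion
model. Inter-trial return runs skirt the maze perimeter so segmentation
sees exactly one pass per trial.

LFP pairs are explicit stable bivariate autoregressions: each channel an
AR(2) resonator at 8 Hz whose pole radius exp(−π·bandwidth/fs) keeps a
2 Hz-wide theta peak at any sampling rate. The cross-coefficient is
normalized by the sender's resonance gain so `coupling_strength` s sets
the coupled-to-intrinsic amplitude ratio at the theta peak (coherence
there ≈ s²/(1+s²)); without this normalization the doubly-filtered shared
component saturates coherence at ~1 for any s > 0. Sessions also carry a
constant reverse (dHPC→mPFC) coupling of 0.25: with a purely
unidirectional plant, finite-sample leakage of the strong forward coupling
made the reverse Granger estimate scale with the forward strength,
producing a spurious reverse condition effect; a true constant reverse
pathway (anatomically realistic) keeps that direction's estimate dominated
by unchanged structure. A phase-lagged filtered-noise mode provides
coherence-only ground truth. Clipping injection overwrites seeded,
non-overlapping runs with constant values.

Study conditions (generator defaults, chosen once): 7 rats × 3 conditions
× 2 epochs, 20–24 trials/session; tracking 30 samples/s; LFP synthesized
at 500 samples/s (a standard analysis rate for theta-band work); control
sessions: p(perseverate) = 0.08, p(VTE) = 0.25, forward coupling 0.8;
muscimol-testing sessions: p(perseverate) = 0.4, p(VTE) = 0.4, and forward
coupling 0.3 *on VTE passes only* — the planted deficit the pipeline must
recover. Passing tests show the estimators recover what the generator
plants; they do not certify behavior on real recordings, whose artifacts
(electrode drift, movement artifacts, non-stationary theta frequency,
tracking dropouts) the generator deliberately omits.

## Numerical conventions and limitations

- Theta is 5–10 Hz everywhere, inclusive, from `vtesync.defaults`.
- The clipping threshold comparison is inclusive at 1%.
- zlnIdPhi uses the sample SD (n−1); `normalize_over_frequencies` uses the
  population SD over the fixed 39-bin grid — each matches its contract's
  test values.
- Round-half-even for the pooled VAR order (documented; configurable
  upstream of `round`).
- Granger here is bivariate only: no conditional/multichannel GC, no
  spectral-factorization (nonparametric) GC, no state-space GC.
- The coherence estimator's bias depends on segment count; comparisons
  across conditions should use the pipeline's matched-resolution setting
  rather than per-condition defaults.
- Problem sizes in the test suite (e.g. 3–7 rats, 20 trials, 500
  samples/s, 20–60 s series) are the package's own validation scale,
  chosen so the full suite runs on a laptop; all sizes are parameters.
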
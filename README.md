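# vtesync

Detection of vicarious trial and error (VTE) behaviors and analysis of
medial-prefrontal–dorsal-hippocampal (mPFC–dHPC) theta synchrony in T-maze
delayed-alternation sessions, packaged as a tested, reusable pipeline for
behavioral-neuroscience researchers working with head-tracking and dual-site
LFP recordings.

## What it computes

**VTE detection (IdPhi).** At the maze choice point, rats sometimes pause
and reorient toward the alternatives instead of passing ballistically —
behavior read as deliberation. From 2-D head coordinates, the pipeline
smooths position with a 30-sample Gaussian-weighted moving average,
estimates velocities dX, dY with a discrete time-adaptive windowing method,
forms the movement orientation Phi = atan2(dY, dX) (unwrapped), estimates
its rate of change dPhi the same way, and integrates:

    IdPhi = ∫ |dPhi| dt

over the choice-point pass. zlnIdPhi — the z-score of ln IdPhi — is
thresholded at 0 to label VTE trials; a complementary head-sweep extractor
(did the head enter both goal-arm regions while still within the
choice-point box?) recovers fast sweeps that score low on IdPhi. The final
VTE label is the union of the two detectors.

**Behavioral metrics.** Alternation scoring (trial t is correct iff its arm
differs from trial t−1's), perseveration (% of overlapping 3-trial windows
with the same arm choice), turn bias (|#L − #R|/n), VTE overlap with
perseverative error sequences, choice accuracy by VTE class, and the
normalized difference score (Y − X)/(Y + X) for per-subject condition
contrasts.

**Spectral analyses.** Choice-point LFP is screened for clipping (runs of
repeated voltage values; trials ≥1% clipped are dropped), concatenated by
VTE class, and analyzed with averaged-periodogram power spectra (natural
log), magnitude-squared coherence on a 1–20 Hz grid in 0.5 Hz steps with
rectangular non-overlapping segments, z-normalization across frequencies,
and theta (5–10 Hz) band means.

**Granger prediction.** Nested autoregressions per direction,
GC = log(Var[e]/Var[ε]) in the time domain, Geweke's frequency
decomposition from the fitted VAR's transfer function, and BIC-based order
selection (per-session argmin over lags 1–20, averaged and rounded).

**Statistics.** One-way repeated-measures ANOVA with Greenhouse–Geisser
correction, paired/one-sample t-tests with 95% CIs, Bonferroni conversion
(raw p × comparisons, capped at 1), Cohen's d, and Pearson correlations.

Because no public dataset accompanies this design, the `synthetic` module
generates complete sessions with known ground truth — heading-parameterized
trajectory passes (ballistic / head-sweep / pause), alternation sequences
with injectable perseveration, and theta-resonant coupled autoregressive
LFP pairs with controllable coherence and lead/lag direction.

## Worked example

```python
from vtesync.behavior import perseveration_score, turn_bias
arms = ["L"] * 10 + ["R"] * 10
print(round(perseveration_score(arms)), turn_bias(arms))
# 89 0.0
```

Ten repeated lefts followed by ten rights contain 16 all-equal triples out
of 18 windows — an 89% perseveration score — yet the left/right counts
balance, so turn bias is 0%: the two metrics dissociate.

A full synthetic study:

```bash
vtesync run-all --out results/ --seed 1
```

simulates a 7-rat cohort (each rat: baseline + testing under no-infusion,
saline and muscimol), runs every stage, and writes `trials.tsv` (per-trial
VTE labels), `summary.tsv` / `contrasts.tsv` (behavior), `spectra.tsv` /
`theta.tsv` (coherence and directional theta Granger per rat × condition ×
VTE class), `stats.tsv`, and `run_report.json` (per-stage counts and the
subject-exclusion ledger). In the simulated muscimol testing sessions,
perseveration and VTE rates rise and mPFC→dHPC theta coupling is weakened
on VTE passes only; the statistics table then shows a significant paired
reduction of normalized theta coherence on VTE (but not non-VTE) trials and
negative mPFC→dHPC (but not dHPC→mPFC) Granger difference scores — the
planted pattern, recovered end to end.

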
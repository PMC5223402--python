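# Methods

This note documents the models, parameters and numerical choices behind
`iinfb`, and what the synthetic test bench does and does not establish
about real data.

## Signal chain

All processing operates on 10 channels at 1000 Hz in µV — EEG C3, CP3,
C4, CP4; EOG up/down/left/right; bipolar EMG flexor/extensor — in 500-ms
ticks (500 samples).

**Online preprocessing** (the streaming path feeding the controller):
mastoid re-referencing (mean of the two reference traces subtracted from
EEG only), a causal 4th-order Butterworth band-pass 1–100 Hz plus a
60-Hz notch (Q = 30), DC correction from the first 3 s, and
PCA-based ocular artifact attenuation triggered when any EOG channel
exceeds ±360 µV. The IIR state is carried across chunk boundaries, so
streamed output is bit-identical to filtering the concatenated signal;
the filter starts from zero state (strict linearity) and the engine
primes it with the step response scaled by the first sample to soften
the onset transient. Filter order and notch Q are conventional defaults;
only the cutoffs are prescribed by the system design.

**Offline preprocessing**: 0.5-Hz high-pass (no low-pass), the same
notch, applied zero-phase (forward–backward), DC correction, and the
same PCA attenuation at a more sensitive ±200 µV threshold. The original
thresholds are quoted in mV in the source description; mV-scale EOG is
physically implausible, so both are interpreted as µV.

**EOG events and PCA attenuation**: an event is an excursion of the
largest absolute EOG amplitude above threshold; excursions closer than
500 ms merge, the event index is the excursion's absolute maximum
(earliest sample on ties). Within each window of −200…+500 ms around an
event (overlapping windows merged), the first left singular vector of
the windowed EEG+EOG block — local covariance, no mean removal — is
projected out; samples outside windows are untouched. A rank-1 artifact
is removed exactly; spatially orthogonal signals survive. In the
streaming engine the attenuation is chunk-local (per trial/rest
segment), which is exact for the synthetic schedule because windows
never span chunk boundaries.

## Spectral estimation and the feedback score

Per tick, band power is the sum of rectangular-window periodogram bins
whose center frequency lies in the closed mu band [7.5, 14.5] Hz; a
500-point FFT gives 2-Hz bins, so the in-band centers are 8, 10, 12,
14 Hz. One-sided scaling is such that a pure in-bin sinusoid of
amplitude A contributes A²/2 and the total over all bins equals the
time-domain mean square (Parseval). No tapering or overlap is applied —
the estimator mirrors the bare segment-FFT of the original system; the
band-edge convention (closed interval on bin centers) is recorded here
because the 2-Hz grid makes edge bins moot.

The baseline profile is computed from the 15-s rest block before the
first feedback block: per-channel mean of the 30 tick powers, plus mean
and sample SD (ddof = 1) of the per-tick rectified EMG means. ERD/S is
log2(P/B); a zero-power tick returns a floor of −20 instead of −∞.

The feedback score uses the printed sum-of-ratios form,
`rw·log2(ΣR_right) − lw·log2(ΣR_left)`, computed on channel powers
smoothed by a 6-tick running mean (fewer ticks at trial start). Two
consequences are deliberate: the rest-state expectation is rw − lw (−1
at levels ≤ 4), and smoothing is applied to the powers entering the
score rather than to the score itself, keeping the equation's inputs
well defined. A `normalize=True` option divides each hemisphere sum by
2 (rest expectation 0 at all weights) but is off by default for
fidelity to the original design.

## Controller semantics

The difficulty table is stored literally (levels −1…15; lw = 1
everywhere; rw = 0 through level 4, +0.1 per level through 13, 1.0 at
14–15; thresholds [−8 −4], [−6 −2], [−4 0], [−2 2], [0 4] for −1…3,
[2 6] for 4–14, [2 2] at 15). Threshold and titration comparisons are
strict (`> upper`, `< lower`, `> 4`, `< 2`); boundary values hold.

The video score presented during tick t is the controller state at the
start of t; the tick's comparison updates what t+1 presents, so the
first tick of every trial presents the default score 1. A change starts
a 4-tick (2-s) lockout; an EMG flag resets the score to 1 and restarts
the lockout unconditionally (the safety gate dominates). Difficulty
starts at level 1 each session and changes only at trial ends, from the
mean video score of the final 40 ticks; demotion below level 1 requires
three consecutive completed trials at level 1, with a floor of −1 and a
cap of 15. At level 15 the degenerate band [2, 2] means any score ≠ 2
moves the video score (promotion is a no-op at the cap).

Sham sessions replay the yoked session's per-tick video-score and level
streams verbatim; the sham subject's own EMG flags are computed and
logged but never touch the presented stimulus. The per-tick CSV log is
itself the yoke file, and yoke files are validated against the
configured schedule (tick count) before use.

## The virtual subject

The generator's purpose is statistical controllability, not biophysical
realism. Its components:

- **Mu rhythm**: a sinusoid at `mu_freq` (default 10 Hz — on the 2-Hz
  bin grid, so tick power is exact) with per-channel random phase,
  amplitude `mu_amp` (default 10 µV). During task states the amplitude
  is multiplied by sqrt(ratio), so band power scales exactly by the
  programmed ratio: `contra_ratio_task` on C3/CP3, `ipsi_ratio_task` on
  C4/CP4. Phase is continuous across chunks.
- **Background**: 1/f-power noise, RMS `noise_amp` (default 5 µV),
  regenerated per chunk and RMS-normalized.
- **Blinks**: Poisson events (`blink_rate`, default 12/min) of 400-ms
  raised-cosine deflections, +300 µV on upper and −300 µV on lower EOG,
  with 20% bleed into every EEG channel. Note 300 µV is below the
  online ±360 µV detection threshold, so the streaming PCA rarely fires
  on synthetic data while the offline ±200 µV pass catches every blink —
  a faithful consequence of the two printed thresholds.
- **EMG**: resting EMG is a frozen tick-periodic band-limited
  (30–300 Hz) noise template per channel, RMS `emg_amp` (default 2 µV).
  Because every quiet tick's rectified mean is bit-identical, the
  baseline SD is zero and the strict 2-SD gate has *exact* specificity;
  a stochastic resting EMG would make a 2-SD threshold fire at ~2.3%
  chance level by construction, defeating deterministic tests of the
  gate. Bursts (Poisson, `emg_burst_rate`, default 2/min, or scheduled
  explicitly per tick) add band-limited noise bringing the tick to 5×
  the resting RMS, guaranteeing the gate trips. The trade-off — no
  tonic EMG variability — is deliberate and means chance-level
  rejection rates of real recordings are *not* emulated.
- **Learning**: after each trial with mean video score > 4 the
  contralateral ratio is multiplied by (1 − `responsiveness`), floored
  at 0.05 — a minimal model sufficient to exercise titration dynamics.
  `responsiveness = 0` yields statistically identical trials all
  session.

Default effect sizes: `contra_ratio_task = 0.5` (50% ERD, a strong but
plausible motor-imagery effect), `ipsi_ratio_task = 1`. The "null"
phenotype (both ratios 1, responsiveness 0) and "strong" phenotype
(contra ratio 0.1) bracket the plausible range for closed-loop sanity
checks.

The session schedule follows the experimental design: 15-s baseline,
3 × 10 trials of 50 s + 10 s rest, then 10 motor-imagery trials of 20 s
each preceded by a rest drawn uniformly from [8, 12] s and rounded to
the 0.5-s tick grid (keeping every recording tick-aligned and EDF
records exact). Not modeled: cortical geometry, volume conduction,
alpha-peak variability, non-stationary mu amplitude, or the cognitive
content of the baseline (plain rest stands in for silent counting).

## Offline pipeline

Epochs are cut marker-to-marker (trial, MI and rest epochs; rests are
attributed to the MI task when they immediately precede an MI trial).
Epoch lengths therefore follow whatever schedule produced the
recording; `validate_schedule` surfaces any mismatch with the analysis
configuration as a warning instead of silently resolving it (relevant
because descriptions of such protocols sometimes quote MI epoch lengths
that include cue/rest padding).

EMG rejection applies the same gate as the online engine, tick-for-tick,
to feedback-task ticks (the transfer block is analyzed without
rejection, matching the original analysis). ERD/S uses *raw* per-tick
powers — the 6-tick smoothing is a feedback-presentation device, not an
analysis step. Baselines are task-specific: the final 4 s (8 ticks) of
the baseline block for the feedback task, the final 4 s of the first MI
rest for the MI task. Hemisphere values are the mean of the two
channels' log2 ratios. Group-level output is restricted to descriptive
mean/SD summaries; the tidy table (group, session, task, hemisphere,
tick, log2_erds) is the interface to external inferential tooling.

## File formats

CSV recordings are bit-exact round-trips (17 significant digits, LF,
marker sidecar CSV). EDF+ files use 0.5-s data records, 16-bit samples
over a fixed ±3276.7 µV physical range (0.1 µV per digital unit, so
round-trip error ≤ 0.05 µV), and an annotation channel carrying the
markers; the reader is cross-checked against an independent EDF
implementation in the test suite. All file writes are atomic.

## Problem sizes and verification

The package's checks compute: exactness of the periodogram against an
explicit-DFT oracle (100 random ticks, tolerance 1e-9); ERD recovery
within ±0.2 log2 units for programmed ratios 0.25–2 over 200 task
ticks per ratio (noise-free, where the estimator is exact up to filter
ripple); closed-loop separation of null vs. strong phenotypes over 20
seeded full sessions each (the null subject's mean final difficulty
stays ≤ 2 — its score hovers at the rest expectation −1, which the
level-0/−1 thresholds were designed to catch); and bit-exact sham
replay with active EMG bursts. These sizes give stable statistics at
interactive runtimes; all randomness is seed-derived.

## Known limitations

- The difficulty ceiling implied by the printed thresholds is real: with
  the sum-of-ratios score, promotion past level 3 requires a combined
  left-hemisphere ratio below 1/16, which neither the default virtual
  subjects nor (per the original report) most human participants
  sustain. The engine reproduces this rather than correcting it.
- Streaming PCA attenuation is chunk-local; a true ring-buffer
  implementation would be needed for artifact windows spanning chunk
  boundaries in arbitrary acquisition setups.
- The EDF writer targets this package's fixed montage and rate; it is
  not a general-purpose EDF library.
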
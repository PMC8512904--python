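# Methods

This note documents the models, conventions and numerical choices behind
`betarebound`, in the spirit of a methods appendix: what each stage
assumes, which knobs matter, and what the synthetic generator does and
does not emulate.

## Session protocol

A session is a contiguous partition of `[0, T)` into phases. The motor
imagery (MI) presets follow the classic neurofeedback timeline: a 30 s
WAIT for system preparation, then 10 s IDLE (rest) and 10 s ACTIVE
(imagery) windows alternating until the 5-minute capture ends. With the
wait modeled and the alternation starting active-first, 27 whole phases
fit after the wait and 14 of them are active; with no modeled wait and an
idle-first start, all 15 active opportunities of a 5-minute capture
appear. Both variants are exposed as presets (`default`, `no_wait`)
because both counts are legitimate readings of the same protocol,
depending on whether the preparation wait consumes session time. The
calibration capture is a single uninterrupted idle block — the participant
remains static while the baseline is measured.

Intervals are half-open `[start, end)` in seconds from recording start, so
each sample belongs to exactly one phase. Only whole phases are emitted;
a partial tail shortens the schedule rather than producing a truncated
window. Active phases carry the condition's stimulus tag (visual for MIV,
visual+haptic for MIVH); the tag is timeline metadata only — no stimulus
hardware is modeled.

## Online detection path

The detector follows the standard ERS-thresholding chain:

* **Small Laplacian around Cz.** Center minus the mean of FCz, C1, C2,
  CPz. Sharpens foot-area cortical activity and rejects common-mode
  signals. Applied before spectral filtering.
* **Beta band-pass 16–24 Hz,** Butterworth of design order 4 (the realized
  transfer function has 8 poles, as is conventional). The online path runs
  the recursion causally; offline analyses use zero-phase
  forward–backward filtering. A Chebyshev-I variant with 0.5 dB passband
  ripple is available through `FilterSpec` for users who prefer that
  design; Butterworth (maximally flat, −3 dB corners) is the default.
* **Epoch power.** Mean of squared samples over sliding 1 s epochs with a
  100 ms stride (i.e., 900 ms overlap between consecutive epochs — a power
  update every 100 ms, matching the command cadence of an online system).
  The literal alternative reading of "100 ms overlap" (stride 900 ms) is
  available via the `stride` parameter. Epoch timestamps mark epoch ends.
* **Threshold.** `Th = mean + k·sd` over the calibration capture's epoch
  power, `k = 3` by default, sample (n−1) standard deviation (calibration
  is an estimate from finitely many epochs; at ~3000 epochs the
  population/sample difference is negligible, but the convention is fixed
  and documented). A crossing is a strictly greater comparison.

### Window attribution of epochs

Epochs are end-stamped, and an epoch is attributed to a schedule window
only when its full data interval `[t − epoch_len, t]` lies inside the
window. An epoch straddling the rest→active boundary carries up to 900 ms
of rest data, so a rest-period power excursion would otherwise register as
an active-window detection (and vice versa). Under the fully-inside rule
the earliest reportable latency is one epoch length, and detection latency
for a rebound with true onset `t₀` falls within `(t₀, t₀ + epoch_len +
stride]` — the stride-resolution bound. Rest (IDLE) windows use the same
rule; a rest window containing any crossing counts once as a rest
activation, regardless of how many epochs crossed.

## Streaming runtime

`run_session` consumes the recording in stride-sized chunks, carrying the
band-pass filter state across chunks, and emits one command bit per stride
outside the WAIT phase: 1 exactly when the current epoch power exceeds the
threshold inside an active window. Because a causal IIR filter applied
chunk-wise with persistent state is sample-for-sample identical to batch
filtering, streamed and batch detection agree exactly — this is asserted
as a property, not assumed. The mock exoskeleton log records one trigger
per detected active window in BCI mode; in stationary-therapy (ST) mode it
ignores the EEG and fires every 3 s inside active windows (at +3, +6, +9 s
of a 10 s window). Transports are in-process; no network is involved.

A non-finite sample mid-stream (channel dropout) aborts the run with the
partial command stream and device log attached to the exception.

## Synthetic sessions

Each channel is `background + weight × rhythm`:

* **Background**: Gaussian noise with a 1/f^α spectrum (α = 1 by default,
  the canonical EEG slope), 10 µV rms, independent per channel.
* **Rhythm**: a shared 16–24 Hz band-limited noise carrier, 6 µV rms at
  Cz, volume-conducted with per-channel weights (Cz 1.0, C1/C2 0.4,
  FCz/CPz 0.3) so the Laplacian retains 0.65 of it. The carrier is
  amplitude-stabilized (divided by its smoothed Hilbert envelope): it
  keeps the random phase structure of filtered noise — so Welch spectra
  are non-degenerate — while its power follows the injected event
  envelope rather than the large spontaneous amplitude excursions of raw
  filtered noise. This is a deliberate idealization: real beta activity is
  bursty, and the stabilization is what makes exact ground-truth recovery
  a meaningful test.

The rhythm's envelope encodes the event structure: ×`erd_gain` (default
0.5) during active windows (event-related desynchronization), ×`ers_gain`
(default 5) for `ers_duration` (1 s) at the rebound onset in windows where
the ground truth places a rebound. Onsets are drawn from N(1.5 s, 0.5 s)
truncated to the window — consistent with online detection times reported
in the ~1–3.3 s range. Rest windows contain the same kind of burst with
probability `spurious_rate` (default 0.3, giving ≈4–5 rest activations per
session, the order observed in practice); spurious bursts are suppressed
during calibration (supervised, participant static) and end at least one
epoch before the next window so that rest/active ground truth stays
unambiguous.

Artifacts are opt-in (`inject_artifacts`): Poisson-process eye blinks
(<4 Hz Gaussian lobes, 80 µV, frontally weighted) and broadband >20 Hz
EMG bursts. The generator does **not** model volume conduction,
stroke-lesion asymmetries beyond the channel weights, electrode impedance
drift, or amplitude-bursty beta; passing tests therefore demonstrate
algorithmic correctness under the stated signal model, not clinical
performance on patient EEG.

Default amplitudes were chosen once so that the 3σ threshold regime is
exercised realistically: calibration exceedance at k = 3 is a fraction of
a percent, rebounds at 5× gain clear the threshold decisively, and rest
activations occur at a realistic rate. With `erd_gain = ers_gain = 1` the
generator is stationary by construction.

## Offline analyses

* **Event-related power (per channel)**: zero-phase 0.16 Hz high-pass
  (drift removal), zero-phase 8–30 Hz band-pass (the MI band), squaring,
  segmentation into active windows, averaging across segments → `P(t)`;
  baseline = mean power over the last 500 ms of each preceding rest
  window, averaged; `ERP(t) = P(t) − P_baseline`, held as a pointwise
  identity. Active windows without a ≥500 ms preceding IDLE period (e.g.
  a first window following the WAIT) are skipped with a warning.
* **Welch PSD**: Hann windows of 0.5 s at 50 % overlap, density scaling
  (integral ≈ variance; the Parseval check is part of the test suite).
  PSDs are computed on the band-filtered signal of the active segments —
  spectral analysis of a squared power trace would not live in the 8–30 Hz
  band. Band means over 8–30 Hz are reported in both µV²/Hz and dB/Hz,
  because the two conventions are easily conflated in published tables.

## Statistics

Condition comparisons are gated on Shapiro–Wilk normality per group at
α = 0.05 (reject normality when p < α): two related samples → paired t if
both groups look normal, Wilcoxon signed-rank otherwise; three related
samples → repeated-measures ANOVA or Friedman by the same rule. The branch
taken is recorded in the report. Identical paired samples (all-zero
differences) return p = 1 explicitly, since the signed-rank statistic is
undefined there. Raw p-values are the primary output; a Holm step-down
adjustment across channels is available but off by default. Note that with
n = 5 the signed-rank test cannot reject at α = 0.05 at all (its smallest
attainable p is 0.0625), which slightly deflates the gated branch's type-I
rate below the nominal level — the null simulation in the test suite
quantifies this.

## QUEST scoring

QUEST (Quebec User Evaluation of Satisfaction with Assistive Technology)
uses 1–5 Likert scores over seven core criteria (dimensions, weight,
adjustment, safety, ease of use, effectiveness, information/instructions)
plus four extended ones (reliability, speed, learning, aesthetic design).
A subject's total is the mean over answered criteria, kept at full
precision internally. Published tables of this kind truncate (not round)
totals to two decimals — 31/7 = 4.428… prints as 4.42 — and compute the
group display average from the truncated subject totals; both the
full-precision and display values are exposed. Per-criterion averages are
computed arithmetically from the responses.

## Problem sizes and numerics

Test and acceptance runs use 5-minute sessions at 500 Hz (150 000 samples
× 5 channels), 20-session recovery sweeps, 1000-replicate null
simulations, and 100-case detection-oracle sweeps; the full suite runs in
well under a minute of compute per module. Seeds are explicit everywhere;
identical seeds give bitwise-identical sessions. Filters are implemented
as second-order sections for numerical stability; stability over 10⁶
samples is asserted in the suite. EDF output quantizes to 16 bits over a
configurable physical range (default ±200 µV, step ≈ 0.006 µV); CSV output
is lossless to 10⁻⁹ µV.

## Known limitations

* The synthetic rhythm's amplitude stabilization trades realism for
  testability (see above); detection performance on real, bursty beta will
  be worse than on the generator's sessions.
* The ERP baseline uses only the immediately preceding rest window; other
  baseline policies (whole-session, pre-stimulus regression) are not
  implemented.
* No artifact removal (ICA/regression) is included — artifact handling is
  behavioral in the intended protocol, and the artifact injector exists to
  measure robustness, not to be corrected for.
* Machine-learning classification of MI is out of scope; the detector is
  deliberately the transparent thresholding rule.
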
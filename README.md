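# betarebound

A tested, reusable implementation of a beta-rebound motor-imagery
brain–computer interface (BCI) pipeline of the kind used to trigger ankle
exoskeletons (e.g. T-FLEX) in post-stroke rehabilitation. It is aimed at
BCI/neuroengineering researchers who want to study, stress-test, or extend
threshold-based event-related synchronization (ERS) detection without
access to recorded patient EEG: the package generates seeded synthetic
sessions with known ground truth, runs the online detection path exactly
as a streaming system would, and reproduces the offline analysis stack
(event-related power, Welch PSD, normality-gated statistics, QUEST
satisfaction scoring).

## The method

During motor imagery the sensorimotor beta rhythm (16–24 Hz) desynchronizes
(ERD); roughly 0.3–0.5 s after imagery ends it rebounds above baseline for
about one second (ERS, the "beta rebound"). The online detector measures
beta power in a small-Laplacian montage around Cz (neighbors FCz, C1, C2,
CPz; 500 Hz sampling):

1. spatial filter: `x(t) = Cz(t) − mean(FCz, C1, C2, CPz)(t)`
2. causal 4th-order Butterworth band-pass, 16–24 Hz
3. squaring and averaging over sliding 1 s epochs, updated every 100 ms
4. per-user threshold from a 5-minute static calibration capture:

   `Th = x̄ + k·σ` with `k = 3`,

   where x̄ and σ are the mean and (sample) standard deviation of the
   calibration epoch power.

During a session, 10 s active (imagery) and rest windows alternate after an
initial 30 s wait. The first epoch whose power strictly exceeds `Th` inside
an active window counts as a successful attempt and triggers the (mocked)
exoskeleton; session accuracy is

`accuracy(%) = 100 · successful_attempts / total_attempts`

with total attempts fixed by the schedule (14 windows with the 30 s wait,
15 without). Threshold crossings inside rest windows are tallied as rest
activations. Offline, per-channel event-related power is computed as
`ERP(t) = P(t) − P_baseline` (0.16 Hz drift removal, zero-phase 8–30 Hz
band-pass, squaring, averaging over active windows, baseline from the last
500 ms of the preceding rest), and spectral densities use Welch's method
with 0.5 s windows at 50 % overlap.

## Worked example

```python
import betarebound as br

# calibration capture (participant static) -> per-user threshold
cal_sched = br.preset_schedule("calibration")
cal_rec, _ = br.generate_session(cal_sched, br.SynthesisParams(seed=4242))
filt = br.bandpass(br.laplacian(cal_rec), cal_rec.fs, br.beta_spec())
th = br.calibrate(br.epoch_power(filt, cal_rec.fs))
print(f"Th = {th.th:.2f} uV^2  (mean {th.mean:.2f}, sd {th.sd:.2f})")

# a motor-imagery session with rebounds in 9 of 14 active windows
sched = br.preset_schedule("default")
present = (True,)*5 + (False,)*5 + (True,)*4
rec, truth = br.generate_session(sched, br.SynthesisParams(seed=7, ers_present=present))
filt = br.bandpass(br.laplacian(rec), rec.fs, br.beta_spec())
result = br.detect(br.epoch_power(filt, rec.fs), th, sched)
m = br.score_session(result, sched)
print(f"accuracy {m.accuracy_pct:.1f}%  ({m.successful_attempts}/{m.total_attempts}), "
      f"mean latency {m.mean_latency_ms:.0f} ms, {m.rest_activation_count} rest activations")
print(f"ground truth: {truth.accuracy_pct:.1f}%")
```

prints

```
Th = 32.60 uV^2  (mean 18.79, sd 4.60)
accuracy 64.3%  (9/14), mean latency 1689 ms, 7 rest activations
ground truth: 64.3%
```

The detector recovers exactly the nine windows that truly contained a
rebound (64.3 % = 100·9/14); the ~1.7 s mean latency reflects the injected
rebound onsets (~1.5 s after window start) plus the 1 s integration epoch,
and the rest activations come from the generator's spurious rest-window
bursts — the same behavior real sessions show.

The same flows are available from the shell:

```
betarebound simulate --schedule calibration --seed 3 --out cal.csv
betarebound calibrate cal.csv --out th.json
betarebound simulate --schedule default --seed 4 --out session.csv
betarebound run session.csv --threshold th.json --out report.json
betarebound quest responses.csv
```

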
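"""Seeded synthetic EEG sessions with known ERD/ERS ground truth.

Each channel is a sum of two components:

* a 1/f-shaped background noise floor (independent per channel), and
* a shared band-limited sensorimotor rhythm in the beta band (16–24 Hz),
  volume-conducted to each electrode with a per-channel weight so the
  Laplacian montage around Cz retains it.

The rhythm's amplitude envelope encodes the event-related dynamics: during
ACTIVE windows it is attenuated by ``erd_gain`` (event-related
desynchronization while the movement is imagined), and — in windows where
the ground truth says a rebound occurs — multiplied by ``ers_gain`` for
``ers_duration`` seconds starting at a random latency after window onset
(the post-imagery beta rebound, lasting about one second).  The rhythm is
realized as band-limited filtered noise rather than a sinusoid so spectral
estimates are non-degenerate.

Ground truth (per-window rebound presence and onset) is returned alongside
the recording, which makes the full detection pipeline testable without
any recorded data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording import DEFAULT_CHANNELS, EEGRecording
from .session_protocol import (
    Condition,
    ProtocolSchedule,
    active_windows,
    idle_windows,
)

__all__ = ["SynthesisParams", "GroundTruth", "ArtifactLog",
           "generate_session", "inject_artifacts"]

#: Volume-conduction weight of the central beta generator at each electrode.
#: Strongest under Cz, weaker at the surrounding montage, so the Laplacian
#: (center minus neighbor mean) keeps 1 − mean(neighbors) = 0.65 of it.
DEFAULT_CHANNEL_WEIGHTS = {"FCz": 0.3, "C1": 0.4, "Cz": 1.0, "C2": 0.4, "CPz": 0.3}


@dataclass(frozen=True)
class SynthesisParams:
    """Knobs of the session generator (amplitudes in µV).

    ``ers_present`` optionally fixes per-active-window rebound presence;
    when None every active window contains a rebound.  ``spurious_rate`` is
    the probability that an idle window contains the same kind of burst
    (models the rest activations seen in practice; default 0).
    """

    noise_exponent: float = 1.0
    background_rms: float = 10.0
    beta_band: tuple[float, float] = (16.0, 24.0)
    beta_rms: float = 6.0
    erd_gain: float = 0.5
    ers_gain: float = 5.0
    ers_duration: float = 1.0
    ers_latency_dist: tuple[float, float] = (1.5, 0.5)
    ers_present: tuple[bool, ...] | None = None
    spurious_rate: float = 0.3
    channel_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_WEIGHTS)
    )
    fs: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.erd_gain < 0 or self.ers_gain < 0:
            raise ValueError("gains must be non-negative")
        if self.ers_duration <= 0:
            raise ValueError("ers_duration must be positive")
        if any(w < 0 for w in self.channel_weights.values()):
            raise ValueError("channel weights must be non-negative")
        if not 0.0 <= self.spurious_rate <= 1.0:
            raise ValueError("spurious_rate must be a probability")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually injected, window by window."""

    rebound_present: tuple[bool, ...]          # per active window
    rebound_onset: tuple[float | None, ...]    # absolute seconds, per active window
    spurious_burst: tuple[bool, ...]           # per idle window

    @property
    def n_present(self) -> int:
        return sum(self.rebound_present)

    @property
    def accuracy_pct(self) -> float:
        """Accuracy a perfect detector would score on this session."""
        if not self.rebound_present:
            raise ValueError("no active windows in ground truth")
        return 100.0 * self.n_present / len(self.rebound_present)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "rebound_present": list(self.rebound_present),
                    "rebound_onset": list(self.rebound_onset),
                    "spurious_burst": list(self.spurious_burst),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            tuple(d["rebound_present"]),
            tuple(None if v is None else float(v) for v in d["rebound_onset"]),
            tuple(d["spurious_burst"]),
        )


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float,
                      exponent: float, rms: float) -> np.ndarray:
    """Gaussian noise with power spectrum ∝ 1/f^exponent, scaled to rms."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.empty_like(freqs)
    shape[0] = 0.0  # no DC offset
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    return x * (rms / np.std(x))


def _beta_carrier(rng: np.random.Generator, n: int, fs: float,
                  band: tuple[float, float]) -> np.ndarray:
    """Unit-rms band-limited noise in the beta band, amplitude-stabilized.

    Band-pass filtered white noise has a strongly fluctuating instantaneous
    amplitude; dividing by its smoothed Hilbert envelope keeps the random
    phase structure (so spectra are non-degenerate) while making the
    rhythm's power follow the injected ERD/ERS envelope rather than its
    own amplitude excursions.  Event timing in the output is therefore
    controlled entirely by the ground truth.
    """
    from scipy.ndimage import gaussian_filter1d

    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    env = np.abs(signal.hilbert(x))
    env = gaussian_filter1d(env, sigma=0.25 * fs)
    x = x / np.maximum(env, 0.1 * env.mean())
    return x / np.std(x)


def generate_session(
    schedule: ProtocolSchedule,
    params: SynthesisParams | None = None,
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS,
) -> tuple[EEGRecording, GroundTruth]:
    """Synthesize one session following the schedule; fully seeded."""
    if params is None:
        params = SynthesisParams()
    fs = params.fs
    if fs < 2 * params.beta_band[1]:
        raise ValueError(
            f"fs={fs} Hz cannot represent the {params.beta_band[1]} Hz band edge"
        )
    rng = np.random.default_rng(params.seed)
    n = int(round(schedule.total_duration * fs))

    actives = active_windows(schedule)
    idles = idle_windows(schedule)
    if params.ers_present is not None:
        if len(params.ers_present) != len(actives):
            raise ValueError(
                f"ers_present has {len(params.ers_present)} entries for "
                f"{len(actives)} active windows"
            )
        present = tuple(bool(b) for b in params.ers_present)
    else:
        present = tuple(True for _ in actives)

    # amplitude envelope of the rhythm: 1 at rest, erd_gain in active
    # windows, ers_gain within rebound bursts
    env = np.ones(n)
    t_axis = np.arange(n) / fs
    lat_mean, lat_sd = params.ers_latency_dist
    onsets: list[float | None] = []
    for (w0, w1), has in zip(actives, present):
        sel = (t_axis >= w0) & (t_axis < w1)
        env[sel] = params.erd_gain
        if not has:
            onsets.append(None)
            continue
        max_lat = max((w1 - w0) - params.ers_duration, 0.0)
        lat = float(np.clip(rng.normal(lat_mean, lat_sd), 0.0, max_lat))
        onset = w0 + lat
        burst = (t_axis >= onset) & (t_axis < onset + params.ers_duration)
        env[burst] = params.ers_gain
        onsets.append(onset)
    # Spurious rest-window bursts model the rest activations observed in
    # practice.  They never occur during the supervised calibration capture
    # and are kept at least one epoch away from the following window so the
    # rest/active ground truth stays unambiguous for end-stamped epochs.
    spurious = []
    spurious_rate = (
        0.0 if schedule.condition is Condition.CALIBRATION else params.spurious_rate
    )
    for (w0, w1) in idles:
        guard = params.ers_duration + 1.0
        hit = bool(rng.random() < spurious_rate) and (w1 - w0) > guard
        spurious.append(hit)
        if hit:
            onset = w0 + float(rng.uniform(0.0, (w1 - w0) - guard))
            burst = (t_axis >= onset) & (t_axis < onset + params.ers_duration)
            env[burst] = params.ers_gain

    carrier = _beta_carrier(rng, n, fs, params.beta_band) * env * params.beta_rms
    rows = []
    for label in channel_labels:
        w = params.channel_weights.get(label, 0.5)
        bg = _one_over_f_noise(rng, n, fs, params.noise_exponent,
                               params.background_rms)
        rows.append(bg + w * carrier)
    rec = EEGRecording(np.vstack(rows), fs, tuple(channel_labels))
    gt = GroundTruth(present, tuple(onsets), tuple(spurious))
    return rec, gt


@dataclass(frozen=True)
class ArtifactLog:
    blink_times: tuple[float, ...]
    emg_bursts: tuple[tuple[float, float], ...]  # (start, duration) seconds


#: Scalp distribution of ocular artifacts: frontal electrodes dominate.
_BLINK_TOPOGRAPHY = {"FCz": 1.0, "C1": 0.5, "Cz": 0.6, "C2": 0.5, "CPz": 0.3}


def inject_artifacts(
    recording: EEGRecording,
    blink_rate: float = 0.0,
    emg_rms: float = 0.0,
    seed: int = 0,
    blink_amplitude: float = 80.0,
    emg_rate: float = 6.0,
    emg_burst_duration: float = 0.5,
    return_log: bool = False,
):
    """Add ocular and muscular artifacts to a recording.

    Blinks are low-frequency (< 4 Hz) Gaussian-lobe transients occurring as
    a Poisson process at ``blink_rate`` per minute, strongest frontally.
    EMG contamination is modeled as broadband (> 20 Hz) noise bursts of
    ``emg_burst_duration`` seconds at ``emg_rate`` per minute with the
    given within-burst rms.  Zero rates return the input unchanged.
    """
    if blink_rate < 0 or emg_rms < 0:
        raise ValueError("artifact rates must be non-negative")
    if blink_rate == 0 and emg_rms == 0:
        return (recording.copy(), ArtifactLog((), ())) if return_log else recording.copy()

    rng = np.random.default_rng(seed)
    fs = recording.fs
    n = recording.n_samples
    dur_min = recording.duration / 60.0
    out = recording.samples.copy()
    t_axis = np.arange(n) / fs

    blink_times: list[float] = []
    if blink_rate > 0:
        for _ in range(rng.poisson(blink_rate * dur_min)):
            t0 = float(rng.uniform(0.3, recording.duration - 0.3))
            blink_times.append(t0)
            # ~0.4 s Gaussian lobe: spectral content well below 4 Hz
            lobe = np.exp(-0.5 * ((t_axis - t0) / 0.08) ** 2)
            for i, label in enumerate(recording.channel_labels):
                w = _BLINK_TOPOGRAPHY.get(label, 0.5)
                out[i] += blink_amplitude * w * lobe

    emg_bursts: list[tuple[float, float]] = []
    if emg_rms > 0:
        sos = signal.butter(4, 20.0, btype="highpass", fs=fs, output="sos")
        for _ in range(rng.poisson(emg_rate * dur_min)):
            t0 = float(rng.uniform(0.0, recording.duration - emg_burst_duration))
            emg_bursts.append((t0, emg_burst_duration))
            i0 = int(round(t0 * fs))
            i1 = min(i0 + int(round(emg_burst_duration * fs)), n)
            for i in range(recording.n_channels):
                burst = signal.sosfilt(sos, rng.standard_normal(i1 - i0))
                sd = np.std(burst)
                if sd > 0:
                    out[i, i0:i1] += burst * (emg_rms / sd)

    rec = EEGRecording(out, fs, recording.channel_labels, recording.start_time)
    if return_log:
        return rec, ArtifactLog(tuple(blink_times), tuple(emg_bursts))
    return rec
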
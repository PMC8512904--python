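"""Beta-rebound detection: epoch power, threshold calibration, crossings.

The filtered Laplacian signal is squared and averaged over sliding 1 s
epochs updated every 100 ms, giving a band-power trace in µV².  A 5-minute
calibration capture fixes a per-user threshold

    Th = mean + k · sd        (k = 3 by default)

with the sample (n−1) standard deviation.  During a test capture, an
active window counts as a successful motor-imagery attempt the first time
an epoch's power strictly exceeds Th; crossings inside rest (IDLE) windows
are tallied separately as spurious rest activations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .session_protocol import ProtocolSchedule, active_windows, idle_windows

__all__ = [
    "BandPowerSeries",
    "CalibrationThreshold",
    "WindowDetection",
    "DetectionResult",
    "epoch_power",
    "calibrate",
    "detect",
]


@dataclass(frozen=True)
class BandPowerSeries:
    """Sliding-epoch power trace.

    ``times`` are epoch-END timestamps in seconds: the epoch stamped ``t``
    averages the squared samples over ``[t - epoch_len, t)``.
    """

    times: np.ndarray
    power: np.ndarray
    epoch_len: float
    stride: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "power", np.asarray(self.power, dtype=float))
        if self.times.shape != self.power.shape:
            raise ValueError("times and power must have the same length")
        if np.any(self.power < 0):
            raise ValueError("epoch power cannot be negative")
        if len(self.times) > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(steps, self.stride, atol=1e-6):
                raise ValueError("timestamps must increase by exactly the stride")

    def __len__(self) -> int:
        return len(self.power)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time_s": self.times, "power_uv2": self.power}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class CalibrationThreshold:
    """Per-user detection threshold Th = mean + k·sd, in µV²."""

    th: float
    mean: float
    sd: float
    k: float = 3.0
    n_epochs: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd cannot be negative")
        if not np.isclose(self.th, self.mean + self.k * self.sd):
            raise ValueError("threshold must equal mean + k*sd")

    def to_dict(self) -> dict:
        return {
            "th_uv2": self.th,
            "mean_uv2": self.mean,
            "sd_uv2": self.sd,
            "k": self.k,
            "n_epochs": self.n_epochs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationThreshold":
        return cls(
            th=d["th_uv2"], mean=d["mean_uv2"], sd=d["sd_uv2"],
            k=d.get("k", 3.0), n_epochs=d.get("n_epochs", 0),
        )


@dataclass(frozen=True)
class WindowDetection:
    """Outcome for one active window."""

    window: tuple[float, float]
    detected: bool
    first_crossing_time: float | None = None
    latency_ms: float | None = None

    def __post_init__(self) -> None:
        if self.detected:
            dur_ms = (self.window[1] - self.window[0]) * 1000.0
            if self.latency_ms is None or not 0.0 <= self.latency_ms <= dur_ms:
                raise ValueError("detected window needs a latency within the window")


@dataclass(frozen=True)
class DetectionResult:
    windows: tuple[WindowDetection, ...]
    rest_crossing_windows: tuple[int, ...] = ()

    @property
    def n_detected(self) -> int:
        return sum(w.detected for w in self.windows)

    @property
    def latencies_ms(self) -> list[float]:
        return [w.latency_ms for w in self.windows if w.detected]

    def to_dict(self) -> dict:
        return {
            "windows": [
                {
                    "start_s": w.window[0],
                    "end_s": w.window[1],
                    "detected": w.detected,
                    "first_crossing_s": w.first_crossing_time,
                    "latency_ms": w.latency_ms,
                }
                for w in self.windows
            ],
            "rest_crossing_windows": list(self.rest_crossing_windows),
        }


def epoch_power(
    series: np.ndarray,
    fs: float,
    epoch_len: float = 1.0,
    stride: float = 0.1,
    start_time: float = 0.0,
) -> BandPowerSeries:
    """Square-and-average the series over sliding epochs.

    Number of epochs is ``floor((N/fs − epoch_len)/stride) + 1``; each
    epoch value is the mean of squared samples in its window.
    """
    x = np.asarray(series, dtype=float)
    n_epoch = int(round(epoch_len * fs))
    n_stride = int(round(stride * fs))
    if n_epoch < 1 or n_stride < 1:
        raise ValueError("epoch_len and stride must each span at least one sample")
    if x.size < n_epoch:
        raise ValueError(
            f"series of {x.size} samples is shorter than one epoch ({n_epoch})"
        )
    sq = np.square(x)
    csum = np.concatenate(([0.0], np.cumsum(sq)))
    starts = np.arange(0, x.size - n_epoch + 1, n_stride)
    power = (csum[starts + n_epoch] - csum[starts]) / n_epoch
    times = start_time + (starts + n_epoch) / fs
    return BandPowerSeries(times, power, epoch_len, stride)


def calibrate(power: BandPowerSeries, k: float = 3.0) -> CalibrationThreshold:
    """Fit the detection threshold from a calibration power trace."""
    n = len(power)
    if n < 2:
        raise ValueError(f"calibration needs at least 2 epochs, got {n}")
    mean = float(np.mean(power.power))
    sd = float(np.std(power.power, ddof=1))
    return CalibrationThreshold(th=mean + k * sd, mean=mean, sd=sd, k=k, n_epochs=n)


def detect(
    power: BandPowerSeries,
    th: CalibrationThreshold | float,
    schedule: ProtocolSchedule,
) -> DetectionResult:
    """Scan the power trace against the schedule.

    Epoch timestamps mark epoch ENDS.  An epoch is attributed to a window
    only when its data lies fully inside it, ``[t − epoch_len, t] ⊆
    [start, end]``: an epoch straddling a phase boundary mixes rest and
    active data and can report a power excursion that happened entirely in
    the neighboring phase, so straddling epochs count toward no window.
    Per active window only the first strict crossing is kept; idle windows
    containing any crossing are listed by index.
    """
    thr = th.th if isinstance(th, CalibrationThreshold) else float(th)
    end = schedule.phases[-1].end
    if power.times[-1] + power.stride < end - 1e-9:
        raise ValueError(
            f"schedule runs to {end} s but power series ends at {power.times[-1]} s"
        )
    above = power.power > thr
    el = power.epoch_len
    results = []
    for (w0, w1) in active_windows(schedule):
        in_win = (power.times >= w0 + el - 1e-9) & (power.times <= w1 + 1e-9)
        hits = np.flatnonzero(above & in_win)
        if hits.size:
            t_cross = float(power.times[hits[0]])
            results.append(
                WindowDetection((w0, w1), True, t_cross, (t_cross - w0) * 1000.0)
            )
        else:
            results.append(WindowDetection((w0, w1), False))
    rest = []
    for i, (w0, w1) in enumerate(idle_windows(schedule)):
        in_win = (power.times >= w0 + el - 1e-9) & (power.times <= w1 + 1e-9)
        if np.any(above & in_win):
            rest.append(i)
    return DetectionResult(tuple(results), tuple(rest))
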
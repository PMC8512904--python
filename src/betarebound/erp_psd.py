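"""Offline event-related power and spectral-density analysis.

Per channel, the offline path is: zero-phase 0.16 Hz high-pass (drift
removal) → zero-phase 4th-order band-pass over the motor-imagery band
(8–30 Hz) → squaring into instantaneous power → segmentation by the
10 s active windows.  Averaging segments gives P(t); subtracting the mean
power over the last 500 ms of each preceding rest period gives the
baseline-corrected event-related power

    ERP_channel(t) = P(t) − P_baseline .

Spectral densities use Welch's method with 0.5 s Hann windows and 50 %
overlap, normalized so the integral over frequency approximates the
series variance.  Band means over the 8–30 Hz MI band summarize each
channel; both linear (µV²/Hz) and decibel values are reported because the
two conventions are easy to conflate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .preprocessing import FilterMode, MI_BAND, bandpass, highpass, mi_spec
from .recording import EEGRecording
from .session_protocol import PhaseKind, ProtocolSchedule, active_windows

__all__ = ["ERPPower", "PSDEstimate", "compute_erp", "welch", "band_mean",
           "band_mean_table"]

BASELINE_SECONDS = 0.5


@dataclass(frozen=True)
class ERPPower:
    """Baseline-corrected average power trace for one channel."""

    channel: str
    times: np.ndarray            # seconds relative to window onset
    p_t: np.ndarray              # average power across segments, µV²
    p_baseline: float            # mean pre-stimulus power, µV²
    n_segments: int
    segment_means: np.ndarray    # per-segment mean power, µV²
    segment_baselines: np.ndarray

    @property
    def corrected_power(self) -> np.ndarray:
        return self.p_t - self.p_baseline


@dataclass(frozen=True)
class PSDEstimate:
    channel: str
    freqs: np.ndarray
    density_linear: np.ndarray   # µV²/Hz
    window_len: float
    overlap_frac: float

    def __post_init__(self) -> None:
        if np.any(self.density_linear < 0):
            raise ValueError("spectral density cannot be negative")

    @property
    def density_db(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 10.0 * np.log10(self.density_linear)


def compute_erp(
    recording: EEGRecording,
    schedule: ProtocolSchedule,
    band: tuple[float, float] = MI_BAND,
    baseline_seconds: float = BASELINE_SECONDS,
) -> dict[str, ERPPower]:
    """Event-related power per channel over the session's active windows.

    Active windows whose preceding phase is not a rest (IDLE) period of at
    least ``baseline_seconds`` are skipped with a warning.
    """
    import warnings

    actives = active_windows(schedule)
    if not actives:
        raise ValueError("schedule has no active windows")
    fs = recording.fs
    spec = mi_spec(FilterMode.ZERO_PHASE)
    if band != MI_BAND:
        from .preprocessing import FilterSpec

        spec = FilterSpec(band=band, mode=FilterMode.ZERO_PHASE)

    # resolve usable windows once: need >= baseline_seconds of idle before
    usable: list[tuple[float, float]] = []
    for (w0, w1) in actives:
        prev = schedule.phase_at(w0 - 1e-6)
        if prev is None or prev.kind is not PhaseKind.IDLE or \
                w0 - prev.start < baseline_seconds:
            warnings.warn(
                f"active window at {w0:.1f}s lacks a >= {baseline_seconds}s "
                "preceding rest period; skipped in ERP averaging"
            )
            continue
        usable.append((w0, w1))
    if not usable:
        raise ValueError("no active window has a usable pre-stimulus baseline")

    win_len = int(round((usable[0][1] - usable[0][0]) * fs))
    n_base = int(round(baseline_seconds * fs))
    out: dict[str, ERPPower] = {}
    for label in recording.channel_labels:
        x = recording.channel(label) - 0.0
        x = highpass(x, fs, corner=0.16, mode=FilterMode.ZERO_PHASE)
        x = bandpass(x, fs, spec)
        p = np.square(x)
        segs, bases = [], []
        for (w0, w1) in usable:
            i0 = int(round((w0 - recording.start_time) * fs))
            segs.append(p[i0:i0 + win_len])
            bases.append(float(np.mean(p[i0 - n_base:i0])))
        segs = np.vstack(segs)
        p_t = segs.mean(axis=0)
        p_baseline = float(np.mean(bases))
        out[label] = ERPPower(
            channel=label,
            times=np.arange(win_len) / fs,
            p_t=p_t,
            p_baseline=p_baseline,
            n_segments=len(usable),
            segment_means=segs.mean(axis=1),
            segment_baselines=np.asarray(bases),
        )
    return out


def welch(
    series: np.ndarray,
    fs: float,
    window_len: float = 0.5,
    overlap: float = 0.5,
) -> PSDEstimate:
    """Welch spectral density of a 1-D series (Hann window)."""
    x = np.asarray(series, dtype=float)
    nperseg = int(round(window_len * fs))
    if x.size < nperseg:
        raise ValueError(
            f"series of {x.size} samples shorter than one {window_len}s window"
        )
    freqs, pxx = sp_signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)), detrend=False,
        scaling="density",
    )
    return PSDEstimate("", freqs, pxx, window_len, overlap)


def band_mean(psd: PSDEstimate, band: tuple[float, float] = MI_BAND) -> dict:
    """Mean spectral density over a frequency band, linear and dB."""
    low, high = band
    sel = (psd.freqs >= low) & (psd.freqs <= high)
    if not np.any(sel):
        raise ValueError(f"no frequency bins inside band {band}")
    lin = float(np.mean(psd.density_linear[sel]))
    with np.errstate(divide="ignore"):
        db = float(10.0 * np.log10(lin)) if lin > 0 else -np.inf
    return {"linear_uv2_per_hz": lin, "db_per_hz": db}


def band_mean_table(
    recordings: dict[tuple[str, str], EEGRecording],
    schedules: dict[str, ProtocolSchedule],
    band: tuple[float, float] = MI_BAND,
    window_len: float = 0.5,
) -> pd.DataFrame:
    """Per test × subject × channel MI-band PSD means (CSV-ready).

    ``recordings`` maps (test, subject) to a recording; PSDs are computed
    over the concatenated active-window segments of the matching schedule,
    band-filtered as in the ERP path.
    """
    rows = []
    for (test, subject), rec in sorted(recordings.items()):
        sched = schedules[test]
        for label in rec.channel_labels:
            x = highpass(rec.channel(label), rec.fs, corner=0.16,
                         mode=FilterMode.ZERO_PHASE)
            x = bandpass(x, rec.fs, mi_spec())
            pieces = [
                x[int(round(w0 * rec.fs)):int(round(w1 * rec.fs))]
                for (w0, w1) in active_windows(sched)
            ]
            est = welch(np.concatenate(pieces), rec.fs, window_len)
            bm = band_mean(est, band)
            rows.append(
                {"test": test, "subject": subject, "channel": label} | bm
            )
    return pd.DataFrame(rows)
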
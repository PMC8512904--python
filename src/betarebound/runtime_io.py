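"""Streaming session runtime and recording I/O.

``run_session`` replays a recording the way the online system consumed it:
samples arrive in stride-sized chunks, the causal detection path
(Laplacian → beta band-pass → sliding epoch power) updates every 100 ms,
and a logical '1' is emitted whenever the current epoch power exceeds the
calibrated threshold during an active window ('0' otherwise).  A mocked
exoskeleton log records the dorsi-plantarflexion triggers: in BCI mode the
first crossing of each active window, in stationary-therapy (ST) mode a
timer firing every 3 s within active windows regardless of the EEG.

Because the causal filter state is carried across chunks, the streamed
path is sample-for-sample identical to batch filtering, so streamed and
batch detection always agree on the detected-window set.

Recordings round-trip through plain CSV (a time column plus one column
per channel, in µV) and through EDF.  EDF files are read with MNE; they
are written by a small built-in EDF writer (16-bit samples over a
configurable physical range, 1 s data records).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .preprocessing import beta_spec, design_sos, laplacian
from .rebound_detection import CalibrationThreshold, detect
from .recording import EEGRecording
from .session_protocol import PhaseKind, ProtocolSchedule, active_windows

__all__ = [
    "RunMode",
    "CommandStream",
    "DeviceLog",
    "StreamAborted",
    "run_session",
    "detected_window_indices",
    "read_recording",
    "write_recording",
]


class RunMode(str, enum.Enum):
    BCI = "BCI"   # EEG-triggered
    ST = "ST"     # stationary therapy: timer-triggered, EEG ignored


@dataclass(frozen=True)
class CommandStream:
    """Ordered (time, bit) events sent to the device, one per stride."""

    events: tuple[tuple[float, int], ...]
    emit_rate: float

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(b not in (0, 1) for _, b in self.events):
            raise ValueError("command bits must be 0 or 1")
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("command times must be non-decreasing")

    @property
    def ones(self) -> list[float]:
        return [t for t, b in self.events if b == 1]


@dataclass(frozen=True)
class DeviceLog:
    """Times of dorsi-plantarflexion commands executed by the mock device."""

    triggers: tuple[float, ...]
    mode: RunMode


class StreamAborted(RuntimeError):
    """Mid-stream failure (e.g. channel dropout); partial logs attached."""

    def __init__(self, message: str, command_stream: CommandStream,
                 device_log: DeviceLog):
        super().__init__(message)
        self.command_stream = command_stream
        self.device_log = device_log


ST_TRIGGER_PERIOD = 3.0


def run_session(
    recording: EEGRecording,
    schedule: ProtocolSchedule,
    th: CalibrationThreshold | float | None = None,
    mode: RunMode | str = RunMode.BCI,
    epoch_len: float = 1.0,
    stride: float = 0.1,
    center: str = "Cz",
    neighbors: tuple[str, ...] = ("FCz", "C1", "C2", "CPz"),
) -> tuple[CommandStream, DeviceLog]:
    """Stream a recording through the online detection path.

    Returns the command stream (one event per stride outside WAIT) and the
    device log.  In BCI mode a calibrated threshold is required and the
    device triggers once per active window, at the first crossing.
    """
    mode = RunMode(mode)
    if mode is RunMode.BCI and th is None:
        raise ValueError("BCI mode requires a calibrated threshold")
    thr = th.th if isinstance(th, CalibrationThreshold) else th
    fs = recording.fs
    n_stride = int(round(stride * fs))
    n_epoch = int(round(epoch_len * fs))
    if n_stride < 1 or n_epoch < 1:
        raise ValueError("stride and epoch_len must each span >= 1 sample")

    sos = design_sos(beta_spec(), fs)
    zi = np.zeros((sos.shape[0], 2))
    ci = recording.channel_labels.index(center)
    ni = [recording.channel_labels.index(nb) for nb in neighbors]

    actives = active_windows(schedule)
    triggered = [False] * len(actives)
    events: list[tuple[float, int]] = []
    triggers: list[float] = []
    filt_buf = np.empty(recording.n_samples)
    n_filt = 0

    def _window_index(t: float) -> int | None:
        # end-stamped epochs count only when fully inside the window
        for i, (w0, w1) in enumerate(actives):
            if w0 + epoch_len - 1e-9 <= t <= w1 + 1e-9:
                return i
        return None

    if mode is RunMode.ST:
        for (w0, w1) in actives:
            k = 1
            while w0 + k * ST_TRIGGER_PERIOD < w1 - 1e-9:
                triggers.append(w0 + k * ST_TRIGGER_PERIOD)
                k += 1

    pos = 0
    t0 = recording.start_time
    while pos < recording.n_samples:
        chunk = recording.samples[:, pos:pos + n_stride]
        if not np.all(np.isfinite(chunk)):
            raise StreamAborted(
                f"channel dropout at sample {pos} "
                f"(t={t0 + pos / fs:.2f} s): non-finite samples",
                CommandStream(tuple(events), 1.0 / stride),
                DeviceLog(tuple(sorted(triggers)), mode),
            )
        lap = chunk[ci] - chunk[ni].mean(axis=0)
        filt, zi = signal.sosfilt(sos, lap, zi=zi)
        filt_buf[n_filt:n_filt + filt.size] = filt
        n_filt += filt.size
        pos += n_stride

        if n_filt < n_epoch:
            continue
        t_now = t0 + n_filt / fs  # epoch-end timestamp
        phase = schedule.phase_at(t_now - 1e-9)
        if phase is None or phase.kind is PhaseKind.WAIT:
            continue
        power = float(np.mean(np.square(filt_buf[n_filt - n_epoch:n_filt])))
        if mode is RunMode.BCI:
            widx = _window_index(t_now)
            bit = int(widx is not None and power > thr)
            events.append((t_now, bit))
            if bit and not triggered[widx]:
                triggered[widx] = True
                triggers.append(t_now)
        else:
            events.append((t_now, 0))

    return (
        CommandStream(tuple(events), 1.0 / stride),
        DeviceLog(tuple(sorted(triggers)), mode),
    )


def detected_window_indices(
    stream: CommandStream, schedule: ProtocolSchedule
) -> set[int]:
    """Active-window indices that received at least one '1' command."""
    actives = active_windows(schedule)
    out = set()
    for t in stream.ones:
        for i, (w0, w1) in enumerate(actives):
            if w0 < t <= w1 + 1e-9:
                out.add(i)
                break
    return out


def batch_detected_indices(
    recording: EEGRecording,
    schedule: ProtocolSchedule,
    th: CalibrationThreshold | float,
    epoch_len: float = 1.0,
    stride: float = 0.1,
) -> set[int]:
    """Offline reference: full-recording causal path then window scan."""
    from .preprocessing import bandpass
    from .rebound_detection import epoch_power

    lap = laplacian(recording)
    filt = bandpass(lap, recording.fs, beta_spec())
    power = epoch_power(filt, recording.fs, epoch_len, stride,
                        start_time=recording.start_time)
    result = detect(power, th, schedule)
    return {i for i, w in enumerate(result.windows) if w.detected}


# ---------------------------------------------------------------------------
# Recording file formats
# ---------------------------------------------------------------------------

def write_recording(
    recording: EEGRecording,
    path,
    fmt: str | None = None,
    physical_range: tuple[float, float] = (-200.0, 200.0),
) -> None:
    """Write a recording as CSV or EDF (inferred from the suffix)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        df = pd.DataFrame(recording.samples.T, columns=recording.channel_labels)
        df.insert(0, "time_s", recording.times)
        df.to_csv(path, index=False, float_format="%.9f")
    elif fmt == "edf":
        _write_edf(recording, path, physical_range)
    else:
        raise ValueError(f"unknown recording format {fmt!r}")


def read_recording(
    path,
    fmt: str | None = None,
    require_channels: tuple[str, ...] | None = None,
) -> EEGRecording:
    """Read a CSV or EDF recording back into memory (samples in µV)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise ValueError("CSV recording must contain a 'time_s' column")
        t = df["time_s"].to_numpy()
        steps = np.diff(t)
        if len(steps) == 0 or np.ptp(steps) > 1e-6 * steps[0] + 1e-12:
            raise ValueError("CSV time column is not uniformly sampled")
        fs = 1.0 / float(np.median(steps))
        labels = tuple(c for c in df.columns if c != "time_s")
        rec = EEGRecording(
            df[list(labels)].to_numpy().T, fs, labels, start_time=float(t[0])
        )
    elif fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        rec = EEGRecording(
            raw.get_data() * 1e6,  # volts → µV
            float(raw.info["sfreq"]),
            tuple(raw.ch_names),
        )
    else:
        raise ValueError(f"unknown recording format {fmt!r}")
    if require_channels:
        missing = [c for c in require_channels if c not in rec.channel_labels]
        if missing:
            raise ValueError(f"recording is missing required channel(s): {missing}")
    return rec


def _edf_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field {value!r} exceeds {width} bytes")
    return b.ljust(width)


def _write_edf(
    recording: EEGRecording,
    path: Path,
    physical_range: tuple[float, float],
) -> None:
    """Minimal EDF writer: 16-bit samples, 1 s data records, zero-padded tail.

    Samples are linearly mapped from ``physical_range`` (µV) onto the full
    digital range, so the quantization step is span / 65535 µV.
    """
    pmin, pmax = physical_range
    data = recording.samples
    if data.min() < pmin or data.max() > pmax:
        raise ValueError(
            f"samples outside the physical range {physical_range}; "
            "widen the range or rescale"
        )
    fs = recording.fs
    spr = int(round(fs))  # samples per 1 s record
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch = recording.n_channels
    n_rec = int(np.ceil(recording.n_samples / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, : recording.n_samples] = data

    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((padded - pmin) * scale + dmin).astype("<i2")

    hdr = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate X X X X", 80),
            _edf_field("01.01.01", 8),
            _edf_field("00.00.00", 8),
            _edf_field(str(256 * (1 + n_ch)), 8),
            _edf_field("", 44),
            _edf_field(str(n_rec), 8),
            _edf_field("1", 8),
            _edf_field(str(n_ch), 4),
        ]
    )

    def sig(field: str, width: int) -> bytes:
        return b"".join(_edf_field(field.format(ch=ch), width)
                        for ch in recording.channel_labels)

    hdr += sig("{ch}", 16)
    hdr += sig("", 80)                       # transducer
    hdr += sig("uV", 8)                      # physical dimension
    hdr += sig(f"{pmin:g}", 8)
    hdr += sig(f"{pmax:g}", 8)
    hdr += sig(str(dmin), 8)
    hdr += sig(str(dmax), 8)
    hdr += sig("", 80)                       # prefiltering
    hdr += sig(str(spr), 8)
    hdr += sig("", 32)                       # reserved

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())
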
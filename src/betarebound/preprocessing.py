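"""Spatial and spectral filtering.

The online detection path applies a small-Laplacian spatial filter around
Cz followed by a causal 4th-order band-pass in the beta band (16–24 Hz).
The offline ERP/PSD path uses zero-phase (forward–backward) filtering so
that power excursions stay aligned with their stimuli: a 0.16 Hz high-pass
removes slow drifts before the 8–30 Hz motor-imagery band-pass.

"4th-order" refers to the design order of the band-pass prototype; the
realized transfer function has twice as many poles, as is conventional.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import EEGRecording

__all__ = [
    "FilterFamily",
    "FilterMode",
    "FilterSpec",
    "BETA_BAND",
    "MI_BAND",
    "beta_spec",
    "mi_spec",
    "design_sos",
    "laplacian",
    "bandpass",
    "highpass",
    "frequency_response_db",
]

BETA_BAND = (16.0, 24.0)
MI_BAND = (8.0, 30.0)


class FilterFamily(str, enum.Enum):
    BUTTERWORTH = "BUTTERWORTH"
    CHEBYSHEV1 = "CHEBYSHEV1"


class FilterMode(str, enum.Enum):
    CAUSAL = "CAUSAL"       # forward-only recursion, online path
    ZERO_PHASE = "ZERO_PHASE"  # forward-backward, offline path


@dataclass(frozen=True)
class FilterSpec:
    """IIR filter description.

    ``band`` is ``(low, high)`` in Hz for a band-pass, or a single corner
    frequency for a high-pass.  ``ripple_db`` only applies to Chebyshev-I
    (a Butterworth response is maximally flat and has no ripple parameter).
    """

    family: FilterFamily = FilterFamily.BUTTERWORTH
    order: int = 4
    band: tuple[float, float] | float = BETA_BAND
    ripple_db: float | None = None
    mode: FilterMode = FilterMode.CAUSAL

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"filter order must be >= 1, got {self.order}")
        if isinstance(self.band, tuple):
            low, high = self.band
            if not 0 < low < high:
                raise ValueError(f"need 0 < low < high, got band {self.band}")
        elif self.band <= 0:
            raise ValueError(f"corner frequency must be positive, got {self.band}")
        if self.family is FilterFamily.CHEBYSHEV1 and self.ripple_db is None:
            object.__setattr__(self, "ripple_db", 0.5)

    @property
    def btype(self) -> str:
        return "bandpass" if isinstance(self.band, tuple) else "highpass"


def beta_spec(mode: FilterMode = FilterMode.CAUSAL) -> FilterSpec:
    """Default online beta-band filter: 4th-order Butterworth, 16–24 Hz."""
    return FilterSpec(band=BETA_BAND, mode=mode)


def mi_spec(mode: FilterMode = FilterMode.ZERO_PHASE) -> FilterSpec:
    """Offline motor-imagery band filter: 4th-order Butterworth, 8–30 Hz."""
    return FilterSpec(band=MI_BAND, mode=mode)


def design_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    """Design the filter as second-order sections for the given rate."""
    nyq = fs / 2.0
    wn = (
        np.asarray(spec.band, dtype=float)
        if isinstance(spec.band, tuple)
        else float(spec.band)
    )
    if np.any(np.asarray(wn) >= nyq):
        raise ValueError(
            f"filter band {spec.band} reaches the Nyquist frequency {nyq} Hz"
        )
    if spec.family is FilterFamily.BUTTERWORTH:
        return signal.butter(spec.order, wn, btype=spec.btype, fs=fs, output="sos")
    return signal.cheby1(
        spec.order, spec.ripple_db, wn, btype=spec.btype, fs=fs, output="sos"
    )


def _apply(sos: np.ndarray, x: np.ndarray, mode: FilterMode) -> np.ndarray:
    if mode is FilterMode.ZERO_PHASE:
        return signal.sosfiltfilt(sos, x)
    return signal.sosfilt(sos, x)


def laplacian(
    recording: EEGRecording,
    center: str = "Cz",
    neighbors: tuple[str, ...] = ("FCz", "C1", "C2", "CPz"),
) -> np.ndarray:
    """Small-Laplacian spatial filter: center minus the mean of its neighbors.

    Sharpens local cortical activity under the center electrode by
    rejecting activity common to the surrounding montage.
    """
    out = recording.channel(center).astype(float).copy()
    out -= np.mean([recording.channel(nb) for nb in neighbors], axis=0)
    return out


def bandpass(series: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Band-pass filter a 1-D series; defaults to the causal beta-band spec."""
    if spec is None:
        spec = beta_spec()
    if spec.btype != "bandpass":
        raise ValueError("bandpass() requires a (low, high) band in the spec")
    sos = design_sos(spec, fs)
    return _apply(sos, np.asarray(series, dtype=float), spec.mode)


def highpass(
    series: np.ndarray,
    fs: float,
    corner: float = 0.16,
    order: int = 2,
    mode: FilterMode = FilterMode.ZERO_PHASE,
) -> np.ndarray:
    """High-pass filter removing slow drifts (default corner 0.16 Hz)."""
    spec = FilterSpec(order=order, band=float(corner), mode=mode)
    sos = design_sos(spec, fs)
    return _apply(sos, np.asarray(series, dtype=float), mode)


def frequency_response_db(
    spec: FilterSpec, fs: float, freqs: np.ndarray
) -> np.ndarray:
    """Realized magnitude response in dB at the given frequencies.

    Zero-phase mode doubles the attenuation (the filter is applied twice).
    """
    sos = design_sos(spec, fs)
    _, h = signal.sosfreqz(sos, worN=np.asarray(freqs, dtype=float), fs=fs)
    mag = np.abs(h)
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(mag)
    if spec.mode is FilterMode.ZERO_PHASE:
        db = 2.0 * db
    return db
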
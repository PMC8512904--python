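"""Multichannel EEG recording container.

Samples are stored channels × time in microvolts.  The default montage is
the small Laplacian cluster used for foot motor imagery: Cz surrounded by
FCz, C1, C2 and CPz, sampled at 500 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EEGRecording", "DEFAULT_CHANNELS", "DEFAULT_FS"]

DEFAULT_CHANNELS = ("FCz", "C1", "Cz", "C2", "CPz")
DEFAULT_FS = 500.0


@dataclass
class EEGRecording:
    """EEG time series: ``samples[i, t]`` is channel i at sample t, in µV."""

    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels × time array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channel rows"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's samples by label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in recording "
                f"(have {list(self.channel_labels)})"
            ) from None
        return self.samples[idx]

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            self.samples.copy(), self.fs, self.channel_labels, self.start_time
        )
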
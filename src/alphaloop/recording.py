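"""Multichannel EEG container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import MONTAGE_16


@dataclass
class EEGRecording:
    """A multichannel sampled EEG signal in microvolts.

    Parameters
    ----------
    channel_names
        Ordered 10-20 labels, a subset of the 16-channel montage.
    fs
        Sampling rate in Hz. Must exceed twice the upper passband edge.
    data
        Array of shape ``(n_channels, n_samples)``, microvolts.
    band
        Effective acquisition passband in Hz (high-pass, low-pass).
    """

    channel_names: tuple[str, ...]
    fs: float
    data: np.ndarray
    band: tuple[float, float] = (2.0, 30.0)

    def __post_init__(self) -> None:
        self.channel_names = tuple(self.channel_names)
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        unknown = set(self.channel_names) - set(MONTAGE_16)
        if unknown:
            raise ValueError(f"labels outside the 16-channel montage: {sorted(unknown)}")
        if not self.fs > 2 * self.band[1]:
            raise ValueError(
                f"fs={self.fs} must exceed twice the upper passband edge {self.band[1]}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, names: tuple[str, ...] | list[str]) -> np.ndarray:
        """Indices of `names` in this recording's channel order."""
        lookup = {c: i for i, c in enumerate(self.channel_names)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"channels not in recording: {missing}")
        return np.array([lookup[n] for n in names], dtype=int)

    def pick(self, names: tuple[str, ...] | list[str]) -> "EEGRecording":
        idx = self.channel_index(names)
        return EEGRecording(tuple(names), self.fs, self.data[idx].copy(), self.band)

    def copy(self) -> "EEGRecording":
        return EEGRecording(self.channel_names, self.fs, self.data.copy(), self.band)
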
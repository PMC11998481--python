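"""Multichannel time-series container (simulated or loaded EEG)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import Montage

__all__ = ["Recording"]


@dataclass
class Recording:
    """channels x samples matrix with sampling rate, labels and montage."""

    data: np.ndarray
    fs: float
    labels: list[str]
    montage: Montage

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("channel labels must be unique")
        if self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but {len(self.labels)} labels"
            )
        missing = [l for l in self.labels if l not in self.montage]
        if missing:
            raise ValueError(f"montage is missing channels: {missing}")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no such channel: {label!r}") from None
        return self.data[idx]
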
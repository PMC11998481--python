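"""Uniformly sampled 1-D traces (audio, envelopes, continuous surprisal)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ContinuousSignal"]


@dataclass
class ContinuousSignal:
    """A real-valued trace sampled at ``fs`` Hz starting at time ``t0``."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def copy_with(self, samples: np.ndarray, fs: float | None = None) -> "ContinuousSignal":
        return ContinuousSignal(samples=samples, fs=self.fs if fs is None else fs, t0=self.t0)
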
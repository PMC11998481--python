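"""Electrode montages.

The template is the standard 32-channel 10-20 layout (BioSemi cap ordering)
taken from mne's built-in montage definitions; it can be exported to / loaded
from a small JSON file of ``{label: [x, y, z]}`` positions in meters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

__all__ = ["Montage", "template_montage_32"]


@dataclass
class Montage:
    """Channel label -> 3-D position (meters, head-centered)."""

    positions: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        if len(self.positions) != len(set(self.positions)):
            raise ValueError("montage labels must be unique")
        for label, pos in self.positions.items():
            if not np.all(np.isfinite(pos)) or len(pos) != 3:
                raise ValueError(f"invalid position for channel {label!r}: {pos}")
        self.positions = {k: tuple(float(c) for c in v) for k, v in self.positions.items()}

    @property
    def labels(self) -> list[str]:
        return list(self.positions)

    def __len__(self) -> int:
        return len(self.positions)

    def __contains__(self, label: str) -> bool:
        return label in self.positions

    def array(self, labels: list[str] | None = None) -> np.ndarray:
        labels = self.labels if labels is None else labels
        missing = [l for l in labels if l not in self.positions]
        if missing:
            raise KeyError(f"montage is missing channels: {missing}")
        return np.array([self.positions[l] for l in labels], dtype=float)

    def to_json(self, path: str | Path) -> None:
        payload = [{"label": l, "x": p[0], "y": p[1], "z": p[2]} for l, p in self.positions.items()]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Montage":
        payload = json.loads(Path(path).read_text())
        return cls({d["label"]: (d["x"], d["y"], d["z"]) for d in payload})


@lru_cache(maxsize=1)
def template_montage_32() -> Montage:
    """The 32-channel 10-20 template montage (includes the Cz reference site)."""
    import mne

    std = mne.channels.make_standard_montage("biosemi32")
    pos = std.get_positions()["ch_pos"]
    return Montage({label: tuple(map(float, xyz)) for label, xyz in pos.items()})
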
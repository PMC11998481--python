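"""Symbolic note material: timed, pitched, voiced events.

`NoteSequence` is the common currency between the stimulus generators and the
surprisal model: a flat, onset-sorted list of notes with tempo and meter
metadata. Durations are in seconds, pitches are integer MIDI numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = ["NoteEvent", "NoteSequence", "MELODY", "BASS"]

MELODY = "melody"
BASS = "bass"


@dataclass(frozen=True)
class NoteEvent:
    """A single note: onset and duration in seconds, MIDI pitch, voice label."""

    onset: float
    duration: float
    pitch: int
    voice: str = MELODY

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if not (0 <= int(self.pitch) <= 127):
            raise ValueError(f"pitch must be a MIDI number in 0..127, got {self.pitch}")


@dataclass
class NoteSequence:
    """Ordered polyphonic note list with tempo (quarter-note bpm) and meter."""

    events: list[NoteEvent] = field(default_factory=list)
    tempo: float = 120.0
    meter: tuple[int, int] = (4, 4)

    def __post_init__(self) -> None:
        if self.tempo <= 0:
            raise ValueError(f"tempo must be > 0, got {self.tempo}")
        self.events = sorted(self.events, key=lambda e: (e.onset, e.voice, e.pitch))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def duration(self) -> float:
        """Total span in seconds (end of the last-sounding note)."""
        if not self.events:
            return 0.0
        return max(e.onset + e.duration for e in self.events)

    @property
    def voices(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.events:
            seen.setdefault(e.voice, None)
        return list(seen)

    def voice_events(self, voice: str) -> list[NoteEvent]:
        return [e for e in self.events if e.voice == voice]

    def to_monophonic(self, voice: str) -> "NoteSequence":
        """Reduce one voice to a strictly monophonic line.

        Where several notes of the voice share an onset, the melody keeps the
        highest pitch and any other voice (the bass line) keeps the lowest.
        """
        events = self.voice_events(voice)
        by_onset: dict[float, list[NoteEvent]] = {}
        for e in events:
            by_onset.setdefault(round(e.onset, 9), []).append(e)
        pick = max if voice == MELODY else min
        mono = [pick(group, key=lambda e: e.pitch) for group in by_onset.values()]
        return NoteSequence(events=mono, tempo=self.tempo, meter=self.meter)

    def transpose_map(self, shifts: Iterable[int]) -> "NoteSequence":
        """New sequence with per-event semitone shifts, timing untouched."""
        new = [replace(e, pitch=e.pitch + s) for e, s in zip(self.events, shifts, strict=True)]
        return NoteSequence(events=new, tempo=self.tempo, meter=self.meter)


def pitches(events: Sequence[NoteEvent]) -> list[int]:
    return [e.pitch for e in events]
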
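"""File formats: note lists, tapping logs, covariates, recordings, WAV.

All interchange formats are plain text: note lists and tap logs are TSV,
recordings are a delimited sample matrix plus a montage JSON, models and
cluster results are JSON. EDF recordings are read through mne when given an
``.edf`` path. A minimal standard-MIDI reader (type 0/1, note-on/off only,
single tempo, monophonic-per-track assumption) covers symbolic imports.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import Montage
from .notes import BASS, MELODY, NoteEvent, NoteSequence
from .recording import Recording
from .signals import ContinuousSignal
from .synth import TappingTrial

__all__ = [
    "read_notes",
    "write_notes",
    "read_midi",
    "read_taps",
    "write_taps",
    "read_covariates",
    "read_recording",
    "write_recording",
    "read_wav",
    "write_wav",
]

NOTE_COLUMNS = ["onset_s", "duration_s", "midi_pitch", "voice"]
TAP_COLUMNS = ["participant", "condition", "trial", "tap_time_s"]


# ---------------------------------------------------------------------------
# Note lists
# ---------------------------------------------------------------------------

def write_notes(seq: NoteSequence, path: str | Path) -> None:
    frame = pd.DataFrame(
        [(e.onset, e.duration, e.pitch, e.voice) for e in seq.events], columns=NOTE_COLUMNS
    )
    with open(path, "w") as fh:
        fh.write(f"# tempo_bpm={seq.tempo}\tmeter={seq.meter[0]}/{seq.meter[1]}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_notes(path: str | Path) -> NoteSequence:
    tempo, meter = 120.0, (4, 4)
    lines = Path(path).read_text().splitlines()
    start = 0
    if lines and lines[0].startswith("#"):
        for token in lines[0][1:].split("\t"):
            key, _, val = token.strip().partition("=")
            if key == "tempo_bpm":
                tempo = float(val)
            elif key == "meter":
                a, _, b = val.partition("/")
                meter = (int(a), int(b))
        start = 1
    header = lines[start].split("\t")
    if header != NOTE_COLUMNS:
        raise ValueError(f"{path}: expected header {NOTE_COLUMNS}, got {header}")
    events = []
    for lineno, line in enumerate(lines[start + 1 :], start=start + 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        try:
            events.append(
                NoteEvent(
                    onset=float(parts[0]),
                    duration=float(parts[1]),
                    pitch=int(parts[2]),
                    voice=parts[3],
                )
            )
        except (IndexError, ValueError) as err:
            raise ValueError(f"{path}: malformed note row at line {lineno}: {err}") from None
    return NoteSequence(events=events, tempo=tempo, meter=meter)


# ---------------------------------------------------------------------------
# Minimal standard MIDI import
# ---------------------------------------------------------------------------

def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos


def _parse_track(data: bytes, ticks_per_quarter: int):
    """note (tick_on, tick_off, pitch) triples and tempo events of one track."""
    pos, notes, tempos = 0, [], []
    active: dict[int, int] = {}
    tick = 0
    status = 0
    while pos < len(data):
        delta, pos = _read_varlen(data, pos)
        tick += delta
        byte = data[pos]
        if byte & 0x80:
            status = byte
            pos += 1
        kind = status & 0xF0
        if status == 0xFF:  # meta
            meta = data[pos]
            length, pos2 = _read_varlen(data, pos + 1)
            payload = data[pos2 : pos2 + length]
            if meta == 0x51:
                tempos.append((tick, int.from_bytes(payload, "big")))
            pos = pos2 + length
        elif status in (0xF0, 0xF7):  # sysex
            length, pos2 = _read_varlen(data, pos)
            pos = pos2 + length
        elif kind in (0x80, 0x90):
            pitch, vel = data[pos], data[pos + 1]
            pos += 2
            if kind == 0x90 and vel > 0:
                active[pitch] = tick
            else:
                if pitch in active:
                    notes.append((active.pop(pitch), tick, pitch))
        elif kind in (0xA0, 0xB0, 0xE0):
            pos += 2
        elif kind in (0xC0, 0xD0):
            pos += 1
        else:
            raise ValueError(f"unsupported MIDI event 0x{status:02x}")
    return notes, tempos


def read_midi(path: str | Path) -> NoteSequence:
    """Type-0/1 standard MIDI import with a monophonic-per-track assumption.

    The first tempo event (default 120 bpm) is applied globally. With two or
    more note-carrying tracks, the track with the higher mean pitch becomes
    the melody and the lowest becomes the bass; a single track maps to the
    melody.
    """
    raw = Path(path).read_bytes()
    if raw[:4] != b"MThd":
        raise ValueError(f"{path}: not a standard MIDI file")
    _, fmt, ntrks, division = struct.unpack(">IHHH", raw[4:14])
    if division & 0x8000:
        raise ValueError("SMPTE time division is not supported")
    pos = 14
    tracks = []
    tempo_us = 500000
    tempo_seen = False
    for _ in range(ntrks):
        if raw[pos : pos + 4] != b"MTrk":
            raise ValueError(f"{path}: malformed track chunk at byte {pos}")
        (length,) = struct.unpack(">I", raw[pos + 4 : pos + 8])
        notes, tempos = _parse_track(raw[pos + 8 : pos + 8 + length], division)
        if tempos and not tempo_seen:
            tempo_us = tempos[0][1]
            tempo_seen = True
        if notes:
            tracks.append(notes)
        pos += 8 + length
    if not tracks:
        raise ValueError(f"{path}: no notes found")
    sec_per_tick = tempo_us / 1e6 / division
    mean_pitch = [float(np.mean([p for _, _, p in t])) for t in tracks]
    order = np.argsort(mean_pitch)[::-1]
    events = []
    for rank, t_idx in enumerate(order):
        voice = MELODY if rank == 0 else BASS
        for on, off, pitch in tracks[t_idx]:
            dur = max((off - on) * sec_per_tick, 1e-3)
            events.append(
                NoteEvent(onset=on * sec_per_tick, duration=dur, pitch=pitch, voice=voice)
            )
    return NoteSequence(events=events, tempo=60e6 / tempo_us)


# ---------------------------------------------------------------------------
# Tapping logs and covariates
# ---------------------------------------------------------------------------

def write_taps(trials: list[TappingTrial], path: str | Path) -> None:
    rows = [
        (tr.participant, tr.condition, i, t)
        for i, tr in enumerate(trials)
        for t in tr.tap_times
    ]
    pd.DataFrame(rows, columns=TAP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_taps(path: str | Path) -> list[TappingTrial]:
    frame = pd.read_csv(path, sep="\t")
    missing = set(TAP_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    trials = []
    for (participant, condition, trial), grp in frame.groupby(
        ["participant", "condition", "trial"], sort=False
    ):
        taps = np.sort(grp["tap_time_s"].to_numpy(dtype=float))
        trials.append(
            TappingTrial(
                tap_times=taps,
                trial_length=float(taps[-1]) if taps.size else 0.0,
                condition=str(condition),
                participant=str(participant),
            )
        )
    return trials


def read_covariates(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    if "participant" not in frame.columns:
        raise ValueError(f"{path}: covariate table needs a 'participant' column")
    return frame.set_index("participant")


# ---------------------------------------------------------------------------
# Surprisal traces
# ---------------------------------------------------------------------------

def write_surprisal(trace, seq: NoteSequence, path: str | Path) -> None:
    """Per-note IC as TSV: note_index, onset_s, duration_s, ic_bits, voice."""
    mono = seq.to_monophonic(trace.voice)
    rows = [
        (i, e.onset, e.duration, ic, trace.voice)
        for i, (e, ic) in enumerate(zip(mono.events, trace.per_note_ic))
    ]
    pd.DataFrame(
        rows, columns=["note_index", "onset_s", "duration_s", "ic_bits", "voice"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, data_path: str | Path, montage_path: str | Path) -> None:
    """Delimited sample matrix (channels as columns) + montage JSON."""
    with open(data_path, "w") as fh:
        fh.write(f"# fs_hz={rec.fs}\n")
        pd.DataFrame(rec.data.T, columns=rec.labels).to_csv(
            fh, sep="\t", index=False, float_format="%.10g"
        )
    rec.montage.to_json(montage_path)


def read_recording(data_path: str | Path, montage_path: str | Path) -> Recording:
    """Read a recording from a delimited matrix or an EDF file.

    The montage JSON must cover every channel; a missing channel raises an
    error naming it.
    """
    montage = Montage.from_json(montage_path)
    data_path = Path(data_path)
    if data_path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(data_path, preload=True, verbose="error")
        labels = list(raw.ch_names)
        data, fs = raw.get_data(), float(raw.info["sfreq"])
    else:
        with open(data_path) as fh:
            first = fh.readline()
            if not first.startswith("# fs_hz="):
                raise ValueError(f"{data_path}: expected a '# fs_hz=' header line")
            fs = float(first.split("=", 1)[1])
            frame = pd.read_csv(fh, sep="\t")
        labels = list(frame.columns)
        data = frame.to_numpy(dtype=float).T
    for label in labels:
        if label not in montage:
            raise ValueError(f"montage is missing channel {label!r}")
    return Recording(data=data, fs=fs, labels=labels, montage=montage)


# ---------------------------------------------------------------------------
# WAV
# ---------------------------------------------------------------------------

def read_wav(path: str | Path) -> ContinuousSignal:
    from scipy.io import wavfile

    fs, raw = wavfile.read(path)
    data = np.asarray(raw, dtype=float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(np.asarray(raw).dtype, np.integer):
        data = data / np.iinfo(np.asarray(raw).dtype).max
    return ContinuousSignal(samples=data, fs=float(fs))


def write_wav(signal: ContinuousSignal, path: str | Path) -> None:
    from scipy.io import wavfile

    peak = np.max(np.abs(signal.samples)) or 1.0
    wavfile.write(path, int(signal.fs), (signal.samples / peak).astype(np.float32))
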
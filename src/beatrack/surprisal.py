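"""Melodic surprisal: a simplified variable-order Markov predictor.

The model follows the IDyOM architecture in outline: a long-term component
(LTM) whose n-gram statistics are collected over a training corpus, and a
short-term component (STM) that accumulates the same statistics online within
the piece being scored. Both components turn counts into a predictive
distribution by interpolated back-off with PPM escape method C: at each
context length the observed symbols receive ``c / (t + e)`` and the escape
mass ``e / (t + e)`` (``t`` total count, ``e`` distinct continuations) is
passed to the next-shorter context, bottoming out at a uniform distribution
over the alphabet — so no symbol ever has zero probability. The two
components are merged by an entropy-weighted geometric combination (weights
proportional to ``1 / (H + 1)``: the more confident component dominates).

Surprisal (information content) of a note is ``-log2 P(note | merged)``, in
bits; the per-note values are expanded into a continuous signal by holding
each value over its note's duration and smoothing with a unit-area Gaussian
kernel.

Viewpoints: ``"pitch"`` scores MIDI pitch numbers; ``"onset-interval"``
scores inter-onset intervals (rounded to ms), the control viewpoint for note
timing rather than pitch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .notes import MELODY, NoteSequence
from .signals import ContinuousSignal

__all__ = [
    "PredictiveModel",
    "SurprisalTrace",
    "CountTables",
    "viewpoint_symbols",
    "train_ltm",
    "predict_next",
    "note_surprisal",
    "continuous_surprisal",
]

Symbol = Hashable
VIEWPOINTS = ("pitch", "onset-interval")


class CountTables:
    """n-gram counts for context lengths 0..max_order."""

    def __init__(self, max_order: int):
        if max_order < 0:
            raise ValueError("max_order must be >= 0")
        self.max_order = max_order
        self.tables: list[dict[tuple, dict[Symbol, int]]] = [
            {} for _ in range(max_order + 1)
        ]

    def add_sequence(self, symbols: Sequence[Symbol]) -> None:
        for i, sym in enumerate(symbols):
            self.add_event(symbols[:i], sym)

    def add_event(self, context: Sequence[Symbol], sym: Symbol) -> None:
        for k in range(min(self.max_order, len(context)) + 1):
            ctx = tuple(context[len(context) - k :])
            slot = self.tables[k].setdefault(ctx, {})
            slot[sym] = slot.get(sym, 0) + 1

    def get(self, k: int, context: tuple) -> dict[Symbol, int] | None:
        return self.tables[k].get(context)


@dataclass
class PredictiveModel:
    """Corpus-trained LTM counts plus smoothing/merging configuration."""

    ltm: CountTables
    alphabet: list[Symbol]
    max_order: int = 3
    viewpoint: str = "pitch"
    escape: str = "C"
    merge_rule: str = "entropy-weighted-geometric"

    def save(self, path: str | Path) -> None:
        payload = {
            "max_order": self.max_order,
            "viewpoint": self.viewpoint,
            "escape": self.escape,
            "merge_rule": self.merge_rule,
            "alphabet": list(self.alphabet),
            "tables": [
                {json.dumps(list(ctx)): counts for ctx, counts in table.items()}
                for table in self.ltm.tables
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "PredictiveModel":
        payload = json.loads(Path(path).read_text())
        ltm = CountTables(payload["max_order"])
        ltm.tables = [
            {tuple(json.loads(ctx)): {int(s): c for s, c in counts.items()}
             for ctx, counts in table.items()}
            for table in payload["tables"]
        ]
        return cls(
            ltm=ltm,
            alphabet=[int(s) for s in payload["alphabet"]],
            max_order=payload["max_order"],
            viewpoint=payload["viewpoint"],
            escape=payload["escape"],
            merge_rule=payload["merge_rule"],
        )


@dataclass
class SurprisalTrace:
    """Per-note information content in bits, aligned to the scored voice."""

    per_note_ic: np.ndarray
    voice: str = MELODY
    viewpoint: str = "pitch"

    def __post_init__(self) -> None:
        self.per_note_ic = np.asarray(self.per_note_ic, dtype=float)
        if np.any(self.per_note_ic < 0):
            raise ValueError("information content must be >= 0")

    def __len__(self) -> int:
        return self.per_note_ic.size


# ---------------------------------------------------------------------------
# Viewpoints
# ---------------------------------------------------------------------------

def viewpoint_symbols(seq: NoteSequence, voice: str, viewpoint: str) -> list[Symbol]:
    """Symbol sequence of one monophonic voice under a viewpoint.

    ``pitch``: MIDI numbers. ``onset-interval``: inter-onset intervals in
    integer milliseconds; the first note takes the interval from time zero.
    """
    mono = seq.to_monophonic(voice)
    if viewpoint == "pitch":
        return [e.pitch for e in mono.events]
    if viewpoint == "onset-interval":
        onsets = [e.onset for e in mono.events]
        prev = [0.0] + onsets[:-1]
        return [int(round((o - p) * 1000)) for o, p in zip(onsets, prev)]
    raise ValueError(f"unknown viewpoint {viewpoint!r}; choose from {VIEWPOINTS}")


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

def train_ltm(
    corpus: list[NoteSequence],
    max_order: int = 3,
    viewpoint: str = "pitch",
    *,
    voice: str = MELODY,
) -> PredictiveModel:
    """Collect LTM n-gram statistics over a corpus of (monophonic) melodies."""
    if not corpus:
        raise ValueError("training corpus must be non-empty")
    ltm = CountTables(max_order)
    alphabet: dict[Symbol, None] = {}
    for seq in corpus:
        symbols = viewpoint_symbols(seq, voice, viewpoint)
        ltm.add_sequence(symbols)
        for s in symbols:
            alphabet.setdefault(s, None)
    return PredictiveModel(
        ltm=ltm, alphabet=list(alphabet), max_order=max_order, viewpoint=viewpoint
    )


def _ppm_distribution(
    counts: CountTables, context: Sequence[Symbol], alphabet: list[Symbol]
) -> np.ndarray:
    """Interpolated escape-C back-off distribution over ``alphabet``."""
    n = len(alphabet)
    index = {s: i for i, s in enumerate(alphabet)}
    p = np.full(n, 1.0 / n)
    for k in range(min(counts.max_order, len(context)) + 1):
        ctx = tuple(context[len(context) - k :])
        slot = counts.get(k, ctx)
        if not slot:
            continue
        t = sum(slot.values())
        e = len(slot)
        blended = (e / (t + e)) * p
        for sym, c in slot.items():
            if sym in index:  # counts for out-of-alphabet symbols stay in escape mass
                blended[index[sym]] += c / (t + e)
        p = blended / blended.sum()
    return p


def _entropy(p: np.ndarray) -> float:
    return float(-np.sum(p * np.log2(np.maximum(p, 1e-300))))


def _merge(distributions: list[np.ndarray]) -> np.ndarray:
    """Entropy-weighted geometric combination, renormalized."""
    weights = np.array([1.0 / (_entropy(p) + 1.0) for p in distributions])
    weights = weights / weights.sum()
    logp = sum(w * np.log(np.maximum(p, 1e-300)) for w, p in zip(weights, distributions))
    merged = np.exp(logp - logp.max())
    return merged / merged.sum()


def predict_next(
    model: PredictiveModel,
    context: Sequence[Symbol],
    stm_counts: CountTables | None = None,
    *,
    alphabet: list[Symbol] | None = None,
) -> dict[Symbol, float]:
    """Merged LTM+STM predictive distribution given a context.

    All alphabet symbols receive strictly positive probability; the
    distribution sums to one to machine precision.
    """
    alpha = list(alphabet) if alphabet is not None else list(model.alphabet)
    ltm_p = _ppm_distribution(model.ltm, context, alpha)
    if stm_counts is None:
        merged = ltm_p
    else:
        stm_p = _ppm_distribution(stm_counts, context, alpha)
        merged = _merge([ltm_p, stm_p])
    return dict(zip(alpha, merged))


def note_surprisal(
    model: PredictiveModel,
    seq: NoteSequence,
    viewpoint: str | None = None,
    *,
    voice: str = MELODY,
    use_stm: bool = True,
) -> SurprisalTrace:
    """Per-note information content of one voice under the merged model.

    The voice is reduced to a monophonic line first (highest pitch per onset
    for the melody, lowest for the bass). The STM starts empty and is updated
    incrementally after each note, as in online prediction.
    """
    viewpoint = viewpoint or model.viewpoint
    symbols = viewpoint_symbols(seq, voice, viewpoint)
    # the effective alphabet covers training plus test symbols, so every
    # ground-truth note has positive probability
    alpha = list(dict.fromkeys(list(model.alphabet) + symbols))
    stm = CountTables(model.max_order) if use_stm else None
    ic = np.empty(len(symbols))
    for i, sym in enumerate(symbols):
        dist = predict_next(model, symbols[:i], stm, alphabet=alpha)
        ic[i] = -math.log2(dist[sym])
        if stm is not None:
            stm.add_event(symbols[:i], sym)
    return SurprisalTrace(per_note_ic=ic, voice=voice, viewpoint=viewpoint)


# ---------------------------------------------------------------------------
# Continuous surprisal signal
# ---------------------------------------------------------------------------

def continuous_surprisal(
    seq: NoteSequence,
    trace: SurprisalTrace,
    fs: float = 150.0,
    sigma: float = 50.0,
    *,
    gap_value: float = 0.0,
) -> ContinuousSignal:
    """Step function of note-wise IC, Gaussian-smoothed.

    Each note's IC spans its duration; gaps between notes take ``gap_value``
    (0 by default). ``sigma`` is the kernel width in SAMPLES at ``fs``
    (sigma=50 at 150 Hz is roughly a 333-ms kernel); sigma=0 returns the raw
    step function.
    """
    if len(trace) == 0:
        raise ValueError("empty surprisal trace")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    mono = seq.to_monophonic(trace.voice)
    if len(mono.events) != len(trace):
        raise ValueError(
            f"trace length {len(trace)} does not match voice {trace.voice!r} "
            f"({len(mono.events)} notes)"
        )
    n = int(np.ceil(mono.duration * fs))
    out = np.full(n, float(gap_value))
    for e, ic in zip(mono.events, trace.per_note_ic):
        i0 = int(round(e.onset * fs))
        i1 = max(i0 + 1, int(round((e.onset + e.duration) * fs)))
        out[i0 : min(i1, n)] = ic
    if sigma > 0:
        out = gaussian_filter1d(out, sigma=sigma, mode="reflect")
    return ContinuousSignal(samples=out, fs=fs)
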
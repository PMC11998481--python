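"""Synthetic stimuli, corpora, recordings and tapping data with known ground truth.

This module emulates the study conditions end to end:

* two-voice tonal note sequences on an eighth-note grid (46 bpm quarter-note
  tempo, 4/4 meter -> a 92-bpm dominant eighth-note beat, 652 ms apart), with
  pitches drawn from a first-order Markov chain over major scale degrees whose
  weights concentrate probability on the tonic triad ("high pitch
  predictability");
* "atonalized" counterparts in which every note is shifted by a random 1-9
  semitones up or down while the timing stays identical;
* a corpus of monophonic melodies from the same tonal family for training the
  long-term component of the surprisal model;
* simulated 32-channel recordings in which chosen channels carry a lagged,
  standardized copy of a stimulus feature embedded in 1/f noise at a
  controlled SNR;
* simulated finger-tap sequences at a fixed beat with Gaussian timing jitter
  and random lapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import child_rng
from .notes import BASS, MELODY, NoteEvent, NoteSequence
from .recording import Recording
from .montage import Montage, template_montage_32
from .signals import ContinuousSignal

__all__ = [
    "EEGSimConfig",
    "TappingTrial",
    "MAJOR_SCALE",
    "DEFAULT_DEGREE_WEIGHTS",
    "degree_transition_matrix",
    "stationary_distribution",
    "gen_tonal_sequence",
    "atonalize",
    "gen_corpus",
    "render_envelope",
    "simulate_recording",
    "simulate_tapping",
]

#: Semitone offsets of the major scale degrees above the key root.
MAJOR_SCALE = (0, 2, 4, 5, 7, 9, 11)

#: Tonal weighting of the seven scale degrees (Krumhansl-style profile
#: restricted to in-key degrees): probability mass concentrates on the tonic
#: triad (degrees 1, 3, 5). Config, not a constant of nature.
DEFAULT_DEGREE_WEIGHTS = (5.0, 2.0, 3.5, 2.5, 4.5, 2.0, 1.5)


@dataclass(frozen=True)
class EEGSimConfig:
    """Ground-truth parameters of a simulated recording."""

    n_channels: int = 32
    driven_channels: frozenset[str] = frozenset({"Cz", "C3", "C4", "FC1", "FC2", "Fz"})
    lag: float = 120.0  # ms, stimulus-to-brain delay
    snr: float = 0.5  # linear variance ratio signal/noise on driven channels
    noise_exponent: float = 1.0  # 1/f slope of the channel noise
    fs: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise ValueError("lag must be >= 0")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")


@dataclass
class TappingTrial:
    """Raw tap times (seconds) of one trial."""

    tap_times: np.ndarray
    trial_length: float
    condition: str = "tonal"
    participant: str = "p01"

    def __post_init__(self) -> None:
        self.tap_times = np.asarray(self.tap_times, dtype=float)
        if np.any(np.diff(self.tap_times) <= 0):
            raise ValueError("tap_times must be strictly increasing")
        if self.tap_times.size and self.tap_times[-1] > self.trial_length:
            raise ValueError("tap_times must lie within trial_length")


# ---------------------------------------------------------------------------
# Symbolic stimuli
# ---------------------------------------------------------------------------

def degree_transition_matrix(
    weights: tuple[float, ...] = DEFAULT_DEGREE_WEIGHTS, proximity_tau: float = 1.5
) -> np.ndarray:
    """First-order transition matrix over scale degrees.

    ``P[i, j] ∝ w_j * exp(-dist(i, j)/tau)`` where dist is the circular
    degree distance; the proximity kernel makes small melodic steps likelier,
    the weights keep the tonic triad dominant.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or np.any(w <= 0):
        raise ValueError("weights must be a vector of positive values")
    n = w.size
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    dist = np.minimum(dist, n - dist)
    P = w[None, :] * np.exp(-dist / proximity_tau)
    return P / P.sum(axis=1, keepdims=True)


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary law of a row-stochastic matrix (left eigenvector at 1)."""
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _degree_walk(rng: np.random.Generator, n: int, P: np.ndarray) -> np.ndarray:
    pi = stationary_distribution(P)
    out = np.empty(n, dtype=int)
    out[0] = rng.choice(P.shape[0], p=pi)
    for k in range(1, n):
        out[k] = rng.choice(P.shape[0], p=P[out[k - 1]])
    return out


def gen_tonal_sequence(
    n_bars: int,
    tempo: float = 46.0,
    seed: int = 0,
    *,
    meter: tuple[int, int] = (4, 4),
    key_root: int = 60,
    weights: tuple[float, ...] = DEFAULT_DEGREE_WEIGHTS,
    proximity_tau: float = 1.5,
) -> NoteSequence:
    """Two-voice tonal sequence (melody + bass) on an eighth-note grid.

    The melody walks the scale-degree Markov chain in eighth notes one octave
    above the key root; the bass walks the same chain in quarter notes one
    octave below. Deterministic given ``seed``.
    """
    if n_bars < 1:
        raise ValueError(f"n_bars must be >= 1, got {n_bars}")
    if tempo <= 0:
        raise ValueError("tempo must be > 0")
    rng = child_rng(seed, "gen_tonal_sequence")
    P = degree_transition_matrix(weights, proximity_tau)

    beats_per_bar, unit = meter
    quarter = 60.0 / tempo
    bar = beats_per_bar * quarter * (4 / unit)
    eighth = quarter / 2

    n_mel = int(round(n_bars * bar / eighth))
    n_bass = int(round(n_bars * bar / quarter))
    mel_deg = _degree_walk(rng, n_mel, P)
    bass_deg = _degree_walk(rng, n_bass, P)

    events = [
        NoteEvent(onset=k * eighth, duration=eighth, pitch=key_root + 12 + MAJOR_SCALE[d], voice=MELODY)
        for k, d in enumerate(mel_deg)
    ]
    events += [
        NoteEvent(onset=k * quarter, duration=quarter, pitch=key_root - 12 + MAJOR_SCALE[d], voice=BASS)
        for k, d in enumerate(bass_deg)
    ]
    return NoteSequence(events=events, tempo=tempo, meter=meter)


def atonalize(seq: NoteSequence, seed: int = 0) -> NoteSequence:
    """Shift every pitch by 1-9 semitones up or down (100-900 cents).

    Onsets, durations, voices, tempo and meter are untouched. Shifts that
    would leave the MIDI range 0-127 are re-drawn (rather than clipped) so
    the shift-magnitude distribution stays uniform away from range edges.
    """
    rng = child_rng(seed, "atonalize")
    shifts = []
    for e in seq.events:
        while True:
            s = int(rng.integers(1, 10)) * (1 if rng.random() < 0.5 else -1)
            if 0 <= e.pitch + s <= 127:
                shifts.append(s)
                break
    return seq.transpose_map(shifts)


def gen_corpus(
    n_melodies: int,
    mean_length: int = 40,
    seed: int = 0,
    *,
    tempo: float = 46.0,
    key_root: int = 60,
    weights: tuple[float, ...] = DEFAULT_DEGREE_WEIGHTS,
) -> list[NoteSequence]:
    """Monophonic training melodies from the tonal generator family.

    Lengths are Poisson-dispersed around ``mean_length`` (minimum 2 notes).
    """
    if n_melodies < 1:
        raise ValueError("n_melodies must be >= 1")
    rng = child_rng(seed, "gen_corpus")
    P = degree_transition_matrix(weights)
    eighth = 60.0 / tempo / 2
    corpus = []
    for _ in range(n_melodies):
        n = max(2, int(rng.poisson(mean_length)))
        degrees = _degree_walk(rng, n, P)
        events = [
            NoteEvent(onset=k * eighth, duration=eighth, pitch=key_root + 12 + MAJOR_SCALE[d], voice=MELODY)
            for k, d in enumerate(degrees)
        ]
        corpus.append(NoteSequence(events=events, tempo=tempo))
    return corpus


# ---------------------------------------------------------------------------
# Audio-free envelope rendering
# ---------------------------------------------------------------------------

def render_envelope(
    seq: NoteSequence,
    fs: float = 150.0,
    *,
    attack: float = 0.010,
    amplitude: float = 1.0,
) -> ContinuousSignal:
    """Onset-locked percussive envelope of a note sequence.

    Each note contributes a kernel with a 10-ms linear attack and an
    exponential decay with time constant ``duration / 3``; overlapping notes
    sum. The render is linear in ``amplitude`` and translation-equivariant in
    onset.
    """
    if not seq.events:
        raise ValueError("cannot render an empty sequence")
    beat_rate = seq.tempo / 60.0 * 2  # eighth-note grid
    if fs < 2 * beat_rate:
        raise ValueError(f"fs={fs} must be >= twice the beat rate ({beat_rate:.2f} Hz)")
    n = int(np.ceil(seq.duration * fs))
    out = np.zeros(n)
    for e in seq.events:
        k0 = int(round(e.onset * fs))
        nk = max(1, int(round(e.duration * fs)))
        t = np.arange(nk) / fs
        tau = e.duration / 3.0
        kernel = np.where(t < attack, t / attack if attack > 0 else 1.0, np.exp(-(t - attack) / tau))
        if attack <= 0:
            kernel = np.exp(-t / tau)
        k1 = min(n, k0 + nk)
        out[k0:k1] += kernel[: k1 - k0]
    return ContinuousSignal(samples=amplitude * out, fs=fs)


# ---------------------------------------------------------------------------
# Simulated recordings
# ---------------------------------------------------------------------------

def one_over_f_noise(
    rng: np.random.Generator, n: int, fs: float, exponent: float = 1.0
) -> np.ndarray:
    """Unit-variance noise with a 1/f^exponent power spectrum."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.ones_like(freqs)
    nz = freqs > 0
    amp[nz] = freqs[nz] ** (-exponent / 2.0)
    amp[0] = 0.0
    spec = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n=n)
    return (x - x.mean()) / x.std()


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant signal")
    return (x - x.mean()) / sd


def simulate_recording(
    features: list[ContinuousSignal],
    config: EEGSimConfig,
    *,
    montage: Montage | None = None,
    return_parts: bool = False,
):
    """Multichannel recording with feature-driven channels in 1/f noise.

    Driven channels carry the standardized feature mixture, delayed by
    ``config.lag`` ms (circular shift, keeping stationarity), scaled so the
    signal/noise variance ratio equals ``config.snr``; all channels carry
    independent 1/f noise. Deterministic given ``config.seed``.
    """
    if not features:
        raise ValueError("need at least one feature")
    fs = config.fs
    for f in features:
        if f.fs != fs:
            raise ValueError(f"feature fs {f.fs} != config fs {fs}")
    n = min(len(f) for f in features)
    montage = montage or template_montage_32()
    labels = montage.labels[: config.n_channels]
    unknown = set(config.driven_channels) - set(labels)
    if unknown:
        raise ValueError(f"driven channels not in montage: {sorted(unknown)}")

    mixture = _standardize(np.sum([_standardize(f.samples[:n]) for f in features], axis=0))
    lag_samples = int(round(config.lag / 1000.0 * fs))
    lagged = np.roll(mixture, lag_samples)
    signal_part = np.sqrt(config.snr) * lagged

    rng = np.random.default_rng(child_rng(config.seed, "simulate_recording").bit_generator)
    data = np.empty((len(labels), n))
    noise_parts = np.empty_like(data)
    for i, label in enumerate(labels):
        noise = one_over_f_noise(rng, n, fs, config.noise_exponent)
        noise_parts[i] = noise
        data[i] = noise + (signal_part if label in config.driven_channels else 0.0)
    rec = Recording(data=data, fs=fs, labels=labels, montage=montage)
    if return_parts:
        return rec, {"signal": signal_part, "noise": noise_parts, "lag_samples": lag_samples}
    return rec


# ---------------------------------------------------------------------------
# Simulated tapping
# ---------------------------------------------------------------------------

def simulate_tapping(
    beat_interval: float = 652.0,
    jitter_sd: float = 30.0,
    lapse_rate: float = 0.0,
    n_taps: int = 16,
    seed: int = 0,
    *,
    condition: str = "tonal",
    participant: str = "p01",
) -> TappingTrial:
    """Taps at multiples of the beat with Gaussian jitter and random lapses.

    ``beat_interval`` and ``jitter_sd`` are in milliseconds. Each intended tap
    at ``k * beat_interval`` is independently dropped with probability
    ``lapse_rate``; non-increasing collisions are resolved by re-drawing the
    jitter of the offending tap.
    """
    if beat_interval <= 0:
        raise ValueError("beat_interval must be > 0")
    if not (0 <= lapse_rate < 0.5):
        raise ValueError("lapse_rate must be in [0, 0.5)")
    rng = child_rng(seed, "simulate_tapping")
    beat_s = beat_interval / 1000.0
    jit_s = jitter_sd / 1000.0
    # the first tap falls on the first beat at t=0 (the cleaning rules are
    # designed to drop the first two taps of a ~650-ms beat)
    targets = np.arange(n_taps) * beat_s
    keep = rng.random(n_taps) >= lapse_rate
    targets = targets[keep]
    taps = targets + rng.normal(0.0, jit_s, size=targets.size)
    for i in range(1, taps.size):  # enforce strict increase by resampling
        guard = 0
        while taps[i] <= taps[i - 1]:
            taps[i] = targets[i] + rng.normal(0.0, jit_s)
            guard += 1
            if guard > 1000:
                taps[i] = taps[i - 1] + 1e-4
    trial_length = n_taps * beat_s
    if taps.size:
        trial_length = max(trial_length, float(taps[-1]))
    return TappingTrial(
        tap_times=taps, trial_length=trial_length, condition=condition, participant=participant
    )
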
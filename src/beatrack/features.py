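"""Acoustic stimulus features: cochlear-filterbank envelope, modulation
spectrum, beat-related averages, and roughness (sensory dissonance).

The wideband envelope is extracted by band-passing the audio into bands that
are equidistant on the ERB-rate (cochlear) frequency map, taking the analytic
(Hilbert) magnitude per band, averaging across bands, and downsampling the
result to the analysis rate (150 Hz). Filtering happens at the native audio
rate; only the envelope is downsampled, since a 100-8000 Hz filterbank cannot
be applied to a 150-Hz signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import numpy as np
from scipy import signal as sps

from .signals import ContinuousSignal

__all__ = [
    "FilterSpec",
    "ModulationSpectrum",
    "RoughnessSeries",
    "erb_rate",
    "erb_rate_inverse",
    "cochlear_band_edges",
    "extract_envelope",
    "modulation_spectrum",
    "beat_related_average",
    "roughness",
    "plomp_levelt_dissonance",
]


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification: order-3 Butterworth, forward-reverse."""

    low: float
    high: float
    order: int = 3
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"need 0 < low < high, got ({self.low}, {self.high})")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass
class ModulationSpectrum:
    """Mean +/- SEM amplitude spectrum of fixed-length signal chunks."""

    freqs: np.ndarray
    mean_amp: np.ndarray
    sem_amp: np.ndarray
    n_segments: int

    def nearest_bin(self, freq: float) -> int:
        return int(np.argmin(np.abs(self.freqs - freq)))


@dataclass
class RoughnessSeries:
    """Frame-wise roughness estimates (arbitrary units, >= 0)."""

    frame_times: np.ndarray
    values: np.ndarray
    frame_len: float
    hop: float


# ---------------------------------------------------------------------------
# Cochlear map
# ---------------------------------------------------------------------------

def erb_rate(f: np.ndarray | float) -> np.ndarray | float:
    """ERB-rate (cochlear place) scale of frequency ``f`` in Hz."""
    return 21.4 * np.log10(1.0 + 0.00437 * np.asarray(f, dtype=float))


def erb_rate_inverse(e: np.ndarray | float) -> np.ndarray | float:
    return (10.0 ** (np.asarray(e, dtype=float) / 21.4) - 1.0) / 0.00437


def cochlear_band_edges(n_bands: int, low: float = 100.0, high: float = 8000.0):
    """Contiguous band edges equally spaced on the ERB-rate scale."""
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if low >= high:
        raise ValueError(f"need low < high, got ({low}, {high})")
    edges = erb_rate_inverse(np.linspace(erb_rate(low), erb_rate(high), n_bands + 1))
    edges[0], edges[-1] = low, high  # pin exact endpoints against roundoff
    return [(float(edges[i]), float(edges[i + 1])) for i in range(n_bands)]


# ---------------------------------------------------------------------------
# Envelope extraction
# ---------------------------------------------------------------------------

def _butter_sos(low: float, high: float, fs: float, order: int = 3) -> np.ndarray:
    nyq = fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) invalid at fs={fs}")
    return sps.butter(order, [low, high], btype="bandpass", output="sos", fs=fs)


def _resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    if fs_in == fs_out:
        return x
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return sps.resample_poly(x, frac.numerator, frac.denominator)


def extract_envelope(
    audio: ContinuousSignal,
    n_bands: int = 8,
    out_fs: float = 150.0,
    *,
    low: float = 100.0,
    high: float = 8000.0,
) -> ContinuousSignal:
    """Wideband envelope via an ERB-spaced Butterworth filterbank.

    Per band: zero-phase order-3 band-pass at the native audio rate, analytic
    magnitude; bands are averaged and the result resampled to ``out_fs``.
    The output is clipped at zero (polyphase resampling can undershoot).
    """
    if audio.fs <= 2 * high:
        raise ValueError(f"audio fs {audio.fs} must exceed twice the top band edge {high}")
    min_len = int(3 * audio.fs / low)
    if len(audio) < min_len:
        raise ValueError(f"audio too short: need >= {min_len} samples at fs={audio.fs}")
    from scipy.fft import next_fast_len

    x = audio.samples
    acc = np.zeros_like(x)
    nfast = next_fast_len(x.size)
    for lo, hi in cochlear_band_edges(n_bands, low, high):
        band = sps.sosfiltfilt(_butter_sos(lo, hi, audio.fs), x)
        acc += np.abs(sps.hilbert(band, N=nfast)[: x.size])
    env = acc / n_bands
    env = _resample(env, audio.fs, out_fs)
    return ContinuousSignal(samples=np.maximum(env, 0.0), fs=out_fs, t0=audio.t0)


# ---------------------------------------------------------------------------
# Modulation spectrum
# ---------------------------------------------------------------------------

def modulation_spectrum(
    signal: ContinuousSignal, seg_len: float = 6.0, fmax: float = 12.0
) -> ModulationSpectrum:
    """Mean amplitude spectrum over non-overlapping ``seg_len`` windows.

    Each window is demeaned and Hann-tapered before the amplitude (not
    power) spectrum is taken; the result is restricted to [0, fmax].
    """
    fs = signal.fs
    if fmax > fs / 2:
        raise ValueError(f"fmax {fmax} exceeds Nyquist {fs / 2}")
    nseg = int(round(seg_len * fs))
    if len(signal) < nseg:
        raise ValueError("signal shorter than one segment")
    n_windows = len(signal) // nseg
    taper = sps.windows.hann(nseg, sym=False)
    freqs = np.fft.rfftfreq(nseg, d=1.0 / fs)
    keep = freqs <= fmax
    amps = np.empty((n_windows, int(keep.sum())))
    for w in range(n_windows):
        chunk = signal.samples[w * nseg : (w + 1) * nseg]
        chunk = (chunk - chunk.mean()) * taper
        amps[w] = np.abs(np.fft.rfft(chunk))[keep]
    mean = amps.mean(axis=0)
    sem = amps.std(axis=0, ddof=1) / np.sqrt(n_windows) if n_windows > 1 else np.zeros_like(mean)
    return ModulationSpectrum(freqs=freqs[keep], mean_amp=mean, sem_amp=sem, n_segments=n_windows)


DEFAULT_BEAT_MULTIPLIERS = frozenset({0.5, 1.0, 2.0, 3.0, 4.0})


def beat_related_average(
    spec: ModulationSpectrum,
    beat: float = 1.52,
    include: frozenset[float] = DEFAULT_BEAT_MULTIPLIERS,
) -> float:
    """Mean spectral amplitude at the beat subharmonic and harmonics."""
    if not include:
        raise ValueError("multiplier set must be non-empty")
    targets = [m * beat for m in sorted(include)]
    top = float(spec.freqs.max())
    bad = [t for t in targets if t > top]
    if bad:
        raise ValueError(f"beat multiples {bad} exceed the spectrum range ({top} Hz)")
    return float(np.mean([spec.mean_amp[spec.nearest_bin(t)] for t in targets]))


# ---------------------------------------------------------------------------
# Roughness
# ---------------------------------------------------------------------------

def plomp_levelt_dissonance(f1: float, f2: float, a1: float, a2: float) -> float:
    """Pairwise sensory dissonance of two partials (Plomp-Levelt curve,
    Sethares parameterization). Peaks near ~25% of the critical bandwidth
    of the lower partial and decays for wider separations."""
    lo, hi = (f1, f2) if f1 <= f2 else (f2, f1)
    s = 0.24 / (0.0207 * lo + 18.96)
    d = hi - lo
    return a1 * a2 * (np.exp(-3.5 * s * d) - np.exp(-5.75 * s * d))


def roughness(
    audio: ContinuousSignal,
    frame_len: float = 0.05,
    hop: float = 0.025,
    *,
    n_peaks: int = 20,
) -> RoughnessSeries:
    """Frame-wise roughness: summed Plomp-Levelt dissonance over spectral
    peak pairs (the ``n_peaks`` largest peaks per frame)."""
    if hop > frame_len:
        raise ValueError("hop must be <= frame_len")
    fs = audio.fs
    nwin = int(round(frame_len * fs))
    nhop = int(round(hop * fs))
    if len(audio) < nwin:
        raise ValueError("audio shorter than one frame")
    taper = sps.windows.hann(nwin, sym=False)
    freqs = np.fft.rfftfreq(nwin, d=1.0 / fs)
    starts = np.arange(0, len(audio) - nwin + 1, nhop)
    values = np.empty(starts.size)
    for i, s0 in enumerate(starts):
        amp = np.abs(np.fft.rfft(audio.samples[s0 : s0 + nwin] * taper))
        peaks, _ = sps.find_peaks(amp)
        if peaks.size > n_peaks:
            peaks = peaks[np.argsort(amp[peaks])[-n_peaks:]]
        total = 0.0
        for p, q in combinations(peaks, 2):
            total += plomp_levelt_dissonance(freqs[p], freqs[q], amp[p], amp[q])
        values[i] = max(total, 0.0)
    times = (starts + nwin / 2) / fs + audio.t0
    return RoughnessSeries(frame_times=times, values=values, frame_len=frame_len, hop=hop)
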
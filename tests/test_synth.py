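"""Synthetic stimuli, recordings and tapping: ground-truth properties."""

import numpy as np
import pytest
from scipy import stats as sstats

import beatrack as bt
from beatrack.synth import (
    EEGSimConfig,
    degree_transition_matrix,
    simulate_recording,
    simulate_tapping,
    stationary_distribution,
)


class TestTonalSequence:
    def test_two_bars_last_about_ten_seconds(self):
        seq = bt.gen_tonal_sequence(2, tempo=46.0, seed=0)
        assert seq.duration == pytest.approx(2 * 4 * 60 / 46, abs=1e-9)  # 10.43 s

    def test_deterministic_under_seed_and_varies_across_seeds(self):
        a = bt.gen_tonal_sequence(3, seed=5)
        b = bt.gen_tonal_sequence(3, seed=5)
        c = bt.gen_tonal_sequence(3, seed=6)
        assert a.events == b.events
        assert a.events != c.events

    def test_rejects_empty_score(self):
        with pytest.raises(ValueError):
            bt.gen_tonal_sequence(0)

    def test_two_voices_on_eighth_grid(self, tonal_two_bars):
        eighth = 60.0 / 46.0 / 2
        assert set(tonal_two_bars.voices) == {"melody", "bass"}
        for e in tonal_two_bars.events:
            assert e.onset / eighth == pytest.approx(round(e.onset / eighth), abs=1e-9)

    def test_degree_histogram_matches_stationary_law(self):
        """Long-run scale-degree frequencies match the chain's stationary
        distribution (computed independently by eigendecomposition)."""
        seq = bt.gen_tonal_sequence(1000, seed=3)
        P = degree_transition_matrix()
        pi = stationary_distribution(P)
        melody = [e.pitch for e in seq.voice_events("melody")]
        degrees = [bt.synth.MAJOR_SCALE.index((p - 72) % 12) for p in melody]
        counts = np.bincount(degrees, minlength=7)
        chi = sstats.chisquare(counts, pi * counts.sum())
        assert chi.pvalue > 1e-3


class TestAtonalize:
    def test_timing_and_voices_unchanged(self, tonal_two_bars):
        shifted = bt.atonalize(tonal_two_bars, seed=1)
        assert [(e.onset, e.duration, e.voice) for e in shifted.events] == [
            (e.onset, e.duration, e.voice) for e in tonal_two_bars.events
        ]

    def test_shift_magnitudes_between_one_and_nine_semitones(self):
        seq = bt.gen_tonal_sequence(50, seed=2)
        shifted = bt.atonalize(seq, seed=3)
        mags = {abs(a.pitch - b.pitch) for a, b in zip(shifted.events, seq.events)}
        assert mags <= set(range(1, 10)) and 0 not in mags

    def test_shift_distribution_uniform(self):
        """|shift| is uniform on 1..9 (chi-square), pitches are mid-range so
        no re-draws distort the law."""
        seq = bt.gen_tonal_sequence(900, seed=4)  # ~11k notes
        shifted = bt.atonalize(seq, seed=5)
        mags = [abs(a.pitch - b.pitch) for a, b in zip(shifted.events, seq.events)]
        counts = np.bincount(mags, minlength=10)[1:]
        assert counts.sum() >= 10_000
        assert sstats.chisquare(counts).pvalue > 1e-3

    def test_pitches_stay_in_midi_range(self):
        events = [bt.NoteEvent(onset=i * 0.1, duration=0.1, pitch=p) for i, p in enumerate([0, 1, 126, 127])]
        seq = bt.NoteSequence(events=events, tempo=60)
        shifted = bt.atonalize(seq, seed=0)
        assert all(0 <= e.pitch <= 127 for e in shifted.events)


class TestCorpus:
    def test_requested_number_of_melodies(self):
        assert len(bt.gen_corpus(1, seed=0)) == 1
        assert len(bt.gen_corpus(25, seed=0)) == 25

    def test_melodies_are_monophonic(self):
        for seq in bt.gen_corpus(5, mean_length=20, seed=1):
            onsets = [e.onset for e in seq.events]
            assert len(onsets) == len(set(onsets))


class TestRenderEnvelope:
    def test_single_note_peaks_at_onset(self):
        seq = bt.NoteSequence(
            events=[bt.NoteEvent(onset=1.0, duration=0.5, pitch=60)], tempo=60
        )
        env = bt.render_envelope(seq, 150.0)
        peak = int(np.argmax(env.samples))
        assert abs(peak - round(1.0 * 150 + 0.010 * 150)) <= 2  # attack apex

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            bt.render_envelope(bt.NoteSequence(events=[], tempo=60), 150.0)

    def test_spectral_peak_at_event_rate(self):
        """Isochronous eighth notes at 92 bpm put the strongest 0-12 Hz
        component at the event rate."""
        seq = bt.gen_tonal_sequence(16, tempo=92.0, seed=0)
        melody_only = bt.NoteSequence(events=seq.voice_events("melody"), tempo=92.0)
        env = bt.render_envelope(melody_only, 150.0)
        x = env.samples - env.samples.mean()
        freqs = np.fft.rfftfreq(x.size, 1 / 150.0)
        amp = np.abs(np.fft.rfft(x))
        sel = (freqs > 0.2) & (freqs <= 12)
        peak = freqs[sel][np.argmax(amp[sel])]
        event_rate = 92.0 * 2 / 60.0
        assert peak == pytest.approx(event_rate, abs=150.0 / x.size)

    def test_linear_in_amplitude_and_translation_equivariant(self):
        seq = bt.NoteSequence(
            events=[bt.NoteEvent(onset=0.5, duration=0.4, pitch=60),
                    bt.NoteEvent(onset=1.1, duration=0.3, pitch=64)],
            tempo=60,
        )
        base = bt.render_envelope(seq, 150.0)
        doubled = bt.render_envelope(seq, 150.0, amplitude=2.0)
        assert np.allclose(doubled.samples, 2 * base.samples)
        delta = 0.2
        shifted_seq = bt.NoteSequence(
            events=[bt.NoteEvent(e.onset + delta, e.duration, e.pitch, e.voice) for e in seq.events],
            tempo=60,
        )
        shifted = bt.render_envelope(shifted_seq, 150.0)
        k = round(delta * 150)
        n = min(len(base), len(shifted) - k)
        assert np.allclose(shifted.samples[k : k + n], base.samples[:n], atol=1e-12)

    def test_voices_sum_pointwise(self):
        mel = bt.NoteSequence(events=[bt.NoteEvent(0.0, 1.0, 72, "melody")], tempo=60)
        bas = bt.NoteSequence(events=[bt.NoteEvent(0.2, 0.8, 48, "bass")], tempo=60)
        both = bt.NoteSequence(events=mel.events + bas.events, tempo=60)
        a, b, ab = (bt.render_envelope(s, 150.0) for s in (mel, bas, both))
        assert np.allclose(ab.samples, a.samples + b.samples[: len(a)])


class TestSimulateRecording:
    def test_snr_matches_configuration(self, study_envelope):
        cfg = EEGSimConfig(lag=100.0, snr=0.5, seed=11)
        rec, parts = simulate_recording([study_envelope], cfg, return_parts=True)
        i = rec.labels.index("Cz")
        ratio = parts["signal"].var() / parts["noise"][i].var()
        assert ratio == pytest.approx(0.5, rel=0.10)

    def test_deterministic_given_seed(self, study_envelope):
        cfg = EEGSimConfig(seed=4)
        a = simulate_recording([study_envelope], cfg)
        b = simulate_recording([study_envelope], cfg)
        assert np.array_equal(a.data, b.data)

    def test_mismatched_sampling_rate_rejected(self, study_envelope):
        bad = bt.ContinuousSignal(np.ones(100), fs=100.0)
        with pytest.raises(ValueError):
            simulate_recording([study_envelope, bad], EEGSimConfig())

    def test_vanishing_snr_driven_channels_match_pure_noise(self, study_envelope):
        """In the snr -> 0 limit a driven channel's MI is indistinguishable
        from the same-seed noise-only channel."""
        band = bt.FilterSpec(0.5, 3.0)
        tiny = simulate_recording([study_envelope], EEGSimConfig(lag=120.0, snr=1e-8, seed=5))
        none = simulate_recording(
            [study_envelope], EEGSimConfig(driven_channels=frozenset(), lag=120.0, snr=1.0, seed=5)
        )
        mi_tiny = bt.track(tiny, study_envelope, band, 120.0).mi
        mi_none = bt.track(none, study_envelope, band, 120.0).mi
        assert np.allclose(mi_tiny, mi_none, atol=1e-3)

    def test_driven_channel_beats_noise_channels(self):
        seq = bt.gen_tonal_sequence(58, seed=9)  # ~300 s
        env = bt.render_envelope(seq, 150.0)
        cfg = EEGSimConfig(lag=120.0, snr=0.25, seed=13)
        rec = simulate_recording([env], cfg)
        mimap = bt.track(rec, env, bt.FilterSpec(0.5, 3.0), 120.0)
        noise = [m for ch, m in zip(mimap.labels, mimap.mi) if ch not in cfg.driven_channels]
        assert mimap["Cz"] > np.percentile(noise, 95)


class TestSimulateTapping:
    def test_noiseless_taps_are_exactly_periodic(self):
        tr = simulate_tapping(652.0, 0.0, 0.0, 16, seed=0)
        intervals = np.diff(tr.tap_times) * 1000
        assert np.allclose(intervals, 652.0)
        assert bt.trial_mad(intervals) == pytest.approx(0.0, abs=1e-9)

    def test_lapses_drop_taps(self):
        tr = simulate_tapping(652.0, 5.0, 0.3, 200, seed=1)
        assert 100 < tr.tap_times.size < 180

    def test_interval_mad_matches_monte_carlo_oracle(self):
        """MAD of jittered inter-tap intervals agrees with a brute-force
        draw from the interval law (difference of two jitters)."""
        tr = simulate_tapping(652.0, 30.0, 0.0, 10_001, seed=2)
        intervals = np.diff(tr.tap_times) * 1000
        oracle_rng = np.random.default_rng(99)
        draws = oracle_rng.normal(0, 30.0, 10**6) - oracle_rng.normal(0, 30.0, 10**6)
        oracle_mad = np.median(np.abs(draws - np.median(draws)))
        assert bt.trial_mad(intervals) == pytest.approx(oracle_mad, rel=0.05)

    def test_invalid_lapse_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_tapping(652.0, 1.0, 0.7, 10, seed=0)
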
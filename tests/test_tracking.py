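"""Gaussian-copula MI estimator, filtering, lag search, and tracking."""

import numpy as np
import pytest
from scipy.special import ndtri

import beatrack as bt
from beatrack.synth import EEGSimConfig, simulate_recording
from beatrack.tracking import lag_coherence


class TestCopulaNormalize:
    def test_three_point_example(self):
        out = bt.copula_normalize(np.array([5.0, 1.0, 9.0]))
        expected = ndtri(np.array([3, 1, 5]) / 6.0)  # ranks 2,1,3 -> (r-.5)/3
        assert np.allclose(out, expected)

    def test_invariant_to_monotone_transforms(self, rng):
        x = rng.standard_normal(500)
        assert np.array_equal(bt.copula_normalize(x), bt.copula_normalize(np.exp(x)))
        assert np.array_equal(bt.copula_normalize(x), bt.copula_normalize(x**3))

    def test_output_is_centred(self, rng):
        out = bt.copula_normalize(rng.random(10_000))
        assert abs(out.mean()) < 1e-6

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            bt.copula_normalize(np.ones(100))


class TestGCMI:
    def test_independent_signals_near_zero(self, rng):
        mi = bt.gcmi(rng.standard_normal(10_000), rng.standard_normal(10_000))
        assert abs(mi) < 0.01

    @pytest.mark.parametrize("rho", [0.3, 0.6, 0.9])
    def test_matches_gaussian_closed_form(self, rho, rng):
        n = 100_000
        z = rng.standard_normal(n)
        x = rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        expected = -0.5 * np.log2(1 - rho**2)
        assert bt.gcmi(x, z) == pytest.approx(expected, rel=0.05)

    def test_symmetry_is_exact(self, rng):
        x = rng.standard_normal(2000)
        y = x + rng.standard_normal(2000)
        assert bt.gcmi(x, y) == bt.gcmi(y, x)

    def test_invariant_to_marginal_transforms(self, rng):
        x = rng.standard_normal(3000)
        y = 0.5 * x + rng.standard_normal(3000)
        assert bt.gcmi(x, y) == bt.gcmi(np.exp(x), np.tanh(y))

    def test_multivariate_at_least_best_single_column(self, rng):
        n = 10_000
        z = rng.standard_normal(n)
        y1 = 0.7 * z + rng.standard_normal(n)
        y2 = 0.3 * z + rng.standard_normal(n)
        joint = bt.gcmi(z, np.column_stack([y1, y2]))
        best = max(bt.gcmi(z, y1), bt.gcmi(z, y2))
        assert joint >= best - 0.01


class TestConditionalGCMI:
    def test_reduces_to_mi_when_conditioner_is_independent(self, rng):
        n = 100_000
        z = rng.standard_normal(n)
        x = 0.6 * z + 0.8 * rng.standard_normal(n)
        w = rng.standard_normal(n)
        assert bt.conditional_gcmi(x, z, w) == pytest.approx(bt.gcmi(x, z), abs=0.01)

    def test_markov_chain_conditioning_removes_dependence(self, rng):
        n = 100_000
        z = rng.standard_normal(n)
        x = z + rng.standard_normal(n)
        y = z + rng.standard_normal(n)
        assert bt.conditional_gcmi(x, y, z) == pytest.approx(0.0, abs=0.01)

    def test_floored_at_zero(self, rng):
        x, y, z = (rng.standard_normal(500) for _ in range(3))
        assert bt.conditional_gcmi(x, y, z) >= 0.0


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        fs = 150.0
        t = np.arange(int(60 * fs)) / fs
        x = np.sin(2 * np.pi * 1.5 * t)
        y = bt.bandpass(x, fs, bt.FilterSpec(0.5, 3.0))
        assert np.abs(y[900:-900]).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_heavily_attenuated(self):
        fs = 150.0
        t = np.arange(int(60 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        y = bt.bandpass(x, fs, bt.FilterSpec(0.5, 3.0))
        assert np.abs(y[900:-900]).max() < 0.1

    def test_zero_phase_in_band_sine_not_shifted(self):
        """A passband sinusoid comes out phase-aligned with the input: the
        cross-correlation over candidate shifts peaks at lag zero."""
        fs = 150.0
        t = np.arange(int(60 * fs)) / fs
        x = np.sin(2 * np.pi * 1.5 * t)
        y = bt.bandpass(x, fs, bt.FilterSpec(0.5, 3.0))
        lags = np.arange(-10, 11)
        xc = [np.corrcoef(x[900 + l : -901 + l], y[900:-901])[0, 1] for l in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bt.bandpass(np.zeros(1000), 150.0, bt.FilterSpec(0.5, 80.0))


class TestOptimalLag:
    def test_recovers_injected_lag(self, study_envelope):
        cfg = EEGSimConfig(lag=120.0, snr=1.0, seed=21)
        rec = simulate_recording([study_envelope], cfg)
        assert bt.optimal_lag(rec, study_envelope) == 120.0

    def test_grid_has_nine_default_candidates(self):
        cfg = bt.LagSearchConfig()
        assert len(cfg.lags) == 9
        assert cfg.lags[0] == 40.0 and cfg.lags[-1] == 200.0

    def test_tie_breaks_toward_smaller_lag(self, montage):
        labels = montage.labels
        rng = np.random.default_rng(0)
        rec = bt.Recording(rng.standard_normal((32, 3000)), 150.0, labels, montage)
        feature = bt.ContinuousSignal(rng.standard_normal(3000), 150.0)
        coh = lag_coherence(rec, feature)
        cfg = bt.LagSearchConfig()
        lag = bt.optimal_lag(rec, feature, cfg)
        assert lag == cfg.lags[int(np.argmax(coh))]  # first maximum

    def test_missing_reference_channel_rejected(self, montage, study_envelope):
        labels = [l for l in montage.labels if l != "Cz"][:4]
        rec = bt.Recording(np.random.default_rng(1).standard_normal((4, 9000)), 150.0, labels, montage)
        with pytest.raises(ValueError):
            bt.optimal_lag(rec, study_envelope)


class TestTrack:
    def test_driven_channels_dominate(self, study_envelope):
        cfg = EEGSimConfig(lag=120.0, snr=0.5, seed=31)
        rec = simulate_recording([study_envelope], cfg)
        mimap = bt.track(rec, study_envelope, bt.FilterSpec(0.5, 3.0), 120.0)
        ranked = [mimap.labels[i] for i in np.argsort(mimap.mi)[::-1]]
        assert set(ranked[:6]) == set(cfg.driven_channels)

    def test_deterministic(self, study_envelope):
        rec = simulate_recording([study_envelope], EEGSimConfig(seed=5))
        a = bt.track(rec, study_envelope, bt.FilterSpec(0.5, 3.0), 120.0)
        b = bt.track(rec, study_envelope, bt.FilterSpec(0.5, 3.0), 120.0)
        assert np.array_equal(a.mi, b.mi)

    def test_equivariant_to_joint_time_shift(self, study_envelope, montage):
        cfg = EEGSimConfig(lag=100.0, snr=1.0, seed=8)
        rec = simulate_recording([study_envelope], cfg)
        shift = 300
        rec2 = bt.Recording(rec.data[:, shift:], rec.fs, rec.labels, montage)
        feat2 = bt.ContinuousSignal(study_envelope.samples[shift:], rec.fs)
        a = bt.track(rec, study_envelope, bt.FilterSpec(0.5, 3.0), 120.0)
        b = bt.track(rec2, feat2, bt.FilterSpec(0.5, 3.0), 120.0)
        assert np.corrcoef(a.mi, b.mi)[0, 1] > 0.99

    def test_lag_exceeding_signal_rejected(self, montage):
        rec = bt.Recording(np.random.default_rng(0).standard_normal((32, 100)), 150.0,
                           montage.labels, montage)
        feat = bt.ContinuousSignal(np.random.default_rng(1).standard_normal(100), 150.0)
        with pytest.raises(ValueError):
            bt.track(rec, feat, bt.FilterSpec(0.5, 3.0), lag=5000.0)

    def test_surprisal_mode_uses_two_column_block(self, study_envelope, montage):
        """Melody+bass surprisal enters as a joint two-column block; the
        joint MI is at least each single-trace MI up to estimator bias."""
        seq = bt.gen_tonal_sequence(12, seed=2)
        model = bt.train_ltm(bt.gen_corpus(10, 25, seed=1), max_order=2)
        sigs = [
            bt.continuous_surprisal(seq, bt.note_surprisal(model, seq, voice=v), fs=150.0)
            for v in ("melody", "bass")
        ]
        cfg = EEGSimConfig(lag=100.0, snr=0.5, seed=9)
        rec = simulate_recording(sigs, cfg)
        band = bt.FilterSpec(0.1, 50.0)
        joint = bt.track(rec, sigs, band, 100.0)
        singles = [bt.track(rec, [s], band, 100.0) for s in sigs]
        i = joint.labels.index("Cz")
        assert joint.mi[i] >= max(s.mi[i] for s in singles) - 0.01
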
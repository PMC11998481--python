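"""Surrogates, cluster tests, lateralization and regression models."""

import numpy as np
import pandas as pd
import pytest

import beatrack as bt
from beatrack.cluster import (
    Adjacency,
    _corr_cols,
    cluster_condition_contrast,
    cluster_correlation,
    cluster_vs_chance,
    linear_model,
    permutation_null,
    segment_shuffle,
    t_critical,
    track_with_null,
    with_interaction,
)
from beatrack.signals import ContinuousSignal
from beatrack.synth import EEGSimConfig, simulate_recording


class TestSegmentShuffle:
    def test_sample_multiset_preserved_exactly(self, rng):
        sig = ContinuousSignal(rng.standard_normal(1234), 150.0)
        out = segment_shuffle(sig, 1.0, seed=3)
        assert np.array_equal(np.sort(out.samples), np.sort(sig.samples))

    def test_trailing_partial_segment_stays_in_place(self, rng):
        sig = ContinuousSignal(rng.standard_normal(1234), 150.0)
        out = segment_shuffle(sig, 1.0, seed=3)
        assert np.array_equal(out.samples[1200:], sig.samples[1200:])

    def test_seed_fixed_permutation(self, rng):
        sig = ContinuousSignal(rng.standard_normal(3000), 150.0)
        a = segment_shuffle(sig, 1.0, seed=7)
        b = segment_shuffle(sig, 1.0, seed=7)
        c = segment_shuffle(sig, 1.0, seed=8)
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_destroys_structure_beyond_the_segment_length(self):
        """An AR(1) at 150 Hz keeps within-segment autocorrelation but loses
        the 2-s-lag correlation after 1-s segment shuffling."""
        rng = np.random.default_rng(0)
        n = 60 * 150
        x = np.empty(n)
        x[0] = rng.standard_normal()
        phi = 0.999  # ACF ~ 0.74 at a 2-s (300-sample) lag
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        sig = ContinuousSignal(x, 150.0)

        def acf(v, lag):
            return np.corrcoef(v[:-lag], v[lag:])[0, 1]

        lag2s = 300
        shuffled = [acf(segment_shuffle(sig, 1.0, seed=s).samples, lag2s) for s in range(20)]
        assert abs(acf(x, lag2s)) > 0.4
        assert np.mean(np.abs(shuffled)) < 0.2
        assert np.mean(np.abs(shuffled)) < abs(acf(x, lag2s)) / 2

    def test_zero_segment_length_rejected(self, rng):
        with pytest.raises(ValueError):
            segment_shuffle(ContinuousSignal(rng.standard_normal(300), 150.0), 0.0)


class TestPermutationNull:
    def test_shape_and_near_zero_mean(self, study_envelope):
        rec = simulate_recording([study_envelope], EEGSimConfig(seed=2))
        null = permutation_null(rec, study_envelope, bt.FilterSpec(0.5, 3.0), 120.0, 50, seed=1)
        assert null.shape == (32, 50)
        assert abs(null.mean()) < 0.01  # bias-corrected chance level

    def test_observed_driven_mi_beats_the_null(self, study_envelope):
        cfg = EEGSimConfig(lag=120.0, snr=0.5, seed=3)
        rec = simulate_recording([study_envelope], cfg)
        mimap, null = track_with_null(rec, study_envelope, bt.FilterSpec(0.5, 3.0), 120.0, 100, seed=4)
        i = mimap.labels.index("Cz")
        assert mimap.mi[i] > np.percentile(null[i], 95)

    def test_combined_helper_matches_separate_calls(self, study_envelope):
        rec = simulate_recording([study_envelope], EEGSimConfig(seed=6))
        band = bt.FilterSpec(0.5, 3.0)
        mi = bt.track(rec, study_envelope, band, 120.0)
        null = permutation_null(rec, study_envelope, band, 120.0, 25, seed=9)
        mi2, null2 = track_with_null(rec, study_envelope, band, 120.0, 25, seed=9)
        assert np.array_equal(mi.mi, mi2.mi)
        assert np.array_equal(null, null2)


def synthetic_group(labels, hot_channels, n_part=12, n_perm=100, effect=0.05, seed=0):
    """Gaussian MI maps with an additive effect on chosen channels, plus a
    matching zero-mean null."""
    rng = np.random.default_rng(seed)
    C = len(labels)
    base = rng.normal(0.0, 0.01, size=(n_part, C))
    for ch in hot_channels:
        base[:, labels.index(ch)] += effect
    nulls = rng.normal(0.0, 0.01, size=(n_part, C, n_perm))
    return base, nulls


class TestClusterVsChance:
    def test_adjacent_hot_channels_form_a_significant_cluster(self, adjacency, montage):
        labels = montage.labels
        gm, gn = synthetic_group(labels, ["Cz", "FC1", "FC2"], seed=1)
        res = cluster_vs_chance(gm, gn, labels, adjacency)
        assert res.significant
        found = set().union(*(c["channels"] for c in res.significant))
        assert {"Cz", "FC1", "FC2"} <= found
        assert all(c["mi_sum"] > 0 for c in res.significant)

    def test_single_isolated_channel_is_not_a_cluster(self, adjacency, montage):
        labels = montage.labels
        gm, gn = synthetic_group(labels, ["Oz"], seed=2)
        res = cluster_vs_chance(gm, gn, labels, adjacency)
        assert all("Oz" not in c["channels"] for c in res.clusters)

    def test_invariant_to_adjacency_preserving_relabeling(self, adjacency, montage):
        labels = montage.labels
        gm, gn = synthetic_group(labels, ["Cz", "FC1"], seed=3)
        res1 = cluster_vs_chance(gm, gn, labels, adjacency)
        swap = {l: l + "_x" for l in labels}
        labels2 = [swap[l] for l in labels]
        adj2 = Adjacency({swap[k]: frozenset(swap[o] for o in v)
                          for k, v in adjacency.neighbors.items()})
        res2 = cluster_vs_chance(gm, gn, labels2, adj2)
        assert [c["p_value"] for c in res1.clusters] == [c["p_value"] for c in res2.clusters]

    def test_shape_mismatch_rejected(self, adjacency, montage):
        labels = montage.labels
        gm, gn = synthetic_group(labels, [], seed=4)
        with pytest.raises(ValueError):
            cluster_vs_chance(gm[:, :10], gn, labels, adjacency)


class TestConditionContrast:
    def test_default_critical_value_for_twenty_participants(self):
        assert t_critical(20) == pytest.approx(2.093, abs=0.001)

    def test_identical_conditions_yield_no_clusters(self, adjacency, montage):
        labels = montage.labels
        gm, gn = synthetic_group(labels, [], seed=5)
        res = cluster_condition_contrast(gm, gm, gn, gn, labels, adjacency)
        assert res.clusters == []

    def test_effect_sign_recovered(self, adjacency, montage):
        labels = montage.labels
        rng = np.random.default_rng(6)
        a = rng.normal(0.0, 0.01, size=(20, 32))
        b = a + rng.normal(0.0, 0.005, size=a.shape)
        for ch in ("Fz", "FC1", "FC2", "Cz"):
            b[:, labels.index(ch)] += 0.05  # condition B stronger
        na = rng.normal(0.0, 0.01, size=(20, 32, 200))
        nb = rng.normal(0.0, 0.01, size=(20, 32, 200))
        res = cluster_condition_contrast(a, b, na, nb, labels, adjacency)
        assert res.significant
        assert all(c["sign"] == -1 for c in res.significant)  # A < B

    def test_mismatched_shapes_rejected(self, adjacency, montage):
        labels = montage.labels
        gm, gn = synthetic_group(labels, [], seed=7)
        with pytest.raises(ValueError):
            cluster_condition_contrast(gm, gm[:6], gn, gn, labels, adjacency)


class TestClusterCorrelation:
    def test_perfect_correlation_guarded_to_finite_z(self, adjacency, montage):
        labels = montage.labels
        gm, gn = synthetic_group(labels, [], n_part=10, seed=8)
        behavior = gm[:, labels.index("Cz")].copy()
        res, cmap = cluster_correlation(gm, behavior, gn, labels, adjacency)
        i = labels.index("Cz")
        assert cmap.r[i] == pytest.approx(1.0)
        assert np.isfinite(cmap.fisher_z[i]) and cmap.fisher_z[i] > 15

    def test_fisher_z_closed_form(self):
        assert bt.fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
        assert bt.fisher_z(-0.5) == pytest.approx(-0.5493, abs=1e-4)

    def test_correlated_behavior_detected(self, adjacency, montage):
        labels = montage.labels
        rng = np.random.default_rng(9)
        trait = rng.standard_normal(20)
        gm = rng.normal(0.0, 0.01, size=(20, 32))
        for ch in ("Cz", "FC1", "FC2"):
            gm[:, labels.index(ch)] += 0.03 * trait
        gn = rng.normal(0.0, 0.01, size=(20, 32, 200))
        res, _ = cluster_correlation(gm, trait, gn, labels, adjacency)
        assert res.significant
        found = set().union(*(c["channels"] for c in res.significant))
        assert {"Cz", "FC1", "FC2"} <= found

    def test_constant_behavior_rejected(self, adjacency, montage):
        labels = montage.labels
        gm, gn = synthetic_group(labels, [], seed=10)
        with pytest.raises(ValueError):
            cluster_correlation(gm, np.ones(gm.shape[0]), gn, labels, adjacency)

    def test_too_few_participants_rejected(self, adjacency, montage):
        labels = montage.labels
        gm, gn = synthetic_group(labels, [], n_part=4, seed=11)
        with pytest.raises(ValueError):
            cluster_correlation(gm, np.arange(4.0), gn, labels, adjacency)

    def test_spearman_variant_matches_rank_transformed_pearson(self, adjacency, montage):
        labels = montage.labels
        rng = np.random.default_rng(12)
        gm = rng.normal(0, 0.01, size=(15, 32))
        behavior = rng.standard_normal(15)
        from scipy.stats import spearmanr

        _, cmap = cluster_correlation(
            gm, behavior, rng.normal(0, 0.01, (15, 32, 50)), labels, adjacency,
            method="spearman",
        )
        i = labels.index("Pz")
        assert cmap.r[i] == pytest.approx(spearmanr(behavior, gm[:, i]).statistic)


class TestLateralization:
    def test_symmetric_data_gives_null_result(self, montage):
        labels = montage.labels
        rng = np.random.default_rng(13)
        vals = rng.standard_normal((10, 32))
        i, j = labels.index("C3"), labels.index("C4")
        vals[:, j] = vals[:, i]
        out = bt.lateralization_test(vals, labels, [("C3", "C4")])
        assert out.loc[0, "t"] == 0.0 and out.loc[0, "p"] == 1.0

    def test_single_test_fdr_equals_raw_p(self, montage):
        labels = montage.labels
        vals = np.random.default_rng(14).standard_normal((12, 32))
        out = bt.lateralization_test(vals, labels, [("P3", "P4")])
        assert out.loc[0, "p_fdr"] == pytest.approx(out.loc[0, "p"])

    def test_hemisphere_averaging_over_multiple_pairs(self, montage):
        labels = montage.labels
        rng = np.random.default_rng(15)
        vals = rng.standard_normal((12, 32))
        for ch in ("C3", "P3"):
            vals[:, labels.index(ch)] += 1.0  # left boost
        out = bt.lateralization_test(vals, labels, [[("C3", "C4"), ("P3", "P4")]])
        assert out.loc[0, "t"] > 0

    def test_unknown_channel_rejected(self, montage):
        vals = np.zeros((8, 32))
        with pytest.raises(ValueError):
            bt.lateralization_test(vals, montage.labels, [("C3", "Nope")])


class TestLinearModel:
    def test_noise_free_fit_is_exact(self):
        x = np.linspace(0, 1, 30)
        y = 2 * x + 3
        res = linear_model(y, pd.DataFrame({"x": x}))
        assert res.coefficients == pytest.approx([3.0, 2.0], abs=1e-10)
        assert res.r_squared == pytest.approx(1.0)

    def test_f_and_r2_match_sum_of_squares_oracle(self):
        rng = np.random.default_rng(16)
        n = 40
        design = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.standard_normal(n)})
        design = with_interaction(design, "a", "b")
        y = 1.0 + 0.5 * design["a"] - 0.2 * design["b"] + rng.standard_normal(n)
        res = linear_model(y.to_numpy(), design)
        # independent decomposition via lstsq
        X = np.column_stack([np.ones(n), design.to_numpy()])
        beta, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
        resid = y.to_numpy() - X @ beta
        ss_res = resid @ resid
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1 - ss_res / ss_tot
        k = X.shape[1] - 1
        f = (r2 / k) / ((1 - r2) / (n - k - 1))
        assert res.r_squared == pytest.approx(r2)
        assert res.f_value == pytest.approx(f)
        assert res.df == (k, n - k - 1)

    def test_rank_deficient_design_rejected(self):
        x = np.arange(10.0)
        design = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(ValueError):
            linear_model(x, design)


class TestEffectSizes:
    def test_cohens_d_from_paired_t(self):
        assert bt.cohens_d_from_t(6.47, 20) == pytest.approx(1.45, abs=0.005)

    def test_fisher_z_is_odd_and_monotone(self, rng):
        r = np.sort(rng.uniform(-0.99, 0.99, 50))
        z = np.asarray(bt.fisher_z(r))
        assert np.all(np.diff(z) > 0)
        assert np.allclose(np.asarray(bt.fisher_z(-r)), -z)
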
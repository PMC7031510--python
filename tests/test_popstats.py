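"""Volumes, distances, MANOVA, bespoke tests, correlations, PCA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hvcx import popstats as ps
from hvcx.popstats import (
    BirdConductances,
    clustering_distance_test,
    geometric_volume,
    mahalanobis_distance,
    manova,
    pairwise_manova,
    pairwise_waveform_msd,
    pca_summary,
    rundown_check,
    similarity_distance_correlation,
    spike_time_ratio_test,
    trace_volume,
    variance_ratio_test,
    volume_stats,
    volume_vs_covariate,
    waveform_mse_test,
)


def cloud_with_exact_cov(rng, n, stds, mean=None):
    """n-by-5 data whose sample covariance is exactly diag(stds^2)."""
    X = rng.standard_normal((n, 5))
    X -= X.mean(axis=0)
    q, _ = np.linalg.qr(X)
    X = q[:, :5] * np.sqrt(n - 1) * np.asarray(stds)
    if mean is not None:
        X = X + np.asarray(mean)
    return X


class TestVolumes:
    def test_identical_neurons_have_zero_trace_volume(self):
        b = BirdConductances("b", np.tile([800, 250, 3, 4, 3], (5, 1)))
        assert trace_volume(b) == 0.0

    def test_two_neurons_one_axis_apart(self):
        G = np.tile([800.0, 250, 3, 4, 3], (2, 1))
        G[1, 0] += 12.0
        assert trace_volume(BirdConductances("b", G)) == pytest.approx(12.0 / math.sqrt(2))

    def test_trace_volume_squared_equals_covariance_trace(self, rng):
        G = rng.uniform(1, 100, size=(9, 5))
        b = BirdConductances("b", G)
        assert trace_volume(b) ** 2 == pytest.approx(np.trace(b.cov()), abs=1e-10)

    def test_geometric_volume_zero_and_flagged_below_six_neurons(self, rng):
        v, degenerate = geometric_volume(BirdConductances("b", rng.uniform(1, 10, (4, 5))))
        assert v == 0.0 and degenerate

    def test_axis_aligned_cloud_volume_is_product_of_stds(self, rng):
        stds = [3.0, 2.0, 1.5, 1.0, 0.5]
        X = cloud_with_exact_cov(rng, 40, stds, mean=[100, 50, 5, 5, 5])
        v, degenerate = geometric_volume(BirdConductances("b", X))
        assert not degenerate
        assert v == pytest.approx(np.prod(stds), rel=1e-9)

    def test_translation_and_scaling_behavior(self, rng):
        G = rng.uniform(10, 100, (8, 5))
        b1 = BirdConductances("a", G)
        b2 = BirdConductances("b", G + 57.0)
        assert trace_volume(b1) == pytest.approx(trace_volume(b2))
        assert geometric_volume(b1)[0] == pytest.approx(geometric_volume(b2)[0])
        b3 = BirdConductances("c", G * 3.0)
        assert trace_volume(b3) == pytest.approx(3.0 * trace_volume(b1))
        assert geometric_volume(b3)[0] == pytest.approx(3.0**5 * geometric_volume(b1)[0])

    def test_normalized_isotropic_tenth_cloud_is_1e_minus_5(self, rng):
        species = cloud_with_exact_cov(rng, 60, [1.0] * 5)
        bird = cloud_with_exact_cov(rng, 30, [0.1] * 5)
        df = volume_stats(
            [BirdConductances("b", bird)], species=BirdConductances("sp", species)
        )
        assert df.loc[0, "norm_geometric_volume"] == pytest.approx(1e-5, rel=1e-9)

    def test_single_neuron_refused(self):
        with pytest.raises(ValueError):
            trace_volume(BirdConductances("b", np.ones((1, 5))))


class TestMahalanobis:
    def test_equal_centroids_give_zero(self, rng):
        G = rng.uniform(1, 10, (8, 5))
        shuffled = G[rng.permutation(8)]
        d = mahalanobis_distance(BirdConductances("a", G), BirdConductances("b", shuffled))
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_one_dimensional_reduction(self, rng):
        stds = [2.0, 1.0, 1.0, 1.0, 1.0]
        delta = 5.0
        g1 = cloud_with_exact_cov(rng, 20, stds, mean=[0, 0, 0, 0, 0])
        g2 = cloud_with_exact_cov(rng, 20, stds, mean=[delta, 0, 0, 0, 0])
        d = mahalanobis_distance(BirdConductances("a", g1), BirdConductances("b", g2))
        assert d == pytest.approx(delta / 2.0, rel=1e-9)  # pooled sd on that axis

    def test_scale_invariance(self, rng):
        g1 = rng.uniform(1, 10, (8, 5))
        g2 = rng.uniform(1, 10, (8, 5))
        d1 = mahalanobis_distance(BirdConductances("a", g1), BirdConductances("b", g2))
        d2 = mahalanobis_distance(
            BirdConductances("a", g1 * 10.0), BirdConductances("b", g2 * 10.0)
        )
        assert d1 == pytest.approx(d2, rel=1e-9)

    def test_invariance_under_common_linear_transform(self, rng):
        g1 = rng.uniform(1, 10, (9, 5))
        g2 = rng.uniform(1, 10, (9, 5))
        A = rng.standard_normal((5, 5)) + 5 * np.eye(5)
        d1 = mahalanobis_distance(BirdConductances("a", g1), BirdConductances("b", g2))
        d2 = mahalanobis_distance(
            BirdConductances("a", g1 @ A), BirdConductances("b", g2 @ A)
        )
        assert d1 == pytest.approx(d2, rel=1e-6)


def feature_frame(rng, means, n_per_bird=8, sd=1.0):
    rows = []
    for b, mu in enumerate(means):
        X = rng.normal(mu, sd, size=(n_per_bird, len(mu)))
        for x in X:
            rows.append({"bird_id": f"b{b}", "n_spikes": 5,
                         "spike_rate_hz": x[0], "isi1_ms": x[1],
                         "isi2_ms": x[2], "isi3_ms": x[3]})
    return pd.DataFrame(rows)


class TestManova:
    def test_lambda_is_one_when_group_means_equal_by_construction(self, rng):
        X = rng.standard_normal((10, 4))
        df = pd.DataFrame(np.vstack([X, X]), columns=["spike_rate_hz", "isi1_ms", "isi2_ms", "isi3_ms"])
        df["bird_id"] = ["a"] * 10 + ["b"] * 10
        df["n_spikes"] = 5
        res = manova(df)
        assert res.wilks_lambda == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n_groups", [2, 4])
    def test_single_covariate_matches_oneway_anova(self, rng, n_groups):
        df = feature_frame(rng, [[i, 0, 0, 0] for i in range(n_groups)])
        res = manova(df, covariates=("spike_rate_hz",))
        groups = [g["spike_rate_hz"].to_numpy() for _, g in df.groupby("bird_id")]
        f, p = stats.f_oneway(*groups)
        assert res.f_stat == pytest.approx(f, rel=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_agrees_with_statsmodels_manova(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        df = feature_frame(rng, [[0, 0, 0, 0], [1, 0.5, 0, 0], [0, 1, 1, 0.5]])
        res = manova(df)
        sm = MANOVA.from_formula(
            "spike_rate_hz + isi1_ms + isi2_ms + isi3_ms ~ bird_id", data=df
        ).mv_test()
        tbl = sm.results["bird_id"]["stat"]
        assert res.wilks_lambda == pytest.approx(tbl.loc["Wilks' lambda", "Value"], rel=1e-6)
        assert res.p_value == pytest.approx(tbl.loc["Wilks' lambda", "Pr > F"], rel=1e-4)

    def test_separated_groups_rejected_low_spikers_filtered(self, rng):
        df = feature_frame(rng, [[0, 0, 0, 0], [5, 5, 5, 5]])
        # neurons below the spike-count filter must not influence the test
        junk = df.iloc[:4].copy()
        junk["n_spikes"] = 2
        junk["spike_rate_hz"] = 1e6
        res = manova(pd.concat([df, junk], ignore_index=True))
        assert res.p_value < 1e-6
        assert res.n_obs == len(df)

    def test_pairwise_mode_reports_testable_pairs_and_bonferroni(self, rng):
        df = feature_frame(rng, [[0, 0, 0, 0], [4, 4, 4, 4], [0, 4, 0, 4]])
        tiny = feature_frame(rng, [[9, 9, 9, 9]], n_per_bird=2)
        tiny["bird_id"] = "b3"
        res = pairwise_manova(pd.concat([df, tiny], ignore_index=True))
        pw = res.pairwise
        assert len(pw) == 6  # C(4, 2)
        assert res.bonferroni_m == 3  # pairs that include the 2-neuron bird are untestable
        strong = pw[(pw.bird_1 == "b0") & (pw.bird_2 == "b1")]
        assert bool(strong["significant"].iloc[0])

    def test_type_one_error_near_nominal(self):
        rejections = 0
        reps = 300
        for s in range(reps):
            r = np.random.default_rng(s)
            df = feature_frame(r, [[0, 0, 0, 0]] * 4, n_per_bird=6)
            if manova(df).p_value < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.03)


class TestClusteringDistance:
    def test_tight_clusters_detected(self, rng):
        rows = []
        for b in range(10):
            center = rng.uniform(0, 100, 2)
            for _ in range(8):
                x = center + rng.normal(0, 1.0, 2)
                rows.append({"bird_id": f"b{b}",
                             "first_spike_amplitude_mV": x[0],
                             "first_spike_threshold_mV": x[1]})
        res = clustering_distance_test(pd.DataFrame(rows), seed=0)
        assert res.statistic < 0
        assert res.p_value < 0.01
        assert res.detail["same_mean"] < res.detail["across_mean"]

    def test_degenerate_single_point_flagged(self):
        rows = [{"bird_id": f"b{b}", "first_spike_amplitude_mV": 1.0,
                 "first_spike_threshold_mV": 2.0} for b in range(3) for _ in range(4)]
        res = clustering_distance_test(pd.DataFrame(rows), seed=0)
        assert res.degenerate

    def test_requires_multiple_eligible_birds(self):
        rows = [{"bird_id": "b0", "first_spike_amplitude_mV": i,
                 "first_spike_threshold_mV": i} for i in range(5)]
        with pytest.raises(ValueError):
            clustering_distance_test(pd.DataFrame(rows), seed=0)


def spike_table(rng, bird, n_cells, n_spikes, base_times, jitter):
    rows = []
    for _ in range(n_cells):
        times = np.asarray(base_times) * (1 + rng.normal(0, jitter, len(base_times)))
        row = {"bird_id": bird, "n_spikes": n_spikes}
        row.update({f"t_spike_{i}": t for i, t in enumerate(times)})
        rows.append(row)
    return pd.DataFrame(rows)


class TestSpikeTimeRatios:
    def test_identical_trains_have_zero_ratio_variance(self, rng):
        a = spike_table(rng, "a0", 5, 4, [10, 40, 90, 150], 0.0)
        assert ps._spike_time_ratios(a).var() == 0.0

    def test_variable_cohort_flagged_against_precise_cohort(self, rng):
        precise = pd.concat([spike_table(rng, f"a{i}", 6, 4, [10, 40, 90, 150], 0.01)
                             for i in range(2)])
        sloppy = pd.concat([spike_table(rng, f"j{i}", 6, 4, [10, 40, 90, 150], 0.2)
                            for i in range(2)])
        out = spike_time_ratio_test(sloppy, precise)
        tested = out[out.testable]
        assert (tested["F"] > 1).all()
        assert (tested["p_value"] < 0.01).all()

    def test_cohort_against_itself_is_unity(self, rng):
        a = pd.concat([spike_table(rng, f"a{i}", 8, 4, [10, 40, 90, 150], 0.05)
                       for i in range(2)])
        out = spike_time_ratio_test(a, a)
        same = out[out.bird_a == out.bird_b]
        np.testing.assert_allclose(same["F"], 1.0)

    def test_singleton_groups_discarded(self, rng):
        a = spike_table(rng, "a0", 1, 4, [10, 40, 90, 150], 0.05)  # lone cell
        b = spike_table(rng, "b0", 6, 4, [10, 40, 90, 150], 0.05)
        with pytest.raises(ValueError):
            spike_time_ratio_test(a, b)


class TestWaveformMse:
    def test_identical_waveforms_have_zero_msd(self):
        w = np.tile(np.sin(np.linspace(0, 3, 50)), (4, 1))
        assert np.all(pairwise_waveform_msd(w) == 0.0)

    def test_variable_group_flagged(self, rng):
        base = np.sin(np.linspace(0, 3, 50)) * 40
        tight = base + rng.normal(0, 0.5, (8, 50))
        loose = base + rng.normal(0, 8.0, (8, 50))
        res = waveform_mse_test(pairwise_waveform_msd(loose), pairwise_waveform_msd(tight))
        assert res.statistic > 1
        assert res.p_value < 1e-6

    def test_unequal_window_lengths_refused(self, rng):
        with pytest.raises(ValueError, match="window"):
            pairwise_waveform_msd(rng.standard_normal((3, 50)), rng.standard_normal((3, 40)))

    def test_null_calibration_with_independent_pairs(self):
        # each MSD value comes from a fresh waveform pair, matching the
        # independence assumption of the two-sample F test
        rej = 0
        reps = 300
        for s in range(reps):
            r = np.random.default_rng(10_000 + s)
            a = [np.mean((r.standard_normal(30) - r.standard_normal(30)) ** 2)
                 for _ in range(15)]
            b = [np.mean((r.standard_normal(30) - r.standard_normal(30)) ** 2)
                 for _ in range(15)]
            if waveform_mse_test(a, b).p_value < 0.05:
                rej += 1
        assert rej / reps == pytest.approx(0.05, abs=0.03)


class TestRundown:
    def test_constant_amplitudes_give_unit_ratios(self):
        df = pd.DataFrame({"bird_id": ["a"] * 4 + ["b"] * 4, "order": list(range(4)) * 2,
                           "amplitude": [70.0] * 8})
        out = rundown_check(df)
        assert out["later_vs_first"].statistic == 0.0
        assert out["later_vs_first"].detail["mean_ratio"] == 1.0

    def test_driftless_data_rarely_rejects(self):
        # two cells per bird: one ratio per bird, so the pooled ratios are
        # independent and the t test is calibrated
        keep = 0
        reps = 200
        for s in range(reps):
            r = np.random.default_rng(s)
            rows = []
            for b in range(20):
                amps = 70.0 * (1 + r.normal(0, 0.02, 2))
                rows += [{"bird_id": f"b{b}", "order": i, "amplitude": a}
                         for i, a in enumerate(amps)]
            out = rundown_check(pd.DataFrame(rows))
            if out["later_vs_first"].p_value > 0.05:
                keep += 1
        assert keep / reps >= 0.90

    def test_monotone_drift_detected(self, rng):
        rows = []
        for b in range(10):
            amps = 70.0 * (0.95 ** np.arange(5)) * (1 + rng.normal(0, 0.01, 5))
            rows += [{"bird_id": f"b{b}", "order": i, "amplitude": a}
                     for i, a in enumerate(amps)]
        out = rundown_check(pd.DataFrame(rows))
        assert out["later_vs_first"].p_value < 0.01
        assert out["last_vs_first"].p_value < 0.01


class TestSimilarityCorrelation:
    def matrix_pair(self, rng, n=10):
        pos = rng.uniform(0, 100, (n, 1))
        D = np.abs(pos - pos.T)
        ids = [f"b{i}" for i in range(n)]
        return (pd.DataFrame(100.0 - D, index=ids, columns=ids),
                pd.DataFrame(D, index=ids, columns=ids))

    def test_linear_decreasing_similarity_gives_R_minus_one(self, rng):
        sim, dist = self.matrix_pair(rng)
        res = similarity_distance_correlation(sim, dist)
        assert res.statistic == pytest.approx(-1.0)
        assert res.p_value < 1e-10

    def test_per_bird_mode_returns_row_correlations(self, rng):
        sim, dist = self.matrix_pair(rng)
        df = similarity_distance_correlation(sim, dist, mode="per-bird")
        assert len(df) == 10
        assert (df["R"] < -0.99).all()
        assert (df["n_pairs"] == 9).all()

    def test_shuffled_similarity_uncorrelated(self, rng):
        small = 0
        reps = 50
        for s in range(reps):
            r = np.random.default_rng(s)
            sim, dist = self.matrix_pair(r, n=12)
            perm = r.permutation(12)
            shuffled = sim.to_numpy()[np.ix_(perm, perm)]
            sim2 = pd.DataFrame(shuffled, index=sim.index, columns=sim.columns)
            res = similarity_distance_correlation(sim2, dist)
            if abs(res.statistic) < 0.3 and res.p_value > 0.05:
                small += 1
        assert small / reps >= 0.7

    def test_asymmetry_rejected(self, rng):
        sim, dist = self.matrix_pair(rng)
        sim.iloc[0, 1] += 5.0
        with pytest.raises(ValueError, match="symmetric"):
            similarity_distance_correlation(sim, dist)


class TestVolumeRegression:
    def test_exact_linear_data(self):
        x = np.array([1.0, 2, 3, 4, 5])
        res = volume_vs_covariate(2 * x + 1, x, model="linear")
        assert res.statistic == pytest.approx(1.0)
        assert res.detail["slope"] == pytest.approx(2.0)

    def test_log_model_recovers_log_slope(self, rng):
        m = np.array([10, 30, 100, 300, 1000, 3000], float)
        v = 5.0 + 2.0 * np.log(m) + rng.normal(0, 0.01, len(m))
        res = volume_vs_covariate(v, m, model="log")
        assert res.detail["slope"] == pytest.approx(2.0, rel=0.02)

    def test_constant_volumes_give_zero_slope(self, rng):
        res = volume_vs_covariate(np.full(6, 3.0), np.arange(1, 7.0))
        assert res.detail["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_birds_or_bad_covariate_refused(self):
        with pytest.raises(ValueError):
            volume_vs_covariate([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            volume_vs_covariate([1, 2, 3, 4], [0, 1, 2, 3], model="log")


class TestPca:
    def test_rank_one_matrix_loads_on_first_component(self, rng):
        u = rng.standard_normal((30, 1))
        w = np.array([[1.0, 2.0, -1.0, 0.5]])
        shares = pca_summary(u @ w, standardize=False)
        assert shares[0] == pytest.approx(1.0)

    def test_shares_sum_to_one(self, rng):
        shares = pca_summary(rng.standard_normal((50, 5)))
        assert shares.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(shares) <= 1e-12)

    def test_isotropic_noise_spreads_evenly(self):
        r = np.random.default_rng(3)
        shares = pca_summary(r.standard_normal((4000, 5)))
        np.testing.assert_allclose(shares, 0.2, atol=0.03)

    def test_zero_variance_column_dropped_with_warning(self, rng):
        X = rng.standard_normal((30, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            shares = pca_summary(X)
        assert len(shares) == 2


class TestVarianceRatio:
    def test_f_statistic_direction_and_two_tailed_p(self, rng):
        x = rng.normal(0, 3.0, 40)
        y = rng.normal(0, 1.0, 40)
        res = variance_ratio_test(x, y)
        inv = variance_ratio_test(y, x)
        assert res.statistic == pytest.approx(1.0 / inv.statistic)
        assert res.p_value == pytest.approx(inv.p_value, rel=1e-9)
        assert res.p_value < 0.01
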
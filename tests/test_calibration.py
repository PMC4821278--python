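"""Calibration statistics: regressions, ANCOVA, cross-validation, t-tests."""

import numpy as np
import pytest
import statsmodels.api as sm

from batcensus import (
    Observation,
    ancova_slope_homogeneity,
    cross_validate,
    feature_correlations,
    fit_count_model,
    load_table1,
    paired_t_bonferroni,
    per_day_interaction,
)
from batcensus.audio import AcousticFeatures
from batcensus.calibration import (
    observations_from_frame,
    observations_to_frame,
    read_observations_csv,
    write_observations_csv,
)
from batcensus.experiments import simulated_line_observations


def obs_from_xy(x, counts, cave="A", day=1):
    return [
        Observation(
            time=float(i), cave_id=cave, day=day, bat_count=int(c),
            features=AcousticFeatures(
                rms_db=float(xi), p2p_db=float(xi) + 6.0,
                total_energy=10 ** (float(xi) / 10.0), time=float(i),
            ),
        )
        for i, (xi, c) in enumerate(zip(x, counts))
    ]


@pytest.fixture
def exact_line_obs():
    # counts 10, 100, 1000, 10000 at x = 0, 10, 20, 30: exactly
    # log10(count) = 1 + 0.1 x
    return obs_from_xy([0.0, 10.0, 20.0, 30.0], [10, 100, 1000, 10000])


class TestFitCountModel:
    def test_perfect_line_recovered_exactly(self, exact_line_obs):
        fit = fit_count_model(exact_line_obs, "rms_db", log_transform=True)
        assert fit.slope == pytest.approx(0.1, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.n == 4 and fit.log_transformed

    def test_fewer_than_three_observations_rejected(self):
        obs = obs_from_xy([0.0, 10.0], [10, 100])
        with pytest.raises(ValueError):
            fit_count_model(obs, "rms_db")

    def test_constant_predictor_rejected(self):
        obs = obs_from_xy([5.0, 5.0, 5.0], [10, 20, 30])
        with pytest.raises(ValueError):
            fit_count_model(obs, "rms_db")

    def test_noisy_line_recovered_within_three_stderr(self, rng):
        obs = simulated_line_observations(rng, 300, slope=0.1, intercept=6.0, noise_sd=0.1)
        fit = fit_count_model(obs, "rms_db", log_transform=True)
        assert abs(fit.slope - 0.1) < 3 * fit.slope_stderr

    def test_default_transform_follows_feature_convention(self, exact_line_obs):
        assert fit_count_model(exact_line_obs, "rms_db").log_transformed
        assert fit_count_model(exact_line_obs, "p2p_db").log_transformed
        assert not fit_count_model(exact_line_obs, "total_energy").log_transformed

    def test_log_base_does_not_change_fit_quality(self, rng):
        # identical R^2 and back-transformed predictions whether counts are
        # log10- or ln-transformed; slopes differ by exactly ln(10)
        obs = simulated_line_observations(rng, 150, slope=0.1, intercept=6.0, noise_sd=0.15)
        fit10 = fit_count_model(obs, "rms_db", log_transform=True)
        x = np.array([o.feature("rms_db") for o in obs])
        y_ln = np.log(np.array([o.bat_count for o in obs], dtype=float))
        fit_ln = sm.OLS(y_ln, sm.add_constant(x)).fit()
        assert fit_ln.rsquared == pytest.approx(fit10.r_squared, abs=1e-12)
        assert fit_ln.params[1] == pytest.approx(fit10.slope * np.log(10), rel=1e-9)
        preds10 = 10 ** (fit10.intercept + fit10.slope * x)
        preds_ln = np.exp(fit_ln.params[0] + fit_ln.params[1] * x)
        np.testing.assert_allclose(preds10, preds_ln, rtol=1e-9)

    def test_r_squared_invariant_to_predictor_rescaling(self, rng):
        obs = simulated_line_observations(rng, 100, slope=0.1, intercept=6.0, noise_sd=0.1)
        fit = fit_count_model(obs, "rms_db", log_transform=True)
        scaled = [
            Observation(
                time=o.time, cave_id=o.cave_id, day=o.day, bat_count=o.bat_count,
                features=AcousticFeatures(
                    rms_db=3.0 * o.features.rms_db + 7.0,
                    p2p_db=o.features.p2p_db,
                    total_energy=o.features.total_energy, time=o.time,
                ),
            )
            for o in obs
        ]
        fit_scaled = fit_count_model(scaled, "rms_db", log_transform=True)
        assert fit_scaled.r_squared == pytest.approx(fit.r_squared, abs=1e-12)
        assert fit_scaled.slope == pytest.approx(fit.slope / 3.0, rel=1e-9)


class TestAncova:
    def test_null_groups_usually_not_significant(self, rng):
        obs = simulated_line_observations(
            rng, 200, 0.1, 6.0, 0.1, cave_id="N"
        ) + simulated_line_observations(rng, 200, 0.1, 6.0, 0.1, cave_id="S")
        result = ancova_slope_homogeneity(obs, "rms_db")
        assert result.interaction_p > 0.05
        assert result.df_num == 1 and result.df_den == 396

    def test_different_slopes_detected(self, rng):
        # intercepts keep log-counts in a realistic range for each slope
        obs = simulated_line_observations(
            rng, 200, 0.1, 6.0, 0.05, cave_id="N"
        ) + simulated_line_observations(rng, 200, 0.3, 10.5, 0.05, cave_id="S")
        result = ancova_slope_homogeneity(obs, "rms_db")
        assert result.interaction_p < 0.001
        assert result.f_statistic > 0

    def test_collinear_group_rejected(self):
        obs = obs_from_xy([1.0, 1.0, 1.0], [10, 20, 30], cave="N") + obs_from_xy(
            [0.0, 10.0, 20.0], [10, 100, 1000], cave="S"
        )
        with pytest.raises(ValueError, match="constant within group"):
            ancova_slope_homogeneity(obs, "rms_db")

    def test_single_group_rejected(self, rng):
        obs = simulated_line_observations(rng, 30, 0.1, 6.0, 0.1)
        with pytest.raises(ValueError):
            ancova_slope_homogeneity(obs, "rms_db")


class TestPerDayInteraction:
    def test_days_from_one_line_not_significant(self, rng):
        obs = []
        for day in (1, 2, 3):
            obs += simulated_line_observations(rng, 120, 0.1, 6.0, 0.1, day=day)
        result = per_day_interaction(obs, "rms_db")
        assert result["A"].interaction_p > 0.05

    def test_days_with_different_slopes_detected(self, rng):
        obs = simulated_line_observations(rng, 150, 0.08, 5.5, 0.05, day=1)
        obs += simulated_line_observations(rng, 150, 0.3, 10.5, 0.05, day=2)
        result = per_day_interaction(obs, "rms_db")
        assert result["A"].interaction_p < 0.01

    def test_single_day_rejected(self, rng):
        obs = simulated_line_observations(rng, 30, 0.1, 6.0, 0.1, day=1)
        with pytest.raises(ValueError):
            per_day_interaction(obs, "rms_db")


class TestCrossValidate:
    def test_exact_line_scores_one(self, exact_line_obs):
        fit = fit_count_model(exact_line_obs, "rms_db", log_transform=True)
        # a different sample of exact points on the same line
        other = obs_from_xy([10.0, 30.0, 40.0], [100, 10000, 100000], cave="B")
        cv = cross_validate(fit, other)
        assert cv.r_squared == pytest.approx(1.0, abs=1e-6)
        assert cv.r_squared_sse == pytest.approx(1.0, abs=1e-4)

    def test_permuted_responses_score_near_zero(self, rng):
        obs = simulated_line_observations(rng, 400, 0.1, 6.0, 0.05)
        fit = fit_count_model(obs, "rms_db", log_transform=True)
        counts = np.array([o.bat_count for o in obs])
        rng.shuffle(counts)
        permuted = obs_from_xy(
            [o.feature("rms_db") for o in obs], counts, cave="B"
        )
        cv = cross_validate(fit, permuted)
        assert cv.r_squared < 0.05

    def test_self_application_recovers_own_r_squared(self, rng):
        obs = simulated_line_observations(rng, 200, 0.1, 6.0, 0.2)
        fit = fit_count_model(obs, "rms_db", log_transform=True)
        cv = cross_validate(fit, obs)
        assert cv.r_squared == pytest.approx(fit.r_squared, abs=1e-10)
        # for OLS on its own training data both definitions coincide
        assert cv.r_squared_sse == pytest.approx(fit.r_squared, abs=1e-10)

    def test_too_few_observations_rejected(self, exact_line_obs):
        fit = fit_count_model(exact_line_obs, "rms_db")
        with pytest.raises(ValueError):
            cross_validate(fit, exact_line_obs[:2])


class TestFeatureCorrelations:
    def test_perfectly_coupled_features(self, rng):
        # p2p is rms + 6 dB by construction: r = +1
        obs = simulated_line_observations(rng, 50, 0.1, 6.0, 0.1)
        corr = feature_correlations(obs)
        r, p = corr[("rms_db", "p2p_db")]
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p < 1e-10

    def test_anticorrelated_features(self):
        x = np.linspace(-30.0, -10.0, 20)
        obs = [
            Observation(
                time=float(i), cave_id="A", day=1, bat_count=10,
                features=AcousticFeatures(
                    rms_db=float(xi), p2p_db=-float(xi), total_energy=1.0 + i, time=float(i)
                ),
            )
            for i, xi in enumerate(x)
        ]
        r, _ = feature_correlations(obs)[("rms_db", "p2p_db")]
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_simulator_features_highly_correlated(self, desk_observations):
        corr = feature_correlations(desk_observations)
        for (pair, (r, p)) in corr.items():
            assert r > 0.65, pair
            assert p < 0.001, pair

    def test_constant_feature_rejected(self):
        obs = [
            Observation(
                time=float(i), cave_id="A", day=1, bat_count=10 + i,
                features=AcousticFeatures(-20.0, -14.0 + i, 1.0 + i, float(i)),
            )
            for i in range(5)
        ]
        with pytest.raises(ValueError):
            feature_correlations(obs)


class TestPairedTBonferroni:
    def test_reference_table_north_video_vs_north_model(self):
        table = load_table1()
        result = paired_t_bonferroni(table["N_v"], table["N_N"], n_comparisons=4)
        assert result.df == 8  # 9 complete pairs
        assert result.adjusted_p == pytest.approx(0.737, abs=5e-4)

    def test_reference_table_south_video_vs_north_model(self):
        # day 1 South is missing: 8 complete pairs; Bonferroni caps at 1
        table = load_table1()
        result = paired_t_bonferroni(table["S_v"], table["S_N"], n_comparisons=4)
        assert result.df == 7
        assert result.adjusted_p == 1.0

    def test_constant_differences_rejected(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            paired_t_bonferroni(x, x, n_comparisons=4)
        with pytest.raises(ValueError):
            paired_t_bonferroni(x, x + 2.0, n_comparisons=4)

    def test_bonferroni_capped_and_monotone(self, rng):
        x = rng.normal(size=12)
        y = x + rng.normal(scale=0.5, size=12)
        results = [paired_t_bonferroni(x, y, m) for m in (1, 2, 4, 50)]
        adj = [r.adjusted_p for r in results]
        assert all(a <= b for a, b in zip(adj, adj[1:]))
        assert adj[-1] <= 1.0
        assert results[0].adjusted_p == results[0].raw_p

    def test_incomplete_pairs_dropped(self):
        x = np.array([1.0, np.nan, 3.0, 4.0, 2.0])
        y = np.array([1.5, 2.0, np.nan, 3.0, 4.0])
        result = paired_t_bonferroni(x, y, n_comparisons=2)
        assert result.df == 2  # 3 complete pairs


def test_observations_csv_roundtrip(tmp_path, rng):
    obs = simulated_line_observations(rng, 10, 0.1, 6.0, 0.1)
    path = tmp_path / "observations.csv"
    write_observations_csv(obs, path)
    loaded = read_observations_csv(path)
    assert len(loaded) == len(obs)
    for a, b in zip(loaded, obs):
        assert (a.time, a.cave_id, a.day, a.bat_count) == (b.time, b.cave_id, b.day, b.bat_count)
        assert a.features.rms_db == pytest.approx(b.features.rms_db, rel=1e-9)
        assert a.features.total_energy == pytest.approx(b.features.total_energy, rel=1e-9)
    # in-memory DataFrame conversion is lossless
    frame = observations_to_frame(obs)
    assert observations_from_frame(frame) == obs
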
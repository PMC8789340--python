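import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hothand as hh
from hothand.probmodel import ModelConfig
from hothand.shotlog import ConfigurationError


@pytest.fixture(scope="module")
def covariate_league():
    cfg = hh.SynthConfig(n_players=10, games_per_player=60, shots_per_game_mean=12,
                         probability_column="none", seed=71)
    return hh.generate_league(cfg, seed=71)


class TestBaselineModel:
    def test_recovers_truth_within_tolerance(self, covariate_league):
        log, truth = covariate_league
        model = hh.fit_baseline_model(log)
        pred = model.predict(log)
        assert np.mean(np.abs(pred - truth["baseline_prob"].to_numpy())) < 0.03

    def test_intercept_only_predicts_training_rate(self):
        df = pd.DataFrame(dict(player_id="p", game_id="g", order_index=range(100),
                               outcome=[1] * 60 + [0] * 40))
        model = hh.fit_baseline_model(
            hh.ShotLog(df), ModelConfig(numeric_covariates=(), use_shot_type=False)
        )
        assert model.predict(df) == pytest.approx(np.full(100, 0.6), abs=1e-6)

    def test_single_class_training_is_an_error(self):
        df = pd.DataFrame(dict(player_id="p", game_id="g", order_index=range(10),
                               outcome=1))
        with pytest.raises(ConfigurationError):
            hh.fit_baseline_model(
                hh.ShotLog(df), ModelConfig(numeric_covariates=(), use_shot_type=False)
            )

    def test_unseen_shot_type_falls_back_to_baseline(self, covariate_league, caplog):
        log, _ = covariate_league
        model = hh.fit_baseline_model(log)
        row = log.df.iloc[[0]].copy()
        row["shot_type"] = "sky_hook"
        import logging

        with caplog.at_level(logging.WARNING, logger="hothand.probmodel"):
            p = model.predict(row)
        assert 0.0 < p[0] < 1.0
        assert any("unseen" in r.message for r in caplog.records)

    def test_spline_model_fits_and_predicts(self, covariate_league):
        log, truth = covariate_league
        model = hh.fit_baseline_model(log, ModelConfig(distance_spline_df=4))
        pred = model.predict(log)
        assert np.mean(np.abs(pred - truth["baseline_prob"].to_numpy())) < 0.04

    def test_json_round_trip(self, covariate_league, tmp_path):
        log, _ = covariate_league
        model = hh.fit_baseline_model(log)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = hh.ShotProbabilityModel.from_json(path)
        np.testing.assert_allclose(back.predict(log), model.predict(log))


class TestLOSO:
    def test_predictions_are_out_of_sample(self, covariate_league):
        log, _ = covariate_league
        filled = hh.loso_predict(log)
        assert filled.has_probabilities
        # leakage check: perturbing held-out-season outcomes must not move
        # that season's predictions
        df = log.df.copy()
        s2 = df["season"] == "S2"
        rng = np.random.default_rng(3)
        df.loc[s2, "outcome"] = rng.integers(0, 2, size=int(s2.sum()))
        refilled = hh.loso_predict(hh.ShotLog(df))
        np.testing.assert_allclose(
            refilled.df.loc[s2.to_numpy(), "make_probability"],
            filled.df.loc[s2.to_numpy(), "make_probability"],
        )

    def test_season_reliability_curves_agree(self, covariate_league):
        log, _ = covariate_league
        filled = hh.loso_predict(log)
        df = filled.df
        rates = []
        for s, sub in df.groupby("season"):
            curve = hh.reliability_curve(sub["make_probability"], sub["outcome"])
            big = curve.bin_counts > 100
            rates.append(np.abs(curve.predicted_mean[big] - curve.observed_rate[big]))
        assert max(float(r.max()) for r in rates) < 0.1

    def test_single_season_is_an_error(self, covariate_league):
        log, _ = covariate_league
        df = log.df[log.df["season"] == "S1"]
        with pytest.raises(ConfigurationError, match="k-fold"):
            hh.loso_predict(hh.ShotLog(df))

    def test_missing_season_column_is_an_error(self, covariate_league):
        log, _ = covariate_league
        df = log.df.drop(columns=["season"])
        with pytest.raises(ConfigurationError):
            hh.loso_predict(hh.ShotLog(df))

    def test_near_separable_truth_yields_high_accuracy(self):
        rng = np.random.default_rng(8)
        n = 4000
        easy = rng.integers(0, 2, size=n).astype(bool)
        df = pd.DataFrame(
            dict(player_id="p", game_id=np.arange(n) // 10, order_index=np.arange(n) % 10,
                 distance_to_basket=np.where(easy, 1.0, 28.0) + rng.normal(0, 0.2, n),
                 defender_distance=5.0, touch_time=2.0, dribbles=1,
                 shot_type="jump_shot",
                 season=np.where(np.arange(n) < n // 2, "S1", "S2"))
        )
        p_true = np.where(easy, 0.99, 0.01)
        df["outcome"] = (rng.random(n) < p_true).astype(int)
        filled = hh.loso_predict(hh.ShotLog(df))
        acc = hh.accuracy(filled.df["make_probability"], filled.df["outcome"])
        assert acc > 0.95


class TestReliabilityAndAccuracy:
    def test_perfect_binary_predictions_occupy_end_bins(self):
        y = np.array([0, 0, 1, 1, 1])
        p = np.array([0.001, 0.001, 0.999, 0.999, 0.999])
        curve = hh.reliability_curve(p, y)
        occ = np.nonzero(curve.occupied)[0]
        assert list(occ) == [0, 19]
        np.testing.assert_allclose(curve.observed_rate[occ], [0.0, 1.0])

    def test_constant_half_probabilities_single_bin(self):
        rng = np.random.default_rng(5)
        y = rng.permutation([0, 1] * 200)
        curve = hh.reliability_curve(np.full(400, 0.5), y)
        assert curve.occupied.sum() == 1
        idx = int(np.nonzero(curve.occupied)[0][0])
        assert curve.predicted_mean[idx] == pytest.approx(0.5)
        assert curve.observed_rate[idx] == pytest.approx(0.5)

    def test_calibrated_by_construction_curve_hugs_diagonal(self):
        rng = np.random.default_rng(6)
        p = rng.random(30_000)
        y = (rng.random(30_000) < p).astype(int)
        curve = hh.reliability_curve(p, y)
        ok = 0
        occ = np.nonzero(curve.occupied)[0]
        for b in occ:
            n = curve.bin_counts[b]
            pb = curve.predicted_mean[b]
            lo, hi = stats.binom.ppf([0.025, 0.975], n, pb) / n
            ok += lo <= curve.observed_rate[b] <= hi
        assert ok / occ.size >= 0.9

    def test_probability_sum_preserved_across_bins(self):
        rng = np.random.default_rng(7)
        p = rng.random(1000)
        y = rng.integers(0, 2, 1000)
        curve = hh.reliability_curve(p, y)
        assert curve.bin_counts.sum() == 1000

    def test_uneven_bin_width_warns(self):
        with pytest.warns(UserWarning, match="truncated"):
            hh.reliability_curve(np.array([0.2, 0.9]), np.array([0, 1]), bin_width=0.3)

    def test_accuracy_extremes_and_ties(self):
        y = np.array([1, 0, 1, 0])
        assert hh.accuracy(np.array([1.0, 0.0, 1.0, 0.0]), y) == 1.0
        assert hh.accuracy(np.array([0.0, 1.0, 0.0, 1.0]), y) == 0.0
        # ties at the threshold count as predicted success
        assert hh.accuracy(np.full(4, 0.5), y) == 0.5
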
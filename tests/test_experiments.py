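"""Batch runner and the robust statistics against independent oracles."""

import numpy as np
import pandas as pd
import pingouin
import pytest
from scipy import stats

from pestgrid import (
    BatchResult,
    SimConfig,
    brown_forsythe_anova,
    cohens_d,
    compare_strategies,
    levene_test,
    run_batch,
    run_simulation,
    summarize,
    welch_anova,
)

SMALL = SimConfig(columns=5, rows=5, hours=12, initial_affected_areas=1)


class TestRunBatch:
    def test_single_replicate_equals_single_run(self):
        batch = run_batch(SMALL, "neighbor", 1, base_seed=7)
        final = run_simulation(SMALL.replace(strategy="neighbor", seed=7)).final
        row = batch.table.iloc[0]
        assert row["power"] == final.avg_power
        assert row["crop_health"] == final.crop_health_pct
        assert row["alive_bugs"] == final.alive_bugs_pct
        assert row["pesticide"] == final.pesticide_per_station

    def test_batches_reproducible_and_seeds_distinct(self):
        b1 = run_batch(SMALL, "neighbor", 5, base_seed=3)
        b2 = run_batch(SMALL, "neighbor", 5, base_seed=3)
        assert b1.table.equals(b2.table)
        assert b1.table["seed"].is_unique

    def test_csv_round_trip(self, tmp_path):
        batch = run_batch(SMALL, "broadcast", 3, base_seed=0)
        path = tmp_path / "batch.csv"
        batch.to_csv(path)
        loaded = BatchResult.from_csv(path)
        assert loaded.strategy == "broadcast"
        assert np.allclose(loaded.table.to_numpy(), batch.table.to_numpy())


class TestSummarize:
    def test_hand_computed_mean_and_sample_sd(self):
        batch = BatchResult(
            "x",
            pd.DataFrame(
                {
                    "replicate": [0, 1, 2],
                    "seed": [0, 1, 2],
                    "power": [1.0, 2.0, 3.0],
                    "crop_health": [5.0, 5.0, 5.0],
                    "alive_bugs": [0.0, 0.0, 3.0],
                    "pesticide": [1.0, 1.0, 1.0],
                }
            ),
        )
        s = summarize(batch).set_index("metric")
        assert s.loc["power", "mean"] == pytest.approx(2.0)
        assert s.loc["power", "sd"] == pytest.approx(1.0)  # n-1 denominator
        assert s.loc["crop_health", "sd"] == pytest.approx(0.0)

    def test_single_replicate_sd_rejected(self):
        batch = run_batch(SMALL, "neighbor", 1, base_seed=0)
        with pytest.raises(ValueError):
            summarize(batch)


def _hand_levene_mean(groups):
    # textbook mean-centred Levene: one-way F on z_ij = |x_ij - mean_i|
    z = [np.abs(np.asarray(g) - np.mean(g)) for g in groups]
    return stats.f_oneway(*z)


class TestLevene:
    def test_matches_hand_computed_formula(self):
        groups = [[1.0, 2.0, 3.0, 4.0], [10.0, 20.0, 30.0, 40.0]]
        stat, p = levene_test(groups)
        expected_stat, expected_p = _hand_levene_mean(groups)
        assert stat == pytest.approx(expected_stat)
        assert p == pytest.approx(expected_p)

    def test_identical_groups_give_zero_statistic(self):
        stat, p = levene_test([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_location_shift_invariance(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(0, 1, 20), rng.normal(0, 3, 20)]
        shifted = [g + 100.0 for g in groups]
        assert levene_test(groups)[0] == pytest.approx(levene_test(shifted)[0])

    def test_degenerate_constant_data_rejected(self):
        with pytest.raises(ValueError):
            levene_test([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])


class TestWelchAnova:
    def test_equal_sample_means_give_zero_statistic(self):
        f, *_ = welch_anova([[1.0, 2.0, 3.0], [0.0, 2.0, 4.0]])
        assert f == pytest.approx(0.0)

    def test_matches_pingouin_three_groups(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(0, 1, 15), rng.normal(1, 2, 25), rng.normal(0.5, 0.5, 10)]
        f, df1, df2, p = welch_anova(groups)
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(["a", "b", "c"], [15, 25, 10]),
            }
        )
        oracle = pingouin.welch_anova(data=df, dv="y", between="g")
        assert f == pytest.approx(float(oracle["F"].iloc[0]))
        assert df1 == pytest.approx(float(oracle["ddof1"].iloc[0]))
        assert df2 == pytest.approx(float(oracle["ddof2"].iloc[0]))
        assert p == pytest.approx(float(oracle["p_unc"].iloc[0]))

    def test_two_groups_equal_squared_welch_t(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 3, 20)
        f, df1, df2, p = welch_anova([a, b])
        t_res = stats.ttest_ind(a, b, equal_var=False)
        assert f == pytest.approx(t_res.statistic**2, abs=1e-10)
        assert df2 == pytest.approx(t_res.df)
        assert p == pytest.approx(t_res.pvalue)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError):
            welch_anova([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])

    def test_type_one_error_rate_near_nominal(self):
        # identical-distribution groups: the 0.05-level rejection rate
        # over 1000 resamples (3 groups of 30) stays within 5% +/- 1.5%
        rng = np.random.default_rng(3)
        rejections = 0
        n_resamples = 1000
        for _ in range(n_resamples):
            groups = rng.normal(0.0, 1.0, size=(3, 30))
            _, _, _, p = welch_anova(list(groups))
            rejections += p < 0.05
        assert abs(rejections / n_resamples - 0.05) <= 0.015


class TestBrownForsythe:
    def test_identical_groups_give_zero_statistic(self):
        f, *_ = brown_forsythe_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert f == pytest.approx(0.0)

    def test_equal_group_sizes_match_classical_f_statistic(self):
        # with equal n the variance-weighted denominator reduces to the
        # classical MSE, so the statistic equals one-way ANOVA's F
        rng = np.random.default_rng(4)
        groups = [rng.normal(mu, 1.0, 30) for mu in (0.0, 0.3, 0.8)]
        f, *_ = brown_forsythe_anova(groups)
        assert f == pytest.approx(stats.f_oneway(*groups).statistic, abs=1e-10)

    def test_two_equal_sized_groups_match_squared_welch_t(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 25), rng.normal(1, 2, 25)
        f, df1, df2, p = brown_forsythe_anova([a, b])
        t_res = stats.ttest_ind(a, b, equal_var=False)
        assert f == pytest.approx(t_res.statistic**2, abs=1e-10)
        assert df2 == pytest.approx(t_res.df)
        assert p == pytest.approx(t_res.pvalue)


class TestCohensD:
    def test_hand_computed_value(self):
        assert cohens_d([1.0, 2.0, 3.0], [2.0, 3.0, 4.0]) == pytest.approx(-1.0)

    def test_identical_samples_give_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(0.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 15)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_matches_pingouin(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 40), rng.normal(0.6, 1.4, 30)
        assert cohens_d(a, b) == pytest.approx(
            pingouin.compute_effsize(a, b, eftype="cohen")
        )

    def test_recovers_true_standardized_difference(self):
        rng = np.random.default_rng(8)
        delta = 0.8
        a = rng.normal(delta, 1.0, 1000)
        b = rng.normal(0.0, 1.0, 1000)
        assert cohens_d(a, b) == pytest.approx(delta, abs=0.1)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestCompareStrategies:
    def _fake_batch(self, name, rng, shift=0.0):
        n = 100
        return BatchResult(
            name,
            pd.DataFrame(
                {
                    "replicate": range(n),
                    "seed": range(n),
                    "power": rng.normal(shift, 1, n),
                    "crop_health": rng.normal(99 + shift, 0.1, n),
                    "alive_bugs": rng.normal(3 + shift, 1, n),
                    "pesticide": rng.normal(1 + shift, 0.2, n),
                }
            ),
        )

    def test_well_separated_groups_detected(self):
        rng = np.random.default_rng(9)
        batches = {
            "neighbor": self._fake_batch("neighbor", rng, shift=0.0),
            "lowcost_neighbor": self._fake_batch("lowcost_neighbor", rng, shift=5.0),
        }
        report = compare_strategies(batches)
        power_rows = report.robust_tests.query(
            "metric == 'power' and comparison != 'all'"
        )
        assert (power_rows["p"] < 0.001).all()
        assert (power_rows["sig"] == "**").all()
        d = report.effects.query("metric == 'power'")["cohens_d"].iloc[0]
        assert d == pytest.approx(5.0, abs=0.6)

    def test_near_identical_groups_give_small_effects(self):
        rng = np.random.default_rng(10)
        batches = {
            "a": self._fake_batch("a", rng),
            "b": self._fake_batch("b", rng),
            "c": self._fake_batch("c", rng),
        }
        report = compare_strategies(batches, pairs=[("a", "b")])
        assert (report.robust_tests["p"] > 0.001).all()
        assert abs(report.effects["cohens_d"]).max() < 0.5

    def test_report_structure(self):
        rng = np.random.default_rng(11)
        batches = {
            "broadcast": self._fake_batch("broadcast", rng, 2.0),
            "neighbor": self._fake_batch("neighbor", rng, 1.0),
            "lowcost_neighbor": self._fake_batch("lowcost_neighbor", rng, 0.0),
        }
        report = compare_strategies(batches)
        assert set(report.summary["strategy"]) == set(batches)
        for metric in ("power", "crop_health", "alive_bugs", "pesticide"):
            assert f"{metric}_mean" in report.summary.columns
            assert f"{metric}_sd" in report.summary.columns
        # 2 comparisons x 4 metrics x 2 tests
        assert len(report.robust_tests) == 16
        assert set(report.robust_tests["test"]) == {"welch", "brown_forsythe"}
        assert set(report.effects["pair"]) == {"lowcost_neighbor - neighbor"}
        assert len(report.effects) == 4
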
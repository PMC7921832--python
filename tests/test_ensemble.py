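import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elaforecast.core import ArimaConfig, ElmanConfig, RunConfig, train_test_split
from elaforecast.ensemble import (
    ELAModel,
    ForecastResult,
    compare_models,
    demand,
    demand_from_forecasts,
    ela_forecast,
    mape,
    scan_split_k,
)


def _fast_config(seed=0, **kw):
    """Reduced-size pipeline configuration for quick ensemble tests."""
    base = dict(seed=seed,
                elman=ElmanConfig(epochs=100),
                arima=ArimaConfig(max_p=2, max_q=1))
    base.update(kw)
    return RunConfig(**base)


@pytest.fixture(scope="module")
def fitted(flu_series):
    train, test = train_test_split(flu_series, 21)
    res = ELAModel(train, _fast_config(seed=7)).fit()
    return train, test, res


class TestMape:
    def test_perfect_forecast_is_zero(self):
        assert mape([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_computed_example(self):
        assert mape([100, 200], [110, 180]) == pytest.approx(10.0)

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_common_scaling(self, c):
        a = np.array([100.0, 200.0, 50.0])
        p = np.array([90.0, 230.0, 55.0])
        assert mape(c * a, c * p) == pytest.approx(mape(a, p))

    def test_zero_actual_rejected(self):
        with pytest.raises(ValueError):
            mape([1.0, 0.0], [1.0, 1.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mape([1.0, 2.0], [1.0])


class TestDemand:
    def test_alpha_one_is_identity(self):
        assert demand(79283.0, 1.0) == 79283.0

    def test_scales_linearly_in_alpha(self):
        assert demand(100.0, 1.2) == pytest.approx(120.0)
        assert demand(100.0, 2.4) == pytest.approx(2 * demand(100.0, 1.2))

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            demand(10.0, 0.0)

    def test_negative_weekly_forecasts_floored_only_for_demand(self):
        fc = np.array([10.0, -5.0, 20.0])
        assert demand_from_forecasts(fc, 1.0) == 30.0
        # MAPE keeps the raw forecasts
        assert mape([10.0, 5.0, 20.0], fc) == pytest.approx(200.0 / 3)


class TestForecastResult:
    def test_length_must_match_horizon(self):
        with pytest.raises(ValueError):
            ForecastResult("m", np.ones(3), horizon=4)

    def test_evaluate_attaches_mape_and_demand(self):
        fr = ForecastResult("m", np.array([110.0, 180.0]), horizon=2)
        fr.evaluate([100.0, 200.0], alpha=1.0)
        assert fr.mape == pytest.approx(10.0)
        assert fr.demand == pytest.approx(290.0)


class TestElaPipeline:
    def test_forecast_is_sum_of_component_forecasts(self, fitted):
        _, _, res = fitted
        f1, f2 = res.component_forecasts(21)
        np.testing.assert_allclose(res.forecast(21), f1 + f2, rtol=1e-12)

    def test_groups_reconstruct_training_series(self, fitted):
        train, _, res = fitted
        np.testing.assert_allclose(res.x1 + res.x2, train.values,
                                   atol=1e-8 * np.max(train.values))

    def test_deterministic_under_fixed_seed(self, flu_series):
        train, _ = train_test_split(flu_series, 21)
        cfg = _fast_config(seed=3, elman=ElmanConfig(epochs=30))
        a = ELAModel(train, cfg).fit().forecast(10)
        b = ELAModel(train, cfg).fit().forecast(10)
        np.testing.assert_array_equal(a, b)

    def test_forecast_result_has_protocol_shape(self, fitted):
        train, test, res = fitted
        fr = res.forecast_result(21, actual=test.values)
        assert fr.horizon == 21 and len(fr.point_forecasts) == 21
        assert fr.mape >= 0
        assert fr.demand == pytest.approx(
            demand_from_forecasts(fr.point_forecasts, 1.0))

    def test_summary_mentions_fit_ingredients(self, fitted):
        _, _, res = fitted
        s = res.summary()
        assert "IMFs" in s and "ARIMA" in s and "Elman" in s

    def test_short_training_series_rejected(self, flu_series):
        short, _ = train_test_split(flu_series, len(flu_series) - 30)
        with pytest.raises(ValueError, match=">= 60"):
            ELAModel(short, _fast_config())

    def test_unreachable_split_k_reported_with_guidance(self, flu_series):
        train, _ = train_test_split(flu_series, 21)
        cfg = _fast_config(split_k=9)
        with pytest.raises(ValueError, match="split_k"):
            ELAModel(train, cfg).fit()

    def test_functional_wrapper_matches_results_object(self, flu_series):
        train, _ = train_test_split(flu_series, 21)
        cfg = _fast_config(seed=5, elman=ElmanConfig(epochs=30))
        fr = ela_forecast(train, 21, cfg)
        direct = ELAModel(train, cfg).fit().forecast(21)
        np.testing.assert_array_equal(fr.point_forecasts, direct)

    def test_from_dataframe_constructor(self, flu_series):
        df = flu_series.to_frame()
        model = ELAModel.from_dataframe(df.iloc[:200], _fast_config())
        assert len(model.train) == 200


@pytest.fixture(scope="module")
def table(flu_series):
    return compare_models(flu_series, 21, _fast_config(seed=7))


class TestCompareModels:
    def test_reports_all_four_models(self, table):
        assert list(table["model"]) == [
            "ARIMA-original", "ARIMA-dummy", "ELMAN", "ELA"]

    def test_mapes_nonnegative_and_demands_positive(self, table):
        assert (table["mape_pct"] >= 0).all()
        assert (table["demand"] > 0).all()

    def test_forecasts_share_the_split(self, table):
        for fc in table.attrs["forecasts"].values():
            assert len(fc) == 21
        assert len(table.attrs["actual"]) == 21

    def test_single_step_horizon_boundary(self, flu_series):
        cfg = _fast_config(seed=2, elman=ElmanConfig(epochs=30), n_test=1)
        t = compare_models(flu_series, 1, cfg)
        assert len(t) == 4 and (t["mape_pct"] >= 0).all()


class TestScanSplitK:
    def test_single_candidate_returns_it(self, flu_series):
        train, _ = train_test_split(flu_series, 21)
        cfg = _fast_config(seed=1, elman=ElmanConfig(epochs=30))
        best, table = scan_split_k(train, 10, [2], cfg)
        assert best == 2 and len(table) == 1

    def test_returned_k_attains_minimum_validation_mape(self, flu_series):
        train, _ = train_test_split(flu_series, 21)
        cfg = _fast_config(seed=1, elman=ElmanConfig(epochs=30))
        best, table = scan_split_k(train, 10, [1, 2, 3], cfg)
        row = table.set_index("split_k")["val_mape_pct"]
        assert row[best] == row.min()

    def test_empty_range_rejected(self, flu_series):
        train, _ = train_test_split(flu_series, 21)
        with pytest.raises(ValueError):
            scan_split_k(train, 10, [], _fast_config())
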
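"""The ELA decomposition-ensemble forecaster and its evaluation harness.

Pipeline: EMD-decompose the training series; group the modes into a
high-frequency component ``x1`` (IMF1..split_k) and a low-frequency /
seasonal component ``x2`` (the rest plus residual); forecast ``x1`` with
an Elman recurrent network and ``x2`` with an AIC-selected ARIMA; sum
the two component forecasts; project total predicted cases ``p`` to the
emergency medicine reserve demand ``S = p * alpha``.

The core is exposed as a model/results pair: :class:`ELAModel` is
constructed from a training :class:`~elaforecast.core.TimeSeries` and a
:class:`~elaforecast.core.RunConfig`; ``fit()`` runs decomposition and
component estimation and returns an :class:`ELAResults` carrying the
fitted sub-models, forecasts, diagnostics and a ``summary()`` table.
Thin functions (``ela_forecast``, ``compare_models``, ``scan_split_k``,
``mape``, ``demand``) wrap the pair for scripted use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import arima as _arima
from . import elman as _elman
from .core import RunConfig, TimeSeries, train_test_split
from .emd import EmdConfig, IMFSet, decompose, reconstruct_groups


# ---------------------------------------------------------------------------
# evaluation and demand projection


def mape(actual, predicted) -> float:
    """Mean absolute percentage error, in percent.

    MAPE = (100/n) * sum |x_hat_t - x_t| / |x_t|; undefined (raises)
    when any actual is zero.
    """
    a = np.asarray(getattr(actual, "values", actual), dtype=float)
    p = np.asarray(getattr(predicted, "values", predicted), dtype=float)
    if a.shape != p.shape or a.ndim != 1 or len(a) < 1:
        raise ValueError("actual and predicted must be equal-length 1-D sequences")
    if np.any(a == 0.0):
        raise ValueError("MAPE undefined: an actual observation is zero")
    return float(np.mean(np.abs((p - a) / a))) * 100.0


def demand(forecast_cases: float, alpha: float) -> float:
    """Reserve demand S = p * alpha (alpha = per-case medicine demand)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if forecast_cases < 0:
        raise ValueError("forecast case total must be nonnegative")
    return float(forecast_cases) * float(alpha)


def demand_from_forecasts(point_forecasts, alpha: float) -> float:
    """Demand from weekly forecasts: negatives floored at 0, then summed.

    The floor applies only here — model evaluation (MAPE) always uses the
    raw forecasts.
    """
    p = np.asarray(point_forecasts, dtype=float)
    return demand(float(np.sum(np.clip(p, 0.0, None))), alpha)


@dataclass
class ForecastResult:
    """Point forecasts of one model over a horizon, plus derived metrics."""

    model_name: str
    point_forecasts: np.ndarray
    horizon: int
    mape: float | None = None
    demand: float | None = None

    def __post_init__(self) -> None:
        self.point_forecasts = np.asarray(self.point_forecasts, dtype=float)
        if len(self.point_forecasts) != self.horizon:
            raise ValueError("forecast length must equal horizon")
        if self.mape is not None and self.mape < 0:
            raise ValueError("MAPE cannot be negative")

    def evaluate(self, actual, alpha: float | None = None) -> "ForecastResult":
        """Attach MAPE against actuals (and demand when alpha given)."""
        self.mape = mape(actual, self.point_forecasts)
        if alpha is not None:
            self.demand = demand_from_forecasts(self.point_forecasts, alpha)
        return self


# ---------------------------------------------------------------------------
# the ELA model / results pair


class ELAModel:
    """Decomposition-ensemble forecaster bound to a training series.

    Parameters
    ----------
    train : TimeSeries
        Training observations (>= 60 weeks).
    config : RunConfig, optional
        Pipeline configuration; ``config.split_k`` sets the IMF grouping
        boundary and ``config.seed`` drives all randomness.
    """

    def __init__(self, train: TimeSeries, config: RunConfig | None = None):
        if len(train) < 60:
            raise ValueError(f"ELA needs >= 60 training observations, "
                             f"got {len(train)}")
        self.train = train
        self.config = config or RunConfig()
        self.config.validate()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: RunConfig | None = None,
                       name: str = "series") -> "ELAModel":
        """Build from a DataFrame with ``date`` and ``value`` columns."""
        ts = TimeSeries(pd.DatetimeIndex(pd.to_datetime(df["date"])),
                        df["value"].to_numpy(dtype=float), name=name)
        return cls(ts, config)

    def fit(self) -> "ELAResults":
        """Decompose, group, and estimate both component forecasters."""
        cfg = self.config
        emd_cfg = EmdConfig(sd_tolerance=cfg.emd.sd_tolerance,
                            max_sift_iterations=cfg.emd.max_sift_iterations,
                            max_imfs=cfg.emd.max_imfs)
        imfset = decompose(self.train.values, emd_cfg)
        if imfset.n_imfs < cfg.split_k:
            raise ValueError(
                f"EMD produced {imfset.n_imfs} IMFs but split_k={cfg.split_k}; "
                f"lower split_k (or relax max_imfs) and re-run")
        x1, x2 = reconstruct_groups(imfset, cfg.split_k)
        el_cfg = _elman.ElmanTrainConfig(
            window=cfg.elman.window, hidden_size=cfg.elman.hidden_size,
            epochs=cfg.elman.epochs, learning_rate=cfg.elman.learning_rate,
            momentum=cfg.elman.momentum, feedback_gain=cfg.elman.feedback_gain,
            init_scale=cfg.elman.init_scale, seed=cfg.seed)
        elman_net = _elman.train(x1, el_cfg)
        order, aic_table = _arima.select_order(
            x2, max_p=cfg.arima.max_p, max_q=cfg.arima.max_q, d=cfg.arima.d)
        arima_model = _arima.fit(x2, order)
        return ELAResults(model=self, imfset=imfset, x1=x1, x2=x2,
                          elman_net=elman_net, arima_model=arima_model,
                          aic_table=aic_table)


@dataclass
class ELAResults:
    """Fitted ELA ensemble: sub-models, components and forecast methods."""

    model: ELAModel
    imfset: IMFSet
    x1: np.ndarray
    x2: np.ndarray
    elman_net: _elman.ElmanNetwork
    arima_model: _arima.ArimaModel
    aic_table: list = field(default_factory=list)

    def component_forecasts(self, horizon: int) -> tuple[np.ndarray, np.ndarray]:
        """(Elman forecast of x1, ARIMA forecast of x2) over the horizon."""
        f1 = _elman.forecast(self.elman_net, self.x1, horizon)
        f2 = _arima.forecast(self.arima_model, horizon)
        return f1, f2

    def forecast(self, horizon: int | None = None) -> np.ndarray:
        """Summed ELA point forecast over ``horizon`` weeks."""
        horizon = horizon or self.model.config.n_test
        f1, f2 = self.component_forecasts(horizon)
        return f1 + f2

    def forecast_result(self, horizon: int | None = None, actual=None,
                        alpha: float | None = None) -> ForecastResult:
        horizon = horizon or self.model.config.n_test
        fr = ForecastResult("ELA", self.forecast(horizon), horizon)
        if actual is not None:
            fr.evaluate(actual, alpha if alpha is not None
                        else self.model.config.alpha)
        else:
            fr.demand = demand_from_forecasts(fr.point_forecasts,
                                              alpha or self.model.config.alpha)
        return fr

    def summary(self) -> str:
        """Human-readable fit summary (statsmodels style)."""
        cfg = self.model.config
        lines = [
            "ELA decomposition-ensemble forecast model",
            "=" * 45,
            f"training observations : {len(self.model.train)}",
            f"IMFs extracted        : {self.imfset.n_imfs} (+ residual)",
            f"grouping split_k      : {cfg.split_k} "
            f"(x1 = IMF1..{cfg.split_k}, x2 = rest + residual)",
            f"x1 forecaster         : Elman({cfg.elman.window} lags, "
            f"{cfg.elman.hidden_size} hidden, gain {cfg.elman.feedback_gain})",
            f"x2 forecaster         : ARIMA{self.arima_model.order} "
            f"(AIC {self.arima_model.aic:.2f})",
            f"demand coefficient    : alpha = {cfg.alpha}",
            f"seed                  : {cfg.seed}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers and baselines


def ela_forecast(train: TimeSeries, horizon: int,
                 config: RunConfig | None = None) -> ForecastResult:
    """Fit the ELA ensemble on ``train`` and forecast ``horizon`` weeks."""
    config = config or RunConfig()
    res = ELAModel(train, config).fit()
    return res.forecast_result(horizon)


def _arima_original_forecast(train_values, horizon, cfg: RunConfig):
    order, _ = _arima.select_order(train_values, max_p=cfg.arima.max_p,
                                   max_q=cfg.arima.max_q, d=cfg.arima.d_raw)
    model = _arima.fit(train_values, order)
    return _arima.forecast(model, horizon), model


def _arima_dummy_forecast(train_values, horizon, cfg: RunConfig):
    model, trend = _arima.fit_trend_augmented(
        train_values, hp_lambda=cfg.hp.lamb, max_p=cfg.arima.max_p,
        max_q=cfg.arima.max_q, d=cfg.arima.d_raw)
    return _arima.forecast_trend_augmented(model, trend, horizon), model


def _elman_forecast(train_values, horizon, cfg: RunConfig):
    el_cfg = _elman.ElmanTrainConfig(
        window=cfg.elman.window, hidden_size=cfg.elman.hidden_size,
        epochs=cfg.elman.epochs, learning_rate=cfg.elman.learning_rate,
        momentum=cfg.elman.momentum, feedback_gain=cfg.elman.feedback_gain,
        init_scale=cfg.elman.init_scale, seed=cfg.seed)
    net = _elman.train(train_values, el_cfg)
    return _elman.forecast(net, train_values, horizon), net


def compare_models(series: TimeSeries, n_test: int,
                   config: RunConfig | None = None) -> pd.DataFrame:
    """Four-model comparison on one train/validation split.

    Runs ARIMA on the raw series, trend-augmented ARIMA ("ARIMA-dummy"),
    a standalone Elman network, and the ELA ensemble on the identical
    split, and tabulates MAPE (%) and reserve demand for each.
    """
    config = config or RunConfig()
    config.validate()
    train, test = train_test_split(series, n_test)
    if len(train) < 60:
        raise ValueError("need >= 60 training observations")
    actual = test.values
    rows = []

    fc_ao, _ = _arima_original_forecast(train.values, n_test, config)
    rows.append(("ARIMA-original", fc_ao))
    fc_ad, _ = _arima_dummy_forecast(train.values, n_test, config)
    rows.append(("ARIMA-dummy", fc_ad))
    fc_el, _ = _elman_forecast(train.values, n_test, config)
    rows.append(("ELMAN", fc_el))
    fc_ela = ELAModel(train, config).fit().forecast(n_test)
    rows.append(("ELA", fc_ela))

    table = pd.DataFrame({
        "model": [name for name, _ in rows],
        "mape_pct": [mape(actual, fc) for _, fc in rows],
        "demand": [demand_from_forecasts(fc, config.alpha) for _, fc in rows],
    })
    table.attrs["forecasts"] = {name: fc for name, fc in rows}
    table.attrs["actual"] = actual
    table.attrs["actual_total"] = float(np.sum(actual))
    return table


def scan_split_k(train: TimeSeries, horizon: int, k_range,
                 config: RunConfig | None = None) -> tuple[int, pd.DataFrame]:
    """Formalized "trial and error" search over the IMF grouping boundary.

    Holds the last ``horizon`` weeks of ``train`` out as a validation
    tail, runs the full ELA pipeline per candidate ``k`` on the
    remainder, and returns the k minimizing validation MAPE together
    with the per-k table.
    """
    config = config or RunConfig()
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k range is empty")
    fit_part, val_part = train_test_split(train, horizon)
    rows = []
    for k in ks:
        cfg_k = RunConfig.from_dict({**config.to_dict(), "split_k": k})
        try:
            fc = ELAModel(fit_part, cfg_k).fit().forecast(horizon)
            rows.append({"split_k": k, "val_mape_pct": mape(val_part.values, fc)})
        except ValueError as exc:  # fewer IMFs than k
            rows.append({"split_k": k, "val_mape_pct": np.nan})
    table = pd.DataFrame(rows)
    if table["val_mape_pct"].isna().all():
        raise ValueError("no candidate split_k was feasible for this series")
    best = int(table.loc[table["val_mape_pct"].idxmin(), "split_k"])
    return best, table
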
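"""ARIMA fitting, AIC order selection, diagnostics and forecasting.

Estimation delegates to statsmodels' state-space Gaussian MLE with a
conditional-sum-of-squares fallback; this module adds the Box-Jenkins
grid search (exhaustive (p, q) scan ranked by AIC), the Ljung-Box
residual whiteness check, and the trend-augmented variant in which the
Hodrick-Prescott trend of the series enters as an exogenous regressor
(stripping the slow drift that detection-technology progress adds to
reported case counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.diagnostic import acorr_ljungbox
from statsmodels.tools.sm_exceptions import ConvergenceWarning
from statsmodels.tsa.arima.model import ARIMA as _SmARIMA

from .preprocess import extend_trend, hp_filter


@dataclass(frozen=True)
class ArimaOrder:
    """(p, d, q): AR order, differencing order, MA order."""

    p_ar: int
    d: int
    q: int

    def __post_init__(self) -> None:
        if min(self.p_ar, self.d, self.q) < 0:
            raise ValueError("ARIMA orders must be nonnegative")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.p_ar, self.d, self.q)

    def __str__(self) -> str:
        return f"({self.p_ar},{self.d},{self.q})"


@dataclass
class ArimaModel:
    """A fitted ARIMA(p,d,q) model, optionally with a trend regressor.

    Carries the constant, AR/MA coefficients, innovation variance,
    log-likelihood and AIC; ``exog_coeff`` is the loading on the
    exogenous trend when one was supplied.
    """

    order: ArimaOrder
    constant: float
    ar_coeffs: np.ndarray
    ma_coeffs: np.ndarray
    sigma2: float
    loglik: float
    aic: float
    exog_coeff: float | None = None
    _results: object | None = None
    _exog_train: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        k = self.order.p_ar + self.order.q + 1  # + sigma2
        k += int(self.order.d == 0)             # constant only when d == 0
        k += int(self.exog_coeff is not None)
        return k

    def residuals(self) -> np.ndarray:
        return np.asarray(self._results.resid, dtype=float)


def _trend_spec(d: int) -> str:
    # statsmodels drops the constant under differencing; matching the
    # standard convention the constant is estimated only for d == 0.
    return "c" if d == 0 else "n"


def fit(values, order: ArimaOrder | tuple[int, int, int],
        exog=None) -> ArimaModel:
    """Gaussian MLE fit of ARIMA(p,d,q), optional exogenous regressor.

    Stationarity of the AR part and invertibility of the MA part are
    enforced by the optimizer's parameter transform.  If the state-space
    MLE fails, a conditional-sum-of-squares start followed by MLE is
    attempted before giving up.
    """
    if not isinstance(order, ArimaOrder):
        order = ArimaOrder(*order)
    x = np.asarray(getattr(values, "values", values), dtype=float)
    n_min = order.p_ar + order.d + order.q + 10
    if len(x) <= n_min:
        raise ValueError(f"series of length {len(x)} too short for "
                         f"ARIMA{order} (need > {n_min})")
    ex = None if exog is None else np.asarray(exog, dtype=float).reshape(-1, 1)
    model = _SmARIMA(x, exog=ex, order=order.as_tuple(),
                     trend=_trend_spec(order.d))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit()
        except Exception:
            try:
                res = model.fit(method="statespace",
                                method_kwargs={"maxiter": 200})
            except Exception as exc:  # pragma: no cover - rare
                raise RuntimeError(f"ARIMA{order} failed to converge: {exc}") from exc
    params = dict(zip(res.model.param_names, np.asarray(res.params, dtype=float)))
    constant = float(params.get("const", 0.0))
    exog_coeff = float(params["x1"]) if "x1" in params else None
    ar = np.array([params[f"ar.L{i}"] for i in range(1, order.p_ar + 1)])
    ma = np.array([params[f"ma.L{i}"] for i in range(1, order.q + 1)])
    return ArimaModel(
        order=order,
        constant=constant,
        ar_coeffs=ar,
        ma_coeffs=ma,
        sigma2=float(params["sigma2"]),
        loglik=float(res.llf),
        aic=float(res.aic),
        exog_coeff=exog_coeff,
        _results=res,
        _exog_train=ex,
    )


def select_order(values, max_p: int, max_q: int, d: int,
                 exog=None) -> tuple[ArimaOrder, list[dict]]:
    """Exhaustive (p, q) AIC grid at fixed ``d``; Box-Jenkins by search.

    Returns the AIC-minimizing order among converged fits together with
    the full grid table.  Ties (AIC within 1e-6) break toward smaller
    p + q, then smaller p.
    """
    if not (0 <= max_p <= 6 and 0 <= max_q <= 6):
        raise ValueError("max_p and max_q must lie in [0, 6]")
    table = []
    for p in range(max_p + 1):
        for q in range(max_q + 1):
            try:
                m = fit(values, ArimaOrder(p, d, q), exog=exog)
                table.append({"p": p, "q": q, "aic": m.aic, "converged": True})
            except Exception:
                table.append({"p": p, "q": q, "aic": np.inf, "converged": False})
    converged = [row for row in table if row["converged"]]
    if not converged:
        raise RuntimeError("no (p, q) grid point converged")
    best = min(converged,
               key=lambda r: (round(r["aic"], 6), r["p"] + r["q"], r["p"]))
    return ArimaOrder(best["p"], d, best["q"]), table


def forecast(model: ArimaModel, horizon: int, exog_future=None) -> np.ndarray:
    """h-step-ahead point forecast in original units.

    Runs the ARMA forecast recursion on the differenced scale and
    integrates back internally (statsmodels handles the inverse
    differencing with the last ``d`` observations of the fit sample).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if model._exog_train is not None:
        if exog_future is None:
            raise ValueError("model was fitted with an exogenous regressor; "
                             "future values are required to forecast")
        exog_future = np.asarray(exog_future, dtype=float).reshape(-1, 1)
        if len(exog_future) != horizon:
            raise ValueError("exog_future length must equal horizon")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = model._results.forecast(steps=horizon, exog=exog_future)
    return np.asarray(out, dtype=float)


@dataclass(frozen=True)
class WhitenessResult:
    """Ljung-Box portmanteau check on model residuals."""

    statistic: float
    pvalue: float
    lags: int
    df: int
    white_at_5pct: bool


def residual_whiteness(model: ArimaModel) -> WhitenessResult:
    """Ljung-Box test at lag min(10, n/5), df adjusted for p + q."""
    resid = model.residuals()
    # discard the d burn-in residuals produced by differencing start-up
    resid = resid[model.order.d:]
    n = len(resid)
    if n < 30:
        raise ValueError(f"need >= 30 residuals for a whiteness check, got {n}")
    if np.allclose(resid, 0.0):
        return WhitenessResult(0.0, 1.0, min(10, n // 5), 0, True)
    lags = min(10, n // 5)
    model_df = min(model.order.p_ar + model.order.q, lags - 1)
    lb = acorr_ljungbox(resid, lags=[lags], model_df=model_df)
    stat = float(lb["lb_stat"].iloc[0])
    pval = float(lb["lb_pvalue"].iloc[0])
    return WhitenessResult(stat, pval, lags, lags - model_df, pval > 0.05)


def fit_trend_augmented(values, hp_lambda: float = 129600.0,
                        max_p: int = 4, max_q: int = 4,
                        d: int = 2) -> tuple[ArimaModel, np.ndarray]:
    """ARIMA with the series' own HP trend as exogenous regressor.

    Splits the series with the Hodrick-Prescott filter, then runs the
    AIC grid with the trend as explanatory variable.  Returns the fitted
    model and the HP trend (needed to extrapolate the regressor when
    forecasting).
    """
    x = np.asarray(getattr(values, "values", values), dtype=float)
    hp = hp_filter(x, lamb=hp_lambda)
    order, _ = select_order(x, max_p=max_p, max_q=max_q, d=d, exog=hp.trend)
    model = fit(x, order, exog=hp.trend)
    return model, hp.trend


def forecast_trend_augmented(model: ArimaModel, trend: np.ndarray,
                             horizon: int) -> np.ndarray:
    """Forecast a trend-augmented model, extending the HP trend linearly."""
    return forecast(model, horizon, exog_future=extend_trend(trend, horizon))
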
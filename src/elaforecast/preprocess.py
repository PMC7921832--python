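"""Stationarity tooling: differencing, ADF testing, Hodrick-Prescott split.

The ADF test and HP filter delegate to statsmodels; the module surface
normalizes their outputs into small result types used by the rest of
the pipeline and the CLI stationarity report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.filters.hp_filter import hpfilter
from statsmodels.tsa.stattools import adfuller

_REGRESSIONS = {"constant": "c", "constant+trend": "ct"}


@dataclass(frozen=True)
class AdfResult:
    """Augmented Dickey-Fuller unit-root test outcome.

    ``statistic`` is the t-ratio on the lagged level; rejection
    (statistic below the critical value) indicates no unit root, i.e.
    a stationary series around the chosen deterministic regression.
    """

    statistic: float
    critical_values: dict[str, float]
    lags_used: int
    regression: str
    reject_at_5pct: bool

    def decision(self, level: str = "5%") -> bool:
        return self.statistic < self.critical_values[level]


def difference(values, order: int) -> np.ndarray:
    """Order-1 or order-2 differencing; length shrinks by ``order``."""
    if order not in (1, 2):
        raise ValueError(f"difference order must be 1 or 2, got {order}")
    x = np.asarray(values, dtype=float)
    if len(x) <= order:
        raise ValueError(f"series of length {len(x)} too short for order {order}")
    return np.diff(x, n=order)


def inverse_difference(diffed, initial_values, order: int) -> np.ndarray:
    """Exact inverse of :func:`difference`.

    ``initial_values`` are the ``order`` leading observations of the
    original series (for order 2, the first two raw values, not first
    differences).
    """
    d = np.asarray(diffed, dtype=float)
    init = np.atleast_1d(np.asarray(initial_values, dtype=float))
    if len(init) != order:
        raise ValueError(f"need exactly {order} initial values, got {len(init)}")
    if order == 1:
        return np.cumsum(np.concatenate([init, d]))
    # order 2: rebuild the first-difference sequence, then the levels
    first_diffs = inverse_difference(d, [init[1] - init[0]], 1)
    return inverse_difference(first_diffs, [init[0]], 1)


def adf_test(values, regression: str = "constant+trend",
             max_lags: int | None = None) -> AdfResult:
    """ADF test with AIC lag selection up to ``max_lags``.

    Default regression includes constant and linear trend; the default
    lag bound is the Schwert rule ``floor(12 * (n/100)**0.25)``.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 20:
        raise ValueError(f"need >= 20 observations for the ADF test, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance series has no unit-root behaviour to test")
    if regression not in _REGRESSIONS:
        raise ValueError(f"regression must be one of {sorted(_REGRESSIONS)}")
    stat, _pvalue, lags, _nobs, crit, _icbest = adfuller(
        x, maxlag=max_lags, regression=_REGRESSIONS[regression], autolag="AIC")
    return AdfResult(
        statistic=float(stat),
        critical_values={k: float(v) for k, v in crit.items()},
        lags_used=int(lags),
        regression=regression,
        reject_at_5pct=bool(stat < crit["5%"]),
    )


@dataclass(frozen=True)
class HpDecomposition:
    """Hodrick-Prescott split of a series into trend and cycle.

    ``trend`` minimizes ``sum((x - tau)^2) + lamb * sum((d2 tau)^2)``;
    ``cycle = x - trend`` exactly.
    """

    trend: np.ndarray
    cycle: np.ndarray
    lamb: float


def hp_filter(values, lamb: float = 129600.0) -> HpDecomposition:
    """HP trend/cycle decomposition with smoothing penalty ``lamb``."""
    if lamb <= 0:
        raise ValueError(f"HP lambda must be positive, got {lamb}")
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError(f"need >= 4 observations for the HP filter, got {len(x)}")
    cycle, trend = hpfilter(x, lamb=lamb)
    return HpDecomposition(trend=np.asarray(trend, dtype=float),
                           cycle=np.asarray(cycle, dtype=float),
                           lamb=float(lamb))


def extend_trend(trend, horizon: int) -> np.ndarray:
    """Linear continuation of an HP trend over a forecast horizon.

    The trend is extrapolated at its final slope — the natural boundary
    behaviour of the HP smoother, whose penalty drives second differences
    to zero at the sample edge.
    """
    t = np.asarray(trend, dtype=float)
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    slope = t[-1] - t[-2]
    return t[-1] + slope * np.arange(1, horizon + 1)
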
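"""Seeded generators for influenza-like weekly series and ARIMA processes.

The case-series generator emulates the structure of urban influenza
surveillance data: annual (52-week) seasonality over a base reporting
level, a late trend break where a new detection technology raises the
reported counts week over week, multiplicative surge bursts on epidemic
peaks, and AR(1)-autocorrelated noise.  It stands in for surveillance
data that is not publicly deposited; every generator is a pure function
of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TimeSeries


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the influenza-like weekly case generator.

    Units are cases/week unless stated.  Defaults sketch a large-city
    series of about four years: base reporting level 1000, seasonal
    swing 800 peaking each winter, a detection-technology break at week
    155 (about three years in) adding 25 cases/week thereafter, a
    doubled winter peak in the first post-break season (weeks 166-172,
    around the seasonal maximum at week 169) so the raised-peak regime
    is observed before any forecast origin, and moderately
    autocorrelated noise.
    """

    n: int = 221
    base_level: float = 1000.0
    seasonal_amplitude: float = 800.0
    seasonal_period: float = 52.0
    trend_break_week: int = 155
    trend_break_slope: float = 25.0
    surge_weeks: tuple[int, ...] = (166, 167, 168, 169, 170, 171, 172)
    surge_scale: float = 2.0
    ar_phi: float = 0.6
    noise_sd: float = 120.0
    seed: int = 0
    integer_counts: bool = False
    start_date: str = "2014-07-01"

    def __post_init__(self) -> None:
        if self.n < 60:
            raise ValueError("n must be >= 60")
        if not 0.0 <= self.ar_phi < 1.0:
            raise ValueError("ar_phi must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.surge_scale <= 0 or self.seasonal_period <= 0:
            raise ValueError("surge_scale and seasonal_period must be positive")


def generate(spec: SyntheticSpec) -> TimeSeries:
    """Generate a weekly case series according to ``spec``.

    value_t = max(0, base + seasonal_t * surge_t + ramp_t + noise_t) with
    seasonal_t = A sin(2 pi t / period), surge_t the multiplicative burst
    factor on surge weeks, ramp_t the post-break linear increase, and
    noise_t a stationary AR(1) Gaussian process.
    """
    t = np.arange(spec.n, dtype=float)
    seasonal = spec.seasonal_amplitude * np.sin(2 * np.pi * t / spec.seasonal_period)
    surge = np.ones(spec.n)
    for w in spec.surge_weeks:
        if 0 <= w < spec.n:
            surge[w] = spec.surge_scale
    ramp = np.where(t > spec.trend_break_week,
                    (t - spec.trend_break_week) * spec.trend_break_slope, 0.0)
    rng = np.random.default_rng(spec.seed)
    noise = np.zeros(spec.n)
    if spec.noise_sd > 0:
        innov_sd = spec.noise_sd * np.sqrt(1.0 - spec.ar_phi ** 2)
        e = rng.normal(0.0, innov_sd, spec.n)
        noise[0] = rng.normal(0.0, spec.noise_sd)
        for i in range(1, spec.n):
            noise[i] = spec.ar_phi * noise[i - 1] + e[i]
    values = np.maximum(0.0, spec.base_level + seasonal * surge + ramp + noise)
    if spec.integer_counts:
        values = np.round(values)
    dates = pd.date_range(spec.start_date, periods=spec.n, freq="7D")
    return TimeSeries(dates, values, name=f"synthetic-flu-seed{spec.seed}",
                      raw_counts=True)


def generate_arima(order, ar_coeffs=(), ma_coeffs=(), n: int = 500,
                   seed: int = 0, constant: float = 0.0,
                   sigma: float = 1.0, burn_in: int = 100) -> np.ndarray:
    """Simulate an ARIMA(p,d,q) process with Gaussian innovations.

    The stationary ARMA core is simulated exactly (burn-in discarded),
    then integrated ``d`` times.  Non-stationary AR or non-invertible MA
    coefficient sets are rejected.
    """
    p, d, q = order
    phi = np.asarray(ar_coeffs, dtype=float)
    theta = np.asarray(ma_coeffs, dtype=float)
    if len(phi) != p or len(theta) != q:
        raise ValueError("coefficient lengths must match the order")
    for poly, label in ((np.r_[1.0, -phi], "AR"), (np.r_[1.0, theta], "MA")):
        if len(poly) > 1 and np.any(np.abs(np.roots(poly[::-1])) <= 1.0):
            raise ValueError(f"{label} polynomial has roots inside the unit "
                             "circle (non-stationary/non-invertible)")
    rng = np.random.default_rng(seed)
    total = n + burn_in
    e = rng.normal(0.0, sigma, total) if sigma > 0 else np.zeros(total)
    x = np.zeros(total)
    for t in range(total):
        ar_part = sum(phi[i] * x[t - 1 - i] for i in range(p) if t - 1 - i >= 0)
        ma_part = sum(theta[j] * e[t - 1 - j] for j in range(q) if t - 1 - j >= 0)
        x[t] = constant + ar_part + e[t] + ma_part
    x = x[burn_in:]
    for _ in range(d):
        x = np.cumsum(x)
    return x
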
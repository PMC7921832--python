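"""Time-series data model, CSV I/O, splitting and run configuration.

The universal currency of the pipeline is :class:`TimeSeries`: a weekly,
uniformly spaced sequence of real values with ISO-8601 dates.  All the
numerical modules operate on the bare value vector; dates are carried
along (and spacing-checked) purely for provenance and I/O.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

WEEK = pd.Timedelta(days=7)


class SeriesError(ValueError):
    """Raised for invalid series content (dates, spacing, values)."""


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly spaced weekly series of observations.

    Parameters
    ----------
    timestamps : pandas.DatetimeIndex
        Strictly increasing dates with constant 7-day spacing.
    values : numpy.ndarray
        Real observations, one per timestamp; all finite.  Raw case
        counts are nonnegative; decomposed components may be negative,
        so nonnegativity is only enforced when ``raw_counts=True``.
    name : str
        Free-text label used in reports.
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    name: str = "series"
    raw_counts: bool = False

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or len(vals) != len(ts):
            raise SeriesError(
                f"values must be 1-D and match timestamps "
                f"({vals.shape} vs {len(ts)} dates)"
            )
        if len(vals) < 1:
            raise SeriesError("series must contain at least one observation")
        if not np.all(np.isfinite(vals)):
            bad = int(np.flatnonzero(~np.isfinite(vals))[0])
            raise SeriesError(f"non-finite value at row {bad} ({ts[bad].date()})")
        if ts.has_duplicates:
            dup = ts[ts.duplicated()][0]
            raise SeriesError(f"duplicate date {dup.date()}")
        deltas = np.diff(ts.asi8)
        if len(deltas) and not np.all(deltas == WEEK.value):
            bad = int(np.flatnonzero(deltas != WEEK.value)[0])
            raise SeriesError(
                f"non-weekly spacing between {ts[bad].date()} and "
                f"{ts[bad + 1].date()} (expected 7 days)"
            )
        if self.raw_counts and np.any(vals < 0):
            bad = int(np.flatnonzero(vals < 0)[0])
            raise SeriesError(f"negative case count at row {bad} ({ts[bad].date()})")
        object.__setattr__(self, "timestamps", ts)
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def with_values(self, values: Sequence[float], name: str | None = None) -> "TimeSeries":
        """Same dates, new values (components, fitted series, ...)."""
        return TimeSeries(self.timestamps, np.asarray(values, dtype=float),
                          name=name or self.name)

    def extend_dates(self, horizon: int) -> pd.DatetimeIndex:
        """Dates of the ``horizon`` weeks following the series."""
        start = self.timestamps[-1] + WEEK
        return pd.date_range(start, periods=horizon, freq="7D")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.timestamps.strftime("%Y-%m-%d"),
                             "value": self.values})


def read_series(path: str | Path, name: str | None = None,
                raw_counts: bool = False) -> TimeSeries:
    """Read a ``date,value`` CSV into a validated :class:`TimeSeries`.

    Dates must be ISO-8601, weekly spaced and strictly increasing; any
    violation raises :class:`SeriesError` naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns[:2]) != ["date", "value"]:
        raise SeriesError(f"{path}: expected header 'date,value', got {list(df.columns)}")
    try:
        dates = pd.to_datetime(df["date"], format="%Y-%m-%d")
    except (ValueError, TypeError) as exc:
        raise SeriesError(f"{path}: unparseable ISO-8601 date ({exc})") from exc
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any():
        row = int(values.isna().idxmax())
        raise SeriesError(f"{path}: non-numeric value at row {row + 2} "
                          f"(date {df['date'][row]})")
    return TimeSeries(pd.DatetimeIndex(dates), values.to_numpy(dtype=float),
                      name=name or path.stem, raw_counts=raw_counts)


def write_series(series: TimeSeries, path: str | Path) -> None:
    """Write ``date,value`` CSV (ISO dates, full ``repr`` float precision)."""
    if not str(path):
        raise ValueError("empty output path")
    path = Path(path)
    lines = ["date,value"]
    for ts, v in zip(series.timestamps, series.values):
        lines.append(f"{ts.strftime('%Y-%m-%d')},{float(v)!r}")
    path.write_text("\n".join(lines) + "\n")


def train_test_split(series: TimeSeries, n_test: int) -> tuple[TimeSeries, TimeSeries]:
    """Split off the last ``n_test`` observations as the validation part.

    Mirrors the tuning protocol in which the first 200 of 221 weekly
    observations tune the models and the remaining 21 validate them.
    """
    if not 1 <= n_test < len(series):
        raise ValueError(
            f"n_test must be in [1, {len(series) - 1}], got {n_test}")
    cut = len(series) - n_test
    train = TimeSeries(series.timestamps[:cut], series.values[:cut],
                       name=f"{series.name}[train]")
    test = TimeSeries(series.timestamps[cut:], series.values[cut:],
                      name=f"{series.name}[test]")
    return train, test


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class ElmanConfig:
    window: int = 4
    hidden_size: int = 8
    epochs: int = 800
    learning_rate: float = 0.05
    momentum: float = 0.9
    feedback_gain: float = 0.5
    init_scale: float = 0.5

    def validate(self) -> None:
        if self.window < 1 or self.epochs < 1:
            raise ValueError("window and epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.feedback_gain < 1:
            raise ValueError("feedback_gain must lie in (0, 1)")


@dataclass
class ArimaConfig:
    d: int = 1               # differencing order for the x2 component
    max_p: int = 4
    max_q: int = 2
    d_raw: int = 2           # differencing order for the raw-series baseline

    def validate(self) -> None:
        if not (0 <= self.max_p <= 6 and 0 <= self.max_q <= 6):
            raise ValueError("max_p and max_q must lie in [0, 6]")
        if self.d < 0 or self.d_raw < 0:
            raise ValueError("differencing orders must be >= 0")


@dataclass
class EmdSettings:
    sd_tolerance: float = 0.2
    max_sift_iterations: int = 100
    max_imfs: int = 10

    def validate(self) -> None:
        if self.sd_tolerance <= 0 or self.max_sift_iterations < 1:
            raise ValueError("sd_tolerance > 0 and max_sift_iterations >= 1 required")


@dataclass
class HpConfig:
    lamb: float = 129600.0

    def validate(self) -> None:
        if self.lamb <= 0:
            raise ValueError("HP lambda must be positive")


@dataclass
class RunConfig:
    """Run-wide configuration for the ELA pipeline.

    ``n_test`` is the forecast horizon in weeks, ``split_k`` the IMF
    grouping boundary (x1 = IMF1..split_k), ``alpha`` the per-case
    medicine demand coefficient and ``seed`` the single source of
    randomness for the whole run.
    """

    n_test: int = 21
    split_k: int = 3
    alpha: float = 1.0
    seed: int = 0
    elman: ElmanConfig = field(default_factory=ElmanConfig)
    arima: ArimaConfig = field(default_factory=ArimaConfig)
    emd: EmdSettings = field(default_factory=EmdSettings)
    hp: HpConfig = field(default_factory=HpConfig)

    def validate(self) -> None:
        if self.n_test < 1:
            raise ValueError("n_test must be >= 1")
        if self.split_k < 1:
            raise ValueError("split_k must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        for sub in (self.elman, self.arima, self.emd, self.hp):
            sub.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sub = {
            "elman": ElmanConfig,
            "arima": ArimaConfig,
            "emd": EmdSettings,
            "hp": HpConfig,
        }
        kwargs = {}
        for key, value in data.items():
            if key in sub:
                kwargs[key] = sub[key](**value) if isinstance(value, dict) else value
            else:
                kwargs[key] = value
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, for logging."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration (nested sections mirror RunConfig)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)
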
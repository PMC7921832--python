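"""Empirical Mode Decomposition (EMD).

EMD adaptively decomposes a signal into intrinsic mode functions (IMFs)
by iteratively subtracting the mean of cubic-spline envelopes through
the local extrema ("sifting"), leaving a monotone (or extrema-deficient)
residual.  The modes are ordered from highest to lowest frequency; by
construction ``sum(imfs) + residual`` reproduces the input exactly up to
floating-point round-off.

For the ELA forecaster the modes are regrouped into a high-frequency
component ``x1 = IMF1 + ... + IMF_k`` and a low-frequency/seasonal
component ``x2 = IMF_{k+1} + ... + residual`` (``reconstruct_groups``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)


@dataclass
class EmdConfig:
    """Sifting parameters.

    ``sd_tolerance`` is the Cauchy-type stopping threshold on the
    normalized squared difference between successive sifting iterates
    (0.2-0.3 is the classical recommendation); ``max_sift_iterations``
    bounds the inner loop; ``max_imfs`` bounds the number of extracted
    modes; ``boundary_mode`` selects the envelope end treatment (only
    mirror extension is provided).
    """

    sd_tolerance: float = 0.2
    max_sift_iterations: int = 100
    max_imfs: int = 10
    boundary_mode: str = "mirror"

    def __post_init__(self) -> None:
        if self.sd_tolerance <= 0:
            raise ValueError("sd_tolerance must be positive")
        if self.max_sift_iterations < 1:
            raise ValueError("max_sift_iterations must be >= 1")
        if self.boundary_mode != "mirror":
            raise ValueError(f"unsupported boundary_mode {self.boundary_mode!r}")


@dataclass(frozen=True)
class IMFSet:
    """Ordered IMFs plus the final residual of a decomposition."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    source_length: int = field(default=0)

    def __post_init__(self) -> None:
        if self.source_length == 0:
            object.__setattr__(self, "source_length", len(self.residual))

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        total = self.residual.copy()
        for imf in self.imfs:
            total += imf
        return total


def find_extrema(signal) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima.

    Plateaus (runs of equal values flanked by opposite slopes) contribute
    their midpoint index.  Endpoints are never extrema.
    """
    x = np.asarray(signal, dtype=float)
    if len(x) < 3:
        raise ValueError(f"need at least 3 samples to locate extrema, got {len(x)}")
    dx = np.diff(x)
    # indices where the slope is nonzero; consecutive nonzero slopes of
    # opposite sign bracket an extremum (possibly a plateau).
    nz = np.flatnonzero(dx != 0.0)
    maxima, minima = [], []
    for a, b in zip(nz[:-1], nz[1:]):
        if dx[a] > 0 and dx[b] < 0:
            maxima.append((a + 1 + b) // 2)  # plateau spans a+1 .. b
        elif dx[a] < 0 and dx[b] > 0:
            minima.append((a + 1 + b) // 2)
    return np.array(maxima, dtype=int), np.array(minima, dtype=int)


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x[x != 0.0])
    return int(np.count_nonzero(s[:-1] != s[1:]))


def is_imf(x: np.ndarray) -> bool:
    """IMF property: counts of extrema and zero crossings differ by <= 1."""
    try:
        mx, mn = find_extrema(x)
    except ValueError:
        return False
    return abs((len(mx) + len(mn)) - _zero_crossings(x)) <= 1


def _mirror_knots(signal: np.ndarray, idx: np.ndarray, n_ext: int = 2):
    """Mirror up to ``n_ext`` extremum knots across each end of the signal.

    Extrema at index i are reflected to -i (left) and 2(n-1)-i (right),
    which suppresses envelope end swings without inventing new values.
    """
    n = len(signal)
    t = idx.astype(float)
    v = signal[idx]
    left_t = (-t[:n_ext])[::-1]
    left_v = v[:n_ext][::-1]
    right_t = (2 * (n - 1) - t[-n_ext:])[::-1]
    right_v = v[-n_ext:][::-1]
    tt = np.concatenate([left_t, t, right_t])
    vv = np.concatenate([left_v, v, right_v])
    keep = np.concatenate([[True], np.diff(tt) > 0])  # first occurrence wins
    return tt[keep], vv[keep]


def envelopes(signal, maxima, minima, boundary_mode: str = "mirror"):
    """Cubic-spline upper/lower envelopes through the (mirrored) extrema.

    An end sample lying above the nearest maximum (or below the nearest
    minimum) is promoted to an envelope anchor before mirroring, so that
    a swing still in progress at the boundary is not clipped — this
    matters for forecasting, where end-of-sample fidelity of the slow
    modes drives the component forecasts.

    Returns ``None`` when fewer than two maxima or two minima exist, which
    the sifting loop interprets as "monotone residual" rather than an error.
    """
    if boundary_mode != "mirror":
        raise ValueError(f"unsupported boundary_mode {boundary_mode!r}")
    x = np.asarray(signal, dtype=float)
    maxima = np.asarray(maxima, dtype=int)
    minima = np.asarray(minima, dtype=int)
    if len(maxima) < 2 or len(minima) < 2:
        return None
    n = len(x)
    if x[0] >= x[maxima[0]]:
        maxima = np.r_[0, maxima]
    if x[-1] >= x[maxima[-1]]:
        maxima = np.r_[maxima, n - 1]
    if x[0] <= x[minima[0]]:
        minima = np.r_[0, minima]
    if x[-1] <= x[minima[-1]]:
        minima = np.r_[minima, n - 1]
    grid = np.arange(n, dtype=float)
    tu, vu = _mirror_knots(x, maxima)
    tl, vl = _mirror_knots(x, minima)
    upper = CubicSpline(tu, vu)(grid)
    lower = CubicSpline(tl, vl)(grid)
    return upper, lower


def sift(signal, config: EmdConfig | None = None) -> np.ndarray:
    """Extract one candidate IMF by iterative envelope-mean subtraction.

    Stops when the normalized squared difference between successive
    iterates drops below ``sd_tolerance`` *and* the iterate satisfies the
    IMF extrema/zero-crossing property, or when ``max_sift_iterations``
    is reached (then the current iterate is returned with a warning).
    """
    config = config or EmdConfig()
    h = np.asarray(signal, dtype=float).copy()
    for _ in range(config.max_sift_iterations):
        mx, mn = find_extrema(h)
        env = envelopes(h, mx, mn, config.boundary_mode)
        if env is None:
            return h  # extrema-deficient: caller treats as residual
        mean_env = 0.5 * (env[0] + env[1])
        h_new = h - mean_env
        denom = float(np.sum(h * h))
        sd = float(np.sum(mean_env * mean_env)) / denom if denom > 0 else 0.0
        h = h_new
        if sd < config.sd_tolerance and is_imf(h):
            return h
    logger.warning("sifting did not converge within %d iterations",
                   config.max_sift_iterations)
    return h


def _is_residual(x: np.ndarray) -> bool:
    """Monotone or fewer than 2 maxima / 2 minima: decomposition stops."""
    if len(x) < 3:
        return True
    try:
        mx, mn = find_extrema(x)
    except ValueError:
        return True
    return len(mx) < 2 or len(mn) < 2


def decompose(signal, config: EmdConfig | None = None) -> IMFSet:
    """Full EMD of a signal into IMFs plus a residual.

    The residual after each extraction is the next sifting input; the
    loop ends when the residual is monotone/extrema-deficient or
    ``max_imfs`` modes have been extracted.  Completeness
    (``sum(imfs) + residual == signal``) holds by construction.
    """
    x = np.asarray(signal, dtype=float)
    if len(x) < 10:
        raise ValueError(f"signal too short for EMD ({len(x)} < 10 samples)")
    config = config or EmdConfig()
    residual = x.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < config.max_imfs and not _is_residual(residual):
        imf = sift(residual, config)
        if np.allclose(imf, residual):
            break  # sifting made no progress; residual is effectively done
        imfs.append(imf)
        residual = residual - imf
    return IMFSet(imfs=imfs, residual=residual, source_length=len(x))


def reconstruct_groups(imfset: IMFSet, split_k: int) -> tuple[np.ndarray, np.ndarray]:
    """Regroup modes into the two ELA components.

    ``x1`` is the sum of the first ``split_k`` IMFs (high-frequency
    content); ``x2`` is the sum of the remaining IMFs plus the residual
    (seasonality and trend).  ``x1 + x2`` equals the decomposed signal.
    """
    if not 1 <= split_k <= imfset.n_imfs:
        raise ValueError(
            f"split_k must lie in [1, {imfset.n_imfs}], got {split_k}")
    x1 = np.sum(imfset.imfs[:split_k], axis=0)
    rest = imfset.imfs[split_k:]
    x2 = imfset.residual.copy()
    if rest:
        x2 = x2 + np.sum(rest, axis=0)
    return x1, x2


def mode_summary(imfset: IMFSet) -> list[dict]:
    """Per-mode audit: extrema count, zero crossings, energy share."""
    total_energy = sum(float(np.sum(m * m)) for m in imfset.imfs)
    total_energy += float(np.sum(imfset.residual ** 2))
    rows = []
    for i, m in enumerate(imfset.imfs, start=1):
        try:
            mx, mn = find_extrema(m)
            n_ext = len(mx) + len(mn)
        except ValueError:
            n_ext = 0
        rows.append({
            "mode": f"imf{i}",
            "n_extrema": n_ext,
            "n_zero_crossings": _zero_crossings(m),
            "energy_share": float(np.sum(m * m)) / total_energy if total_energy else 0.0,
        })
    rows.append({
        "mode": "residual",
        "n_extrema": 0,
        "n_zero_crossings": _zero_crossings(imfset.residual),
        "energy_share": float(np.sum(imfset.residual ** 2)) / total_energy
        if total_energy else 0.0,
    })
    return rows
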
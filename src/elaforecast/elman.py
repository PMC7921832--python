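"""Elman recurrent network for one-step-ahead series forecasting.

The network augments a feed-forward layer with a *context layer* that
stores a decayed copy of the previous hidden state and feeds it back as
an extra input, giving the model short memory:

    x_c(k) = gain * x_c(k-1) + x(k-1)          (context update)
    x(k)   = f(W1 u(k) + W2 x_c(k) + b_h)      (hidden state)
    y(k)   = g(W3 x(k) + b_y)                  (output)

with ``gain`` the internal feedback factor in (0, 1), ``u(k)`` a window
of lagged observations, ``f`` a bounded transfer (logistic sigmoid by
default) and ``g`` the identity.  Training minimizes the mean squared
one-step error on min-max-normalized data by full-sequence gradient
descent with classical momentum, the context state treated as a
constant input at each step (the truncated Elman scheme, which keeps
the gradient cheap and exactly checkable by finite differences).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_TRANSFERS = {
    "sigmoid": (lambda z: 1.0 / (1.0 + np.exp(-z)), lambda a: a * (1.0 - a)),
    "tanh": (np.tanh, lambda a: 1.0 - a * a),
}


@dataclass
class ElmanTrainConfig:
    """Training hyperparameters.

    ``window`` is the number of lagged weeks fed to the input layer;
    weights start uniform(-init_scale, init_scale) from ``seed``; the
    values are min-max normalized to [0, 1] on the training split only.
    """

    window: int = 4
    hidden_size: int = 8
    epochs: int = 800
    learning_rate: float = 0.05
    momentum: float = 0.9
    feedback_gain: float = 0.5
    init_scale: float = 0.5
    seed: int = 0
    hidden_transfer: str = "sigmoid"

    def __post_init__(self) -> None:
        if self.window < 1 or self.epochs < 1 or self.hidden_size < 1:
            raise ValueError("window, epochs and hidden_size must be >= 1")
        if self.learning_rate <= 0 or self.init_scale <= 0:
            raise ValueError("learning_rate and init_scale must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if not 0.0 < self.feedback_gain < 1.0:
            raise ValueError("feedback_gain must lie in (0, 1)")
        if self.hidden_transfer not in _TRANSFERS:
            raise ValueError(f"hidden_transfer must be one of {sorted(_TRANSFERS)}")


@dataclass
class ElmanNetwork:
    """Weights and state of a trained Elman network.

    ``w1``: input->hidden (hidden, window); ``w2``: context->hidden
    (hidden, hidden); ``w3``: hidden->output (hidden,); ``norm_lo`` /
    ``norm_hi`` are the training min-max bounds used to (de)normalize.
    """

    w1: np.ndarray
    w2: np.ndarray
    w3: np.ndarray
    b_h: np.ndarray
    b_y: float
    feedback_gain: float
    hidden_transfer: str = "sigmoid"
    norm_lo: float = 0.0
    norm_hi: float = 1.0
    window: int = field(init=False)
    hidden_size: int = field(init=False)

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        self.w3 = np.asarray(self.w3, dtype=float).ravel()
        self.b_h = np.asarray(self.b_h, dtype=float).ravel()
        h, w = self.w1.shape
        if self.w2.shape != (h, h) or self.w3.shape != (h,) or self.b_h.shape != (h,):
            raise ValueError("inconsistent weight shapes")
        self.window = w
        self.hidden_size = h

    # -- normalization ----------------------------------------------------
    def normalize(self, values: np.ndarray) -> np.ndarray:
        scale = self.norm_hi - self.norm_lo
        if scale == 0:
            return np.zeros_like(np.asarray(values, dtype=float))
        return (np.asarray(values, dtype=float) - self.norm_lo) / scale

    def denormalize(self, values: np.ndarray) -> np.ndarray:
        scale = self.norm_hi - self.norm_lo
        if scale == 0:
            return np.full_like(np.asarray(values, dtype=float), self.norm_lo)
        return np.asarray(values, dtype=float) * scale + self.norm_lo

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        blob = {
            "w1": self.w1.tolist(), "w2": self.w2.tolist(),
            "w3": self.w3.tolist(), "b_h": self.b_h.tolist(),
            "b_y": self.b_y, "feedback_gain": self.feedback_gain,
            "hidden_transfer": self.hidden_transfer,
            "norm_lo": self.norm_lo, "norm_hi": self.norm_hi,
        }
        Path(path).write_text(json.dumps(blob, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ElmanNetwork":
        blob = json.loads(Path(path).read_text())
        return cls(
            w1=np.array(blob["w1"]), w2=np.array(blob["w2"]),
            w3=np.array(blob["w3"]), b_h=np.array(blob["b_h"]),
            b_y=float(blob["b_y"]), feedback_gain=float(blob["feedback_gain"]),
            hidden_transfer=blob["hidden_transfer"],
            norm_lo=float(blob["norm_lo"]), norm_hi=float(blob["norm_hi"]),
        )


def _forward_pass(net: ElmanNetwork, windows: np.ndarray):
    """Run the recursion over a window sequence (normalized scale).

    Returns outputs y, hidden states h, contexts c and pre-activations,
    each with one row per step.  Context and hidden state start at zero.
    """
    f, _ = _TRANSFERS[net.hidden_transfer]
    T = len(windows)
    H = net.hidden_size
    y = np.empty(T)
    hs = np.empty((T, H))
    cs = np.empty((T, H))
    h_prev = np.zeros(H)
    c_prev = np.zeros(H)
    for k in range(T):
        c = net.feedback_gain * c_prev + h_prev
        pre = net.w1 @ windows[k] + net.w2 @ c + net.b_h
        h = f(pre)
        y[k] = net.w3 @ h + net.b_y
        cs[k], hs[k] = c, h
        c_prev, h_prev = c, h
    return y, hs, cs


def forward(net: ElmanNetwork, windows) -> np.ndarray:
    """Outputs of the network over an ordered sequence of input windows."""
    windows = np.atleast_2d(np.asarray(windows, dtype=float))
    if windows.shape[1] != net.window:
        raise ValueError(
            f"window length {windows.shape[1]} does not match w1 ({net.window})")
    y, _, _ = _forward_pass(net, windows)
    return y


def loss_and_gradients(net: ElmanNetwork, windows: np.ndarray,
                       targets: np.ndarray, contexts: np.ndarray):
    """Mean squared error and its gradients with *frozen* contexts.

    The context rows are taken as given constants, so each step is an
    independent two-layer network and the gradient is exact for the
    truncated objective (what finite differences must also hold fixed).
    """
    f, fprime = _TRANSFERS[net.hidden_transfer]
    pre = windows @ net.w1.T + contexts @ net.w2.T + net.b_h
    h = f(pre)
    y = h @ net.w3 + net.b_y
    err = y - targets
    T = len(targets)
    loss = float(np.mean(err ** 2))
    dy = 2.0 * err / T
    g_w3 = h.T @ dy
    g_by = float(np.sum(dy))
    dpre = np.outer(dy, net.w3) * fprime(h)
    g_w1 = dpre.T @ windows
    g_w2 = dpre.T @ contexts
    g_bh = dpre.sum(axis=0)
    return loss, {"w1": g_w1, "w2": g_w2, "w3": g_w3, "b_h": g_bh, "b_y": g_by}


def _make_windows(z: np.ndarray, window: int):
    """Lagged design: u_t = z[t-window:t], target z[t]."""
    T = len(z) - window
    U = np.lib.stride_tricks.sliding_window_view(z, window)[:T]
    return np.ascontiguousarray(U), z[window:]


def train(values, config: ElmanTrainConfig | None = None) -> ElmanNetwork:
    """Train a network on a value sequence (one-step-ahead objective).

    Deterministic for a given ``config.seed``.  Raises if the series is
    shorter than ``window + 2`` or if the loss turns non-finite.
    """
    config = config or ElmanTrainConfig()
    x = np.asarray(getattr(values, "values", values), dtype=float)
    if len(x) <= config.window + 1:
        raise ValueError(
            f"series of length {len(x)} too short for window {config.window}")
    lo, hi = float(np.min(x)), float(np.max(x))
    rng = np.random.default_rng(config.seed)
    s = config.init_scale
    H, W = config.hidden_size, config.window
    net = ElmanNetwork(
        w1=rng.uniform(-s, s, (H, W)),
        w2=rng.uniform(-s, s, (H, H)),
        w3=rng.uniform(-s, s, H),
        b_h=rng.uniform(-s, s, H),
        b_y=float(rng.uniform(-s, s)),
        feedback_gain=config.feedback_gain,
        hidden_transfer=config.hidden_transfer,
        norm_lo=lo, norm_hi=hi,
    )
    z = net.normalize(x)
    U, targets = _make_windows(z, W)
    lr, mom = config.learning_rate, config.momentum
    vel = {k: 0.0 for k in ("w1", "w2", "w3", "b_h", "b_y")}
    for _ in range(config.epochs):
        _, _, contexts = _forward_pass(net, U)
        loss, g = loss_and_gradients(net, U, targets, contexts)
        if not np.isfinite(loss):
            raise FloatingPointError(
                "training loss became non-finite; lower the learning rate")
        for k in vel:
            vel[k] = mom * vel[k] - lr * g[k]
        net.w1 += vel["w1"]
        net.w2 += vel["w2"]
        net.w3 += vel["w3"]
        net.b_h += vel["b_h"]
        net.b_y = float(net.b_y + vel["b_y"])
    return net


def forecast(net: ElmanNetwork, history, horizon: int) -> np.ndarray:
    """Recursive multi-step forecast in original units.

    The network is first run across the full history (warming the
    context), then each prediction is appended to the lag window to
    produce the next, ``horizon`` times.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    x = np.asarray(getattr(history, "values", history), dtype=float)
    if len(x) < net.window:
        raise ValueError(f"history shorter than window ({len(x)} < {net.window})")
    f, _ = _TRANSFERS[net.hidden_transfer]
    z = list(net.normalize(x))
    h = np.zeros(net.hidden_size)
    c = np.zeros(net.hidden_size)
    # warm-up over history windows (targets beyond window index exist)
    for k in range(net.window, len(z)):
        u = np.array(z[k - net.window:k])
        c = net.feedback_gain * c + h
        h = f(net.w1 @ u + net.w2 @ c + net.b_h)
    preds = []
    for _ in range(horizon):
        u = np.array(z[-net.window:])
        c = net.feedback_gain * c + h
        h = f(net.w1 @ u + net.w2 @ c + net.b_h)
        y = float(net.w3 @ h + net.b_y)
        preds.append(y)
        z.append(y)
    return net.denormalize(np.array(preds))
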
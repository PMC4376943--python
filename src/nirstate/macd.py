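"""Streaming EMA and MACD (moving average convergence divergence) filters.

The exponential moving average with window length ``N`` samples is the
recursion ``y_n = α·x_n + (1-α)·y_{n-1}`` with ``α = 2/(N+1)``.  The MACD is
the difference between a short-window and a long-window EMA; at 2 Hz the
default pair (N_short=12, N_long=26 samples, i.e. 6 s and 13 s) acts as a
low-order band-pass that removes slow drifts (< 0.02 Hz) and fast
physiological/measurement noise (> 0.33 Hz) from hemodynamic series.  The
*signal line* is a further EMA (N=10 samples, 5 s) of the MACD output; the
state estimator looks for crossings between the two.

Every EMA here warm-starts at the first sample (``y_0 = x_0``).  A zero
initialisation would inject a startup transient proportional to the signal
offset and cause spurious crossovers; with warm start a constant input maps
to a constant output from the first sample on.

Batch and streaming paths use the identical floating-point update, so
chunked processing is bit-exact with whole-series processing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .io import Recording

__all__ = [
    "EmaState",
    "MacdConfig",
    "MacdStream",
    "ema_update",
    "ema",
    "macd",
    "signal_line",
    "stream_filter",
    "filter_recording",
]


def _alpha(n: int) -> float:
    if n < 1:
        raise ValueError("EMA window length must be >= 1 sample")
    return 2.0 / (n + 1)


@dataclass
class EmaState:
    """State of one exponential moving average stream."""

    n: int
    y_prev: float = math.nan
    initialized: bool = False

    def __post_init__(self) -> None:
        self.alpha = _alpha(self.n)

    def update(self, x: float) -> float:
        if not math.isfinite(x):
            raise ValueError(f"non-finite input sample: {x!r}")
        if not self.initialized:
            y = float(x)
            self.initialized = True
        else:
            a = self.alpha
            y = a * x + (1.0 - a) * self.y_prev
        self.y_prev = y
        return y


def ema_update(state: EmaState, x: float) -> tuple[EmaState, float]:
    """Functional wrapper around :meth:`EmaState.update`."""
    return state, state.update(x)


@dataclass(frozen=True)
class MacdConfig:
    """Filter windows in samples at the recording rate (defaults for 2 Hz)."""

    n_short: int = 12
    n_long: int = 26
    n_signal: int = 10
    fs: float = 2.0

    def __post_init__(self) -> None:
        if self.n_short >= self.n_long:
            raise ValueError("n_short must be smaller than n_long")
        for n in (self.n_short, self.n_long, self.n_signal):
            if n < 1:
                raise ValueError("EMA window lengths must be >= 1")


def ema(series: np.ndarray, n: int, axis: int = -1) -> np.ndarray:
    """Batch EMA along ``axis``, warm-started, bit-identical to streaming."""
    x = np.asarray(series, dtype=float)
    if x.shape[axis] < 1:
        raise ValueError("series must contain at least one sample")
    if not np.isfinite(x).all():
        raise ValueError("non-finite input sample")
    x = np.moveaxis(x, axis, -1)
    a = _alpha(n)
    y = np.empty_like(x)
    y[..., 0] = x[..., 0]
    for t in range(1, x.shape[-1]):
        y[..., t] = a * x[..., t] + (1.0 - a) * y[..., t - 1]
    return np.moveaxis(y, -1, axis)


def macd(series: np.ndarray, cfg: MacdConfig | None = None, axis: int = -1) -> np.ndarray:
    """MACD band-pass: short-window EMA minus long-window EMA, same length."""
    cfg = cfg or MacdConfig()
    return ema(series, cfg.n_short, axis=axis) - ema(series, cfg.n_long, axis=axis)


def signal_line(macd_series: np.ndarray, cfg: MacdConfig | None = None, axis: int = -1) -> np.ndarray:
    """EMA of the MACD output with the signal window (default 10 samples)."""
    cfg = cfg or MacdConfig()
    return ema(macd_series, cfg.n_signal, axis=axis)


class MacdStream:
    """Sample-at-a-time MACD (and optionally signal-line) computation."""

    def __init__(self, cfg: MacdConfig | None = None):
        self.cfg = cfg or MacdConfig()
        self._short = EmaState(self.cfg.n_short)
        self._long = EmaState(self.cfg.n_long)
        self._signal = EmaState(self.cfg.n_signal)

    def update(self, x: float) -> tuple[float, float]:
        """Feed one sample; return (macd, signal_line) values."""
        m = self._short.update(x) - self._long.update(x)
        return m, self._signal.update(m)

    def process(self, chunk: np.ndarray) -> np.ndarray:
        """Feed a block of samples; return the MACD values for the block."""
        chunk = np.asarray(chunk, dtype=float)
        return np.array([self.update(x)[0] for x in chunk.ravel()], dtype=float)


def stream_filter(chunks, cfg: MacdConfig | None = None) -> np.ndarray:
    """MACD-filter a chunked 1-D stream.

    The concatenated output is bit-identical to ``macd`` on the concatenated
    input, for any chunk boundaries (including empty chunks).
    """
    stream = MacdStream(cfg)
    out = [stream.process(c) for c in chunks]
    return np.concatenate(out) if out else np.empty(0)


def filter_recording(rec: Recording, cfg: MacdConfig | None = None) -> Recording:
    """MACD-filter each channel of each species independently."""
    cfg = cfg or MacdConfig()
    return replace(rec, hbo2=macd(rec.hbo2, cfg, axis=-1), hhb=macd(rec.hhb, cfg, axis=-1))
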
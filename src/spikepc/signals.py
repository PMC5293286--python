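"""Feed-forward inputs and target signals.

The driving input ``s(t)`` is white noise smoothed with an exponential
filter ``exp(-lambda_input * t)``; the target ``x(t)`` that the network
tries to represent is the same input convolved with the decoder filter
``exp(-lambda * t)``.  Discrete white noise is scaled by ``1/sqrt(dt)``
per step so the statistics of the smoothed signal do not depend on the
step size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .network import TopographicParams

__all__ = [
    "InputSignal",
    "TargetSignal",
    "smoothed_white_noise",
    "circular_bump_drive",
    "quiescent_input",
    "leaky_filter",
    "target_from_input",
]


@dataclass
class InputSignal:
    """Feed-forward drive on a uniform time grid: ``s`` is (J, T)."""

    s: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.s = np.atleast_2d(np.asarray(self.s, dtype=float))
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not np.all(np.isfinite(self.s)):
            raise ValueError("input signal contains non-finite values")

    @property
    def n_dims(self) -> int:
        return self.s.shape[0]

    @property
    def n_steps(self) -> int:
        return self.s.shape[1]

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt

    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt

    def to_csv(self, path: str | Path) -> None:
        cols = {"time_s": self.times()}
        for j in range(self.n_dims):
            cols[f"s{j}"] = self.s[j]
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "InputSignal":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
        s = df.drop(columns=["time_s"]).to_numpy().T
        return cls(s=s, dt=dt)


@dataclass
class TargetSignal:
    """Target ``x`` (J, T) on the same grid as its input."""

    x: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))


def leaky_filter(
    series: np.ndarray,
    rate: float,
    dt: float,
    initial: np.ndarray | None = None,
) -> np.ndarray:
    """Leaky integration ``dy/dt = -rate * y + series`` on the grid.

    Uses the exact exponential update ``y[t] = y[t-1] * exp(-rate*dt) +
    series[t] * dt`` per step, which is unconditionally stable.
    """
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    series = np.atleast_2d(np.asarray(series, dtype=float))
    k, n = series.shape
    decay = np.exp(-rate * dt)
    # the recursion is a first-order IIR filter: y[t] - decay*y[t-1] = dt*s[t]
    out = lfilter([dt], [1.0, -decay], series, axis=1)
    if initial is not None:
        y0 = np.asarray(initial, dtype=float).reshape(k, 1)
        out = out + y0 * decay ** np.arange(1, n + 1)[None, :]
    return out


def smoothed_white_noise(
    n_dims: int,
    duration: float,
    dt: float,
    smoothing_rate: float = 2.0,
    amplitude: float = 1.0,
    rng_seed: int = 0,
) -> InputSignal:
    """White noise smoothed with an exponential filter, independent per dimension.

    ``amplitude`` is the standard deviation of the underlying continuous-time
    white noise; the stationary standard deviation of the smoothed signal is
    ``amplitude / sqrt(2 * smoothing_rate)``.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if smoothing_rate <= 0:
        raise ValueError("smoothing_rate must be positive")
    n_steps = int(round(duration / dt))
    rng = np.random.default_rng(rng_seed)
    noise = rng.standard_normal((n_dims, n_steps)) * (amplitude / np.sqrt(dt))
    s = leaky_filter(noise, smoothing_rate, dt)
    return InputSignal(s=s, dt=dt)


def circular_bump_drive(
    params: TopographicParams,
    trajectory_rate: float,
    duration: float,
    dt: float,
    rng_seed: int = 0,
    trajectory_amplitude: float = 2.0,
) -> InputSignal:
    """Circular Gaussian bump ``s_j = A exp(B (cos(theta_j - c(t)) - 1))``.

    The bump centre ``c(t)`` is a smoothed-white-noise trajectory on the
    ring (filter rate ``trajectory_rate``, white-noise amplitude
    ``trajectory_amplitude`` in radians).
    """
    centre = smoothed_white_noise(
        1, duration, dt, trajectory_rate, trajectory_amplitude, rng_seed
    ).s[0]
    n_pix = params.pixels
    theta = 2.0 * np.pi * np.arange(n_pix) / n_pix
    s = params.A * np.exp(params.B * (np.cos(theta[:, None] - centre[None, :]) - 1.0))
    return InputSignal(s=s, dt=dt)


def quiescent_input(n_dims: int, duration: float, dt: float) -> InputSignal:
    """All-zero drive (quiescent working regime)."""
    n_steps = int(round(duration / dt))
    return InputSignal(s=np.zeros((n_dims, n_steps)), dt=dt)


def target_from_input(input_signal: InputSignal, leak_rate: float) -> TargetSignal:
    """Target signal: the input convolved with the decoder filter exp(-leak_rate t)."""
    x = leaky_filter(input_signal.s, leak_rate, input_signal.dt)
    return TargetSignal(x=x, dt=input_signal.dt)
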
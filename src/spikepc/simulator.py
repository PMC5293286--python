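"""Network simulation: membrane dynamics, spiking, decoding and diagnostics.

The membrane potential of neuron *i* follows

    dV_i/dt = -lam * V_i + w_i . s(t) - [phi o(t - delay)]_i - mu o_i + sigma eta_i

and a spike is emitted when ``V_i`` exceeds ``||w_i||^2/2 + mu/2 + nu/2``.
The potential is the projection of the global coding error on the
neuron's weight, ``V_i = w_i . (x - xhat) - mu r_i``, which
:func:`membrane_consistency_residual` verifies directly on noiseless runs.

Time is in seconds throughout; the membrane-noise standard deviation is
accepted in the per-millisecond units common in the experimental
literature and converted internally (a factor ``sqrt(1000)`` on the
diffusion coefficient).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels
from .network import CostParams, NetworkSpec, firing_thresholds
from .signals import InputSignal, leaky_filter, target_from_input

__all__ = [
    "SimConfig",
    "SimulationResult",
    "simulate",
    "decode_estimate",
    "membrane_consistency_residual",
]

#: conversion of the noise sd from ms^-1 units to s^-1 diffusion units
_MS_TO_S_NOISE = np.sqrt(1000.0)


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    Parameters
    ----------
    dt : float
        Integration step in seconds (default 0.1 ms).
    duration : float
        Trial length in seconds; ignored when an input signal fixes the grid.
    leak_rate : float
        Membrane/decoder leak ``lam`` in Hz (default 4).
    delay : float
        Synaptic transmission delay in seconds; must be an integer number
        of steps.  Default 1 ms, identical for all connections.
    noise_sd : float
        White-noise sd in ms^-1 units (converted internally).
    p_spike : float
        Probability that a suprathreshold neuron actually emits a spike.
    coupling_mode : str
        ``"delayed"`` (synchronous within-step firing, lateral interaction
        delayed) or ``"instantaneous"`` (greedy one-at-a-time resolution).
    self_delay : bool
        If True the neuron's own reset and adaptation are also delayed;
        by default the reset is immediate (it is the neuron's own
        mechanism, not a synapse).
    record_v : bool
        Store the full membrane-potential trace (memory: N x T doubles).
    """

    dt: float = 1e-4
    duration: float = 1.0
    leak_rate: float = 4.0
    delay: float = 1e-3
    noise_sd: float = 0.0
    p_spike: float = 1.0
    rng_seed: int = 0
    coupling_mode: str = "delayed"
    self_delay: bool = False
    record_v: bool = True
    initial_v: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")
        if not 0.0 <= self.p_spike <= 1.0:
            raise ValueError(f"p_spike must be in [0, 1], got {self.p_spike}")
        if self.coupling_mode not in ("delayed", "instantaneous"):
            raise ValueError(f"unknown coupling_mode {self.coupling_mode!r}")
        steps = self.delay / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError(
                f"delay ({self.delay} s) must be an integer multiple of dt ({self.dt} s)"
            )

    @property
    def delay_steps(self) -> int:
        return int(round(self.delay / self.dt))


@dataclass
class SimulationResult:
    """Raster, rates, potentials, decoded estimate and target of one run."""

    o: np.ndarray                 # (N, T) spike counts per step (uint8)
    v: np.ndarray | None          # (N, T) membrane potentials, or None
    estimate: np.ndarray          # (J, T) decoded signal xhat
    target: np.ndarray            # (J, T) signal x
    rates: np.ndarray             # (N, T) instantaneous rates r
    dt: float
    config: SimConfig
    spec: NetworkSpec
    costs: CostParams
    spikes: list = field(default_factory=list)  # (time_s, neuron_id) pairs

    @property
    def n_neurons(self) -> int:
        return self.o.shape[0]

    @property
    def n_steps(self) -> int:
        return self.o.shape[1]

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt

    @property
    def total_spikes(self) -> int:
        return int(self.o.sum())

    def spike_times(self, neuron: int) -> np.ndarray:
        steps = np.nonzero(self.o[neuron])[0]
        return np.repeat(steps, self.o[neuron][steps]) * self.dt

    def spikes_to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.spikes, columns=["time_s", "neuron_id"])
        df.to_csv(path, index=False, float_format="%.6f")


def _spike_list(o: np.ndarray, dt: float) -> list:
    steps, nrn = np.nonzero(o.T)  # row-major: ordered by time, then neuron id
    out = []
    for s_, i_ in zip(steps, nrn):
        for _ in range(int(o[i_, s_])):
            out.append((float(s_) * dt, int(i_)))
    return out


def simulate(
    spec: NetworkSpec,
    input_signal: InputSignal,
    costs: CostParams,
    config: SimConfig,
    forced_spikes: list[tuple[int, int]] | None = None,
    frozen_noise: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate the network dynamics over the input's time grid.

    Parameters
    ----------
    forced_spikes : list of (step, neuron_id)
        Spikes injected regardless of threshold; the membrane is first
        placed at the neuron's cost-free threshold, emulating a
        noise-driven crossing.
    frozen_noise : (N, T) array, optional
        Pre-drawn per-step noise increments, overriding the internal
        noise generator (used for matched-noise comparisons).
    """
    if abs(input_signal.dt - config.dt) > 1e-12:
        raise ValueError(
            f"input grid dt={input_signal.dt} does not match config dt={config.dt}"
        )
    if input_signal.n_dims != spec.n_signals:
        raise ValueError(
            f"input has {input_signal.n_dims} dimensions but the network "
            f"decodes {spec.n_signals}"
        )
    n, t_steps = spec.n_neurons, input_signal.n_steps
    F = np.ascontiguousarray(spec.w @ input_signal.s)
    thres = firing_thresholds(spec, costs)
    sigma_step = config.noise_sd * _MS_TO_S_NOISE * np.sqrt(config.dt)
    v0 = (
        np.zeros(n)
        if config.initial_v is None
        else np.asarray(config.initial_v, dtype=float)
    )
    if forced_spikes:
        fsteps = np.asarray([f[0] for f in forced_spikes], dtype=np.int64)
        fids = np.asarray([f[1] for f in forced_spikes], dtype=np.int64)
    else:
        fsteps = np.empty(0, dtype=np.int64)
        fids = np.empty(0, dtype=np.int64)
    if frozen_noise is not None:
        noise = np.ascontiguousarray(frozen_noise, dtype=float)
        if noise.shape != (n, t_steps):
            raise ValueError("frozen_noise must have shape (n_neurons, n_steps)")
        use_noise = True
    else:
        noise = _kernels.NO_TRACE
        use_noise = False
    phi = np.ascontiguousarray(spec.phi)
    seed = int(config.rng_seed) % (2**31)

    if config.coupling_mode == "delayed":
        o, vtrace, _ = _kernels.run_delayed(
            F, phi, thres, config.leak_rate, config.dt, config.delay_steps,
            costs.mu, sigma_step, config.p_spike, seed, v0, fsteps, fids,
            config.self_delay, noise, use_noise, config.record_v,
        )
    else:
        o, vtrace, _ = _kernels.run_instantaneous(
            F, phi, thres, config.leak_rate, config.dt, costs.mu, sigma_step,
            config.p_spike, seed, v0, fsteps, fids, noise, use_noise,
            config.record_v,
        )

    rates = _rates_from_raster(o, config.leak_rate, config.dt)
    estimate = spec.w.T @ rates
    target = target_from_input(input_signal, config.leak_rate).x
    return SimulationResult(
        o=o,
        v=vtrace if config.record_v else None,
        estimate=estimate,
        target=target,
        rates=rates,
        dt=config.dt,
        config=config,
        spec=spec,
        costs=costs,
        spikes=_spike_list(o, config.dt),
    )


def _rates_from_raster(o: np.ndarray, leak_rate: float, dt: float) -> np.ndarray:
    # spikes are unit impulses: r[t] = r[t-1] exp(-lam dt) + o[t]
    return leaky_filter(o.astype(float) / dt, leak_rate, dt)


def decode_estimate(
    spikes_or_rates: np.ndarray,
    spec: NetworkSpec,
    leak_rate: float,
    dt: float,
    already_rates: bool = False,
) -> np.ndarray:
    """Linear read-out ``xhat_j = sum_i w_ij r_i`` from a raster or rates."""
    arr = np.asarray(spikes_or_rates, dtype=float)
    rates = arr if already_rates else _rates_from_raster(arr, leak_rate, dt)
    return spec.w.T @ rates


def membrane_consistency_residual(
    result: SimulationResult, costs: CostParams
) -> float:
    """Max deviation between integrated V and ``w (x - xhat) - mu r``.

    Only meaningful for noiseless runs; contract: O(dt) for the
    zero-delay configuration.
    """
    if result.config.noise_sd != 0.0:
        raise ValueError(
            "membrane consistency is only defined for noiseless runs "
            "(the residual does not vanish under stochastic forcing)"
        )
    if result.v is None:
        raise ValueError("simulation was run without record_v")
    predicted = (
        result.spec.w @ (result.target - result.estimate) - costs.mu * result.rates
    )
    return float(np.max(np.abs(result.v - predicted)))
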
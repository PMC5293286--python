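"""Coding efficiency: mean error, spike cost and the Total-error surface.

The network is *efficient* when it is simultaneously accurate (small
time-averaged distance between signal and read-out, normalized by the
mean weight norm so the measure does not depend on the weight scale) and
parsimonious (low population firing rate).  ``Total error =
alpha * <error> + beta * <cost>`` with ``alpha = beta = 1`` by default: a
single spike then contributes one unit to the cost and, through its
weight, order one unit to the error.  Sweeping the (nu, mu) cost plane
and minimizing the Total error locates the optimal working regime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .network import CostParams, NetworkSpec
from .signals import InputSignal
from .simulator import SimConfig, SimulationResult, simulate
from .upstate import detect_up_states

__all__ = [
    "EfficiencyReport",
    "EfficiencySurface",
    "coding_error",
    "spike_cost",
    "total_error",
    "cost_sweep",
]


@dataclass(frozen=True)
class EfficiencyReport:
    mean_error: float
    mean_cost: float
    alpha: float
    beta: float
    trial_length: float
    n_signals: int

    @property
    def total(self) -> float:
        return self.alpha * self.mean_error + self.beta * self.mean_cost


def coding_error(result: SimulationResult, spec: NetworkSpec | None = None) -> float:
    """Time-averaged absolute coding error, normalized by the mean weight norm.

    ``(1/<||w||>) (1/(T J)) integral sum_j |x_j - xhat_j| dt`` — i.e. the
    mean absolute per-dimension deviation in units of the average neuron
    weight norm.
    """
    spec = spec if spec is not None else result.spec
    mean_norm = float(np.mean(np.linalg.norm(spec.w, axis=1)))
    if mean_norm == 0.0:
        raise ValueError("mean weight norm is zero; normalized error undefined")
    return float(np.mean(np.abs(result.target - result.estimate))) / mean_norm


def spike_cost(result: SimulationResult) -> float:
    """Population firing rate: total spike count divided by trial length (Hz)."""
    return result.total_spikes / result.duration


def total_error(
    result: SimulationResult,
    alpha: float = 1.0,
    beta: float = 1.0,
    spec: NetworkSpec | None = None,
) -> EfficiencyReport:
    """Weighted efficiency objective ``alpha * <error> + beta * <cost>``."""
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    if alpha == 0 and beta == 0:
        raise ValueError("at least one of alpha, beta must be positive")
    return EfficiencyReport(
        mean_error=coding_error(result, spec),
        mean_cost=spike_cost(result),
        alpha=alpha,
        beta=beta,
        trial_length=result.duration,
        n_signals=result.target.shape[0],
    )


@dataclass
class EfficiencySurface:
    nu_grid: np.ndarray
    mu_grid: np.ndarray
    error: np.ndarray       # (len(nu), len(mu))
    cost: np.ndarray
    total: np.ndarray
    upstate_freq: np.ndarray | None
    n_repeats: int
    rng_seed: int

    @property
    def optimum(self) -> tuple[float, float]:
        """(nu*, mu*) attaining the minimum of the total-error matrix."""
        i, j = np.unravel_index(np.argmin(self.total), self.total.shape)
        return float(self.nu_grid[i]), float(self.mu_grid[j])

    @property
    def optimum_value(self) -> float:
        return float(np.min(self.total))

    @property
    def optimum_indices(self) -> tuple[int, int]:
        i, j = np.unravel_index(np.argmin(self.total), self.total.shape)
        return int(i), int(j)

    def best_cells(self, k: int = 5) -> list:
        """The k grid cells with smallest total error: the optimum is a
        neighbourhood of good solutions, not a single point."""
        flat = np.argsort(self.total, axis=None)[:k]
        out = []
        for f in flat:
            i, j = np.unravel_index(f, self.total.shape)
            out.append(
                (float(self.nu_grid[i]), float(self.mu_grid[j]),
                 float(self.total[i, j]))
            )
        return out

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for i, nu in enumerate(self.nu_grid):
            for j, mu in enumerate(self.mu_grid):
                rows.append(
                    {
                        "nu": nu,
                        "mu": mu,
                        "error": self.error[i, j],
                        "cost": self.cost[i, j],
                        "total": self.total[i, j],
                        "upstate_freq": (
                            np.nan if self.upstate_freq is None
                            else self.upstate_freq[i, j]
                        ),
                        "n_repeats": self.n_repeats,
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)

    def optimum_json(self, path: str | Path | None = None) -> str:
        nu, mu = self.optimum
        text = json.dumps(
            {
                "nu_opt": nu,
                "mu_opt": mu,
                "total_at_optimum": self.optimum_value,
                "n_repeats": self.n_repeats,
                "rng_seed": self.rng_seed,
            }
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def cost_sweep(
    spec: NetworkSpec,
    input_generator: Callable[[int], InputSignal],
    config: SimConfig,
    nu_grid: np.ndarray,
    mu_grid: np.ndarray,
    n_repeats: int = 3,
    rng_seed: int = 0,
    alpha: float = 1.0,
    beta: float = 1.0,
    track_up_states: bool = True,
    upstate_fraction: float = 0.2,
    upstate_window: float | None = None,
) -> EfficiencySurface:
    """Average <error>, <cost> and Total error over a (nu, mu) grid.

    Each cell is averaged over ``n_repeats`` runs with fresh input and
    noise seeds (drawn from independent substreams of ``rng_seed``); the
    same ``n_repeats`` seeds are reused in every cell so rows and columns
    of the surface are comparable realization by realization.
    """
    nu_grid = np.asarray(nu_grid, dtype=float)
    mu_grid = np.asarray(mu_grid, dtype=float)
    if nu_grid.size == 0 or mu_grid.size == 0:
        raise ValueError("cost grids must be non-empty")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    window = upstate_window if upstate_window is not None else max(
        config.delay, config.dt
    )
    ss = np.random.SeedSequence(rng_seed)
    rep_seeds = [s.generate_state(2) for s in ss.spawn(n_repeats)]

    shape = (len(nu_grid), len(mu_grid))
    err = np.zeros(shape)
    cost = np.zeros(shape)
    upfreq = np.zeros(shape) if track_up_states else None
    cfg_base = config if config.record_v is False else _no_trace(config)
    for i, nu in enumerate(nu_grid):
        for j, mu in enumerate(mu_grid):
            costs = CostParams(nu=float(nu), mu=float(mu))
            for input_seed, sim_seed in rep_seeds:
                try:
                    inp = input_generator(int(input_seed) % (2**31))
                    cfg = _with_seed(cfg_base, int(sim_seed) % (2**31))
                    res = simulate(spec, inp, costs, cfg)
                except Exception as exc:  # annotate with the failing cell
                    raise RuntimeError(
                        f"simulation failed at sweep cell nu={nu}, mu={mu}"
                    ) from exc
                err[i, j] += coding_error(res)
                cost[i, j] += spike_cost(res)
                if track_up_states:
                    seg = detect_up_states(
                        res.o, dt=res.dt, fraction=upstate_fraction,
                        window=window,
                    )
                    upfreq[i, j] += seg.frequency
            err[i, j] /= n_repeats
            cost[i, j] /= n_repeats
            if track_up_states:
                upfreq[i, j] /= n_repeats
    return EfficiencySurface(
        nu_grid=nu_grid, mu_grid=mu_grid, error=err, cost=cost,
        total=alpha * err + beta * cost, upstate_freq=upfreq,
        n_repeats=n_repeats, rng_seed=rng_seed,
    )


def _with_seed(config: SimConfig, seed: int) -> SimConfig:
    from dataclasses import replace

    return replace(config, rng_seed=seed)


def _no_trace(config: SimConfig) -> SimConfig:
    from dataclasses import replace

    return replace(config, record_v=False)
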
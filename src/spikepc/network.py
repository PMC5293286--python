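"""Network construction: decoding weights, recurrent connectivity and thresholds.

A network is defined entirely by its matrix of decoding weights ``w``
(one row per neuron, one column per encoded signal dimension).  The
recurrent connectivity is the Gram matrix ``phi = w @ w.T``: neuron *k*'s
spike moves the read-out by ``w_k``, and the resulting change in every
other neuron's projected coding error is ``-phi[:, k]``.  The firing
threshold of neuron *i* is ``||w_i||^2 / 2`` plus half of each spike-cost
parameter.

Two families of networks are provided: dense random networks whose weights
are i.i.d. standard normal, and topographic ring networks of ON/OFF cells
with blob-shaped (von Mises profile) receptive fields, where connectivity
is local: same-polarity neighbours inhibit each other, opposite-polarity
neighbours excite each other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "NetworkSpec",
    "CostParams",
    "TopographicParams",
    "build_random_network",
    "build_topographic_network",
    "connectivity_matrix",
    "firing_thresholds",
]


@dataclass(frozen=True)
class CostParams:
    """Spike-cost parameters.

    Parameters
    ----------
    nu : float
        Linear cost on firing (units of weight squared).  Raises every
        neuron's threshold by ``nu / 2``; penalises total population rate.
    mu : float
        Quadratic cost on firing (units of weight squared).  Raises every
        threshold by ``mu / 2`` and hyperpolarises the spiking neuron by an
        extra ``mu`` (spike-triggered adaptation); encourages spikes to be
        spread across neurons.
    """

    nu: float = 0.0
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.nu < 0 or self.mu < 0:
            raise ValueError(
                f"cost parameters must be non-negative, got nu={self.nu}, mu={self.mu}"
            )


@dataclass(frozen=True)
class TopographicParams:
    """Parameters of the topographic ON/OFF ring network and its drive.

    ``A`` and ``B`` are the amplitude and concentration of the circular
    Gaussian input bump; ``C`` and ``D`` play the same roles for the
    receptive-field (decoding-weight) profiles.  ``n_on`` and ``n_off``
    are the subpopulation sizes and must be equal: each ON cell shares its
    preferred position with one OFF cell.
    """

    A: float = 1.0
    B: float = 3.0
    C: float = 0.3
    D: float = 3.0
    n_on: int = 200
    n_off: int = 200
    n_pixels: int | None = None  # defaults to n_on (one pixel per position)

    def __post_init__(self) -> None:
        if min(self.A, self.B, self.C, self.D) <= 0:
            raise ValueError("A, B, C, D must all be positive")
        if self.n_on <= 0 or self.n_off <= 0:
            raise ValueError("subpopulation sizes must be positive")
        if self.n_on != self.n_off:
            raise ValueError(
                f"ON and OFF subpopulations must be equal in size, got "
                f"n_on={self.n_on}, n_off={self.n_off}"
            )

    @property
    def pixels(self) -> int:
        return self.n_pixels if self.n_pixels is not None else self.n_on


@dataclass
class NetworkSpec:
    """A fully specified network: weights, connectivity and metadata.

    Attributes
    ----------
    w : (N, J) ndarray
        Decoding weights, one row per neuron.
    phi : (N, N) ndarray
        Recurrent connectivity ``w @ w.T``; symmetric, positive
        semi-definite, rank at most J.
    kind : str
        ``"random_alltoall"`` or ``"topographic"``.
    positions : (N,) ndarray or None
        Preferred angle of each neuron on the ring (topographic only).
    polarity : (N,) ndarray of "+"/"-" or None
        ON / OFF tag per neuron (topographic only).
    """

    w: np.ndarray
    kind: str = "random_alltoall"
    positions: np.ndarray | None = None
    polarity: np.ndarray | None = None
    phi: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2:
            raise ValueError("w must be a 2-D (neurons x signals) array")
        self.phi = self.w @ self.w.T

    @property
    def n_neurons(self) -> int:
        return self.w.shape[0]

    @property
    def n_signals(self) -> int:
        return self.w.shape[1]

    def refresh(self) -> None:
        """Recompute ``phi`` after an in-place edit of ``w``."""
        self.w = np.asarray(self.w, dtype=float)
        self.phi = self.w @ self.w.T

    # -- serialization -------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kind": self.kind,
            "w": self.w.tolist(),
            "positions": None if self.positions is None else self.positions.tolist(),
            "polarity": None if self.polarity is None else list(self.polarity),
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "NetworkSpec":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            source = Path(source).read_text()
        payload = json.loads(source)
        return cls(
            w=np.asarray(payload["w"], dtype=float),
            kind=payload["kind"],
            positions=None
            if payload.get("positions") is None
            else np.asarray(payload["positions"], dtype=float),
            polarity=None
            if payload.get("polarity") is None
            else np.asarray(payload["polarity"], dtype=object),
        )


def build_random_network(
    n_neurons: int, n_signals: int, rng_seed: int = 0
) -> NetworkSpec:
    """Dense all-to-all network with i.i.d. standard-normal decoding weights.

    The same seed always yields bitwise-identical weights.
    """
    if n_neurons < 1 or n_signals < 1:
        raise ValueError(
            f"sizes must be positive, got n_neurons={n_neurons}, n_signals={n_signals}"
        )
    rng = np.random.default_rng(rng_seed)
    w = rng.standard_normal((n_neurons, n_signals))
    return NetworkSpec(w=w, kind="random_alltoall")


def build_topographic_network(params: TopographicParams) -> NetworkSpec:
    """Ring of ON/OFF neurons with local, blob-shaped receptive fields.

    Neuron *i* (ON) at angle ``theta_i`` has weight onto pixel *j*

        ``w_ij = C * exp(D * (cos(theta_j - theta_i) - 1))``

    and the paired OFF neuron has the negated profile.  Angles are equally
    spaced on [0, 2*pi); ON and OFF cells with the same index sit at the
    same physical position.
    """
    n = params.n_on
    n_pix = params.pixels
    theta_neuron = 2.0 * np.pi * np.arange(n) / n
    theta_pix = 2.0 * np.pi * np.arange(n_pix) / n_pix
    # profile[i, j] = exp(D (cos(theta_j - theta_i) - 1)), peak 1 at theta_j = theta_i
    dtheta = theta_pix[None, :] - theta_neuron[:, None]
    profile = np.exp(params.D * (np.cos(dtheta) - 1.0))
    w_on = params.C * profile
    w = np.vstack([w_on, -w_on])
    positions = np.concatenate([theta_neuron, theta_neuron])
    polarity = np.asarray(["+"] * n + ["-"] * n, dtype=object)
    return NetworkSpec(w=w, kind="topographic", positions=positions, polarity=polarity)


def connectivity_matrix(spec: NetworkSpec) -> np.ndarray:
    """Recurrent connectivity ``phi = w @ w.T`` (the interaction is ``-phi``)."""
    return spec.w @ spec.w.T


def firing_thresholds(spec: NetworkSpec, costs: CostParams) -> np.ndarray:
    """Per-neuron firing thresholds ``||w_i||^2/2 + mu/2 + nu/2``."""
    return 0.5 * np.sum(spec.w**2, axis=1) + 0.5 * costs.mu + 0.5 * costs.nu
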
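"""Spike-train statistics: MUA, shuffle-corrected S-MUA, Up-state detection,
interval statistics, CV2 and synchrony.

An *Up state* is operationally a period in which at least a criterion
fraction of the population (default 20%) has fired within a short
trailing window (default: one synaptic delay).  Inter-burst intervals
(IBIs) are the gaps between consecutive Up states and are summarized by a
maximum-likelihood Gamma fit; Up-state durations are summarized by an
Epanechnikov-kernel density.

The spike-triggered multi-unit activity (S-MUA) measures how strongly a
single neuron's spiking locks to the population: the population MUA is
averaged in a +/-100 ms window around each spike, a shuffle estimate
(the same neuron's spikes paired with the MUA of an *incongruent* trial)
is subtracted, and the result is averaged over neurons and normalized by
the total spike count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from scipy.signal import lfilter

__all__ = [
    "MUATrace",
    "SMUAProfile",
    "UpStateSegments",
    "compute_mua",
    "compute_smua",
    "detect_up_states",
    "interburst_statistics",
    "duration_statistics",
    "compute_cv2",
    "synchrony_fraction",
]


@dataclass
class MUATrace:
    values: np.ndarray
    dt: float
    decay_rate: float


@dataclass
class SMUAProfile:
    lags: np.ndarray
    values: np.ndarray
    n_trials: int

    @property
    def peak_lag(self) -> float:
        """Lag of the profile maximum; ties resolved to the smallest |lag|."""
        m = np.max(self.values)
        cand = np.nonzero(self.values >= m - 1e-15 * max(1.0, abs(m)))[0]
        return float(self.lags[cand[np.argmin(np.abs(self.lags[cand]))]])


@dataclass
class UpStateSegments:
    segments: list  # list of (start_s, end_s)
    criterion_fraction: float
    window: float
    trial_length: float

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def durations(self) -> np.ndarray:
        return np.asarray([e - s for s, e in self.segments])

    def interburst_intervals(self) -> np.ndarray:
        if len(self.segments) < 2:
            return np.empty(0)
        starts = np.asarray([s for s, _ in self.segments])
        ends = np.asarray([e for _, e in self.segments])
        return starts[1:] - ends[:-1]

    @property
    def frequency(self) -> float:
        """Up states per second of trial."""
        return self.n_segments / self.trial_length


def _as_raster(raster: np.ndarray) -> np.ndarray:
    arr = np.asarray(raster)
    if arr.ndim != 2:
        raise ValueError("raster must be a 2-D (neurons x steps) array")
    return arr


def compute_mua(
    raster: np.ndarray, n_neurons: int | None = None, dt: float = 1e-4,
    decay_rate: float = 50.0,
) -> MUATrace:
    """Multi-unit activity: population spike train convolved with exp(-lam_D t).

    Each spike contributes a unit-height exponential with decay
    ``decay_rate`` (default 50 Hz, a short memory that tracks fast
    population-rate fluctuations).
    """
    arr = _as_raster(raster)
    pop = arr.sum(axis=0).astype(float)
    decay = np.exp(-decay_rate * dt)
    out = lfilter([1.0], [1.0, -decay], pop)
    return MUATrace(values=out, dt=dt, decay_rate=decay_rate)


def compute_smua(
    trials: list[np.ndarray], dt: float = 1e-4, window: float = 0.1,
    decay_rate: float = 50.0,
) -> SMUAProfile:
    """Shuffle-corrected spike-triggered MUA over a set of trials.

    Requires at least two trials: the shuffle term pairs each neuron's
    spikes with the MUA of the next trial (circular shift), the simplest
    incongruent-trial pairing.  Spikes closer than ``window`` to a trial
    edge see a truncated (zero-extended) window in both terms.
    """
    if len(trials) < 2:
        raise ValueError(
            "S-MUA requires >= 2 trials: the shuffle correction pairs spikes "
            "with the MUA of an incongruent trial"
        )
    rasters = [_as_raster(tr) for tr in trials]
    n = rasters[0].shape[0]
    w = int(round(window / dt))
    lags = np.arange(-w, w + 1) * dt
    muas = [compute_mua(tr, dt=dt, decay_rate=decay_rate).values for tr in rasters]
    raw = np.zeros((n, 2 * w + 1))
    shuf = np.zeros((n, 2 * w + 1))
    total_spikes = 0
    n_trials = len(rasters)
    for k, tr in enumerate(rasters):
        total_spikes += int(tr.sum())
        raw += _spike_triggered_sums(tr, muas[k], w)
        shuf += _spike_triggered_sums(tr, muas[(k + 1) % n_trials], w)
    if total_spikes == 0:
        return SMUAProfile(lags=lags, values=np.zeros(2 * w + 1), n_trials=n_trials)
    corrected = (raw - shuf).mean(axis=0) / total_spikes
    return SMUAProfile(lags=lags, values=corrected, n_trials=n_trials)


def _spike_triggered_sums(raster: np.ndarray, mua: np.ndarray, w: int) -> np.ndarray:
    """Per neuron, ``sum_t o_i(t) * mua(t + tau)`` for lags ``tau`` in
    [-w, w], via FFT cross-correlation (the MUA is zero beyond the trial
    edges, so spikes near an edge see a truncated window)."""
    t_len = raster.shape[1]
    nfft = int(2 ** np.ceil(np.log2(t_len + w + 1)))
    mua_f = np.fft.rfft(mua, nfft)
    out = np.empty((raster.shape[0], 2 * w + 1))
    for i in range(raster.shape[0]):
        if not raster[i].any():
            out[i] = 0.0
            continue
        cc = np.fft.irfft(np.conj(np.fft.rfft(raster[i], nfft)) * mua_f, nfft)
        out[i, w:] = cc[: w + 1]          # tau = 0 .. w
        out[i, :w] = cc[nfft - w :]       # tau = -w .. -1
    return out


def _windowed_active_count(
    raster: np.ndarray, win_steps: int
) -> np.ndarray:
    """Per step, number of distinct neurons with >= 1 spike in the trailing
    window of ``win_steps`` steps (window includes the current step)."""
    arr = (_as_raster(raster) > 0).astype(np.int32)
    csum = np.cumsum(arr, axis=1)
    shifted = np.zeros_like(csum)
    shifted[:, win_steps:] = csum[:, :-win_steps]
    in_window = (csum - shifted) > 0
    return in_window.sum(axis=0)


def detect_up_states(
    raster: np.ndarray,
    n_neurons: int | None = None,
    dt: float = 1e-4,
    fraction: float = 0.2,
    window: float = 1e-3,
) -> UpStateSegments:
    """Detect Up states: >= ``fraction`` of neurons active within ``window``.

    A step qualifies when the count of distinct neurons with at least one
    spike inside the trailing window reaches ``fraction * N``; contiguous
    qualifying steps merge into segments.  The default window is one
    synaptic delay (1 ms): synchronous events recruit many neurons within
    a single delay.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    arr = _as_raster(raster)
    n = n_neurons if n_neurons is not None else arr.shape[0]
    win_steps = max(1, int(round(window / dt)))
    active = _windowed_active_count(arr, win_steps)
    qualifying = active >= fraction * n
    segments = []
    t_steps = arr.shape[1]
    in_seg = False
    start = 0
    for t in range(t_steps):
        if qualifying[t] and not in_seg:
            in_seg, start = True, t
        elif not qualifying[t] and in_seg:
            segments.append((start * dt, t * dt))
            in_seg = False
    if in_seg:
        segments.append((start * dt, t_steps * dt))
    return UpStateSegments(
        segments=segments, criterion_fraction=fraction, window=window,
        trial_length=t_steps * dt,
    )


@dataclass
class IntervalSummary:
    intervals: np.ndarray
    mean: float | None
    gamma_shape: float | None = None
    gamma_scale: float | None = None
    status: str = "ok"


def interburst_statistics(
    segments: UpStateSegments, min_for_fit: int = 10
) -> IntervalSummary:
    """Inter-burst intervals with a maximum-likelihood Gamma fit.

    Fewer than two segments yield an empty interval list; the Gamma fit is
    refused below ``min_for_fit`` intervals (too few for a stable MLE).
    """
    ibis = segments.interburst_intervals()
    if len(ibis) == 0:
        return IntervalSummary(
            intervals=ibis, mean=None,
            status="need >= 2 Up states to form inter-burst intervals",
        )
    mean = float(np.mean(ibis))
    if len(ibis) < min_for_fit:
        return IntervalSummary(
            intervals=ibis, mean=mean,
            status=f"gamma fit refused: {len(ibis)} < {min_for_fit} intervals",
        )
    if np.std(ibis) <= 1e-9 * abs(mean):
        return IntervalSummary(
            intervals=ibis, mean=mean,
            status="gamma fit refused: intervals are degenerate (zero variance)",
        )
    shape, _, scale = sstats.gamma.fit(ibis, floc=0.0)
    return IntervalSummary(
        intervals=ibis, mean=mean, gamma_shape=float(shape),
        gamma_scale=float(scale),
    )


@dataclass
class DurationSummary:
    durations: np.ndarray
    mean: float | None
    density_grid: np.ndarray | None = None
    density: np.ndarray | None = None
    bandwidth: float | None = None
    status: str = "ok"


def duration_statistics(
    segments: UpStateSegments,
    grid: np.ndarray | None = None,
    bandwidth: float | None = None,
) -> DurationSummary:
    """Up-state durations with an Epanechnikov-kernel density estimate.

    The bandwidth defaults to the Epanechnikov plug-in rule
    ``h = 2.345 sigma n^(-1/5)``; the kernel is evaluated on ``grid``
    (default: 512 points spanning the data plus one bandwidth).
    """
    durs = segments.durations()
    if len(durs) == 0:
        return DurationSummary(durations=durs, mean=None, status="no Up states")
    mean = float(np.mean(durs))
    sigma = float(np.std(durs, ddof=1)) if len(durs) > 1 else 0.0
    if bandwidth is None:
        bandwidth = 2.345 * sigma * len(durs) ** (-0.2) if sigma > 0 else max(
            float(np.mean(durs)) * 0.1, 1e-6
        )
    if grid is None:
        lo = max(0.0, float(durs.min()) - bandwidth)
        hi = float(durs.max()) + bandwidth
        grid = np.linspace(lo, hi, 512)
    u = (grid[None, :] - durs[:, None]) / bandwidth
    kern = np.where(np.abs(u) < 1.0, 0.75 * (1.0 - u**2), 0.0) / bandwidth
    density = kern.mean(axis=0)
    return DurationSummary(
        durations=durs, mean=mean, density_grid=grid, density=density,
        bandwidth=bandwidth,
    )


@dataclass
class CV2Summary:
    per_neuron: np.ndarray  # NaN for neurons with < 3 spikes
    mean: float | None
    n_eligible: int
    status: str = "ok"


def _cv2_of_train(times: np.ndarray) -> float:
    isi = np.diff(times)
    pair = 2.0 * np.abs(np.diff(isi)) / (isi[1:] + isi[:-1])
    return float(np.mean(pair))


def compute_cv2(
    raster: np.ndarray | list[np.ndarray],
    dt: float = 1e-4,
    per_neuron: bool = True,
) -> CV2Summary:
    """Local ISI-variability statistic CV2, averaged over neurons.

    ``CV2_i`` is the mean over consecutive ISI pairs of
    ``2 |ISI_{j+1} - ISI_j| / (ISI_{j+1} + ISI_j)``; approximately 1 for a
    Poisson train and 0 for a perfectly regular one.  Neurons with fewer
    than 3 spikes carry no ISI pair and are excluded from the mean.
    """
    if isinstance(raster, np.ndarray):
        arr = _as_raster(raster)
        trains = []
        for i in range(arr.shape[0]):
            steps = np.nonzero(arr[i])[0]
            trains.append(np.repeat(steps, arr[i][steps]).astype(float) * dt)
    else:
        trains = [np.asarray(t, dtype=float) for t in raster]
    vals = np.full(len(trains), np.nan)
    for i, t in enumerate(trains):
        if len(t) >= 3:
            vals[i] = _cv2_of_train(t)
    eligible = np.isfinite(vals)
    if not eligible.any():
        return CV2Summary(
            per_neuron=vals, mean=None, n_eligible=0,
            status="no neuron has >= 3 spikes; CV2 undefined",
        )
    return CV2Summary(
        per_neuron=vals, mean=float(np.nanmean(vals)),
        n_eligible=int(eligible.sum()),
    )


@dataclass
class SynchronySummary:
    percent: np.ndarray  # per-step percentage of neurons active in the window
    summary: float | None  # mean over steps containing at least one spike
    status: str = "ok"


def synchrony_fraction(
    raster: np.ndarray,
    n_neurons: int | None = None,
    dt: float = 1e-4,
    window: float = 1e-3,
) -> SynchronySummary:
    """Per-step percentage of neurons with a spike in the trailing window.

    The scalar summary averages over steps in which at least one spike
    occurred; for an empty raster it is undefined.
    """
    if window < dt:
        raise ValueError("window must be at least one step")
    arr = _as_raster(raster)
    n = n_neurons if n_neurons is not None else arr.shape[0]
    win_steps = max(1, int(round(window / dt)))
    percent = 100.0 * _windowed_active_count(arr, win_steps) / n
    any_spike = arr.sum(axis=0) > 0
    if not any_spike.any():
        return SynchronySummary(
            percent=percent, summary=None, status="empty raster: summary undefined"
        )
    return SynchronySummary(
        percent=percent, summary=float(percent[any_spike].mean())
    )
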
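"""Signal-modulated Brownian dynamics of proteinoid microspheres.

Each particle i follows the Euler-Maruyama discretization of

    dr_i = alpha * S(t) * u_i dt + sigma dW_t

where S(t) is the normalized driving signal, u_i a fixed random unit heading
per particle (so the signal modulates speed while the ensemble stays
isotropic), and dW_t a Wiener increment applied independently per axis.
Particles start uniformly distributed in a rectangular box (default
1000 x 1000 nm) with reflecting walls.

Ensemble statistics: mean pairwise (inter-particle) distance, its histogram
and its time course.  For uniformly dispersed particles in an L x L box the
mean pairwise distance is 0.52141 * L (~521 nm for L = 1000 nm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .signal_metrics import Signal

__all__ = [
    "SimConfig",
    "PositionsTrace",
    "simulate",
    "mean_interparticle_distance",
    "distance_histogram",
    "distance_timeseries",
]

#: Mean pairwise distance of uniform points in a unit square.
UNIFORM_SQUARE_MEAN_DISTANCE = 0.5214054331647207


@dataclass
class SimConfig:
    """Simulation parameters.

    alpha is the drift speed gain in nm/s per unit signal; noise_sigma the
    Wiener scale in nm/sqrt(s) per axis.
    """

    n_particles: int = 100
    box: tuple[float, float] = (1000.0, 1000.0)
    alpha: float = 20.0
    noise_sigma: float = 30.0
    dt: float = 0.01
    t_end: float = 50.0
    seed: int = 0
    boundary: str = "reflect"

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.box[0] <= 0 or self.box[1] <= 0:
            raise ValueError("box dimensions must be positive")
        if self.dt <= 0 or self.t_end <= 0 or self.dt >= self.t_end:
            raise ValueError("need 0 < dt < t_end")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.boundary not in ("reflect", "periodic"):
            raise ValueError("boundary must be 'reflect' or 'periodic'")


@dataclass
class PositionsTrace:
    """Per-frame particle positions: times (s) and positions (nm).

    ``positions`` has shape (n_times, n_particles, 2).
    """

    times: np.ndarray
    positions: np.ndarray
    box: tuple[float, float]

    def __post_init__(self) -> None:
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (n_times, n_particles, 2)")
        if self.positions.shape[0] != self.times.size:
            raise ValueError("times and positions disagree on frame count")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def _reflect(pos: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Fold positions back into [0, L] by specular reflection (triangle wave)."""
    period = 2.0 * L
    p = np.mod(pos, period)
    return np.where(p > L, period - p, p)


def simulate(config: SimConfig, signal: Signal | None = None) -> PositionsTrace:
    """Run the Euler-Maruyama simulation.

    ``signal`` is the normalized drive S(t), interpolated to simulation time;
    if omitted the drift term is zero (pure Brownian motion).  The signal
    must span the full [0, t_end] window.  Identical seeds give identical
    traces.
    """
    rng = np.random.default_rng(config.seed)
    n_steps = int(round(config.t_end / config.dt))
    times = np.arange(n_steps + 1) * config.dt
    L = np.asarray(config.box, dtype=float)

    if signal is not None:
        sig_t = signal.times
        if sig_t[-1] < config.t_end - 1e-9:
            raise ValueError(
                f"signal spans {sig_t[-1]:.3f} s but t_end is {config.t_end:.3f} s"
            )
        S = np.interp(times, sig_t, signal.samples)
    else:
        S = np.zeros(times.size)

    pos = rng.uniform(0.0, 1.0, size=(config.n_particles, 2)) * L
    theta = rng.uniform(0.0, 2.0 * np.pi, size=config.n_particles)
    headings = np.column_stack([np.cos(theta), np.sin(theta)])

    out = np.empty((n_steps + 1, config.n_particles, 2))
    out[0] = pos
    sqrt_dt = np.sqrt(config.dt)
    for k in range(n_steps):
        drift = config.alpha * S[k] * headings * config.dt
        noise = config.noise_sigma * sqrt_dt * rng.standard_normal(pos.shape)
        pos = pos + drift + noise
        if config.boundary == "reflect":
            pos = _reflect(pos, L)
        else:
            pos = np.mod(pos, L)
        out[k + 1] = pos
    return PositionsTrace(times=times, positions=out, box=tuple(L))


def mean_interparticle_distance(frame_positions: np.ndarray) -> float:
    """Mean Euclidean distance over all unordered particle pairs (nm)."""
    frame_positions = np.asarray(frame_positions, dtype=float)
    if frame_positions.ndim != 2 or frame_positions.shape[0] < 2:
        raise ValueError("need a (n_particles >= 2, 2) position array")
    return float(np.mean(pdist(frame_positions)))


def distance_histogram(
    frame_positions: np.ndarray, bins: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram (counts, bin_edges) of all pairwise distances in one frame.

    Counts sum to N(N-1)/2.
    """
    frame_positions = np.asarray(frame_positions, dtype=float)
    if frame_positions.ndim != 2 or frame_positions.shape[0] < 2:
        raise ValueError("need a (n_particles >= 2, 2) position array")
    return np.histogram(pdist(frame_positions), bins=bins)


def distance_timeseries(trace: PositionsTrace) -> Signal:
    """Mean pairwise distance per frame, as a Signal (nm vs s)."""
    d = np.array([np.mean(pdist(frame)) for frame in trace.positions])
    return Signal(d, sample_rate=1.0 / trace.dt, t0=float(trace.times[0]))
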
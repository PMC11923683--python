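"""Seeded generators for every input the analysis pipeline consumes.

These stand in for wet recordings so the whole pipeline is testable offline:

* :func:`gen_response_recording` — an attenuated, DC-shifted, noisy
  RC-low-pass-filtered copy of a stimulus, with statistics matched to the
  order of magnitude observed for real proteinoid recordings (output sd
  roughly 1% of input sd, slight negative DC shift).
* :func:`gen_confined_trajectories` — 2-D Ornstein-Uhlenbeck motion whose
  ensemble MSD follows the saturating exponential y0 * (1 - exp(R0 * tau)).
* :func:`gen_sphere_diameters` — normally distributed microsphere diameters
  truncated at zero.
* :func:`gen_golden_walk` — a positive-control walk whose consecutive step
  lengths grow by exactly the golden ratio.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .morphometry import SpherePopulation
from .rc_model import RCParams
from .signal_metrics import Signal
from .stimuli import PHI
from .tracking_stats import TrajectorySet

__all__ = [
    "ResponseModelConfig",
    "gen_response_recording",
    "gen_confined_trajectories",
    "gen_sphere_diameters",
    "gen_golden_walk",
]


@dataclass
class ResponseModelConfig:
    """Synthetic response model: gain * RC_lowpass(x) + dc_offset + noise.

    Defaults emulate the attenuation observed in real recordings (output sd
    ~ 0.0049 V for an input sd ~ 0.4532 V, i.e. gain ~ 0.0108, and a DC
    shift of about -0.01 V).
    """

    gain: float = 0.0108
    dc_offset: float = -0.0104
    rc: RCParams = field(default_factory=lambda: RCParams(R=128.0, C=2.888e-6))
    noise_sd: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gain <= 1.0:
            raise ValueError("gain must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def gen_response_recording(stimulus: Signal, cfg: ResponseModelConfig) -> Signal:
    """Synthetic proteinoid response to a stimulus.

    A first-order RC low-pass (time constant cfg.rc.tau, discretized as an
    exponential smoother) is applied, then gain, DC offset and white Gaussian
    noise.  Deterministic per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = 1.0 / stimulus.sample_rate
    tau = cfg.rc.tau
    a = dt / (tau + dt)  # tau -> 0 gives a = 1: identity filter
    filtered = sps.lfilter([a], [1.0, a - 1.0], stimulus.samples)
    out = cfg.gain * filtered + cfg.dc_offset
    if cfg.noise_sd > 0:
        out = out + rng.normal(0.0, cfg.noise_sd, size=out.shape)
    return Signal(out, sample_rate=stimulus.sample_rate, t0=stimulus.t0)


def gen_confined_trajectories(
    n_particles: int = 200,
    frames: int = 400,
    frame_interval: float = 0.005,
    y0: float = 3853.0,
    R0: float = -12.90,
    noise: float = 0.0,
    seed: int = 0,
) -> TrajectorySet:
    """Confined-diffusion trajectories with MSD ~ y0 * (1 - exp(R0 * tau)).

    Each axis is a stationary Ornstein-Uhlenbeck process with relaxation rate
    theta = -R0 and stationary variance y0/4, exactly reproducing the 2-D
    stationary MSD 4 * var * (1 - exp(-theta * tau)).  Uses the exact OU
    transition, so any frame interval is unbiased.  ``noise`` adds
    independent Gaussian localization error (um) to the stored positions.

    Units: positions in um, rates in 1/s, y0 in um^2.
    """
    if y0 <= 0:
        raise ValueError("y0 must be positive")
    if R0 >= 0:
        raise ValueError("R0 must be negative (confined relaxation)")
    if n_particles < 1 or frames < 2:
        raise ValueError("need >= 1 particle and >= 2 frames")
    rng = np.random.default_rng(seed)
    theta = -R0
    var = y0 / 4.0
    rho = np.exp(-theta * frame_interval)
    innov_sd = np.sqrt(var * (1.0 - rho**2))

    centers = rng.uniform(0.0, 100.0, size=(n_particles, 2))
    x = rng.normal(0.0, np.sqrt(var), size=(n_particles, 2))
    trajs = {}
    store = np.empty((n_particles, frames, 2))
    store[:, 0, :] = x
    for t in range(1, frames):
        x = rho * x + innov_sd * rng.standard_normal((n_particles, 2))
        store[:, t, :] = x
    if noise > 0:
        store = store + rng.normal(0.0, noise, size=store.shape)
    for i in range(n_particles):
        trajs[i] = centers[i] + store[i]
    return TrajectorySet(frame_interval=frame_interval, trajectories=trajs)


def gen_sphere_diameters(
    n: int = 200, mu: float = 1581.27, sigma: float = 302.02, seed: int = 0
) -> SpherePopulation:
    """Normally distributed diameters (nm) truncated at > 0, seeded."""
    if mu <= 0 or sigma < 0:
        raise ValueError("mu must be positive and sigma nonnegative")
    rng = np.random.default_rng(seed)
    if sigma == 0:
        return SpherePopulation(np.full(n, mu))
    a = (0.0 - mu) / sigma  # truncate the (negligible) negative tail
    d = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n, random_state=rng)
    return SpherePopulation(d)


def gen_golden_walk(
    n_steps: int = 20,
    seed: int = 0,
    initial_step: float = 1.0,
    length_noise: float = 0.0,
) -> TrajectorySet:
    """2-D walk whose consecutive step lengths grow by a factor of phi.

    Positive control for the step-ratio analysis: noise-free, every
    consecutive ratio equals phi exactly.  ``length_noise`` applies
    multiplicative Gaussian jitter (relative sd) to each step length.
    Turning angles are uniform on [0, 2*pi).
    """
    if n_steps < 3:
        raise ValueError("n_steps must be >= 3")
    rng = np.random.default_rng(seed)
    lengths = initial_step * PHI ** np.arange(n_steps)
    if length_noise > 0:
        lengths = lengths * (1.0 + length_noise * rng.standard_normal(n_steps))
        lengths = np.abs(lengths)
    angles = rng.uniform(0.0, 2.0 * np.pi, size=n_steps)
    steps = lengths[:, None] * np.column_stack([np.cos(angles), np.sin(angles)])
    pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return TrajectorySet(frame_interval=1.0, trajectories={0: pos})
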
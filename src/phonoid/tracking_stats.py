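"""Trajectory statistics for tracked microspheres.

Given per-particle 2-D positions (micrometres) at a fixed frame interval the
module computes the ensemble mean displacement, the time-and-ensemble
averaged mean squared displacement (MSD), fits of the MSD to a saturating
exponential y0 + A*exp(R0*tau) (confined diffusion: A < 0, R0 < 0, plateau
y0) and to a power law K*tau**alpha (alpha = 1 normal diffusion, alpha < 1
subdiffusion, alpha = 2 ballistic), the diffusion coefficient from the
model's initial slope, and the consecutive step-size ratio distribution
compared against the golden ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .stimuli import PHI

__all__ = [
    "TrajectorySet",
    "MSDCurve",
    "FitResult",
    "StepRatioSummary",
    "mean_displacement",
    "msd",
    "fit_exponential",
    "diffusion_coefficient",
    "fit_powerlaw",
    "step_ratios",
]


@dataclass
class TrajectorySet:
    """Per-particle ordered 2-D positions (um) sampled at a fixed interval."""

    frame_interval: float  # seconds
    trajectories: dict[int, np.ndarray] = field(default_factory=dict)
    # particle id -> (n_frames, 2) array

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        clean = {}
        for pid, arr in self.trajectories.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"particle {pid}: positions must be (n, 2)")
            clean[int(pid)] = arr
        self.trajectories = clean

    @property
    def particle_ids(self) -> list[int]:
        return sorted(self.trajectories)

    @property
    def n_particles(self) -> int:
        return len(self.trajectories)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, frame_interval: float) -> "TrajectorySet":
        """Build from a table with columns frame, particle_id, x_um, y_um."""
        required = {"frame", "particle_id", "x_um", "y_um"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing trajectory columns: {sorted(missing)}")
        trajs = {}
        for pid, grp in df.groupby("particle_id"):
            grp = grp.sort_values("frame")
            if not grp["frame"].is_monotonic_increasing:
                raise ValueError(f"particle {pid}: frames not sortable")
            trajs[int(pid)] = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        return cls(frame_interval=frame_interval, trajectories=trajs)

    @classmethod
    def from_csv(cls, path, frame_interval: float) -> "TrajectorySet":
        return cls.from_dataframe(pd.read_csv(path), frame_interval)

    def to_csv(self, path) -> Path:
        rows = []
        for pid in self.particle_ids:
            arr = self.trajectories[pid]
            for frame, (x, y) in enumerate(arr):
                rows.append((frame, pid, x, y))
        pd.DataFrame(rows, columns=["frame", "particle_id", "x_um", "y_um"]).to_csv(
            path, index=False
        )
        return Path(path)


@dataclass
class MSDCurve:
    """Lag-indexed mean squared displacement with per-lag pair counts."""

    lags: np.ndarray     # seconds, ascending, starting at 0
    msd: np.ndarray      # um^2
    n_pairs: np.ndarray  # displacement pairs averaged per lag


@dataclass
class FitResult:
    """Parameters and goodness-of-fit of an MSD model fit."""

    model: str                      # "exponential" or "powerlaw"
    params: dict[str, float]
    stderr: dict[str, float]
    r_squared: float
    adj_r_squared: float
    reduced_chi2: float
    converged: bool = True
    degenerate: bool = False

    @property
    def characteristic_time(self) -> float:
        """1/|R0| for the exponential model (seconds)."""
        r0 = self.params.get("R0")
        if r0 in (None, 0.0):
            return float("nan")
        return 1.0 / abs(r0)


@dataclass
class StepRatioSummary:
    """Summary of consecutive step-length ratios R_i = |dr_{i+1}| / |dr_i|."""

    mean: float
    median: float
    sd: float
    n_ratios: int
    n_dropped: int
    fraction_near_phi: float
    phi: float = PHI


def mean_displacement(traj: TrajectorySet) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame ensemble mean position (x_bar, y_bar) over present particles."""
    if traj.n_particles == 0:
        raise ValueError("empty trajectory set")
    max_len = max(arr.shape[0] for arr in traj.trajectories.values())
    sums = np.zeros((max_len, 2))
    counts = np.zeros(max_len)
    for arr in traj.trajectories.values():
        sums[: arr.shape[0]] += arr
        counts[: arr.shape[0]] += 1
    means = sums / counts[:, None]
    return means[:, 0], means[:, 1]


def msd(
    traj: TrajectorySet, max_lag: int | None = None, mode: str = "time-ensemble"
) -> MSDCurve:
    """Mean squared displacement versus lag.

    ``mode='time-ensemble'`` (default) averages |r(t+lag) - r(t)|^2 over all
    start times of all particles (overlapping windows); ``'ensemble'`` uses
    only t = 0; ``'time'`` averages within particles first, then over
    particles with equal weight.
    """
    if traj.n_particles == 0:
        raise ValueError("empty trajectory set")
    if mode not in ("time-ensemble", "ensemble", "time"):
        raise ValueError("mode must be 'time-ensemble', 'ensemble' or 'time'")
    longest = max(arr.shape[0] for arr in traj.trajectories.values())
    if max_lag is None:
        max_lag = longest - 1
    if max_lag >= longest:
        raise ValueError(f"max_lag {max_lag} >= record length {longest}")

    lags = np.arange(max_lag + 1)
    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1)
    per_particle = np.zeros((traj.n_particles, max_lag + 1))
    per_particle_mask = np.zeros((traj.n_particles, max_lag + 1), dtype=bool)
    for i, arr in enumerate(traj.trajectories.values()):
        n = arr.shape[0]
        for lag in range(1, min(max_lag, n - 1) + 1):
            d = arr[lag:] - arr[:-lag]
            sq = np.sum(d**2, axis=1)
            if mode == "ensemble":
                sums[lag] += sq[0]
                counts[lag] += 1
            else:
                sums[lag] += sq.sum()
                counts[lag] += sq.size
                per_particle[i, lag] = sq.mean()
                per_particle_mask[i, lag] = True
        counts[0] += 1
        per_particle_mask[i, 0] = True

    if mode == "time":
        with np.errstate(invalid="ignore"):
            vals = np.where(
                per_particle_mask.any(axis=0),
                per_particle.sum(axis=0) / np.maximum(per_particle_mask.sum(axis=0), 1),
                np.nan,
            )
        vals[0] = 0.0
        n_pairs = per_particle_mask.sum(axis=0)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        vals[0] = 0.0
        n_pairs = counts.astype(int)
    keep = ~np.isnan(vals)
    return MSDCurve(
        lags=lags[keep] * traj.frame_interval,
        msd=vals[keep],
        n_pairs=np.asarray(n_pairs)[keep],
    )


def _fit_quality(y: np.ndarray, yhat: np.ndarray, n_params: int) -> tuple[float, float, float]:
    resid = y - yhat
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    n = y.size
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1) if n > n_params + 1 else float("nan")
    red_chi2 = ss_res / (n - n_params) if n > n_params else float("nan")
    return r2, adj, red_chi2


def fit_exponential(curve: MSDCurve, weights: np.ndarray | None = None) -> FitResult:
    """Least-squares fit of MSD(tau) = y0 + A*exp(R0*tau).

    For confined diffusion A ~ -y0 and R0 < 0, so the curve rises from 0 to
    the plateau y0 with characteristic time 1/|R0|.  Initial values: y0 from
    the plateau, A from the first point, R0 from the lag at half-saturation;
    a small multi-start ladder handles hard cases.  A flat curve returns a
    degenerate flagged result instead of failing.
    """
    tau = np.asarray(curve.lags, dtype=float)
    y = np.asarray(curve.msd, dtype=float)
    if tau.size < 4:
        raise ValueError("need at least 4 lag points")

    if np.ptp(y) == 0.0:
        return FitResult(
            model="exponential",
            params={"y0": float(y[0]), "A": 0.0, "R0": 0.0},
            stderr={"y0": 0.0, "A": 0.0, "R0": 0.0},
            r_squared=0.0,
            adj_r_squared=0.0,
            reduced_chi2=0.0,
            converged=True,
            degenerate=True,
        )

    def model(t, y0, A, R0):
        return y0 + A * np.exp(R0 * t)

    y0_init = float(np.max(y))
    a_init = float(y[0] - y0_init)
    half = y0_init + a_init / 2.0
    above = np.nonzero(y >= half)[0]
    t_half = tau[above[0]] if above.size and tau[above[0]] > 0 else (tau[-1] / 4 or 1.0)
    r0_init = -math.log(2.0) / t_half

    sigma = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        sigma = np.where(w > 0, 1.0 / np.sqrt(w), np.inf)

    starts = [
        (y0_init, a_init, r0_init),
        (y0_init, a_init, r0_init * 5.0),
        (y0_init, a_init, r0_init / 5.0),
        (float(np.mean(y)), float(y[0] - np.mean(y)), -1.0 / max(tau[-1], 1e-9)),
    ]
    best = None
    for p0 in starts:
        try:
            popt, pcov = optimize.curve_fit(
                model, tau, y, p0=p0, sigma=sigma, maxfev=20000
            )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        yhat = model(tau, *popt)
        ss = float(np.sum((y - yhat) ** 2))
        if best is None or ss < best[0]:
            best = (ss, popt, pcov)
    if best is None:
        return FitResult(
            model="exponential",
            params={"y0": float("nan"), "A": float("nan"), "R0": float("nan")},
            stderr={},
            r_squared=float("nan"),
            adj_r_squared=float("nan"),
            reduced_chi2=float("nan"),
            converged=False,
        )
    _, popt, pcov = best
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.nan)
    r2, adj, red = _fit_quality(y, model(tau, *popt), 3)
    names = ("y0", "A", "R0")
    return FitResult(
        model="exponential",
        params=dict(zip(names, (float(v) for v in popt))),
        stderr=dict(zip(names, (float(v) for v in perr))),
        r_squared=r2,
        adj_r_squared=adj,
        reduced_chi2=red,
    )


def diffusion_coefficient(fit: FitResult, dimensions: int = 2) -> float:
    """Diffusion coefficient from the model's initial slope.

    For MSD = y0 + A*exp(R0*tau) the slope at tau = 0 is A*R0, so
    D = A*R0 / (2 * dimensions) (um^2/s).  For confined fits both A and R0
    are negative, giving a positive D.
    """
    if dimensions not in (1, 2, 3):
        raise ValueError("dimensions must be 1, 2 or 3")
    if fit.model != "exponential":
        raise ValueError("diffusion_coefficient expects an exponential fit")
    a, r0 = fit.params["A"], fit.params["R0"]
    return a * r0 / (2.0 * dimensions)


def fit_powerlaw(curve: MSDCurve) -> FitResult:
    """Power-law fit MSD = K * tau**alpha by linear regression in log-log.

    alpha near 1 flags normal diffusion, alpha < 1 subdiffusion (confined
    motion at long lags), alpha near 2 ballistic motion.
    """
    tau = np.asarray(curve.lags, dtype=float)
    y = np.asarray(curve.msd, dtype=float)
    mask = (tau > 0) & (y > 0)
    if mask.sum() < 2:
        raise ValueError("need at least 2 positive (lag, msd) points")
    lt, ly = np.log(tau[mask]), np.log(y[mask])
    res = stats.linregress(lt, ly)
    alpha = float(res.slope)
    prefactor = float(math.exp(res.intercept))
    yhat = res.intercept + res.slope * lt
    r2, adj, red = _fit_quality(ly, yhat, 2)
    return FitResult(
        model="powerlaw",
        params={"prefactor": prefactor, "alpha": alpha},
        stderr={"alpha": float(res.stderr), "log_prefactor": float(res.intercept_stderr)},
        r_squared=r2,
        adj_r_squared=adj,
        reduced_chi2=red,
    )


def step_ratios(
    traj: TrajectorySet,
    phi_tol: float = 0.05,
    keep_singular: bool = False,
) -> tuple[dict[int, np.ndarray], StepRatioSummary]:
    """Consecutive step-size ratios R_i = |dr_{i+1}| / |dr_i| per particle.

    Ratios whose denominator step has exactly zero length are dropped and
    counted (``keep_singular`` keeps near-zero but nonzero denominators
    either way; it additionally keeps infinite ratios as +inf when True).
    The summary reports mean, median, sd and the fraction of ratios within
    ``phi_tol`` of the golden ratio.
    """
    ratios_by_particle: dict[int, np.ndarray] = {}
    all_ratios = []
    n_dropped = 0
    for pid in traj.particle_ids:
        arr = traj.trajectories[pid]
        if arr.shape[0] < 3:
            continue
        steps = np.linalg.norm(np.diff(arr, axis=0), axis=1)
        denom = steps[:-1]
        numer = steps[1:]
        nz = denom > 0
        n_dropped += int(np.sum(~nz))
        if keep_singular:
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where(nz, numer / np.where(nz, denom, 1.0), np.inf)
            r = r[np.isfinite(r) | (numer > 0)]  # 0/0 dropped, x/0 kept as inf
        else:
            r = numer[nz] / denom[nz]
        ratios_by_particle[pid] = r
        all_ratios.append(r)
    if not all_ratios or all(r.size == 0 for r in all_ratios):
        raise ValueError("no usable steps (all step lengths zero or too few frames)")
    flat = np.concatenate(all_ratios)
    finite = flat[np.isfinite(flat)]
    summary = StepRatioSummary(
        mean=float(np.mean(finite)),
        median=float(np.median(finite)),
        sd=float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0,
        n_ratios=int(flat.size),
        n_dropped=n_dropped,
        fraction_near_phi=float(np.mean(np.abs(finite - PHI) <= phi_tol)),
    )
    return ratios_by_particle, summary
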
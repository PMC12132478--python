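"""Diffusion-coefficient spectra from single-molecule trajectories.

The mobility of reactivated molecules is summarized by an occupation vector
over a fixed log-spaced grid of candidate diffusion coefficients (a "state
array").  Jump magnitudes between consecutive frames follow, for a molecule
diffusing with coefficient D in 2-D and localized with error σ_loc, a
Rayleigh distribution with per-coordinate variance

    v = 2 D Δt + 2 σ_loc²

Mixture weights π over the grid are estimated by expectation–maximization on
per-trajectory likelihoods with jump-count weighting: the E-step computes
trajectory responsibilities ∝ π_j · Π_jumps f(r | D_j) and the M-step sets
π_j to the jump-count-weighted mean of the responsibilities, which is EM on
the jump-weighted log-likelihood (monotone non-decreasing by construction).
The "slow fraction" — occupation strictly below 0.1 μm²/s by default — is the
standard proxy for the chromatin-bound population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._validation import ValidationError, check_int_min, check_nonneg, check_pos
from .synthetic_data import IlluminationSchedule
from .quant import assign_window


@dataclass
class TrajectorySet:
    """Trajectories (``trajectory,frame,y,x`` in pixels) plus imaging scales."""

    data: pd.DataFrame
    frame_interval: float  # s
    pixel_size: float  # μm / px
    loc_error: float = 0.035  # μm
    channel: str = ""

    def __post_init__(self) -> None:
        check_pos("frame_interval", self.frame_interval)
        check_pos("pixel_size", self.pixel_size)
        check_nonneg("loc_error", self.loc_error)
        missing = {"trajectory", "frame", "y", "x"} - set(self.data.columns)
        if missing:
            raise ValidationError(f"trajectory table missing columns: {sorted(missing)}")
        frames = self.data.sort_values(["trajectory", "frame"])
        diffs = frames.groupby("trajectory")["frame"].diff().dropna()
        if (diffs <= 0).any():
            raise ValidationError("frames within a trajectory must strictly increase")

    def jumps(self) -> tuple[np.ndarray, np.ndarray]:
        """(r, traj_index): jump magnitudes in μm between consecutive frames.

        Only unit-frame steps enter (gaps are not bridged).  ``traj_index``
        maps each jump to a 0-based trajectory index for grouping.
        """
        df = self.data.sort_values(["trajectory", "frame"], kind="stable")
        traj = df["trajectory"].to_numpy()
        frame = df["frame"].to_numpy()
        y = df["y"].to_numpy(dtype=float)
        x = df["x"].to_numpy(dtype=float)
        same = traj[1:] == traj[:-1]
        unit = frame[1:] - frame[:-1] == 1
        keep = same & unit
        dy = (y[1:] - y[:-1])[keep]
        dx = (x[1:] - x[:-1])[keep]
        r = np.hypot(dy, dx) * self.pixel_size
        traj_of_jump = traj[1:][keep]
        _, idx = np.unique(traj_of_jump, return_inverse=True)
        return r, idx


def default_grid(n_points: int = 101, d_min: float = 0.01, d_max: float = 100.0):
    """Log-spaced diffusion-coefficient grid (μm²/s), state-array convention."""
    check_int_min("n_points", n_points, 2)
    check_pos("d_min", d_min)
    if d_max <= d_min:
        raise ValidationError("d_max must exceed d_min")
    return np.logspace(np.log10(d_min), np.log10(d_max), n_points)


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValidationError("diffusion grid must be 1-D with >= 2 points")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValidationError("diffusion grid must be positive and strictly increasing")
    return grid


def jump_density(r, D: float, dt: float, loc_error: float):
    """Rayleigh density of 2-D jump magnitudes at diffusion coefficient D.

    ``f(r) = (r / v) exp(-r² / (2 v))`` with per-coordinate variance
    ``v = 2 D dt + 2 loc_error²``.
    """
    check_nonneg("D", D)
    check_pos("dt", dt)
    check_nonneg("loc_error", loc_error)
    v = 2.0 * D * dt + 2.0 * loc_error**2
    if v == 0:
        raise ValidationError("jump variance is zero (D = 0 and loc_error = 0)")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValidationError("jump magnitudes must be >= 0")
    return (r / v) * np.exp(-(r**2) / (2.0 * v))


@dataclass
class DiffusionSpectrum:
    """Occupations over a diffusion grid with the derived slow fraction."""

    grid: np.ndarray
    occupations: np.ndarray
    n_jumps: int
    channel: str = ""
    slow_threshold: float = 0.1  # μm²/s
    converged: bool = True
    n_iter: int = 0
    log_likelihood: float = float("nan")
    log_likelihood_path: np.ndarray = field(default=None, repr=False)

    @property
    def slow_fraction(self) -> float:
        return slow_fraction(self, self.slow_threshold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"D": self.grid, "occupation": self.occupations})


def slow_fraction(spectrum: DiffusionSpectrum, threshold: float = 0.1) -> float:
    """Total occupation at grid points strictly below ``threshold`` μm²/s."""
    check_pos("threshold", threshold)
    return float(spectrum.occupations[spectrum.grid < threshold].sum())


def fit_spectrum(
    trajs: TrajectorySet,
    grid: np.ndarray | None = None,
    max_iter: int = 1000,
    tol: float = 1e-8,
    slow_threshold: float = 0.1,
) -> DiffusionSpectrum:
    """Estimate grid occupations by jump-count-weighted EM.

    Initialization is uniform (``max_iter=0`` returns it unchanged).  The
    weighted log-likelihood is tracked each iteration; convergence is a
    relative change below ``tol``.  A non-converged fit is returned with
    ``converged=False``.
    """
    grid = _check_grid(default_grid() if grid is None else grid)
    check_int_min("max_iter", max_iter, 0)
    r, traj_idx = trajs.jumps()
    if r.size == 0:
        raise ValidationError("trajectory set contains no unit-frame jumps")

    v = 2.0 * grid * trajs.frame_interval + 2.0 * trajs.loc_error**2  # (m,)
    # per-jump log density against every grid point, (n_jumps, m)
    r2 = r[:, None] ** 2
    with np.errstate(divide="ignore"):
        log_f = np.log(np.where(r[:, None] > 0, r[:, None], np.nan) / v[None, :]) - (
            r2 / (2.0 * v[None, :])
        )
    # zero-length jumps have zero Rayleigh density everywhere; they carry no
    # information about D, so give them a flat (constant) log-density
    zero = r == 0
    if zero.any():
        log_f[zero] = 0.0

    n_traj = int(traj_idx.max()) + 1
    # per-trajectory log-likelihood under each grid point
    L = np.zeros((n_traj, grid.size))
    np.add.at(L, traj_idx, log_f)
    weights = np.bincount(traj_idx, minlength=n_traj).astype(float)  # jump counts
    w_sum = weights.sum()

    pi = np.full(grid.size, 1.0 / grid.size)
    ll_path: list[float] = []
    converged = max_iter == 0
    it = 0
    prev_ll = -np.inf
    with np.errstate(divide="ignore"):
        for it in range(1, max_iter + 1):
            # fused E-step + log-likelihood of the incoming pi:
            # one exp pass and two matvecs per iteration
            a = L + np.log(pi)[None, :]
            m = a.max(axis=1)
            g = np.exp(a - m[:, None])
            s = g.sum(axis=1)
            cur_ll = float(weights @ (m + np.log(s)))
            ll_path.append(cur_ll)
            pi = (g.T @ (weights / s)) / w_sum
            pi = np.clip(pi, 0.0, None)
            pi /= pi.sum()
            if abs(cur_ll - prev_ll) <= tol * (abs(cur_ll) + 1e-300):
                converged = True
                break
            prev_ll = cur_ll
    ll = _weighted_ll(pi, L, weights)
    ll_path.append(ll)

    return DiffusionSpectrum(
        grid=grid,
        occupations=pi,
        n_jumps=int(r.size),
        channel=trajs.channel,
        slow_threshold=slow_threshold,
        converged=converged,
        n_iter=it,
        log_likelihood=ll,
        log_likelihood_path=np.asarray(ll_path),
    )


def _weighted_ll(pi: np.ndarray, L: np.ndarray, weights: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        log_pi = np.where(pi > 0, np.log(pi), -np.inf)
    return float((weights * logsumexp(log_pi[None, :] + L, axis=1)).sum())


def split_by_reactivation(
    trajs: TrajectorySet, schedule: IlluminationSchedule
) -> tuple[TrajectorySet, TrajectorySet, int]:
    """Split trajectories into PAPA- and DR-reactivated channels.

    A trajectory belongs to the channel of the window containing its first
    frame; trajectories starting in baseline windows belong to neither and
    are only counted (third return value).
    """
    first = (
        trajs.data.sort_values(["trajectory", "frame"])
        .groupby("trajectory")["frame"]
        .first()
    )
    channel_of = {}
    n_dropped = 0
    for traj, frame in first.items():
        _, window = assign_window(int(frame), schedule)
        if window == "papa":
            channel_of[traj] = "papa"
        elif window == "dr":
            channel_of[traj] = "dr"
        else:
            n_dropped += 1
    mapped = trajs.data["trajectory"].map(channel_of)
    papa = trajs.data[mapped == "papa"].reset_index(drop=True)
    dr = trajs.data[mapped == "dr"].reset_index(drop=True)
    mk = lambda df, ch: TrajectorySet(
        data=df,
        frame_interval=trajs.frame_interval,
        pixel_size=trajs.pixel_size,
        loc_error=trajs.loc_error,
        channel=ch,
    )
    return mk(papa, "papa"), mk(dr, "dr"), n_dropped
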
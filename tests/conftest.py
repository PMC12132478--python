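import numpy as np
import pandas as pd
import pytest

from papaquant import (
    FieldLayout,
    IlluminationSchedule,
    MotionParams,
    PhotophysicsParams,
)
from papaquant.synthetic_data import Ellipse


@pytest.fixture(scope="session")
def schedule():
    return IlluminationSchedule()


@pytest.fixture(scope="session")
def small_schedule():
    """Short cycles for cheap unit tests: 10-frame windows, one cycle."""
    return IlluminationSchedule(frames_per_window=10, n_cycles=1)


@pytest.fixture(scope="session")
def photo():
    return PhotophysicsParams()


@pytest.fixture(scope="session")
def motion():
    return MotionParams()


@pytest.fixture(scope="session")
def small_layout():
    """One nucleus on a small field."""
    return FieldLayout(
        image_shape=(128, 128), nuclei=(Ellipse(64.0, 64.0, 40.0, 34.0),)
    )


def multi_jump_trajectories(
    rng: np.random.Generator,
    d_coef: float,
    n_traj: int,
    jumps_per_traj: int,
    dt: float = 0.01,
    pixel_size: float = 0.108,
    loc_error: float = 0.035,
) -> pd.DataFrame:
    """Brownian trajectories of fixed length at one diffusion coefficient."""
    sd_px = np.sqrt(2.0 * d_coef * dt + 2.0 * loc_error**2) / pixel_size
    steps = rng.normal(0, sd_px, (n_traj, jumps_per_traj, 2))
    start = rng.normal(0, 1, (n_traj, 1, 2))
    pos = np.concatenate([start, start + np.cumsum(steps, axis=1)], axis=1)
    n_pts = jumps_per_traj + 1
    return pd.DataFrame(
        {
            "trajectory": np.repeat(np.arange(n_traj), n_pts),
            "frame": np.tile(np.arange(n_pts), n_traj),
            "y": pos[:, :, 0].ravel(),
            "x": pos[:, :, 1].ravel(),
        }
    )


def single_jump_trajectories(
    rng: np.random.Generator,
    d_coef: float,
    n_jumps: int,
    dt: float = 0.01,
    pixel_size: float = 0.108,
    loc_error: float = 0.035,
    id_offset: int = 0,
) -> pd.DataFrame:
    """Two-point trajectories with Rayleigh jumps at diffusion coefficient D."""
    sd_px = np.sqrt(2.0 * d_coef * dt + 2.0 * loc_error**2) / pixel_size
    y0 = rng.normal(0, 1, n_jumps)
    x0 = rng.normal(0, 1, n_jumps)
    tid = np.arange(id_offset, id_offset + n_jumps)
    return pd.DataFrame(
        {
            "trajectory": np.concatenate([tid, tid]),
            "frame": np.concatenate(
                [np.zeros(n_jumps, int), np.ones(n_jumps, int)]
            ),
            "y": np.concatenate([y0, y0 + rng.normal(0, sd_px, n_jumps)]),
            "x": np.concatenate([x0, x0 + rng.normal(0, sd_px, n_jumps)]),
        }
    )
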
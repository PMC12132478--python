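"""Synthetic PAPA-SMT experiments and FRAP movies with known ground truth.

The generator emulates the raw outputs of a proximity-assisted photoactivation
single-molecule tracking (PAPA-SMT) experiment: per-frame localization tables,
trajectory tables, per-channel intensity stills, an integer-labeled nuclear
mask, plus a ground-truth record of the generative parameters.  It also renders
fluorescence-recovery-after-photobleaching (FRAP) movies with a controllable
bleach depth, mobile fraction, recovery time constant and lateral stage drift.

Illumination model
------------------
Each imaging cycle consists of four windows of ``frames_per_window`` frames:

    baseline_violet | dr (violet pulse) | baseline_green | papa (green pulse)

Receiver fluorophores are shelved into a dark state by continuous red light
(per-frame probability ``shelve_prob``) and return to the fluorescent state

* spontaneously, with a per-frame probability that decays exponentially within
  each half-cycle, ``spont_amp * exp(-spont_rate * t)`` with ``t`` counted from
  the start of the preceding baseline window (the amplitude resets after each
  re-shelving, which is what makes the baseline windows fittable);
* during violet pulse windows, with per-frame probability ``p_reactivate_dr``
  (direct reactivation, proximity independent);
* during green pulse windows, with per-frame probability
  ``p_reactivate_papa_near`` for receivers near a sender and
  ``p_reactivate_papa_far`` for distant ones (the PAPA channel).

Fluorescent molecules are detected with probability ``detect_prob`` per frame,
localized with Gaussian error ``loc_error`` (μm), and diffuse in 2-D with a
bound/free state drawn once per reactivation event.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from ._validation import (
    ValidationError,
    check_int_min,
    check_nonneg,
    check_pos,
    check_prob,
)

WINDOW_NAMES = ("baseline_violet", "dr", "baseline_green", "papa")

DETECTION_COLUMNS = ["frame", "y", "x", "trajectory", "channel"]


@dataclass(frozen=True)
class IlluminationSchedule:
    """Timing of the alternating violet/green reactivation cycles.

    Four 50-frame windows per cycle at 10 ms per frame, repeated for three
    cycles, by default.
    """

    frames_per_window: int = 50
    n_cycles: int = 3
    frame_interval: float = 0.010  # seconds

    windows_per_cycle = 4  # fixed: baseline_violet, dr, baseline_green, papa

    def __post_init__(self) -> None:
        check_int_min("frames_per_window", self.frames_per_window, 2)
        check_int_min("n_cycles", self.n_cycles, 1)
        check_pos("frame_interval", self.frame_interval)

    @property
    def frames_per_cycle(self) -> int:
        return self.frames_per_window * self.windows_per_cycle

    @property
    def total_frames(self) -> int:
        return self.frames_per_cycle * self.n_cycles


@dataclass(frozen=True)
class PhotophysicsParams:
    """Receiver-dye photoswitching and detection parameters (per frame)."""

    n_receivers: int = 150
    shelve_prob: float = 0.20
    spont_amp: float = 0.010
    spont_rate: float = 0.04
    p_reactivate_dr: float = 0.010
    p_reactivate_papa_near: float = 0.015
    p_reactivate_papa_far: float = 0.005
    detect_prob: float = 0.7

    def __post_init__(self) -> None:
        check_int_min("n_receivers", self.n_receivers, 0)
        for name in (
            "shelve_prob",
            "spont_amp",
            "p_reactivate_dr",
            "p_reactivate_papa_near",
            "p_reactivate_papa_far",
            "detect_prob",
        ):
            check_prob(name, getattr(self, name))
        check_nonneg("spont_rate", self.spont_rate)
        if self.p_reactivate_papa_near < self.p_reactivate_papa_far:
            raise ValidationError(
                "p_reactivate_papa_near must be >= p_reactivate_papa_far"
            )


@dataclass(frozen=True)
class MotionParams:
    """Two-state (bound/free) 2-D diffusion with localization error."""

    bound_fraction: float = 0.3
    d_bound: float = 0.02  # μm²/s
    d_free: float = 3.0  # μm²/s
    loc_error: float = 0.035  # μm (1-D localization s.d.)
    pixel_size: float = 0.108  # μm per pixel

    def __post_init__(self) -> None:
        check_prob("bound_fraction", self.bound_fraction)
        check_nonneg("d_bound", self.d_bound)
        check_pos("d_free", self.d_free)
        if not self.d_bound < self.d_free:
            raise ValidationError("d_bound must be < d_free")
        check_nonneg("loc_error", self.loc_error)
        check_pos("pixel_size", self.pixel_size)


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned elliptical nucleus: center (row, col) and semi-axes, px."""

    center_y: float
    center_x: float
    semi_y: float
    semi_x: float

    def contains(self, y, x):
        return (
            ((np.asarray(y) - self.center_y) / self.semi_y) ** 2
            + ((np.asarray(x) - self.center_x) / self.semi_x) ** 2
        ) <= 1.0


@dataclass(frozen=True)
class FieldLayout:
    """Geometry and intensity model of one simulated field of view."""

    image_shape: tuple[int, int] = (512, 512)
    nuclei: tuple[Ellipse, ...] = ()
    nuclear_intensity: float = 800.0
    ring_leak_intensity: float = 100.0
    background_intensity: float = 100.0
    noise_sd: float = 20.0
    allow_edge_contact: bool = False

    def __post_init__(self) -> None:
        check_nonneg("nuclear_intensity", self.nuclear_intensity)
        check_nonneg("ring_leak_intensity", self.ring_leak_intensity)
        check_nonneg("background_intensity", self.background_intensity)
        check_nonneg("noise_sd", self.noise_sd)
        nrows, ncols = self.image_shape
        if not self.allow_edge_contact:
            for i, e in enumerate(self.nuclei):
                if (
                    e.center_y - e.semi_y < 0
                    or e.center_y + e.semi_y > nrows - 1
                    or e.center_x - e.semi_x < 0
                    or e.center_x + e.semi_x > ncols - 1
                ):
                    raise ValidationError(
                        f"nuclei[{i}] extends beyond the image bounds; "
                        "set allow_edge_contact=True for edge-contact fixtures"
                    )

    def labeled_mask(self) -> np.ndarray:
        """Rasterize the nucleus ellipses into a 16-bit labeled mask."""
        mask = np.zeros(self.image_shape, dtype=np.uint16)
        yy, xx = np.indices(self.image_shape)
        for label, e in enumerate(self.nuclei, start=1):
            mask[e.contains(yy, xx)] = label
        return mask


def grid_layout(
    n_nuclei: int = 20,
    image_shape: tuple[int, int] = (512, 512),
    semi_axes: tuple[float, float] = (45.0, 38.0),
    **kwargs,
) -> FieldLayout:
    """Lay out ``n_nuclei`` identical elliptical nuclei on a regular grid."""
    check_int_min("n_nuclei", n_nuclei, 1)
    nrows, ncols = image_shape
    per_side = math.ceil(math.sqrt(n_nuclei))
    dy, dx = nrows / per_side, ncols / per_side
    nuclei = []
    for i in range(n_nuclei):
        r, c = divmod(i, per_side)
        nuclei.append(
            Ellipse((r + 0.5) * dy, (c + 0.5) * dx, semi_axes[0], semi_axes[1])
        )
    return FieldLayout(image_shape=image_shape, nuclei=tuple(nuclei), **kwargs)


@dataclass
class GroundTruth:
    """Generative parameters recorded next to every simulated dataset."""

    rng_seed: int
    true_gv_enrichment: float | None = None
    true_slow_fraction: float | None = None
    true_frap_mobile_fraction: float | None = None
    true_frap_tau: float | None = None
    true_frap_depth: float | None = None
    interacting: bool | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


# ---------------------------------------------------------------------------
# Frame-by-frame reactivation probabilities
# ---------------------------------------------------------------------------


def _window_of(frame: int, schedule: IlluminationSchedule) -> tuple[int, int, int]:
    """(cycle, window index 0-3, offset within window) for a 0-based frame."""
    fpc = schedule.frames_per_cycle
    fpw = schedule.frames_per_window
    return frame // fpc, (frame % fpc) // fpw, frame % fpw


def _spont_prob(photo: PhotophysicsParams, widx: int, t_within: int, fpw: int) -> float:
    # clock runs from the start of the preceding baseline window and is reset
    # by each re-shelving period (i.e. at every baseline window start)
    t = t_within if widx in (0, 2) else fpw + t_within
    return photo.spont_amp * math.exp(-photo.spont_rate * t)


# ---------------------------------------------------------------------------
# Expected-count recursion (deterministic; the analytic oracle and the source
# of the recorded ground-truth enrichment)
# ---------------------------------------------------------------------------


def expected_frame_counts(
    schedule: IlluminationSchedule,
    photo: PhotophysicsParams,
    papa_mode: str = "far",
    pulses_on: bool = True,
) -> np.ndarray:
    """Expected per-receiver detections per frame from the state recursion.

    Propagates the probability of being fluorescent through the same Markov
    chain the stochastic simulator uses.  With ``pulses_on=False`` only
    spontaneous reactivation acts, which is the exact no-pulse counterfactual
    used to define corrected counts analytically.
    """
    if papa_mode not in ("near", "far"):
        raise ValidationError(f"papa_mode must be 'near' or 'far', got {papa_mode!r}")
    p_papa = (
        photo.p_reactivate_papa_near
        if papa_mode == "near"
        else photo.p_reactivate_papa_far
    )
    fpw = schedule.frames_per_window
    out = np.zeros(schedule.total_frames)
    p_f = 0.0
    for t in range(schedule.total_frames):
        _, widx, tw = _window_of(t, schedule)
        p_pulse = 0.0
        if pulses_on and widx == 1:
            p_pulse = photo.p_reactivate_dr
        elif pulses_on and widx == 3:
            p_pulse = p_papa
        p_spont = _spont_prob(photo, widx, tw, fpw)
        p_react = 1.0 - (1.0 - p_spont) * (1.0 - p_pulse)
        p_f = p_f * (1.0 - photo.shelve_prob) + (1.0 - p_f) * p_react
        out[t] = p_f * photo.detect_prob
    return out


def expected_gv_ratio(
    schedule: IlluminationSchedule, photo: PhotophysicsParams, papa_mode: str
) -> float:
    """Analytic GV ratio: pulse-induced detections above the no-pulse
    counterfactual, summed over pulse windows, green over violet."""
    with_pulse = expected_frame_counts(schedule, photo, papa_mode, pulses_on=True)
    without = expected_frame_counts(schedule, photo, papa_mode, pulses_on=False)
    fpw = schedule.frames_per_window
    dr = papa = 0.0
    for t in range(schedule.total_frames):
        _, widx, _ = _window_of(t, schedule)
        if widx == 1:
            dr += with_pulse[t] - without[t]
        elif widx == 3:
            papa += with_pulse[t] - without[t]
    if dr <= 0:
        raise ValidationError("expected DR yield is zero; increase p_reactivate_dr")
    return papa / dr


def expected_gv_enrichment(
    schedule: IlluminationSchedule, photo: PhotophysicsParams
) -> float:
    """Ratio of the near-sender GV ratio to the far (non-interacting) one."""
    return expected_gv_ratio(schedule, photo, "near") / expected_gv_ratio(
        schedule, photo, "far"
    )


def calibrate_papa_near(
    schedule: IlluminationSchedule, photo: PhotophysicsParams, target_enrichment: float
) -> PhotophysicsParams:
    """Return params whose analytic GV enrichment equals ``target_enrichment``.

    Solves for ``p_reactivate_papa_near`` by bisection on the expected-count
    recursion, holding every other parameter fixed.
    """
    from scipy.optimize import brentq

    check_pos("target_enrichment", target_enrichment)

    def f(p_near: float) -> float:
        trial = dataclasses.replace(photo, p_reactivate_papa_near=max(
            p_near, photo.p_reactivate_papa_far))
        return expected_gv_enrichment(schedule, trial) - target_enrichment

    lo = photo.p_reactivate_papa_far
    hi = min(1.0, max(0.5, 50 * photo.p_reactivate_papa_far))
    if f(hi) < 0:
        raise ValidationError(
            f"target_enrichment {target_enrichment} is unreachable; saturation"
        )
    p_near = brentq(f, lo, hi, xtol=1e-10)
    return dataclasses.replace(photo, p_reactivate_papa_near=float(p_near))


# ---------------------------------------------------------------------------
# Stochastic PAPA-SMT simulation
# ---------------------------------------------------------------------------


def _sample_in_ellipse(rng: np.random.Generator, e: Ellipse, n: int) -> np.ndarray:
    r = np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    y = e.center_y + e.semi_y * r * np.sin(theta)
    x = e.center_x + e.semi_x * r * np.cos(theta)
    return np.column_stack([y, x])


def _render_field(
    layout: FieldLayout, rng: np.random.Generator, with_ring_leak: bool
) -> np.ndarray:
    """One still: background + nuclei (+ optional perinuclear leak ring)."""
    img = np.full(layout.image_shape, layout.background_intensity, dtype=float)
    yy, xx = np.indices(layout.image_shape)
    for e in layout.nuclei:
        inside = e.contains(yy, xx)
        if with_ring_leak and layout.ring_leak_intensity > 0:
            ring_e = Ellipse(e.center_y, e.center_x, e.semi_y + 6, e.semi_x + 6)
            ring = ring_e.contains(yy, xx) & ~inside
            img[ring] += layout.ring_leak_intensity
        img[inside] += layout.nuclear_intensity
    if layout.noise_sd > 0:
        img += rng.normal(0.0, layout.noise_sd, layout.image_shape)
    return np.clip(img, 0, 65535).astype(np.uint16)


def simulate_papa_experiment(
    schedule: IlluminationSchedule,
    photo: PhotophysicsParams,
    motion: MotionParams,
    layout: FieldLayout,
    interacting: bool = True,
    seed: int = 0,
    render_images: bool = True,
):
    """Simulate one PAPA-SMT field of view.

    Returns ``(detections, trajectories, images, mask, ground_truth)`` where
    ``detections`` and ``trajectories`` are DataFrames with columns
    ``frame,y,x,trajectory,channel`` (the trajectory table is the detection
    table ordered by trajectory), ``images`` maps channel name ("560", "642")
    to uint16 stills, ``mask`` is the 16-bit labeled nuclear mask and
    ``ground_truth`` records the generative parameters including the analytic
    GV enrichment.

    ``interacting=True`` places every receiver within PAPA range of a sender
    (reactivation probability ``p_reactivate_papa_near`` during green pulses);
    ``interacting=False`` uses ``p_reactivate_papa_far`` throughout,
    emulating the non-interacting nuclear-tag control.
    """
    if not layout.nuclei:
        raise ValidationError("layout must contain at least one nucleus")
    rng = np.random.default_rng(seed)

    n_nuc = len(layout.nuclei)
    n = n_nuc * photo.n_receivers
    pos = (
        np.vstack(
            [_sample_in_ellipse(rng, e, photo.n_receivers) for e in layout.nuclei]
        )
        if n
        else np.zeros((0, 2))
    )

    fpw = schedule.frames_per_window
    dt = schedule.frame_interval
    px = motion.pixel_size
    loc_sd_px = motion.loc_error / px
    step_bound = math.sqrt(2.0 * motion.d_bound * dt) / px
    step_free = math.sqrt(2.0 * motion.d_free * dt) / px
    p_papa = (
        photo.p_reactivate_papa_near if interacting else photo.p_reactivate_papa_far
    )

    bound = rng.random(n) < motion.bound_fraction
    fluor = np.zeros(n, dtype=bool)
    traj_id = np.full(n, -1, dtype=np.int64)
    next_id = 0

    rec_frames: list[np.ndarray] = []
    rec_pos: list[np.ndarray] = []
    rec_traj: list[np.ndarray] = []

    for t in range(schedule.total_frames):
        _, widx, tw = _window_of(t, schedule)
        p_pulse = 0.0
        if widx == 1:
            p_pulse = photo.p_reactivate_dr
        elif widx == 3:
            p_pulse = p_papa
        p_react = 1.0 - (1.0 - _spont_prob(photo, widx, tw, fpw)) * (1.0 - p_pulse)

        dark = ~fluor
        react = dark & (rng.random(n) < p_react)
        k = int(react.sum())
        if k:
            traj_id[react] = np.arange(next_id, next_id + k)
            next_id += k
            bound[react] = rng.random(k) < motion.bound_fraction
        shelved = fluor & (rng.random(n) < photo.shelve_prob)
        fluor = (fluor & ~shelved) | react

        detected = fluor & (rng.random(n) < photo.detect_prob)
        m = int(detected.sum())
        if m:
            noisy = pos[detected] + rng.normal(0.0, loc_sd_px, (m, 2))
            rec_frames.append(np.full(m, t, dtype=np.int64))
            rec_pos.append(noisy)
            rec_traj.append(traj_id[detected].copy())

        step = np.where(bound, step_bound, step_free)
        pos = pos + rng.normal(0.0, 1.0, (n, 2)) * step[:, None]

    if rec_frames:
        detections = pd.DataFrame(
            {
                "frame": np.concatenate(rec_frames),
                "y": np.concatenate(rec_pos)[:, 0],
                "x": np.concatenate(rec_pos)[:, 1],
                "trajectory": np.concatenate(rec_traj),
                "channel": "receiver",
            }
        )
    else:
        detections = pd.DataFrame(
            {
                "frame": np.array([], dtype=np.int64),
                "y": np.array([], dtype=float),
                "x": np.array([], dtype=float),
                "trajectory": np.array([], dtype=np.int64),
                "channel": np.array([], dtype=object),
            }
        )
    detections = detections.sort_values(["frame", "trajectory"], kind="stable")
    detections = detections.reset_index(drop=True)
    trajectories = detections.sort_values(
        ["trajectory", "frame"], kind="stable"
    ).reset_index(drop=True)

    images = {}
    if render_images:
        images["560"] = _render_field(layout, rng, with_ring_leak=False)
        images["642"] = _render_field(layout, rng, with_ring_leak=True)
    mask = layout.labeled_mask()

    try:
        enrichment = expected_gv_enrichment(schedule, photo)
    except ValidationError:
        # degenerate photophysics (no DR yield): enrichment undefined
        enrichment = None
    gt = GroundTruth(
        rng_seed=seed,
        true_gv_enrichment=enrichment,
        true_slow_fraction=motion.bound_fraction,
        interacting=interacting,
    )
    return detections, trajectories, images, mask, gt


# ---------------------------------------------------------------------------
# FRAP movie synthesis
# ---------------------------------------------------------------------------


def frap_recovery_factor(
    frame_1based: int,
    bleach_frame: int,
    depth: float,
    mobile_fraction: float,
    tau: float,
    frame_interval: float,
) -> float:
    """Relative spot intensity at a (1-based) frame of the rendering model.

    Pre-bleach frames sit at 1; from the bleach frame onward the spot follows
    ``(1 - depth) + depth * mobile_fraction * (1 - exp(-t / tau))`` with ``t``
    the time since the bleach.  The long-time plateau is therefore
    ``1 - depth * (1 - mobile_fraction)``.
    """
    if frame_1based < bleach_frame:
        return 1.0
    t = (frame_1based - bleach_frame) * frame_interval
    return (1.0 - depth) + depth * mobile_fraction * (1.0 - math.exp(-t / tau))


def simulate_frap_movie(
    n_frames: int = 600,
    bleach_frame: int = 16,
    spot_center: tuple[float, float] = (128.0, 128.0),
    spot_radius: float = 12.0,
    mobile_fraction: float = 0.6,
    tau: float = 5.0,
    depth: float = 0.7,
    layout: FieldLayout | None = None,
    drift: tuple[float, float] = (0.0, 0.0),
    frame_interval: float = 0.15,
    seed: int = 0,
):
    """Render a FRAP movie: ``(movie, sidecar, ground_truth)``.

    The bleach spot darkens at ``bleach_frame`` (1-based; the preceding frames
    are the pre-bleach baseline) and recovers along a single-exponential with
    plateau ``1 - depth*(1 - mobile_fraction)``.  The whole field is
    translated by ``drift`` (dy, dx) pixels per frame, cumulatively, and the
    sidecar records the spot position in the first frame, so downstream
    analysis must drift-correct.
    """
    check_int_min("n_frames", n_frames, 2)
    check_int_min("bleach_frame", bleach_frame, 2)
    check_prob("mobile_fraction", mobile_fraction)
    check_prob("depth", depth)
    check_pos("tau", tau)
    check_pos("frame_interval", frame_interval)
    if layout is None:
        layout = FieldLayout(
            image_shape=(256, 256),
            nuclei=(Ellipse(128.0, 128.0, 80.0, 70.0),),
            noise_sd=2.0,
        )
    if not any(
        e.contains(spot_center[0], spot_center[1]) for e in layout.nuclei
    ):
        raise ValidationError("spot_center lies outside every nucleus")

    nrows, ncols = layout.image_shape
    max_off = (n_frames - 1) * np.abs(np.asarray(drift, dtype=float))
    for e in layout.nuclei:
        if (
            e.center_y - e.semi_y - max_off[0] < 0
            or e.center_y + e.semi_y + max_off[0] > nrows - 1
            or e.center_x - e.semi_x - max_off[1] < 0
            or e.center_x + e.semi_x + max_off[1] > ncols - 1
        ):
            raise ValidationError("drift pushes a nucleus out of the image field")

    rng = np.random.default_rng(seed)
    yy, xx = np.indices(layout.image_shape)
    movie = np.zeros((n_frames, nrows, ncols), dtype=np.uint16)
    for i in range(n_frames):
        off = (i * drift[0], i * drift[1])
        img = np.full(layout.image_shape, layout.background_intensity, dtype=float)
        for e in layout.nuclei:
            inside = Ellipse(
                e.center_y + off[0], e.center_x + off[1], e.semi_y, e.semi_x
            ).contains(yy, xx)
            img[inside] += layout.nuclear_intensity
        s = frap_recovery_factor(
            i + 1, bleach_frame, depth, mobile_fraction, tau, frame_interval
        )
        spot = (yy - (spot_center[0] + off[0])) ** 2 + (
            xx - (spot_center[1] + off[1])
        ) ** 2 <= spot_radius**2
        img[spot] = layout.background_intensity + layout.nuclear_intensity * s
        if layout.noise_sd > 0:
            img += rng.normal(0.0, layout.noise_sd, layout.image_shape)
        movie[i] = np.clip(img, 0, 65535).astype(np.uint16)

    sidecar = {
        "bleach_frame": int(bleach_frame),
        "spot_center_yx": [float(spot_center[0]), float(spot_center[1])],
        "spot_radius_px": float(spot_radius),
        "frame_interval_s": float(frame_interval),
    }
    gt = GroundTruth(
        rng_seed=seed,
        true_frap_mobile_fraction=mobile_fraction,
        true_frap_tau=tau,
        true_frap_depth=depth,
    )
    return movie, sidecar, gt


# ---------------------------------------------------------------------------
# Run-directory writers
# ---------------------------------------------------------------------------


def write_papa_run(
    out_dir: str | Path,
    detections: pd.DataFrame,
    trajectories: pd.DataFrame,
    images: dict[str, np.ndarray],
    mask: np.ndarray,
    ground_truth: GroundTruth,
) -> dict[str, Path]:
    """Write a simulated PAPA experiment under ``out_dir``; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "detections": out / "detections.csv",
        "trajectories": out / "trajectories.csv",
        "mask": out / "mask.tif",
        "ground_truth": out / "ground_truth.json",
    }
    detections.to_csv(paths["detections"], index=False)
    trajectories.to_csv(paths["trajectories"], index=False)
    tifffile.imwrite(paths["mask"], mask.astype(np.uint16))
    for channel, img in images.items():
        p = out / f"intensity_{channel}.tif"
        tifffile.imwrite(p, img)
        paths[f"intensity_{channel}"] = p
    ground_truth.to_json(paths["ground_truth"])
    return paths


def write_frap_movie(
    out_dir: str | Path,
    movie: np.ndarray,
    sidecar: dict,
    ground_truth: GroundTruth,
    stem: str = "frap",
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "movie": out / f"{stem}.tif",
        "sidecar": out / f"{stem}.json",
        "ground_truth": out / f"{stem}_ground_truth.json",
    }
    tifffile.imwrite(paths["movie"], movie)
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2))
    ground_truth.to_json(paths["ground_truth"])
    return paths
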
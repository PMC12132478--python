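"""Proximity-index quantification from per-nucleus detection counts.

Each imaging cycle is split into four windows (baseline_violet, dr,
baseline_green, papa).  Spontaneous reactivation of dark-state dyes decays
exponentially within each baseline window; the per-condition pooled baseline
count series of each cycle is fit to ``c(t) = A exp(-k t)`` and extrapolated
into the adjacent pulse window.  The projected background is subtracted from
the observed pulse-window detections and negative results are truncated to
zero.  Corrected green (PAPA) totals over corrected violet (DR) totals give
the green-to-violet (GV) ratio; normalizing a condition's GV ratio by that of
a non-interacting control yields the proximity index (1 = no enrichment).
Uncertainty comes from bootstrap resampling of individual cells (default 100
replicates, 2.5th/97.5th percentiles).

A separate per-cell estimator backs the DR-vs-PAPA scatter: there, background
is the raw count in the 50 frames preceding each pulse (no exponential fit),
cells with fewer than 100 detections or negative corrected values are
excluded, and a straight line without intercept (slope = Σxy / Σx²) is fit
with a 500-replicate cell bootstrap for its confidence band.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._validation import ValidationError, check_int_min
from .synthetic_data import WINDOW_NAMES, IlluminationSchedule

logger = logging.getLogger(__name__)

WINDOW_INDEX = {name: i for i, name in enumerate(WINDOW_NAMES)}

#: baseline window index -> pulse window index it is extrapolated into
BASELINE_TO_PULSE = {0: 1, 2: 3}


def assign_window(frame: int, schedule: IlluminationSchedule) -> tuple[int, str]:
    """Map a 0-based frame to its (cycle index, window name)."""
    if not 0 <= frame < schedule.total_frames:
        raise ValidationError(
            f"frame {frame} outside [0, {schedule.total_frames})"
        )
    fpc = schedule.frames_per_cycle
    widx = (frame % fpc) // schedule.frames_per_window
    return frame // fpc, WINDOW_NAMES[widx]


def window_counts(
    assigned: pd.DataFrame,
    schedule: IlluminationSchedule,
    labels: list[int] | None = None,
    label_column: str = "nucleus",
) -> dict[int, np.ndarray]:
    """Per-nucleus per-frame counts, shaped (n_cycles, 4, frames_per_window).

    ``assigned`` must carry ``frame`` and a nucleus-label column.  Only
    detections with label > 0 (or in ``labels`` when given) are counted.
    """
    fpw = schedule.frames_per_window
    fpc = schedule.frames_per_cycle
    if labels is None:
        labels = sorted(l for l in assigned[label_column].unique() if l > 0)
    out = {
        int(l): np.zeros((schedule.n_cycles, 4, fpw), dtype=np.int64) for l in labels
    }
    sub = assigned[assigned[label_column].isin(labels)]
    frames = sub["frame"].to_numpy(dtype=np.int64)
    if np.any((frames < 0) | (frames >= schedule.total_frames)):
        raise ValidationError("detection frame outside the illumination schedule")
    labs = sub[label_column].to_numpy(dtype=np.int64)
    cyc = frames // fpc
    widx = (frames % fpc) // fpw
    tw = frames % fpw
    for l, c, w, t in zip(labs, cyc, widx, tw):
        out[int(l)][c, w, t] += 1
    return out


@dataclass(frozen=True)
class ExponentialFit:
    """Single-exponential baseline model ``c(t) = A exp(-k t)``."""

    amplitude: float
    rate: float
    status: str  # "fit" | "fallback_constant"

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.rate < 0:
            raise ValidationError("amplitude and rate must be non-negative")

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-self.rate * np.asarray(t, dtype=float))


def fit_baseline(counts: np.ndarray) -> ExponentialFit:
    """Fit ``A exp(-k t)`` to a per-frame baseline count series.

    Nonlinear least squares with bounds A >= 0, k >= 0; on degenerate data or
    non-convergence, falls back to a constant model (A = mean, k = 0).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 3:
        raise ValidationError("baseline series must be 1-D with length >= 3")
    mean = float(counts.mean())
    if mean == 0 or np.ptp(counts) == 0:
        return ExponentialFit(mean, 0.0, "fallback_constant")
    t = np.arange(counts.size, dtype=float)
    a0 = max(counts[0], mean, 1e-9)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda tt, a, k: a * np.exp(-k * tt),
                t,
                counts,
                p0=(a0, 0.05),
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=2000,
            )
        return ExponentialFit(float(popt[0]), float(popt[1]), "fit")
    except Exception:  # pragma: no cover - scipy failure path
        return ExponentialFit(mean, 0.0, "fallback_constant")


def corrected_pulse_count(
    pulse_counts: np.ndarray, fit: ExponentialFit, offset: int
) -> float:
    """Pulse-window total minus the extrapolated baseline, truncated at zero.

    ``offset`` is the frame distance from the baseline-window start to the
    pulse-window start (one window), so pulse frame ``t`` is predicted as
    ``A exp(-k (t + offset))`` on the baseline's clock.
    """
    pulse_counts = np.asarray(pulse_counts, dtype=float)
    t = np.arange(pulse_counts.size, dtype=float) + offset
    projected = float(fit.predict(t).sum())
    return max(0.0, float(pulse_counts.sum()) - projected)


def condition_totals(
    cells: list[np.ndarray], schedule: IlluminationSchedule
) -> tuple[float, float]:
    """(papa_total, dr_total) for a pooled condition.

    Per-cell count arrays (n_cycles, 4, frames_per_window) are summed over
    cells; each cycle's two baseline windows are fit independently and
    extrapolated into their adjacent pulse windows; corrected sums are
    truncated at zero per (cycle, window) and pooled across cycles.
    """
    if not cells:
        raise ValidationError("condition has no retained cells")
    pooled = np.sum(cells, axis=0)
    fpw = schedule.frames_per_window
    dr_total = papa_total = 0.0
    for c in range(schedule.n_cycles):
        for b, p in BASELINE_TO_PULSE.items():
            fit = fit_baseline(pooled[c, b])
            corrected = corrected_pulse_count(pooled[c, p], fit, offset=fpw)
            if p == 1:
                dr_total += corrected
            else:
                papa_total += corrected
    return papa_total, dr_total


def gv_ratio(
    cells: list[np.ndarray], schedule: IlluminationSchedule, condition: str = ""
) -> tuple[float, float, float]:
    """(papa_total, dr_total, GV ratio) for a condition's retained cells."""
    papa_total, dr_total = condition_totals(cells, schedule)
    if dr_total == 0:
        raise ValidationError(
            f"GV ratio undefined for condition {condition!r}: corrected DR total is 0"
        )
    return papa_total, dr_total, papa_total / dr_total


def proximity_index(gv_experiment: float, gv_control: float) -> float:
    """Experimental GV ratio over the non-interacting control's GV ratio."""
    if not gv_control > 0:
        raise ValidationError(f"control GV ratio must be > 0, got {gv_control}")
    return gv_experiment / gv_control


@dataclass
class ProximityResult:
    """Proximity index with cell-bootstrap uncertainty for one condition."""

    condition: str
    papa_total: float
    dr_total: float
    gv_ratio: float
    control_gv_ratio: float
    proximity_index: float
    ci_low: float
    ci_high: float
    n_cells: int
    n_cells_control: int
    n_boot: int
    seed: int | None
    bootstrap_indices: np.ndarray = field(repr=False, default=None)


def bootstrap_proximity(
    cells_exp: list[np.ndarray],
    cells_ctrl: list[np.ndarray],
    schedule: IlluminationSchedule,
    n_boot: int = 100,
    percentiles: tuple[float, float] = (2.5, 97.5),
    seed: int | None = None,
    max_redraws: int = 20,
) -> tuple[float, float, np.ndarray]:
    """Cell-bootstrap percentile interval for the proximity index.

    Each replicate resamples cells with replacement, independently in the
    experimental and control conditions, re-pools, refits the baselines and
    recomputes the index.  Replicates whose corrected DR total is zero are
    redrawn (up to ``max_redraws`` attempts each, then a warning).
    """
    check_int_min("n_boot", n_boot, 1)
    if len(cells_exp) < 2 or len(cells_ctrl) < 2:
        raise ValidationError("bootstrap requires >= 2 cells per condition")
    rng = np.random.default_rng(seed)
    indices = np.empty(n_boot, dtype=float)
    for b in range(n_boot):
        for attempt in range(max_redraws + 1):
            exp = [cells_exp[i] for i in rng.integers(0, len(cells_exp), len(cells_exp))]
            ctrl = [
                cells_ctrl[i] for i in rng.integers(0, len(cells_ctrl), len(cells_ctrl))
            ]
            try:
                _, _, gv_e = gv_ratio(exp, schedule)
                _, _, gv_c = gv_ratio(ctrl, schedule)
                if gv_c == 0:
                    raise ValidationError("zero control GV in replicate")
                indices[b] = proximity_index(gv_e, gv_c)
                break
            except ValidationError:
                if attempt == max_redraws:
                    logger.warning(
                        "bootstrap replicate %d: DR total zero after %d redraws; "
                        "recording NaN",
                        b,
                        max_redraws,
                    )
                    indices[b] = np.nan
    finite = indices[np.isfinite(indices)]
    lo, hi = np.percentile(finite, percentiles)
    return float(lo), float(hi), indices


def quantify_condition(
    cells_exp: list[np.ndarray],
    cells_ctrl: list[np.ndarray],
    schedule: IlluminationSchedule,
    condition: str = "experiment",
    n_boot: int = 100,
    percentiles: tuple[float, float] = (2.5, 97.5),
    seed: int | None = None,
) -> ProximityResult:
    """Full proximity-index quantification of one condition vs its control."""
    papa_total, dr_total, gv_e = gv_ratio(cells_exp, schedule, condition)
    _, _, gv_c = gv_ratio(cells_ctrl, schedule, "control")
    index = proximity_index(gv_e, gv_c)
    lo, hi, dist = bootstrap_proximity(
        cells_exp, cells_ctrl, schedule, n_boot=n_boot, percentiles=percentiles,
        seed=seed,
    )
    return ProximityResult(
        condition=condition,
        papa_total=papa_total,
        dr_total=dr_total,
        gv_ratio=gv_e,
        control_gv_ratio=gv_c,
        proximity_index=index,
        ci_low=lo,
        ci_high=hi,
        n_cells=len(cells_exp),
        n_cells_control=len(cells_ctrl),
        n_boot=n_boot,
        seed=seed,
        bootstrap_indices=dist,
    )


# ---------------------------------------------------------------------------
# Per-cell DR-vs-PAPA scatter (simple preceding-window background)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellScatterPoint:
    """Per-cell corrected counts for the DR-vs-PAPA scatter."""

    label: int
    dr_corrected: float
    papa_corrected: float
    total_detections: int
    included: bool
    exclusion_reason: str = ""


def cell_scatter_points(
    cell_counts: dict[int, np.ndarray],
    schedule: IlluminationSchedule,
    min_detections: int = 100,
) -> list[CellScatterPoint]:
    """Per-cell background-corrected DR and PAPA counts across all cycles.

    Background for each pulse is the raw detection count in the window
    preceding it; cells with fewer than ``min_detections`` total detections
    or a negative corrected value are flagged excluded.
    """
    points = []
    for label, arr in sorted(cell_counts.items()):
        total = int(arr.sum())
        dr = float((arr[:, 1].sum(axis=1) - arr[:, 0].sum(axis=1)).sum())
        papa = float((arr[:, 3].sum(axis=1) - arr[:, 2].sum(axis=1)).sum())
        reason = ""
        if total < min_detections:
            reason = f"total detections {total} < {min_detections}"
        elif dr < 0 or papa < 0:
            reason = "negative corrected value"
        points.append(
            CellScatterPoint(
                label=label,
                dr_corrected=dr,
                papa_corrected=papa,
                total_detections=total,
                included=not reason,
                exclusion_reason=reason,
            )
        )
    return points


def no_intercept_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = float((x * x).sum())
    if denom == 0:
        raise ValidationError("no-intercept regression undefined: sum(x^2) = 0")
    return float((x * y).sum() / denom)


def cell_scatter_regression(
    points: list[CellScatterPoint],
    n_boot: int = 500,
    percentiles: tuple[float, float] = (2.5, 97.5),
    seed: int | None = None,
) -> dict:
    """No-intercept regression of per-cell PAPA on DR counts.

    slope = Σ(x·y)/Σ(x²) over included points; the confidence band comes from
    ``n_boot`` cell-resampled slopes at the requested percentiles.
    """
    included = [p for p in points if p.included]
    if len(included) < 2:
        raise ValidationError("scatter regression requires >= 2 included cells")
    x = np.array([p.dr_corrected for p in included])
    y = np.array([p.papa_corrected for p in included])
    slope = no_intercept_slope(x, y)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, len(included), len(included))
        try:
            boot[b] = no_intercept_slope(x[idx], y[idx])
        except ValidationError:
            boot[b] = np.nan
    finite = boot[np.isfinite(boot)]
    lo, hi = np.percentile(finite, percentiles)
    return {
        "slope": slope,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_cells": len(included),
        "n_excluded": len(points) - len(included),
        "n_boot": n_boot,
        "seed": seed,
    }
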
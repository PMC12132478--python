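"""FRAP recovery analysis: masking, drift correction, double-ratio traces.

A still (the first frame by convention) is smoothed and thresholded to mask
the nucleus.  Every frame is registered against that still by 2-D image
cross-correlation at integer-pixel resolution; the recovered drift translates
both the bleach-spot position and the nuclear mask.  Per frame, recovery is
the background-subtracted double ratio

    (mean over spot disk - background) / (mean over nucleus mask - background)

with background the median pixel intensity outside the (shifted) mask.  The
ratio series is normalized by its mean over the pre-bleach frames, so full
recovery corresponds to 1.  Frames are 1-based throughout this module to
match the "bleach at frame 16, pre-bleach frames 1-15" convention; conversion
to 0-based array indices happens in one place (:func:`_idx`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure
from skimage.registration import phase_cross_correlation

from ._validation import ValidationError, check_int_min, check_nonneg, check_pos

logger = logging.getLogger(__name__)


def _idx(frame_1based: int) -> int:
    """Central 1-based → 0-based frame conversion."""
    return frame_1based - 1


@dataclass
class FrapTrace:
    """Drift-corrected, background-subtracted, pre-bleach-normalized trace."""

    values: np.ndarray  # normalized recovery per frame
    drifts: np.ndarray  # (n_frames, 2) integer (dy, dx) per frame
    background: np.ndarray  # median outside-mask intensity per frame
    bleach_frame: int  # 1-based
    frame_interval: float  # s

    @property
    def time_s(self) -> np.ndarray:
        return (np.arange(1, self.values.size + 1) - 1) * self.frame_interval


def make_mask(
    still: np.ndarray, smoothing_sigma: float = 5.0, threshold_method: str = "otsu"
) -> np.ndarray:
    """Binary nuclear mask: largest connected component after smooth+threshold."""
    still = np.asarray(still, dtype=float)
    if still.ndim != 2 or not np.all(np.isfinite(still)):
        raise ValidationError("still must be a finite 2-D array")
    check_nonneg("smoothing_sigma", smoothing_sigma)
    smoothed = filters.gaussian(still, sigma=smoothing_sigma, preserve_range=True)
    if np.ptp(smoothed) == 0:
        raise ValidationError("flat still: cannot segment a nucleus")
    if threshold_method == "otsu":
        thresh = filters.threshold_otsu(smoothed)
    elif threshold_method == "mean":
        thresh = smoothed.mean()
    else:
        raise ValidationError(f"unknown threshold_method {threshold_method!r}")
    fg = smoothed > thresh
    labels = measure.label(fg, connectivity=2)
    if labels.max() == 0:
        raise ValidationError("empty foreground: cannot segment a nucleus")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == sizes.argmax()


def estimate_drift(
    reference: np.ndarray, frame: np.ndarray, cap: float | None = None
) -> tuple[int, int]:
    """Integer-pixel drift of ``frame`` relative to ``reference``.

    Returns (dy, dx) such that the frame content sits at reference position
    + (dy, dx), found at the cross-correlation peak.  Constant images yield
    (0, 0) with a warning; with ``cap`` set, larger shifts are clipped to the
    cap (per axis) with a warning.
    """
    reference = np.asarray(reference, dtype=float)
    frame = np.asarray(frame, dtype=float)
    if reference.shape != frame.shape:
        raise ValidationError("reference and frame must have the same shape")
    if np.ptp(reference) == 0 or np.ptp(frame) == 0:
        logger.warning("degenerate (constant) image in drift estimation; using (0, 0)")
        return (0, 0)
    shift, _, _ = phase_cross_correlation(reference, frame, upsample_factor=1)
    dy, dx = int(round(-shift[0])), int(round(-shift[1]))
    if cap is not None and (abs(dy) > cap or abs(dx) > cap):
        logger.warning(
            "drift (%d, %d) exceeds cap %g; clipping", dy, dx, cap
        )
        dy = int(np.clip(dy, -cap, cap))
        dx = int(np.clip(dx, -cap, cap))
    return (dy, dx)


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float):
    yy, xx = np.indices(shape)
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def frap_trace(
    movie: np.ndarray,
    mask: np.ndarray | None = None,
    spot_center: tuple[float, float] = None,
    spot_radius: float = None,
    bleach_frame: int = 16,
    frame_interval: float = 0.15,
    reference_frame: int = 1,
    drift_cap: float | None = 20.0,
) -> FrapTrace:
    """Compute the normalized FRAP recovery trace of one movie.

    ``spot_center`` (y, x) and ``spot_radius`` are the bleach-spot geometry in
    the reference frame (normally taken from the metadata sidecar).  Drift is
    estimated per frame against the reference still, and applied to the spot
    and the mask.  Raises if the spot leaves the mask or a nuclear
    denominator becomes non-positive, naming the frame.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3 or movie.shape[0] == 0:
        raise ValidationError("movie must be a non-empty (frames, rows, cols) stack")
    check_int_min("bleach_frame", bleach_frame, 2)
    check_pos("frame_interval", frame_interval)
    n_frames = movie.shape[0]
    if bleach_frame > n_frames:
        raise ValidationError("bleach_frame beyond the end of the movie")
    if spot_center is None or spot_radius is None:
        raise ValidationError("spot_center and spot_radius are required")
    reference = movie[_idx(reference_frame)]
    if mask is None:
        mask = make_mask(reference)
    mask = np.asarray(mask, dtype=bool)

    values = np.empty(n_frames)
    drifts = np.zeros((n_frames, 2), dtype=int)
    background = np.empty(n_frames)
    for f in range(1, n_frames + 1):
        img = movie[_idx(f)]
        dy, dx = estimate_drift(reference, img, cap=drift_cap)
        drifts[_idx(f)] = (dy, dx)
        shifted_mask = ndimage.shift(
            mask.astype(np.uint8), (dy, dx), order=0, mode="constant", cval=0
        ).astype(bool)
        spot = _disk_mask(
            img.shape, (spot_center[0] + dy, spot_center[1] + dx), spot_radius
        )
        if not (spot & shifted_mask).any():
            raise ValidationError(f"frame {f}: bleach spot left the nuclear mask")
        bg = float(np.median(img[~shifted_mask])) if (~shifted_mask).any() else 0.0
        background[_idx(f)] = bg
        nuc = img[shifted_mask].mean() - bg
        if nuc <= 0:
            raise ValidationError(
                f"frame {f}: non-positive background-subtracted nuclear mean"
            )
        values[_idx(f)] = (img[spot].mean() - bg) / nuc

    pre = values[: _idx(bleach_frame)]
    pre_mean = pre.mean()
    if pre_mean <= 0:
        raise ValidationError("non-positive pre-bleach mean ratio")
    return FrapTrace(
        values=values / pre_mean,
        drifts=drifts,
        background=background,
        bleach_frame=bleach_frame,
        frame_interval=frame_interval,
    )


def average_traces(traces: list[FrapTrace]) -> tuple[np.ndarray, np.ndarray]:
    """Frame-wise mean and standard error over a condition's traces."""
    if not traces:
        raise ValidationError("no traces to average")
    lengths = {t.values.size for t in traces}
    if len(lengths) != 1:
        raise ValidationError(f"trace length mismatch: {sorted(lengths)}")
    stack = np.vstack([t.values for t in traces])
    mean = stack.mean(axis=0)
    sem = (
        stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
        if stack.shape[0] > 1
        else np.zeros(mean.size)
    )
    return mean, sem
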
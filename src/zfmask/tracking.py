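"""Single-larva video tracking by intensity thresholding.

Per frame: threshold, keep the largest connected component, take its
intensity-weighted centroid row, convert to depth through the linear
calibration.  Frames with no detectable component are linearly
interpolated from their neighbors and flagged; a video with too many
missing frames is rejected as untrackable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .trajectories import CHAMBER_HEIGHT_CM, Calibration, TrajectorySet

MAX_MISSING_FRACTION = 0.2
MAX_GAP_FRAMES = 5  # 1 s at 5 fps


def _centroid_row(frame: np.ndarray, threshold: float) -> float | None:
    mask = frame > threshold
    if not mask.any():
        return None
    labels, n = ndimage.label(mask)
    if n > 1:
        # reflections or debris: keep the largest blob
        sizes = ndimage.sum_labels(np.ones_like(frame), labels, index=np.arange(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    weights = np.where(mask, frame - threshold, 0.0)
    total = weights.sum()
    if total <= 0:
        return None
    rows = np.arange(frame.shape[0])[:, None]
    return float((weights * rows).sum() / total)


def track_positions(
    frames: np.ndarray,
    intensity_threshold: float,
    calibration: Calibration,
    rate_hz: float = 5.0,
    invert: bool = False,
    fish_id: str = "fish00",
) -> TrajectorySet:
    """Track one larva through a frame stack.

    Parameters
    ----------
    frames:
        T x Y x X stack, bright fish on dark background (set ``invert``
        for the opposite polarity).
    intensity_threshold:
        Absolute threshold separating fish from background; must lie
        within the stack's intensity range.
    calibration:
        Row-to-cm map, normally the one emitted by the renderer or
        measured from the chamber.

    Raises
    ------
    ValueError
        If more than 20% of frames have no above-threshold component, or
        any single gap exceeds 5 consecutive frames.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be a T x Y x X stack")
    if invert:
        frames = frames.max() - frames
    lo, hi = frames.min(), frames.max()
    if not lo <= intensity_threshold <= hi:
        raise ValueError(
            f"threshold {intensity_threshold} outside intensity range [{lo}, {hi}]"
        )

    rows = np.array(
        [
            r if (r := _centroid_row(f, intensity_threshold)) is not None else np.nan
            for f in frames
        ]
    )
    missing = np.isnan(rows)
    if missing.mean() > MAX_MISSING_FRACTION:
        raise ValueError(
            f"{missing.mean():.0%} of frames have no detectable fish; video unusable"
        )
    if missing.any():
        # reject long dropouts, interpolate short ones
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, missing.view(np.int8), 0])))[::2]
        if runs.size and runs.max() > MAX_GAP_FRAMES:
            raise ValueError(
                f"gap of {runs.max()} consecutive undetected frames exceeds "
                f"the {MAX_GAP_FRAMES}-frame interpolation limit"
            )
        good = np.flatnonzero(~missing)
        rows[missing] = np.interp(np.flatnonzero(missing), good, rows[good])

    depth = np.clip(calibration.row_to_cm(rows), 0.0, CHAMBER_HEIGHT_CM)
    return TrajectorySet(
        depth=depth[None, :],
        rate_hz=rate_hz,
        ids=[fish_id],
        calibration=calibration,
        interpolated=missing[None, :],
    )


def read_video(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF video into a T x Y x X float array."""
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    return np.asarray(stack, dtype=float)


def write_video(path: str | Path, frames: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(frames, dtype=np.float32))
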
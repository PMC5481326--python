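"""Synthetic calcium-imaging movies with planted, ground-truthed sources.

Each planted source is a non-negative spatial footprint paired with one of
five stimulus-locked response classes observed in the light-evoked
activity data:

* ``blue_onset_sustained`` — elevated throughout blue epochs;
* ``red_onset``            — elevated throughout red epochs;
* ``mixed_onset_transient``  — decaying transient at every light onset;
* ``mixed_offset_transient`` — decaying transient at every light offset;
* ``blue_offset``          — decaying transient at blue offsets only.

The ideal response is convolved with a difference-of-exponentials
calcium-indicator kernel (GCaMP6f-like: 0.1 s rise, 0.7 s decay by
default) and scattered onto the footprint; pixels get additive Gaussian
noise.  The noiseless movie is exactly the analytic superposition of the
planted sources, which downstream decomposition tests rely on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .schedule import StimulusSchedule

RESPONSE_CLASSES = (
    "blue_onset_sustained",
    "red_onset",
    "mixed_onset_transient",
    "mixed_offset_transient",
    "blue_offset",
)

DEFAULT_FRAME_RATE_HZ = 7.1


@dataclass
class PlantedSource:
    """A ground-truth source: footprint, response class, amplitude, kinetics."""

    footprint: np.ndarray  # 2-D weights >= 0, finite support
    response_class: str
    amplitude: float = 1.0  # peak dF/F
    tau_rise_s: float = 0.1
    tau_decay_s: float = 0.7
    transient_tau_s: float = 10.0  # decay of the phasic (sawtooth-like) drive

    def __post_init__(self) -> None:
        self.footprint = np.asarray(self.footprint, dtype=float)
        if self.footprint.ndim != 2:
            raise ValueError("footprint must be 2-D")
        if np.any(self.footprint < 0):
            raise ValueError("footprint weights must be >= 0")
        if not np.any(self.footprint > 0):
            raise ValueError("footprint must have non-empty support")
        if self.response_class not in RESPONSE_CLASSES:
            raise ValueError(f"unknown response class {self.response_class!r}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.tau_rise_s <= 0 or self.tau_decay_s <= 0 or self.transient_tau_s <= 0:
            raise ValueError("time constants must be positive")


def gaussian_footprint(
    shape: tuple[int, int],
    center: tuple[float, float],
    sigma_px: float,
    truncate: float = 3.0,
) -> np.ndarray:
    """Gaussian blob truncated to ``truncate`` sigmas (finite support)."""
    yy = np.arange(shape[0])[:, None]
    xx = np.arange(shape[1])[None, :]
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    fp = np.exp(-d2 / (2 * sigma_px**2))
    fp[d2 > (truncate * sigma_px) ** 2] = 0.0
    return fp


def indicator_kernel(tau_rise_s: float, tau_decay_s: float, rate_hz: float) -> np.ndarray:
    """Unit-area difference-of-exponentials kernel sampled at ``rate_hz``."""
    t = np.arange(0.0, tau_decay_s * 8 + tau_rise_s * 8, 1.0 / rate_hz)
    k = np.exp(-t / tau_decay_s) - np.exp(-t / tau_rise_s)
    s = k.sum() / rate_hz
    if s <= 0:
        raise ValueError("degenerate kernel; check time constants")
    return k / (s * rate_hz)  # discrete sum == 1 so plateaus are preserved


def _transient_drive(event_times: list[float], t: np.ndarray, tau: float) -> np.ndarray:
    """Jump to 1 at each event, then exponential decay; reset at each event."""
    drive = np.zeros_like(t)
    if not event_times:
        return drive
    events = np.asarray(sorted(event_times))
    idx = np.searchsorted(events, t, side="right") - 1
    has = idx >= 0
    drive[has] = np.exp(-(t[has] - events[idx[has]]) / tau)
    return drive


def ideal_response(
    response_class: str,
    schedule: StimulusSchedule,
    rate_hz: float,
    transient_tau_s: float = 10.0,
) -> np.ndarray:
    """Unit-amplitude ideal (pre-indicator) drive for a response class."""
    t = np.arange(schedule.n_samples(rate_hz)) / rate_hz
    if response_class == "blue_onset_sustained":
        return schedule.channel_mask("blue470", rate_hz).astype(float)
    if response_class == "red_onset":
        return schedule.channel_mask("red660", rate_hz).astype(float)
    if response_class == "mixed_onset_transient":
        return _transient_drive(schedule.onset_times(), t, transient_tau_s)
    if response_class == "mixed_offset_transient":
        return _transient_drive(schedule.offset_times(), t, transient_tau_s)
    if response_class == "blue_offset":
        return _transient_drive(schedule.offset_times(["blue470"]), t, transient_tau_s)
    raise ValueError(f"unknown response class {response_class!r}")


def source_trace(
    source: PlantedSource, schedule: StimulusSchedule, rate_hz: float
) -> np.ndarray:
    """Temporal dF/F trace of one source: ideal drive x indicator kernel."""
    drive = ideal_response(
        source.response_class, schedule, rate_hz, source.transient_tau_s
    )
    kernel = indicator_kernel(source.tau_rise_s, source.tau_decay_s, rate_hz)
    return source.amplitude * np.convolve(drive, kernel)[: drive.size]


def simulate_calcium_movie(
    schedule: StimulusSchedule,
    sources: list[PlantedSource],
    shape: tuple[int, int, int],
    noise_sd: float = 0.0,
    baseline: float = 0.0,
    rate_hz: float = DEFAULT_FRAME_RATE_HZ,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Render a T x Y x X movie with planted sources.

    Returns ``(movie, label_masks, classes)`` where ``label_masks`` is a
    sources x Y x X boolean stack of ground-truth supports and ``classes``
    the per-source response-class labels.
    """
    T, Y, X = shape
    expected_T = schedule.n_samples(rate_hz)
    if T != expected_T:
        raise ValueError(
            f"T={T} does not match schedule duration x rate ({expected_T} frames)"
        )
    seen: set[tuple[bytes, str]] = set()
    movie = np.full((T, Y, X), float(baseline))
    masks = np.zeros((len(sources), Y, X), dtype=bool)
    classes = []
    for i, src in enumerate(sources):
        if src.footprint.shape != (Y, X):
            raise ValueError("source footprint shape does not match movie frame")
        key = (src.footprint.tobytes(), src.response_class)
        if key in seen:
            warnings.warn(
                "duplicate footprint with identical response class; the two "
                "sources are unidentifiable",
                stacklevel=2,
            )
        seen.add(key)
        trace = source_trace(src, schedule, rate_hz)
        movie += trace[:, None, None] * src.footprint[None, :, :]
        masks[i] = src.footprint > 0
        classes.append(src.response_class)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        movie = movie + rng.normal(0.0, noise_sd, size=movie.shape)
    return movie, masks, classes


def default_source_bank(
    shape: tuple[int, int],
    amplitude: float = 1.0,
    sigma_px: float = 2.5,
    jitter_px: int = 0,
    seed: int | None = None,
) -> list[PlantedSource]:
    """One source per response class on a fixed grid, optionally jittered.

    The grid spreads five footprints across the field of view; ``jitter_px``
    shifts each center by an integer offset drawn uniformly from
    [-jitter, jitter] to emulate between-animal anatomical variability.
    """
    Y, X = shape
    rng = np.random.default_rng(seed)
    centers = [
        (0.25 * Y, 0.25 * X),
        (0.25 * Y, 0.75 * X),
        (0.55 * Y, 0.50 * X),
        (0.80 * Y, 0.25 * X),
        (0.80 * Y, 0.75 * X),
    ]
    sources = []
    for cls, (cy, cx) in zip(RESPONSE_CLASSES, centers):
        if jitter_px:
            cy += rng.integers(-jitter_px, jitter_px + 1)
            cx += rng.integers(-jitter_px, jitter_px + 1)
        fp = gaussian_footprint((Y, X), (cy, cx), sigma_px)
        sources.append(PlantedSource(fp, cls, amplitude=amplitude))
    return sources
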
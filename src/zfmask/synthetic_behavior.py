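"""Synthetic vertical-migration behavior: trajectories and rendered videos.

The behavior model is a first-order drift-diffusion process in depth.  In
each epoch a fish either responds (drifts toward the epoch-congruent end
of the water column: up during light, down during darkness) or performs a
pure random walk; the per-epoch response probability is the channel
responsiveness.  Boundaries reflect by clipping to the 5 cm column.

Defaults are calibrated so that a blue-light group reproduces the
occurrence rates seen in the assay (climbs/dives crossing the half-depth
mark in roughly three quarters to 90% of fish x cycle events at the
standard irradiance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schedule import StimulusSchedule
from .trajectories import CHAMBER_HEIGHT_CM, Calibration, TrajectorySet


def _default_responsiveness() -> dict:
    # dark must stay 0: darkness never drives the light response itself.
    return {
        "dark": 0.0,
        "blue470": 0.85,
        "green525": 0.85,
        "red660": 0.25,
        "uv375": 0.15,
    }


@dataclass
class BehaviorModelParams:
    """Drift-diffusion parameters for the synthetic fish.

    responsiveness:
        Per-channel probability (in [0, 1]) that a fish responds to an
        epoch.  Dark epochs take the responsiveness of the adjacent light
        epoch's channel: the dark-phase dive is the other half of the same
        wavelength-dependent response.
    climb_speed_mean, dive_speed_mean:
        Drift magnitude of a responding fish, cm/s.  0.08 cm/s crosses the
        2.5 cm half mark in ~30 s, matching the observed initial speeds.
    speed_sd:
        Between-event spread of the drift speed, cm/s.
    position_noise_sd:
        Diffusion scale, cm per sqrt(second).
    start_depth_cm:
        Common start depth; None draws uniformly from the lower half of
        the column (fish rest deep in darkness).
    """

    responsiveness: dict = field(default_factory=_default_responsiveness)
    climb_speed_mean: float = 0.08
    dive_speed_mean: float = 0.08
    speed_sd: float = 0.02
    position_noise_sd: float = 0.08
    boundary_cm: float = CHAMBER_HEIGHT_CM
    start_depth_cm: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.climb_speed_mean < 0 or self.dive_speed_mean < 0:
            raise ValueError("speeds must be >= 0")
        if self.responsiveness.get("dark", 0.0) != 0.0:
            raise ValueError("dark responsiveness must be 0")
        for ch, r in self.responsiveness.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"responsiveness[{ch!r}] outside [0, 1]")


def _epoch_context_channels(schedule: StimulusSchedule) -> list[str]:
    """Channel governing each epoch's response.

    Light epochs govern themselves; a dark epoch inherits the channel of
    the following light epoch (the cycle it opens), falling back to the
    preceding one at the end of the schedule.
    """
    chans = [ep.channel for ep in schedule.epochs]
    out = []
    for i, ch in enumerate(chans):
        if ch != "dark":
            out.append(ch)
            continue
        nxt = next((c for c in chans[i + 1 :] if c != "dark"), None)
        prv = next((c for c in reversed(chans[:i]) if c != "dark"), None)
        out.append(nxt or prv or "dark")
    return out


def simulate_trajectories(
    params: BehaviorModelParams,
    schedule: StimulusSchedule,
    n_fish: int,
    rate_hz: float = 5.0,
) -> TrajectorySet:
    """Simulate ``n_fish`` depth trajectories under ``schedule``.

    Fully reproducible from ``params.seed``; returns an
    fish x (duration * rate) matrix clipped to [0, boundary] cm.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    if n_fish < 1:
        raise ValueError("n_fish must be >= 1")
    if not schedule.epochs:
        raise ValueError("empty schedule")

    rng = np.random.default_rng(params.seed)
    dt = 1.0 / rate_hz
    n_samples = schedule.n_samples(rate_hz)
    contexts = _epoch_context_channels(schedule)

    depth = np.empty((n_fish, n_samples))
    if params.start_depth_cm is None:
        pos = rng.uniform(params.boundary_cm / 2, params.boundary_cm, size=n_fish)
    else:
        pos = np.full(n_fish, float(params.start_depth_cm))

    # Per-epoch response draws and drift speeds, all fish at once.
    i = 0
    for ep, ctx in zip(schedule.epochs, contexts):
        n_ep = int(round(ep.duration_s * rate_hz))
        resp_p = params.responsiveness.get(ctx, 0.0)
        responding = rng.random(n_fish) < resp_p
        if ep.is_light:  # climb: depth decreases
            speed_mean = params.climb_speed_mean
            sign = -1.0
        else:  # dive: depth increases
            speed_mean = params.dive_speed_mean
            sign = 1.0
        speeds = np.clip(rng.normal(speed_mean, params.speed_sd, size=n_fish), 0, None)
        drift = sign * speeds * responding * dt
        noise = rng.normal(
            0.0, params.position_noise_sd * np.sqrt(dt), size=(n_fish, n_ep)
        )
        for k in range(n_ep):
            pos = np.clip(pos + drift + noise[:, k], 0.0, params.boundary_cm)
            depth[:, i + k] = pos
        i += n_ep

    return TrajectorySet(depth=depth, rate_hz=rate_hz, seed=params.seed)


@dataclass
class BlobParams:
    """Rendering parameters for the bright-fish-on-dark video fixture."""

    sigma_px: float = 3.0
    amplitude: float = 200.0
    background: float = 10.0
    noise_sd: float = 0.0
    seed: int | None = None


def render_behavior_video(
    traj: TrajectorySet,
    image_size: tuple[int, int] = (200, 64),
    blob: BlobParams | None = None,
) -> tuple[np.ndarray, Calibration]:
    """Render a single-fish trajectory as a frame stack.

    One bright Gaussian blob per frame on a dark background, at the image
    row given by the linear depth-to-row calibration (returned alongside
    the frames).  One chamber holds one fish, so multi-fish trajectory
    sets are rejected.
    """
    if traj.n_fish != 1:
        raise ValueError("one chamber per video: trajectory set must hold one fish")
    blob = blob or BlobParams()
    height, width = image_size
    if blob.sigma_px * 2 >= height:
        raise ValueError("blob radius must be smaller than the image height")
    if np.any(traj.depth < 0) or np.any(traj.depth > CHAMBER_HEIGHT_CM):
        raise ValueError("trajectory depths outside the chamber")

    cal = Calibration(cm_per_px=CHAMBER_HEIGHT_CM / (height - 1), row_offset=0.0)
    rows = cal.cm_to_row(traj.depth[0])
    col = (width - 1) / 2.0

    rng = np.random.default_rng(blob.seed)
    yy = np.arange(height)[:, None]
    xx = np.arange(width)[None, :]
    frames = np.empty((traj.n_samples, height, width), dtype=np.float32)
    for t, r in enumerate(rows):
        img = blob.background + blob.amplitude * np.exp(
            -((yy - r) ** 2 + (xx - col) ** 2) / (2 * blob.sigma_px**2)
        )
        if blob.noise_sd > 0:
            img = img + rng.normal(0, blob.noise_sd, size=img.shape)
        frames[t] = img
    return frames, cal
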
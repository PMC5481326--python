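"""Light-stimulus schedules.

A schedule is an ordered, gap-free tiling of the recording by epochs, each
with a channel (an LED color, or darkness), an irradiance and a duration.
Two layouts are supported:

* ``behavior_cycles`` — the vertical-migration assay: ``n`` cycles of
  60 s darkness followed by 60 s light of a single color.
* ``imaging_random`` — the imaging assay: 60 s dark epochs interleaved
  with 60 s blue or red pulses delivered in seeded random order with
  equal counts per color.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import constants

CHANNELS = ("dark", "blue470", "green525", "red660", "uv375")

#: Peak wavelength per LED channel, nm.
CHANNEL_WAVELENGTH_NM = {
    "blue470": 470.0,
    "green525": 525.0,
    "red660": 660.0,
    "uv375": 375.0,
}

#: Default irradiance per channel, µW/cm².  Blue uses the standard assay
#: level; the others are photon-matched to blue at ~1.5e15 photons/cm²/s
#: (matched photon flux, not matched power, is what the non-visual system
#: sees).
DEFAULT_IRRADIANCE_UW_CM2 = {
    "dark": 0.0,
    "blue470": 650.0,
    "green525": 580.0,
    "red660": 465.0,
    "uv375": 826.0,
}

EPOCH_DURATION_S = 60.0


@dataclass(frozen=True)
class Epoch:
    start_s: float
    duration_s: float
    channel: str
    irradiance_uw_cm2: float

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def is_light(self) -> bool:
        return self.channel != "dark"


@dataclass
class StimulusSchedule:
    """Ordered light epochs tiling ``[0, total_duration_s]``."""

    epochs: list[Epoch]
    seed: int | None = None

    def __post_init__(self) -> None:
        t = 0.0
        for ep in self.epochs:
            if ep.channel not in CHANNELS:
                raise ValueError(f"unknown channel {ep.channel!r}")
            if abs(ep.start_s - t) > 1e-9:
                raise ValueError("epochs must be contiguous and start at 0")
            t += ep.duration_s

    @property
    def total_duration_s(self) -> float:
        return sum(ep.duration_s for ep in self.epochs)

    def epoch_at(self, t: float) -> Epoch:
        for ep in self.epochs:
            if ep.start_s <= t < ep.end_s:
                return ep
        raise ValueError(f"time {t} outside schedule")

    def light_epochs(self) -> list[Epoch]:
        return [ep for ep in self.epochs if ep.is_light]

    def channels_present(self) -> set[str]:
        return {ep.channel for ep in self.epochs if ep.is_light}

    def n_samples(self, rate_hz: float) -> int:
        return int(round(self.total_duration_s * rate_hz))

    def channel_mask(self, channel: str, rate_hz: float) -> np.ndarray:
        """Boolean vector: sample falls inside an epoch of ``channel``."""
        t = np.arange(self.n_samples(rate_hz)) / rate_hz
        mask = np.zeros(t.size, dtype=bool)
        for ep in self.epochs:
            if ep.channel == channel:
                mask |= (t >= ep.start_s) & (t < ep.end_s)
        return mask

    def onset_times(self, channels: Iterable[str] | None = None) -> list[float]:
        """Start times of light epochs (optionally restricted by channel)."""
        chans = set(channels) if channels is not None else None
        return [
            ep.start_s
            for ep in self.epochs
            if ep.is_light and (chans is None or ep.channel in chans)
        ]

    def offset_times(self, channels: Iterable[str] | None = None) -> list[float]:
        chans = set(channels) if channels is not None else None
        return [
            ep.end_s
            for ep in self.epochs
            if ep.is_light and (chans is None or ep.channel in chans)
        ]

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "epochs": [
                {
                    "start_s": ep.start_s,
                    "duration_s": ep.duration_s,
                    "channel": ep.channel,
                    "irradiance_uw_cm2": ep.irradiance_uw_cm2,
                }
                for ep in self.epochs
            ],
            "total_duration_s": self.total_duration_s,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSchedule":
        epochs = [
            Epoch(e["start_s"], e["duration_s"], e["channel"], e["irradiance_uw_cm2"])
            for e in d["epochs"]
        ]
        return cls(epochs=epochs, seed=d.get("seed"))

    @classmethod
    def from_json(cls, path: str | Path) -> "StimulusSchedule":
        return cls.from_dict(json.loads(Path(path).read_text()))


def make_schedule(
    mode: str,
    n_cycles: int,
    seed: int | None = None,
    channel: str = "blue470",
    epoch_duration_s: float = EPOCH_DURATION_S,
    irradiance_uw_cm2: float | None = None,
) -> StimulusSchedule:
    """Build a stimulus schedule.

    Parameters
    ----------
    mode:
        ``behavior_cycles`` — ``n_cycles`` repeats of 60 s OFF then 60 s ON
        of ``channel``.  ``imaging_random`` — ``n_cycles`` light pulses
        (blue and red in equal numbers, seeded random order), each preceded
        by a 60 s dark epoch.
    n_cycles:
        Number of dark/light cycles (behavior) or light pulses (imaging).
    seed:
        Seeds the pulse-order permutation in ``imaging_random`` mode.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    dur = float(epoch_duration_s)

    if mode == "behavior_cycles":
        if channel == "dark" or channel not in CHANNELS:
            raise ValueError(f"channel must be a light channel, got {channel!r}")
        irr = (
            DEFAULT_IRRADIANCE_UW_CM2[channel]
            if irradiance_uw_cm2 is None
            else float(irradiance_uw_cm2)
        )
        epochs = []
        t = 0.0
        for _ in range(n_cycles):
            epochs.append(Epoch(t, dur, "dark", 0.0))
            epochs.append(Epoch(t + dur, dur, channel, irr))
            t += 2 * dur
        return StimulusSchedule(epochs=epochs, seed=seed)

    if mode == "imaging_random":
        if n_cycles % 2 != 0:
            raise ValueError(
                "imaging_random requires an even pulse count for equal "
                "blue/red numbers"
            )
        rng = np.random.default_rng(seed)
        pulses = ["blue470"] * (n_cycles // 2) + ["red660"] * (n_cycles // 2)
        order = rng.permutation(len(pulses))
        epochs = []
        t = 0.0
        for i in order:
            ch = pulses[i]
            epochs.append(Epoch(t, dur, "dark", 0.0))
            irr = (
                DEFAULT_IRRADIANCE_UW_CM2[ch]
                if irradiance_uw_cm2 is None
                else float(irradiance_uw_cm2)
            )
            epochs.append(Epoch(t + dur, dur, ch, irr))
            t += 2 * dur
        return StimulusSchedule(epochs=epochs, seed=seed)

    raise ValueError(f"unknown mode {mode!r}")


def photon_intensity(power_density_uw_cm2: float, wavelength_nm: float) -> float:
    """Photon flux density I = (P/A) / E with E = hc/λ.

    Parameters are the measured power density in µW/cm² and the peak
    wavelength in nm; the result is in photons·cm⁻²·s⁻¹.  This is the
    quantity matched across wavelengths in the assay, since photoreceptor
    activation counts photons rather than energy.
    """
    if power_density_uw_cm2 <= 0 or wavelength_nm <= 0:
        raise ValueError("power density and wavelength must be positive")
    energy_j = constants.h * constants.c / (wavelength_nm * 1e-9)
    return (power_density_uw_cm2 * 1e-6) / energy_j
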
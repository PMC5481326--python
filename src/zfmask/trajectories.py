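"""Vertical-position trajectories and their CSV dialect.

Depth convention: 0 cm at the water surface, increasing downward, bounded
by the 5.0 cm chamber height.  Shared by the simulator, the tracker and
every statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CHAMBER_HEIGHT_CM = 5.0
HALF_DEPTH_CM = CHAMBER_HEIGHT_CM / 2.0


@dataclass
class Calibration:
    """Linear depth <-> image-row map: depth_cm = cm_per_px * (row - row_offset)."""

    cm_per_px: float
    row_offset: float = 0.0

    def row_to_cm(self, row):
        return self.cm_per_px * (np.asarray(row, dtype=float) - self.row_offset)

    def cm_to_row(self, depth_cm):
        return np.asarray(depth_cm, dtype=float) / self.cm_per_px + self.row_offset


@dataclass
class TrajectorySet:
    """Per-fish vertical depth time series at a fixed sampling rate.

    ``depth`` is fish x time in cm; ``interpolated`` flags samples filled
    in by the tracker rather than measured.
    """

    depth: np.ndarray
    rate_hz: float
    ids: list[str] = field(default_factory=list)
    calibration: Calibration | None = None
    seed: int | None = None
    interpolated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depth = np.atleast_2d(np.asarray(self.depth, dtype=float))
        if not self.ids:
            self.ids = [f"fish{i:02d}" for i in range(self.n_fish)]
        if len(self.ids) != self.n_fish:
            raise ValueError("ids length must match number of fish")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def n_fish(self) -> int:
        return self.depth.shape[0]

    @property
    def n_samples(self) -> int:
        return self.depth.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate_hz

    def subset(self, indices) -> "TrajectorySet":
        idx = list(indices)
        return TrajectorySet(
            depth=self.depth[idx],
            rate_hz=self.rate_hz,
            ids=[self.ids[i] for i in idx],
            calibration=self.calibration,
            seed=self.seed,
            interpolated=None if self.interpolated is None else self.interpolated[idx],
        )

    # -- CSV + JSON sidecar ------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.time_s}
        for i, fid in enumerate(self.ids):
            data[f"depth_cm_{fid}"] = self.depth[i]
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path, metadata_path: str | Path | None = None) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {
            "rate_hz": self.rate_hz,
            "ids": self.ids,
            "seed": self.seed,
            "calibration": None
            if self.calibration is None
            else {
                "cm_per_px": self.calibration.cm_per_px,
                "row_offset": self.calibration.row_offset,
            },
        }
        mpath = (
            Path(metadata_path)
            if metadata_path is not None
            else path.with_suffix(".meta.json")
        )
        mpath.write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(
        cls, path: str | Path, metadata_path: str | Path | None = None
    ) -> "TrajectorySet":
        path = Path(path)
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c.startswith("depth_cm_")]
        if not cols:
            raise ValueError("no depth_cm_* columns in trajectory CSV")
        depth = df[cols].to_numpy().T
        mpath = (
            Path(metadata_path)
            if metadata_path is not None
            else path.with_suffix(".meta.json")
        )
        if mpath.exists():
            meta = json.loads(mpath.read_text())
            rate = float(meta["rate_hz"])
            cal = meta.get("calibration")
            calibration = (
                Calibration(cal["cm_per_px"], cal["row_offset"]) if cal else None
            )
            seed = meta.get("seed")
        else:
            dt = np.diff(df["time_s"].to_numpy())
            rate = 1.0 / float(np.median(dt))
            calibration, seed = None, None
        ids = [c.removeprefix("depth_cm_") for c in cols]
        return cls(depth=depth, rate_hz=rate, ids=ids, calibration=calibration, seed=seed)
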
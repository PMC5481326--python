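"""Template-based classification of light-evoked responses and
cross-animal map integration.

Five stimulus-locked templates are built from each fish's own stimulus
schedule: square waves for the sustained blue and red responses,
sawtooth waves (instant rise, exponential decay) for the transient
mixed-onset, mixed-offset and blue-offset responses.  An ICA temporal
signal is assigned to the template with which it correlates most, if
that correlation exceeds a threshold (0.5 by default).  Spatial maps in
the same category from different animals are registered by integer
translation and averaged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import signal as sp_signal

from .ica_pipeline import ICADecomposition
from .schedule import StimulusSchedule
from .synthetic_imaging import _transient_drive

TEMPLATE_KEYS = ("blue_onset", "red_onset", "mixed_onset", "mixed_offset", "blue_offset")
DEFAULT_SAWTOOTH_TAU_S = 10.0
DEFAULT_CORR_THRESHOLD = 0.5


@dataclass
class ResponseTemplateBank:
    """Unit-amplitude stimulus-locked regressors, one per response category.

    Timing comes solely from the fish's own schedule, so banks from
    different randomized schedules differ in timing but share structure.
    A missing color leaves its templates empty; they are excluded from
    matching.
    """

    templates: dict[str, np.ndarray]
    rate_hz: float
    tau_s: float

    def available(self) -> list[str]:
        return [k for k in TEMPLATE_KEYS if self.templates[k].size > 0]

    def __getitem__(self, key: str) -> np.ndarray:
        return self.templates[key]


def build_templates(
    schedule: StimulusSchedule,
    rate_hz: float,
    tau_s: float = DEFAULT_SAWTOOTH_TAU_S,
) -> ResponseTemplateBank:
    """Build the five-template bank from a stimulus schedule.

    blue_onset / red_onset are 1 during that color's epochs and 0
    elsewhere; mixed_onset / mixed_offset are sawtooths at every light
    onset / offset of either color; blue_offset is a sawtooth at blue
    offsets only.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    t = np.arange(schedule.n_samples(rate_hz)) / rate_hz
    present = schedule.channels_present()
    empty = np.empty(0)

    def _square(channel):
        if channel not in present:
            return empty
        return schedule.channel_mask(channel, rate_hz).astype(float)

    templates = {
        "blue_onset": _square("blue470"),
        "red_onset": _square("red660"),
        "mixed_onset": _transient_drive(schedule.onset_times(), t, tau_s),
        "mixed_offset": _transient_drive(schedule.offset_times(), t, tau_s),
        "blue_offset": (
            _transient_drive(schedule.offset_times(["blue470"]), t, tau_s)
            if "blue470" in present
            else empty
        ),
    }
    missing = [k for k, v in templates.items() if v.size == 0]
    if missing:
        warnings.warn(
            f"schedule lacks a color; templates excluded from matching: {missing}",
            stacklevel=2,
        )
    return ResponseTemplateBank(templates=templates, rate_hz=rate_hz, tau_s=tau_s)


@dataclass
class Classification:
    category: str | None
    max_correlation: float


def classify_components(
    decomp: ICADecomposition,
    bank: ResponseTemplateBank,
    threshold: float = DEFAULT_CORR_THRESHOLD,
) -> list[Classification]:
    """Assign each ICA temporal signal to its best-correlated template.

    The Pearson correlation against every available template is computed;
    the arg-max category is assigned iff the maximum exceeds
    ``threshold``.  Exact ties break by the fixed key order.  A constant
    signal cannot be correlated and is left unclassified with a warning.
    """
    avail = bank.available()
    if not avail:
        raise ValueError("template bank has no available templates")
    T = decomp.temporal_signals.shape[1]
    for key in avail:
        if bank[key].size != T:
            raise ValueError("template and signal lengths differ")
    out = []
    for i, sig in enumerate(decomp.temporal_signals):
        if np.ptp(sig) == 0:
            warnings.warn(f"component {i} has a constant signal", stacklevel=2)
            out.append(Classification(None, np.nan))
            continue
        best_key, best_r = None, -np.inf
        for key in avail:  # fixed order ties toward earlier keys
            r = float(np.corrcoef(sig, bank[key])[0, 1])
            if r > best_r:
                best_key, best_r = key, r
        if best_r > threshold:
            out.append(Classification(best_key, best_r))
        else:
            out.append(Classification(None, best_r))
    return out


def classification_table(results: list[Classification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "component": range(len(results)),
            "category": [r.category or "unclassified" for r in results],
            "max_correlation": [r.max_correlation for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Cross-animal integration
# ---------------------------------------------------------------------------

@dataclass
class CategoryAverage:
    members: list[tuple[str, np.ndarray, float]]  # (fish id, map, best r)
    average: np.ndarray
    offsets: dict[str, tuple[int, int]]


@dataclass
class ClassifiedMaps:
    per_category: dict[str, CategoryAverage] = field(default_factory=dict)

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        offsets = {}
        for cat, avg in self.per_category.items():
            tifffile.imwrite(
                str(out_dir / f"average_map_{cat}.tif"), avg.average.astype(np.float32)
            )
            offsets[cat] = {fid: list(off) for fid, off in avg.offsets.items()}
        (out_dir / "offsets.json").write_text(json.dumps(offsets, indent=1))


def _best_translation(reference: np.ndarray, moving: np.ndarray) -> tuple[int, int]:
    """Integer shift of ``moving`` maximizing 2-D cross-correlation with
    ``reference`` (positive dy shifts the map down)."""
    ref = reference - reference.mean()
    mov = moving - moving.mean()
    xc = sp_signal.fftconvolve(ref, mov[::-1, ::-1], mode="full")
    peak = np.unravel_index(int(np.argmax(xc)), xc.shape)
    dy = int(peak[0]) - (moving.shape[0] - 1)
    dx = int(peak[1]) - (moving.shape[1] - 1)
    return dy, dx


def _shift_into(canvas_shape, image, dy, dx):
    """Place ``image`` shifted by (dy, dx) onto a NaN canvas."""
    out = np.full(canvas_shape, np.nan)
    Y, X = image.shape
    ys0, ys1 = max(0, dy), min(Y, Y + dy)
    xs0, xs1 = max(0, dx), min(X, X + dx)
    out[ys0:ys1, xs0:xs1] = image[ys0 - dy : ys1 - dy, xs0 - dx : xs1 - dx]
    return out


def register_and_average(
    maps_by_category: dict[str, list[tuple[str, np.ndarray, float]]],
    reference_fish: str,
) -> ClassifiedMaps:
    """Register same-category spatial maps across animals and average them.

    Each map is shifted by the integer translation maximizing its 2-D
    cross-correlation with the reference fish's map of that category,
    then maps are averaged per pixel over the animals present there.
    Categories with no maps are omitted.
    """
    out = ClassifiedMaps()
    for cat, entries in maps_by_category.items():
        if not entries:
            continue
        shapes = {m.shape for _, m, _ in entries}
        if len(shapes) != 1:
            raise ValueError(f"maps in category {cat!r} differ in shape")
        ref_entry = next((e for e in entries if e[0] == reference_fish), entries[0])
        reference = ref_entry[1]
        shifted, offsets = [], {}
        for fid, m, r in entries:
            dy, dx = _best_translation(reference, m)
            offsets[fid] = (dy, dx)
            shifted.append(_shift_into(reference.shape, m, dy, dx))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
            average = np.nanmean(np.stack(shifted), axis=0)
        out.per_category[cat] = CategoryAverage(
            members=entries, average=average, offsets=offsets
        )
    return out
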
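"""Occlusion-challenge time-series extraction and summary metrics.

An occlusion run is summarised by three numbers: the mean sO2 before the
cuff is inflated (baseline), the minimum while the cuff is on, and the
maximum after release (the hyperaemic peak). Invalid frames are flagged and
excluded from the statistics, never silently dropped from the series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import MultispectralCube
from .unmixing import (
    ChromophoreMaps,
    compute_so2,
    noise_floor_mask,
    unmix_pseudo_inverse,
)

__all__ = [
    "OcclusionSeries",
    "OcclusionEvents",
    "OcclusionMetrics",
    "WindowEmptyError",
    "extract_series",
    "occlusion_metrics",
    "moving_median",
]

logger = logging.getLogger(__name__)

#: Cuff inflation time used by the acquisition protocol (seconds).
DEFAULT_OCCLUSION_DURATION_S = 120.0


class WindowEmptyError(ValueError):
    """A metric window contains no valid frames."""


@dataclass
class OcclusionSeries:
    """Spatially averaged sO2 per frame with per-frame validity flags."""

    timestamps: np.ndarray
    so2: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.so2 = np.asarray(self.so2, dtype=np.float64)
        if self.valid is None:
            self.valid = np.isfinite(self.so2)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.timestamps) == len(self.so2) == len(self.valid)):
            raise ValueError("timestamps, so2 and valid must be equal length")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        ok = self.valid & np.isfinite(self.so2)
        if np.any((self.so2[ok] < 0) | (self.so2[ok] > 1)):
            raise ValueError("valid sO2 values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class OcclusionEvents:
    """Cuff-on / cuff-off / end times (seconds) of one challenge."""

    cuff_on: float
    cuff_off: float
    series_end: float

    def __post_init__(self) -> None:
        if not (0 < self.cuff_on < self.cuff_off < self.series_end):
            raise ValueError(
                "event times must satisfy 0 < cuff_on < cuff_off < series_end"
            )


@dataclass(frozen=True)
class OcclusionMetrics:
    """Baseline mean, occlusion minimum and post-release maximum sO2."""

    baseline_so2: float
    min_so2: float
    max_so2: float
    t_min: float
    t_max: float


def extract_series(
    cubes: Sequence[MultispectralCube],
    timestamps: Sequence[float],
    roi_mask: np.ndarray,
    design: np.ndarray,
    noise_floor: float,
) -> OcclusionSeries:
    """Mean ROI sO2 per frame, unmixing each cube independently.

    Frames where no ROI voxel clears the noise floor (or whose mean is
    non-finite) are flagged invalid; the series keeps its full length.
    """
    if len(cubes) != len(timestamps):
        raise ValueError("one timestamp per cube is required")
    if len(cubes) == 0:
        raise ValueError("empty cube sequence")
    ref = cubes[0]
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != ref.spatial_shape:
        raise ValueError("ROI mask shape must match the cubes")
    values = np.full(len(cubes), np.nan)
    valid = np.zeros(len(cubes), dtype=bool)
    for i, cube in enumerate(cubes):
        if cube.geometry != ref.geometry or cube.wavelengths != ref.wavelengths:
            raise ValueError(
                f"frame {i} geometry/wavelengths differ from frame 0"
            )
        maps: ChromophoreMaps = unmix_pseudo_inverse(cube, design)
        mask = noise_floor_mask(maps, noise_floor) & roi_mask
        omap = compute_so2(maps, mask)
        if not omap.valid_mask.any():
            logger.warning("frame %d: no voxels above noise floor; flagged", i)
            continue
        mean = float(omap.so2[omap.valid_mask].mean())
        if np.isfinite(mean):
            values[i] = mean
            valid[i] = True
        else:
            logger.warning("frame %d: non-finite mean sO2; flagged", i)
    return OcclusionSeries(np.asarray(timestamps, float), values, valid)


def moving_median(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Centred moving median with edge shrinkage (no padding values invented)."""
    values = np.asarray(values, dtype=np.float64)
    half = window // 2
    out = np.empty_like(values)
    for i in range(len(values)):
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        out[i] = np.median(values[lo:hi])
    return out


def occlusion_metrics(
    series: OcclusionSeries,
    events: OcclusionEvents,
    smooth: bool = False,
    smooth_window: int = 3,
) -> OcclusionMetrics:
    """Window statistics of one occlusion challenge.

    baseline = mean over valid frames in [0, cuff_on); min over
    [cuff_on, cuff_off); max over [cuff_off, series_end]. Optional moving-
    median smoothing (off by default) is applied before the extrema only.
    """
    t = series.timestamps
    vals = series.so2.copy()
    if smooth:
        finite = series.valid & np.isfinite(vals)
        smoothed = vals.copy()
        if finite.any():
            sm = moving_median(vals[finite], smooth_window)
            smoothed[finite] = sm
        vals = smoothed

    windows = {
        "baseline": (t >= 0) & (t < events.cuff_on),
        "occlusion": (t >= events.cuff_on) & (t < events.cuff_off),
        "release": (t >= events.cuff_off) & (t <= events.series_end),
    }
    stats: dict[str, np.ndarray] = {}
    times: dict[str, np.ndarray] = {}
    for name, in_window in windows.items():
        sel = in_window & series.valid
        if not sel.any():
            raise WindowEmptyError(
                f"{name} window contains no valid frames"
            )
        stats[name] = vals[sel]
        times[name] = t[sel]

    i_min = int(np.argmin(stats["occlusion"]))
    i_max = int(np.argmax(stats["release"]))
    return OcclusionMetrics(
        baseline_so2=float(stats["baseline"].mean()),
        min_so2=float(stats["occlusion"][i_min]),
        max_so2=float(stats["release"][i_max]),
        t_min=float(times["occlusion"][i_min]),
        t_max=float(times["release"][i_max]),
    )
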
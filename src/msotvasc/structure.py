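"""Vessel segmentation by moment-preserving thresholding and volumetry.

The threshold is chosen by the moment-preserving (Tsai) criterion: find the
two-level image that preserves the first three raw moments of the intensity
histogram, which fixes the below-level fraction p0; the threshold is then
the p0-quantile of the histogram. Voxels are kept by a strict ``>``
comparison (the cut-off value itself is truncated). Vascular volume is the
above-threshold voxel count times the physical voxel volume.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import VoxelGeometry

__all__ = [
    "IntensityHistogram",
    "VesselMask",
    "VolumeResult",
    "DegenerateHistogramError",
    "moment_preserving_threshold",
    "apply_threshold",
    "vascular_volume",
    "mean_over_fingers",
]

logger = logging.getLogger(__name__)

#: Default bin count for continuous data (8-bit convention).
DEFAULT_BINS = 256


class DegenerateHistogramError(ValueError):
    """Histogram has zero variance; no threshold separates anything."""


@dataclass
class IntensityHistogram:
    """Binned intensities: ``counts[i]`` falls in ``[bin_edges[i], bin_edges[i+1])``."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.counts = np.asarray(self.counts)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @classmethod
    def from_volume(
        cls, volume: np.ndarray, bins: int = DEFAULT_BINS
    ) -> "IntensityHistogram":
        """Equal-width binning over [min, max] of the data."""
        data = np.asarray(volume, dtype=np.float64).ravel()
        if data.size == 0:
            raise ValueError("empty volume")
        lo, hi = float(data.min()), float(data.max())
        if lo == hi:
            raise DegenerateHistogramError(
                "constant volume: histogram has zero variance"
            )
        counts, edges = np.histogram(data, bins=bins, range=(lo, hi))
        return cls(bin_edges=edges, counts=counts)

    @classmethod
    def from_levels(
        cls, values: np.ndarray, n_levels: int = 256
    ) -> "IntensityHistogram":
        """Histogram of integer levels 0..n_levels-1 with unit-width bins
        centred on each level (edges at half-integers)."""
        values = np.asarray(values).ravel()
        counts = np.bincount(values.astype(int), minlength=n_levels)
        edges = np.arange(n_levels + 1) - 0.5
        return cls(bin_edges=edges, counts=counts)

    def raw_moments(self) -> tuple[float, float, float]:
        """First three raw moments m1, m2, m3 over bin centres."""
        total = self.total
        if total < 1:
            raise ValueError("histogram is empty")
        p = self.counts / total
        x = self.bin_centers
        return (
            float(np.sum(p * x)),
            float(np.sum(p * x**2)),
            float(np.sum(p * x**3)),
        )

    def quantile_bin(self, p: float) -> int:
        """Smallest bin index whose left-continuous empirical CDF is >= p."""
        cdf = np.cumsum(self.counts) / self.total
        return int(np.argmax(cdf >= p - 1e-12))


def moment_preserving_fraction(hist: IntensityHistogram) -> float:
    """Below-level fraction p0 preserving the first three raw moments.

    Solves the 2 x 2 linear system for the auxiliary coefficients (c0, c1),
    takes the two representative levels z0 < z1 as the roots of
    z^2 + c1 z + c0 = 0, and returns p0 = (z1 - m1) / (z1 - z0).
    """
    m1, m2, m3 = hist.raw_moments()
    cd = m2 - m1 * m1  # variance of the binned data
    if cd <= 1e-12 * max(1.0, m2):
        raise DegenerateHistogramError(
            "histogram variance is zero: moment-preserving threshold is "
            "undefined"
        )
    c0 = (m1 * m3 - m2 * m2) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc <= 0:
        raise DegenerateHistogramError(
            "moment system has no two distinct representative levels"
        )
    z0 = 0.5 * (-c1 - math.sqrt(disc))
    z1 = 0.5 * (-c1 + math.sqrt(disc))
    return (z1 - m1) / (z1 - z0)


def moment_preserving_threshold(hist: IntensityHistogram) -> float:
    """Intensity cut-off at the p0-quantile of the histogram.

    Returns the upper edge of the selected bin, so that a strict ``>``
    comparison truncates the whole bin (tie-break: smallest bin whose CDF
    reaches p0).
    """
    p0 = moment_preserving_fraction(hist)
    idx = hist.quantile_bin(p0)
    return float(hist.bin_edges[idx + 1])


@dataclass
class VesselMask:
    """Binary segmentation with the threshold that produced it."""

    mask: np.ndarray
    threshold_used: float
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.geometry.shape:
            raise ValueError("mask shape must match geometry shape")


@dataclass(frozen=True)
class VolumeResult:
    """Above-threshold voxel count and its physical volume."""

    n_voxels: int
    voxel_volume_mm3: float
    total_volume_mm3: float


def apply_threshold(
    volume: np.ndarray, threshold: float, geometry: VoxelGeometry
) -> VesselMask:
    """Keep voxels with intensity strictly greater than ``threshold``."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    volume = np.asarray(volume, dtype=np.float64)
    return VesselMask(
        mask=volume > threshold, threshold_used=float(threshold),
        geometry=geometry,
    )


def vascular_volume(mask: VesselMask) -> VolumeResult:
    """Voxels above threshold multiplied by the voxel volume (mm^3)."""
    n = int(mask.mask.sum())
    vv = mask.geometry.voxel_volume_mm3
    return VolumeResult(
        n_voxels=n, voxel_volume_mm3=vv, total_volume_mm3=n * vv
    )


def mean_over_fingers(values: Sequence[float | None]) -> float:
    """Arithmetic mean over up to 8 per-finger values.

    Missing fingers (None or NaN) are excluded with a logged warning; an
    all-missing input is an error.
    """
    present = [
        float(v)
        for v in values
        if v is not None and np.isfinite(v)
    ]
    n_missing = len(list(values)) - len(present)
    if n_missing:
        logger.warning("%d missing finger value(s) excluded", n_missing)
    if not present:
        raise ValueError("all finger values missing: cannot average")
    return float(np.mean(present))
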
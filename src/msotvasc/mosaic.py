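"""Full-depth projections and whole-finger mosaic stitching.

Volumes are compressed to 2-D by maximum-intensity projection along depth
(sum projection available behind a flag). Consecutive projection frames
overlap as the probe slides along the finger; pairwise offsets are estimated
by normalised cross-correlation along the travel axis, unreliable pairs are
imputed with the median reliable offset and flagged, and overlapping pixels
are blended by per-pixel maximum. Stitching is best-effort and qualitative:
no quantitative measures are derived from mosaics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ProjectionFrame",
    "FrameSequence",
    "Mosaic",
    "StitchError",
    "project_cube",
    "estimate_offset",
    "stitch",
]

logger = logging.getLogger(__name__)

#: Pairs with peak correlation below this are considered unreliable.
DEFAULT_RELIABILITY_THRESHOLD = 0.5


class StitchError(RuntimeError):
    """No reliable pairwise overlap could be found."""


@dataclass
class ProjectionFrame:
    """One 2-D projection in an ordered sequence.

    ``nominal_offset`` is the true offset in pixels along the travel axis
    when known (synthetic data); None for acquired frames.
    """

    image: np.ndarray
    index: int
    nominal_offset: int | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 2:
            raise ValueError("projection frames must be 2-D")


@dataclass
class FrameSequence:
    """Ordered overlapping projection frames; travel along ``acquisition_axis``."""

    frames: list[ProjectionFrame]
    acquisition_axis: int = 0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("frame sequence is empty")
        shape = self.frames[0].image.shape
        if any(f.image.shape != shape for f in self.frames):
            raise ValueError("all frames in a sequence must share shape")
        if self.acquisition_axis not in (0, 1):
            raise ValueError("acquisition_axis must be 0 or 1")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def true_offsets(self) -> np.ndarray | None:
        offs = [f.nominal_offset for f in self.frames]
        if any(o is None for o in offs):
            return None
        return np.asarray(offs, dtype=int)


@dataclass
class Mosaic:
    """Stitched image with per-frame offsets and pairwise overlap scores."""

    image: np.ndarray
    offsets: np.ndarray
    overlap_scores: np.ndarray
    imputed_pairs: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))


def project_cube(volume: np.ndarray, method: str = "max") -> np.ndarray:
    """Compress a single-wavelength 3-D volume along depth to a 2-D image.

    ``method`` is "max" (maximum-intensity projection, default) or "sum".
    The depth axis is the last axis.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError("expected a single-wavelength 3-D volume")
    if method == "max":
        return volume.max(axis=-1)
    if method == "sum":
        return volume.sum(axis=-1)
    raise ValueError(f"unknown projection method {method!r}")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def estimate_offset(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    max_shift: int,
    axis: int = 0,
) -> tuple[int, float]:
    """Offset of ``frame_b`` relative to ``frame_a`` along the travel axis.

    Scans integer shifts 0..max_shift maximising the Pearson correlation of
    the overlapping region; returns ``(offset, peak_correlation)``. Frame b
    is assumed downstream of frame a (forward probe travel).
    """
    a = np.asarray(frame_a, dtype=np.float64)
    b = np.asarray(frame_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("frames must share shape")
    if axis == 1:
        a, b = a.T, b.T
    n = a.shape[0]
    if not (0 <= max_shift < n):
        raise ValueError(
            f"search range {max_shift} exceeds frame extent {n} along the "
            "travel axis"
        )
    best_shift, best_score = 0, -np.inf
    for s in range(max_shift + 1):
        score = _pearson(a[s:], b[: n - s] if s else b)
        if score > best_score:
            best_shift, best_score = s, score
    return best_shift, best_score


def stitch(
    sequence: FrameSequence,
    reliability_threshold: float = DEFAULT_RELIABILITY_THRESHOLD,
    max_shift: int | None = None,
    manual_offsets: Sequence[int] | None = None,
) -> Mosaic:
    """Stitch an ordered overlapping sequence into one mosaic.

    Pairwise offsets come from :func:`estimate_offset`; pairs whose peak
    correlation falls below ``reliability_threshold`` receive the median of
    the reliable offsets and are flagged in ``imputed_pairs``. Overlapping
    pixels are combined by per-pixel maximum. ``manual_offsets`` (one
    per-pair step, length n_frames - 1) bypasses estimation entirely.
    """
    frames = [
        f.image if sequence.acquisition_axis == 0 else f.image.T
        for f in sequence.frames
    ]
    n_frames = len(frames)
    if n_frames == 1:
        return Mosaic(
            image=frames[0].copy(),
            offsets=np.zeros(1, dtype=int),
            overlap_scores=np.zeros(0),
        )
    frame_len = frames[0].shape[0]
    if max_shift is None:
        max_shift = frame_len - 1

    if manual_offsets is not None:
        steps = np.asarray(manual_offsets, dtype=int)
        if len(steps) != n_frames - 1:
            raise ValueError("need one manual offset per consecutive pair")
        scores = np.full(n_frames - 1, np.nan)
        imputed = np.zeros(n_frames - 1, dtype=bool)
    else:
        steps = np.zeros(n_frames - 1, dtype=int)
        scores = np.zeros(n_frames - 1)
        for i in range(n_frames - 1):
            steps[i], scores[i] = estimate_offset(
                frames[i], frames[i + 1], max_shift=max_shift
            )
        reliable = scores >= reliability_threshold
        if not reliable.any():
            raise StitchError(
                "no frame pair has a reliable overlap; supply manual offsets"
            )
        imputed = ~reliable
        if imputed.any():
            median_step = int(round(float(np.median(steps[reliable]))))
            logger.warning(
                "%d unreliable pair(s); imputing median offset %d",
                int(imputed.sum()),
                median_step,
            )
            steps[imputed] = median_step

    offsets = np.concatenate([[0], np.cumsum(steps)])
    extent = int(offsets[-1]) + frame_len
    width = frames[0].shape[1]
    canvas = np.full((extent, width), -np.inf)
    for off, frame in zip(offsets, frames):
        region = canvas[off : off + frame_len]
        np.maximum(region, frame, out=region)
    canvas[~np.isfinite(canvas)] = 0.0
    if sequence.acquisition_axis == 1:
        canvas = canvas.T
    return Mosaic(
        image=canvas,
        offsets=offsets,
        overlap_scores=scores,
        imputed_pairs=imputed,
    )
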
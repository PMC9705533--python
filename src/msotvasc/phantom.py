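"""Seeded synthetic data with known ground truth.

Three generators mirror the three acquisition modes of the pipeline:

* :func:`make_finger_phantom` — a multispectral cube containing cylindrical
  digital "arteries" with prescribed Hb/HbO2 concentrations, depth-dependent
  exponential fluence decay and additive Gaussian noise;
* :func:`make_occlusion_series` — a baseline / occlusion-trough /
  hyperaemic-peak sO2 time-course;
* :func:`make_frame_sequence` — overlapping 2-D projection frames cropped
  from a truth image at a constant step.

The forward signal model is single-scatter and depth-only:

    intensity(lambda, voxel) = exp(-k * depth_mm) * ln(10)
        * (eps_hb(lambda) * [Hb] + eps_hbo2(lambda) * [HbO2])
        + background + noise

with no acoustic propagation or bandlimiting — analysis starts from
reconstructed cubes, so the phantom does too. Concentrations and intensities
are in arbitrary units. Identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DEFAULT_GEOMETRY, MultispectralCube, VoxelGeometry
from .dynamics import OcclusionEvents, OcclusionSeries
from .mosaic import FrameSequence, ProjectionFrame
from .unmixing import (
    LN10,
    ConfigurationError,
    ExtinctionTable,
    load_default_extinction_table,
)

__all__ = [
    "VesselSpec",
    "PhantomSpec",
    "GroundTruth",
    "make_finger_phantom",
    "occlusion_trajectory",
    "make_occlusion_series",
    "make_vessel_truth_image",
    "make_frame_sequence",
    "DEFAULT_WAVELENGTHS_NM",
]

#: Acquisition wavelengths for oxygenation cubes (nm).
DEFAULT_WAVELENGTHS_NM = (700.0, 730.0, 760.0, 800.0, 850.0)


@dataclass(frozen=True)
class VesselSpec:
    """A straight cylindrical vessel segment with known chromophore content.

    ``axis_start`` / ``axis_end`` are 3-D points in mm (voxel-centre
    coordinate frame); ``radius_mm`` > 0. Concentrations are arbitrary
    units, non-negative and not both zero.
    """

    axis_start: tuple[float, float, float]
    axis_end: tuple[float, float, float]
    radius_mm: float
    hb: float
    hbo2: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("vessel radius must be > 0")
        if self.hb < 0 or self.hbo2 < 0:
            raise ValueError("concentrations must be >= 0")
        if self.hb + self.hbo2 == 0:
            raise ValueError("hb and hbo2 cannot both be zero")

    @property
    def true_so2(self) -> float:
        """Ground-truth saturation [HbO2] / ([Hb] + [HbO2])."""
        return self.hbo2 / (self.hb + self.hbo2)


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to generate one multispectral phantom cube."""

    geometry: VoxelGeometry = DEFAULT_GEOMETRY
    vessels: tuple[VesselSpec, ...] = ()
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS_NM
    fluence_decay_per_mm: float = 0.0
    noise_sigma: float = 0.0
    background_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "vessels", tuple(self.vessels))
        object.__setattr__(
            self, "wavelengths", tuple(float(w) for w in self.wavelengths)
        )
        wl = np.asarray(self.wavelengths)
        if wl.size == 0:
            raise ConfigurationError("wavelength list must be non-empty")
        if np.any(np.diff(wl) <= 0):
            raise ConfigurationError("wavelengths must be strictly increasing")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.fluence_decay_per_mm < 0:
            raise ConfigurationError("fluence_decay_constant must be >= 0")


@dataclass
class GroundTruth:
    """Voxel-level truth accompanying a generated phantom cube."""

    hb_map: np.ndarray
    hbo2_map: np.ndarray
    so2_map: np.ndarray  # NaN where hb + hbo2 == 0
    vessel_mask: np.ndarray
    total_vessel_volume_mm3: float


def _segment_mask(
    geometry: VoxelGeometry, vessel: VesselSpec
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Voxel-centre-inside-radius rasterisation, restricted to a bounding box."""
    a = np.asarray(vessel.axis_start, dtype=np.float64)
    b = np.asarray(vessel.axis_end, dtype=np.float64)
    r = vessel.radius_mm
    spacing = np.asarray(geometry.spacing_mm)
    lo = np.minimum(a, b) - r
    hi = np.maximum(a, b) + r
    # voxel i covers [i*s, (i+1)*s); clamp to the grid
    i_lo = np.maximum(np.floor(lo / spacing).astype(int) - 1, 0)
    i_hi = np.minimum(
        np.ceil(hi / spacing).astype(int) + 1, np.asarray(geometry.shape)
    )
    if np.any(i_lo >= i_hi):
        empty = (slice(0, 0), slice(0, 0), slice(0, 0))
        return empty, np.zeros((0, 0, 0), dtype=bool)
    box = tuple(slice(int(l), int(h)) for l, h in zip(i_lo, i_hi))
    centers = [
        geometry.axis_centers_mm(ax)[box[ax]].astype(np.float64)
        for ax in range(3)
    ]
    px = centers[0][:, None, None]
    py = centers[1][None, :, None]
    pz = centers[2][None, None, :]
    d = b - a
    len2 = float(d @ d)
    if len2 == 0.0:
        dist2 = (px - a[0]) ** 2 + (py - a[1]) ** 2 + (pz - a[2]) ** 2
        return box, dist2 <= r * r
    # finite cylinder: perpendicular distance to the axis line, restricted
    # to the axial span (no hemispherical end caps, so the voxelised volume
    # converges to pi * r^2 * L)
    t = ((px - a[0]) * d[0] + (py - a[1]) * d[1] + (pz - a[2]) * d[2]) / len2
    dist2 = (
        (px - (a[0] + t * d[0])) ** 2
        + (py - (a[1] + t * d[1])) ** 2
        + (pz - (a[2] + t * d[2])) ** 2
    )
    return box, (dist2 <= r * r) & (t >= 0.0) & (t <= 1.0)


def make_finger_phantom(
    spec: PhantomSpec, table: ExtinctionTable | None = None
) -> tuple[MultispectralCube, GroundTruth]:
    """Generate one multispectral cube plus its voxel-level ground truth.

    Vessels are rasterised by voxel-centre inclusion; where vessels overlap,
    later entries in ``spec.vessels`` take precedence. An empty vessel list
    is valid and yields a background + noise cube.
    """
    if table is None:
        table = load_default_extinction_table()
    design = table.interpolate(spec.wavelengths)
    shape = spec.geometry.shape
    hb_map = np.zeros(shape)
    hbo2_map = np.zeros(shape)
    vessel_mask = np.zeros(shape, dtype=bool)
    for vessel in spec.vessels:
        box, inside = _segment_mask(spec.geometry, vessel)
        if inside.size == 0:
            continue
        hb_map[box][inside] = vessel.hb
        hbo2_map[box][inside] = vessel.hbo2
        vessel_mask[box] |= inside

    total = hb_map + hbo2_map
    so2_map = np.full(shape, np.nan)
    np.divide(hbo2_map, total, out=so2_map, where=total > 0)

    depth_mm = spec.geometry.axis_centers_mm(2)
    fluence = np.exp(-spec.fluence_decay_per_mm * depth_mm)  # (nz,)
    # absorption per wavelength: ln(10) * (eps_hb*[Hb] + eps_hbo2*[HbO2])
    mu = LN10 * (
        hb_map[..., None] * design[:, 0] + hbo2_map[..., None] * design[:, 1]
    )
    cube_data = mu * fluence[None, None, :, None] + spec.background_level
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        cube_data = cube_data + rng.normal(
            0.0, spec.noise_sigma, size=cube_data.shape
        )
    cube = MultispectralCube(
        intensities=cube_data,
        geometry=spec.geometry,
        wavelengths=spec.wavelengths,
    )
    truth = GroundTruth(
        hb_map=hb_map,
        hbo2_map=hbo2_map,
        so2_map=so2_map,
        vessel_mask=vessel_mask,
        total_vessel_volume_mm3=float(
            vessel_mask.sum() * spec.geometry.voxel_volume_mm3
        ),
    )
    return cube, truth


# fractions of each window spent ramping vs holding the extremum; the holds
# guarantee the sampled extrema equal the specified trough/peak exactly
_OCC_RAMP_FRAC = 0.7
_REL_RISE_FRAC = 0.2
_REL_HOLD_FRAC = 0.2


def occlusion_trajectory(
    t: np.ndarray,
    baseline_so2: float,
    trough_so2: float,
    peak_so2: float,
    events: OcclusionEvents,
) -> np.ndarray:
    """Noiseless sO2 trajectory: flat baseline, decay to a trough plateau
    during occlusion, rise to a peak plateau on release, then relaxation
    back toward baseline."""
    t = np.asarray(t, dtype=np.float64)
    out = np.full(t.shape, float(baseline_so2))

    def ramp(u, x0, x1):
        return x0 + (x1 - x0) * 0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0, 1)))

    occ = (t >= events.cuff_on) & (t < events.cuff_off)
    u = (t[occ] - events.cuff_on) / (events.cuff_off - events.cuff_on)
    out[occ] = np.where(
        u < _OCC_RAMP_FRAC,
        ramp(u / _OCC_RAMP_FRAC, baseline_so2, trough_so2),
        trough_so2,
    )

    rel = t >= events.cuff_off
    v = (t[rel] - events.cuff_off) / (events.series_end - events.cuff_off)
    rise = ramp(v / _REL_RISE_FRAC, trough_so2, peak_so2)
    hold_end = _REL_RISE_FRAC + _REL_HOLD_FRAC
    relax = baseline_so2 + (peak_so2 - baseline_so2) * np.exp(
        -(v - hold_end) / _REL_HOLD_FRAC
    )
    out[rel] = np.where(
        v < _REL_RISE_FRAC,
        rise,
        np.where(v < hold_end, peak_so2, relax),
    )
    return out


def make_occlusion_series(
    baseline_so2: float,
    trough_so2: float,
    peak_so2: float,
    events: OcclusionEvents,
    sample_interval_s: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> OcclusionSeries:
    """Seeded occlusion-challenge sO2 series sampled on a regular grid."""
    if not (0 <= trough_so2 <= baseline_so2 <= 1):
        raise ConfigurationError(
            "require 0 <= trough_so2 <= baseline_so2 <= 1"
        )
    if not (0 <= peak_so2 <= 1):
        raise ConfigurationError("peak_so2 must lie in [0, 1]")
    if noise_sigma < 0:
        raise ConfigurationError("noise_sigma must be >= 0")
    t = np.arange(0.0, events.series_end + 1e-9, float(sample_interval_s))
    for name, lo, hi in (
        ("baseline", 0.0, events.cuff_on),
        ("occlusion", events.cuff_on, events.cuff_off),
        ("release", events.cuff_off, events.series_end + 1e-9),
    ):
        if not np.any((t >= lo) & (t < hi)):
            raise ConfigurationError(
                f"sample interval too coarse: {name} window has no samples"
            )
    values = occlusion_trajectory(
        t, baseline_so2, trough_so2, peak_so2, events
    )
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        values = np.clip(
            values + rng.normal(0.0, noise_sigma, size=values.shape), 0.0, 1.0
        )
    return OcclusionSeries(timestamps=t, so2=values)


def make_vessel_truth_image(
    shape: tuple[int, int] = (1600, 96),
    n_vessels: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """A synthetic whole-finger projection: bright sinuous vessel tracks on a
    textured background, varying along the travel axis (axis 0)."""
    from scipy.ndimage import gaussian_filter

    h, w = shape
    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.normal(0.0, 1.0, size=shape), sigma=3.0)
    img = 0.05 * (img - img.min()) / (np.ptp(img) + 1e-12)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    for _ in range(n_vessels):
        c0 = rng.uniform(0.2 * w, 0.8 * w)
        amp = rng.uniform(0.05 * w, 0.15 * w)
        period = rng.uniform(0.2 * h, 0.6 * h)
        phase = rng.uniform(0, 2 * np.pi)
        width = rng.uniform(1.5, 3.5)
        center = c0 + amp * np.sin(2 * np.pi * rows / period + phase)
        brightness = 0.7 + 0.3 * np.sin(
            2 * np.pi * rows / rng.uniform(0.1 * h, 0.3 * h) + phase
        )
        img += brightness * np.exp(-((cols - center) ** 2) / (2 * width**2))
    return img


def make_frame_sequence(
    mosaic_truth: np.ndarray,
    n_frames: int,
    frame_width: int,
    step: int,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> FrameSequence:
    """Crop an ordered, overlapping frame sequence from a truth image.

    Frame ``i`` is ``mosaic_truth[i*step : i*step + frame_width]`` (travel
    along axis 0) plus seeded Gaussian noise; the true offset ``i*step`` is
    recorded on each frame. Requires ``step < frame_width`` so consecutive
    frames overlap.
    """
    truth = np.asarray(mosaic_truth, dtype=np.float64)
    if truth.ndim != 2:
        raise ValueError("mosaic truth must be a 2-D image")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if step < 0:
        raise ConfigurationError("step must be >= 0")
    if step >= frame_width:
        raise ConfigurationError(
            f"step ({step}) must be smaller than frame_width ({frame_width}) "
            "so that adjacent frames overlap"
        )
    needed = (n_frames - 1) * step + frame_width
    if needed > truth.shape[0]:
        raise ConfigurationError(
            f"sequence needs {needed} rows but the truth image has only "
            f"{truth.shape[0]}"
        )
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_frames):
        off = i * step
        crop = truth[off : off + frame_width].copy()
        if noise_sigma > 0:
            crop += rng.normal(0.0, noise_sigma, size=crop.shape)
        frames.append(ProjectionFrame(image=crop, index=i, nominal_offset=off))
    return FrameSequence(frames=frames, acquisition_axis=0)
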
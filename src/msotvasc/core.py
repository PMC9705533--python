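"""Shared geometry and cube containers used by every pipeline stage.

Spatial units are millimetres internally; micrometre spacings are accepted
at construction and converted. Voxel indices are 0-based and voxel-centre
referenced: the centre of voxel ``i`` along an axis with spacing ``s`` sits
at ``(i + 0.5) * s``. The depth axis is ``z``, increasing away from the
probe. Cubes are stored in canonical ``(x, y, z, wavelength)`` order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelGeometry",
    "MultispectralCube",
    "DEFAULT_GEOMETRY",
    "UM_PER_MM",
]

UM_PER_MM = 1000.0


@dataclass(frozen=True)
class VoxelGeometry:
    """Voxel spacing and grid shape of a reconstructed volume.

    Parameters
    ----------
    lateral_spacing_um:
        Voxel edge length in micrometres along both in-plane axes (x, y).
    depth_spacing_um:
        Voxel edge length in micrometres along the depth axis (z).
    shape:
        Voxel counts ``(nx, ny, nz)``.
    """

    lateral_spacing_um: float
    depth_spacing_um: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not (self.lateral_spacing_um > 0 and self.depth_spacing_um > 0):
            raise ValueError("voxel spacings must be strictly positive")
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError("shape must be three voxel counts, each >= 1")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        """Per-axis voxel spacing ``(sx, sy, sz)`` in mm."""
        lat = self.lateral_spacing_um / UM_PER_MM
        return (lat, lat, self.depth_spacing_um / UM_PER_MM)

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of one voxel in mm^3."""
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical edge lengths of the whole grid in mm."""
        sx, sy, sz = self.spacing_mm
        nx, ny, nz = self.shape
        return (nx * sx, ny * sy, nz * sz)

    @property
    def voxel_diagonal_um(self) -> float:
        """Euclidean diagonal of a single voxel in micrometres."""
        return math.sqrt(
            2.0 * self.lateral_spacing_um**2 + self.depth_spacing_um**2
        )

    def axis_centers_mm(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along one axis (0=x, 1=y, 2=z), in mm."""
        s = self.spacing_mm[axis]
        return (np.arange(self.shape[axis]) + 0.5) * s


#: 2 x 2 x 1 cm reconstruction at 80 um lateral / 50 um depth spacing.
DEFAULT_GEOMETRY = VoxelGeometry(
    lateral_spacing_um=80.0, depth_spacing_um=50.0, shape=(250, 250, 200)
)


@dataclass
class MultispectralCube:
    """A 4-D intensity volume with its geometry and wavelength axis.

    ``intensities`` has shape ``(nx, ny, nz, n_wavelengths)`` in arbitrary
    intensity units; ``wavelengths`` are in nm, strictly increasing.
    """

    intensities: np.ndarray
    geometry: VoxelGeometry
    wavelengths: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.wavelengths = tuple(float(w) for w in self.wavelengths)
        if self.intensities.ndim != 4:
            raise ValueError("cube must be 4-D (x, y, z, wavelength)")
        if self.intensities.shape[:3] != self.geometry.shape:
            raise ValueError(
                f"spatial shape {self.intensities.shape[:3]} does not match "
                f"geometry shape {self.geometry.shape}"
            )
        if self.intensities.shape[3] != len(self.wavelengths):
            raise ValueError(
                "wavelength axis length does not match wavelength list"
            )
        wl = np.asarray(self.wavelengths)
        if len(wl) and np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("cube intensities must all be finite")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[:3]

    @property
    def n_wavelengths(self) -> int:
        return self.intensities.shape[3]

    def volume_at(self, wavelength: float) -> np.ndarray:
        """Single-wavelength 3-D volume; wavelength must be present exactly."""
        try:
            idx = self.wavelengths.index(float(wavelength))
        except ValueError:
            raise ValueError(
                f"wavelength {wavelength} nm not in cube "
                f"(available: {self.wavelengths})"
            ) from None
        return self.intensities[..., idx]
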
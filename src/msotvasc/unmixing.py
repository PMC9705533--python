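"""Linear spectral unmixing of multispectral cubes into Hb/HbO2 and sO2.

Per voxel, the measured spectrum is modelled as a linear combination of the
two haemoglobin extinction spectra. The least-squares solution is obtained
with the Moore-Penrose pseudo-inverse of the (n_wavelengths x 2) design
matrix. Negative concentrations are retained by the solver and clamped to
zero only when oxygen saturation is computed, which guarantees sO2 in
[0, 1]. A noise floor on total haemoglobin masks voxels whose signal cannot
be distinguished from background.

Concentrations, intensities and sO2 are all in arbitrary (uncalibrated)
units.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

from .core import MultispectralCube

__all__ = [
    "ExtinctionTable",
    "ChromophoreMaps",
    "OxygenationMap",
    "load_default_extinction_table",
    "build_design_matrix",
    "unmix_pseudo_inverse",
    "noise_floor_mask",
    "auto_noise_floor",
    "compute_so2",
    "mean_so2",
]

LN10 = float(np.log(10.0))


class ConfigurationError(ValueError):
    """Invalid analysis configuration (bad wavelengths, thresholds, ...)."""


@dataclass(frozen=True)
class ExtinctionTable:
    """Tabulated molar absorption of Hb and HbO2 on a wavelength grid.

    The grid must be strictly increasing with strictly positive
    coefficients; between 760 and 850 nm the two spectra cross (the
    isosbestic point of haemoglobin, near 800 nm).
    """

    wavelengths: np.ndarray
    eps_hb: np.ndarray
    eps_hbo2: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=np.float64)
        hb = np.asarray(self.eps_hb, dtype=np.float64)
        hbo2 = np.asarray(self.eps_hbo2, dtype=np.float64)
        if not (wl.shape == hb.shape == hbo2.shape) or wl.ndim != 1:
            raise ValueError("table columns must be equal-length 1-D arrays")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(hb <= 0) or np.any(hbo2 <= 0):
            raise ValueError("extinction coefficients must be positive")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "eps_hb", hb)
        object.__setattr__(self, "eps_hbo2", hbo2)

    @property
    def range_nm(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def interpolate(self, wavelengths_nm) -> np.ndarray:
        """(n, 2) array of (eps_hb, eps_hbo2) rows, linearly interpolated."""
        wl = np.atleast_1d(np.asarray(wavelengths_nm, dtype=np.float64))
        lo, hi = self.range_nm
        bad = wl[(wl < lo) | (wl > hi)]
        if bad.size:
            raise ConfigurationError(
                f"wavelength(s) {bad.tolist()} nm outside the extinction "
                f"table range [{lo}, {hi}] nm"
            )
        hb = np.interp(wl, self.wavelengths, self.eps_hb)
        hbo2 = np.interp(wl, self.wavelengths, self.eps_hbo2)
        return np.column_stack([hb, hbo2])

    def isosbestic_wavelength(self) -> float:
        """Wavelength where eps_hb and eps_hbo2 cross, by linear interpolation.

        Searches the 700-900 nm window so the method returns the
        near-infrared isosbestic point used for structural imaging.
        """
        sel = (self.wavelengths >= 700.0) & (self.wavelengths <= 900.0)
        wl = self.wavelengths[sel]
        diff = self.eps_hb[sel] - self.eps_hbo2[sel]
        sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
        if sign_change.size == 0:
            raise ValueError("no isosbestic crossing in 700-900 nm")
        i = int(sign_change[0])
        # linear root of diff between grid points i and i+1
        t = diff[i] / (diff[i] - diff[i + 1])
        return float(wl[i] + t * (wl[i + 1] - wl[i]))

    @classmethod
    def from_tsv(cls, path) -> "ExtinctionTable":
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line[0].isalpha():
                continue  # blank, comment or header line
            rows.append([float(x) for x in line.split()])
        body = np.asarray(rows, dtype=np.float64)
        return cls(body[:, 0], body[:, 1], body[:, 2])


@lru_cache(maxsize=1)
def load_default_extinction_table() -> ExtinctionTable:
    """The bundled 650-900 nm Hb/HbO2 molar-absorption table."""
    ref = resources.files("msotvasc").joinpath("data/hb_extinction.tsv")
    with resources.as_file(ref) as path:
        return ExtinctionTable.from_tsv(path)


def build_design_matrix(table: ExtinctionTable, wavelengths) -> np.ndarray:
    """Design matrix with row i = (eps_hb(lambda_i), eps_hbo2(lambda_i)).

    Requires at least two distinct wavelengths (otherwise the two-chromophore
    system is underdetermined), each inside the table's grid range.
    """
    wl = np.atleast_1d(np.asarray(wavelengths, dtype=np.float64))
    if np.unique(wl).size < 2:
        raise ConfigurationError(
            "at least 2 distinct wavelengths are required to unmix two "
            "chromophores"
        )
    return table.interpolate(wl)


@dataclass
class ChromophoreMaps:
    """Per-voxel unmixed concentrations and least-squares residual norm."""

    hb: np.ndarray
    hbo2: np.ndarray
    residual: np.ndarray

    def __post_init__(self) -> None:
        if not (self.hb.shape == self.hbo2.shape == self.residual.shape):
            raise ValueError("map shapes must agree")

    @property
    def total(self) -> np.ndarray:
        """Total haemoglobin [Hb] + [HbO2] (may be negative pre-clamp)."""
        return self.hb + self.hbo2


@dataclass
class OxygenationMap:
    """Per-voxel sO2 with a validity mask; sO2 is NaN where invalid."""

    so2: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.so2.shape != self.valid_mask.shape:
            raise ValueError("so2 and valid_mask shapes must agree")


def _check_design(design: np.ndarray) -> np.ndarray:
    design = np.asarray(design, dtype=np.float64)
    if design.ndim != 2 or design.shape[1] != 2:
        raise ValueError("design matrix must be (n_wavelengths, 2)")
    if np.linalg.matrix_rank(design) < 2:
        raise ValueError(
            "design matrix is rank deficient: the eps_hb and eps_hbo2 "
            "columns are collinear at the requested wavelengths"
        )
    return design


def unmix_pseudo_inverse(
    cube: MultispectralCube | np.ndarray, design: np.ndarray
) -> ChromophoreMaps:
    """Solve (hb, hbo2) = pinv(design) @ spectrum for every voxel.

    Works on a :class:`MultispectralCube` or a bare array whose last axis is
    the wavelength axis. Negative solutions are retained; clamping is
    deferred to :func:`compute_so2`. The residual is the Euclidean norm of
    ``design @ (hb, hbo2) - spectrum`` per voxel.
    """
    design = _check_design(design)
    data = cube.intensities if isinstance(cube, MultispectralCube) else cube
    data = np.asarray(data, dtype=np.float64)
    if data.shape[-1] != design.shape[0]:
        raise ValueError(
            f"cube has {data.shape[-1]} wavelengths but design has "
            f"{design.shape[0]} rows"
        )
    spatial = data.shape[:-1]
    spectra = data.reshape(-1, design.shape[0])  # (n_voxels, n_wl)
    coeffs = spectra @ np.linalg.pinv(design).T  # (n_voxels, 2)
    resid = np.linalg.norm(spectra - coeffs @ design.T, axis=1)
    return ChromophoreMaps(
        hb=coeffs[:, 0].reshape(spatial),
        hbo2=coeffs[:, 1].reshape(spatial),
        residual=resid.reshape(spatial),
    )


def noise_floor_mask(maps: ChromophoreMaps, floor: float) -> np.ndarray:
    """Voxels whose total-haemoglobin signal strictly exceeds ``floor``."""
    if floor < 0:
        raise ConfigurationError("noise floor must be >= 0")
    return maps.total > floor


def auto_noise_floor(
    maps: ChromophoreMaps, background_mask: np.ndarray, n_sd: float = 3.0
) -> float:
    """Noise floor as mean + ``n_sd``*SD of total-Hb in a background region."""
    background_mask = np.asarray(background_mask, dtype=bool)
    if background_mask.shape != maps.total.shape:
        raise ValueError("background mask shape must match the maps")
    if not background_mask.any():
        raise ConfigurationError("background region is empty")
    vals = maps.total[background_mask]
    return float(vals.mean() + n_sd * vals.std())


def compute_so2(
    maps: ChromophoreMaps, valid_mask: np.ndarray | None = None
) -> OxygenationMap:
    """sO2 = [HbO2] / ([Hb] + [HbO2]) with negatives clamped to zero.

    Voxels whose clamped total haemoglobin is zero are removed from the
    valid mask; sO2 is NaN wherever invalid.
    """
    if valid_mask is None:
        valid_mask = np.ones(maps.hb.shape, dtype=bool)
    valid_mask = np.asarray(valid_mask, dtype=bool)
    if valid_mask.shape != maps.hb.shape:
        raise ValueError("valid_mask shape must match the maps")
    hb = np.maximum(maps.hb, 0.0)
    hbo2 = np.maximum(maps.hbo2, 0.0)
    total = hb + hbo2
    valid = valid_mask & (total > 0)
    so2 = np.full(hb.shape, np.nan)
    np.divide(hbo2, total, out=so2, where=valid)
    return OxygenationMap(so2=so2, valid_mask=valid)


def mean_so2(omap: OxygenationMap) -> float:
    """Arithmetic mean sO2 over the valid voxels."""
    if not omap.valid_mask.any():
        raise ValueError("no valid voxels: cannot average sO2")
    return float(omap.so2[omap.valid_mask].mean())
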
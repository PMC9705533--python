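"""Volumetric and tabular I/O, pipeline configuration and run manifests.

Supported cube formats: multi-page TIFF (JSON sidecar for geometry and
wavelengths), NIfTI (spacings in the header, wavelengths in the sidecar)
and HDF5 (self-describing attributes). Axis order is normalised to the
canonical ``(x, y, z, wavelength)`` on read; files may declare a different
stored order via the sidecar/attribute ``axes`` string (a permutation of
"XYZW"). Spatial units are mm internally; spacings are stored in µm.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import MultispectralCube, VoxelGeometry
from .dynamics import OcclusionEvents, OcclusionSeries

__all__ = [
    "write_cube",
    "read_cube",
    "write_mask",
    "write_series",
    "read_series",
    "PipelineConfig",
    "RunManifest",
    "sha256_of",
]

CANONICAL_AXES = "XYZW"


class FormatError(IOError):
    """File cannot be interpreted as a multispectral cube."""


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz") or name.endswith(".nii"):
        return "nii"
    if name.endswith(".tif") or name.endswith(".tiff"):
        return "tif"
    if name.endswith(".h5") or name.endswith(".hdf5"):
        return "h5"
    raise FormatError(f"unsupported cube format: {path.name}")


def _axes_permutation(axes: str) -> list[int]:
    axes = axes.upper()
    if sorted(axes) != sorted(CANONICAL_AXES):
        raise FormatError(
            f"axes declaration {axes!r} must be a permutation of "
            f"{CANONICAL_AXES!r}"
        )
    # position of each canonical axis in the stored order
    return [axes.index(c) for c in CANONICAL_AXES]


def write_cube(cube: MultispectralCube, path) -> Path:
    """Write a cube in the format implied by the file extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = _suffix(path)
    meta = {
        "lateral_spacing_um": cube.geometry.lateral_spacing_um,
        "depth_spacing_um": cube.geometry.depth_spacing_um,
        "shape": list(cube.geometry.shape),
        "wavelengths_nm": list(cube.wavelengths),
        "axes": CANONICAL_AXES,
    }
    if fmt == "tif":
        import tifffile

        tifffile.imwrite(
            path,
            cube.intensities.astype(np.float32),
            photometric="minisblack",
        )
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    elif fmt == "nii":
        import nibabel as nib

        sx, sy, sz = cube.geometry.spacing_mm
        affine = np.diag([sx, sy, sz, 1.0])
        img = nib.Nifti1Image(cube.intensities.astype(np.float64), affine)
        img.header.set_zooms((sx, sy, sz, 1.0))
        nib.save(img, str(path))
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    else:  # h5
        import h5py

        with h5py.File(path, "w") as f:
            ds = f.create_dataset("intensities", data=cube.intensities)
            for k, v in meta.items():
                ds.attrs[k] = v
    return path


def read_cube(path) -> MultispectralCube:
    """Read a cube, normalising stored axis order to ``(x, y, z, lambda)``.

    TIFF and NIfTI require the JSON sidecar written by :func:`write_cube`
    (TIFF carries no wavelength metadata of its own); HDF5 is
    self-describing. A declared wavelength count that disagrees with the
    stored wavelength axis is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _suffix(path)
    if fmt == "h5":
        import h5py

        with h5py.File(path, "r") as f:
            if "intensities" not in f:
                raise FormatError(f"{path}: no 'intensities' dataset")
            ds = f["intensities"]
            data = np.asarray(ds)
            meta = {k: ds.attrs[k] for k in ds.attrs}
    else:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FormatError(
                f"{path}: missing metadata sidecar {sidecar.name} declaring "
                "geometry and wavelengths"
            )
        meta = json.loads(sidecar.read_text())
        if fmt == "tif":
            import tifffile

            data = np.asarray(tifffile.imread(path), dtype=np.float64)
        else:
            import nibabel as nib

            data = np.asarray(nib.load(str(path)).get_fdata())

    try:
        wavelengths = [float(w) for w in meta["wavelengths_nm"]]
        lateral = float(meta["lateral_spacing_um"])
        depth = float(meta["depth_spacing_um"])
        axes = str(meta.get("axes", CANONICAL_AXES))
    except KeyError as exc:
        raise FormatError(f"{path}: metadata missing key {exc}") from None

    if data.ndim != 4:
        raise FormatError(f"{path}: expected 4-D data, got {data.ndim}-D")
    data = np.transpose(data, _axes_permutation(axes))
    if data.shape[3] != len(wavelengths):
        raise FormatError(
            f"{path}: metadata declares {len(wavelengths)} wavelengths but "
            f"the stored wavelength axis has length {data.shape[3]}"
        )
    geometry = VoxelGeometry(
        lateral_spacing_um=lateral,
        depth_spacing_um=depth,
        shape=data.shape[:3],
    )
    return MultispectralCube(
        intensities=np.ascontiguousarray(data, dtype=np.float64),
        geometry=geometry,
        wavelengths=tuple(wavelengths),
    )


def write_mask(mask: np.ndarray, path) -> Path:
    """Write a binary mask as an 8-bit (0/255) multi-page TIFF."""
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))
    return path


def write_series(series: OcclusionSeries, path) -> Path:
    """Occlusion series as CSV with columns timestamp_s, so2, valid."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "timestamp_s": series.timestamps,
            "so2": series.so2,
            "valid": series.valid.astype(int),
        }
    ).to_csv(path, index=False)
    return path


def read_series(path) -> OcclusionSeries:
    df = pd.read_csv(path)
    return OcclusionSeries(
        timestamps=df["timestamp_s"].to_numpy(),
        so2=df["so2"].to_numpy(),
        valid=df["valid"].to_numpy().astype(bool),
    )


@dataclass
class PipelineConfig:
    """Validated parameters for the end-to-end synthetic-cohort run.

    Every stage's parameters are checked at load time, before any
    computation, so an invalid configuration produces no partial outputs.
    """

    seed: int = 0
    output_dir: str = "run"
    n_hc: int = 32
    n_ssc: int = 22
    n_ssc_isch: int = 6
    n_occlusion_hc: int = 17
    n_occlusion_ssc: int = 10
    grid_shape: tuple[int, int, int] = (40, 40, 24)
    lateral_spacing_um: float = 80.0
    depth_spacing_um: float = 50.0
    wavelengths_nm: tuple[float, ...] = (700.0, 730.0, 760.0, 800.0, 850.0)
    hc_so2_mean: float = 0.381
    ssc_so2_mean: float = 0.373
    so2_between_subject_sd: float = 0.006
    so2_between_finger_sd: float = 0.002
    noise_fraction_of_peak: float = 0.02
    cuff_on_s: float = 60.0
    cuff_off_s: float = 180.0
    series_end_s: float = 300.0
    occlusion_sample_interval_s: float = 2.0
    occlusion_noise_sigma: float = 0.003
    mwu_mode: str = "asymptotic"

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.wavelengths_nm = tuple(float(w) for w in self.wavelengths_nm)
        # constructing the stage objects runs every precondition check
        self.geometry  # noqa: B018
        self.events  # noqa: B018
        for name in ("n_hc", "n_ssc", "n_occlusion_hc", "n_occlusion_ssc"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.n_ssc_isch <= self.n_ssc:
            raise ValueError("n_ssc_isch must lie in [0, n_ssc]")
        if self.n_occlusion_hc > self.n_hc or self.n_occlusion_ssc > self.n_ssc:
            raise ValueError("occlusion subset larger than the group")
        for name in (
            "so2_between_subject_sd",
            "so2_between_finger_sd",
            "noise_fraction_of_peak",
            "occlusion_noise_sigma",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("hc_so2_mean", "ssc_so2_mean"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.mwu_mode not in ("auto", "exact", "asymptotic"):
            raise ValueError("mwu_mode must be auto/exact/asymptotic")

    @property
    def geometry(self) -> VoxelGeometry:
        return VoxelGeometry(
            lateral_spacing_um=self.lateral_spacing_um,
            depth_spacing_um=self.depth_spacing_um,
            shape=self.grid_shape,
        )

    @property
    def events(self) -> OcclusionEvents:
        return OcclusionEvents(
            cuff_on=self.cuff_on_s,
            cuff_off=self.cuff_off_s,
            series_end=self.series_end_s,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; "
                f"known keys: {sorted(known)}"
            )
        return cls(**raw)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        data = asdict(self)
        data["grid_shape"] = list(self.grid_shape)
        data["wavelengths_nm"] = list(self.wavelengths_nm)
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    software_version: str
    output_checksums: dict[str, str] = field(default_factory=dict)
    started_utc: str = ""
    finished_utc: str = ""

    @staticmethod
    def now() -> str:
        return datetime.now(timezone.utc).isoformat()

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=1, sort_keys=True))
        return path
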
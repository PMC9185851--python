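"""Shared data model and file I/O for the imaging pipeline.

Conventions used throughout the package:

* arrays are indexed ``(x, y, z)`` for volumes and ``(x, y, z, q)`` for
  series, where ``q`` runs over the acquisition axis (saturation delay TI,
  diffusion weighting b, or dynamic frame time);
* voxel indices are 0-based and all masks and maps live on the anatomical
  reference grid unless explicitly resampled;
* invalid voxels are ``valid_mask=False`` in memory and NaN on disk;
* volumes are stored as NIfTI-1 with a diagonal affine built from the voxel
  size, and acquisition metadata travels in a JSON sidecar (canonical keys:
  ``axis_tags``, ``series_kind``, ``flip_angle_deg``, ``tr_ms``, ``te_ms``,
  ``baseline_frame_count``, ``relaxivity_r1``).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGeometry",
    "ImageSeries",
    "AcquisitionParams",
    "ParameterMap",
    "RoiMask",
    "SERIES_KINDS",
    "MAP_UNITS",
    "ConfigurationError",
    "ShapeError",
    "GeometryError",
    "read_image_series",
    "write_image_series",
    "read_parameter_map",
    "write_parameter_map",
    "read_roi_mask",
    "write_roi_mask",
    "read_sidecar",
    "get_logger",
]

SERIES_KINDS = ("saturation_recovery", "diffusion", "dynamic", "anatomical")

#: canonical output units per map kind
MAP_UNITS = {"T1": "ms", "ADC": "1e-6 mm^2/s", "iAUC60": "mmol*s/L"}

_LOG_FORMAT = "%(asctime)s %(levelname)s %(name)s: %(message)s"


def get_logger(name: str = "sarcomap") -> logging.Logger:
    """Package logger writing structured lines to stderr."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
        logger.propagate = False
    return logger


class ConfigurationError(ValueError):
    """Missing or inconsistent sidecar/config metadata."""


class ShapeError(ValueError):
    """Array extent does not match the declared acquisition structure."""


class GeometryError(ValueError):
    """Grids do not share a compatible spatial frame."""


@dataclass(frozen=True)
class VoxelGeometry:
    """Voxel size (mm) and grid shape of a 3-D volume."""

    voxel_size_mm: tuple[float, float, float]
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.voxel_size_mm) != 3 or len(self.grid_shape) != 3:
            raise ShapeError("geometry must be 3-D")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel dimensions must be > 0, got {self.voxel_size_mm}")
        if any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError(f"grid shape must be positive, got {self.grid_shape}")
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))

    @property
    def slice_count(self) -> int:
        return self.grid_shape[2]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical field of view along each axis."""
        return tuple(s * v for s, v in zip(self.grid_shape, self.voxel_size_mm))

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        return aff


@dataclass
class ImageSeries:
    """A stack of co-registered 3-D volumes with per-volume acquisition tags.

    ``axis_tags`` holds TI in ms (saturation recovery), b in s/mm^2
    (diffusion) or frame time in s (dynamic).
    """

    data: np.ndarray
    geometry: VoxelGeometry
    axis_tags: np.ndarray
    series_kind: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.axis_tags = np.asarray(self.axis_tags, dtype=float)
        if self.series_kind not in SERIES_KINDS:
            raise ConfigurationError(
                f"series_kind must be one of {SERIES_KINDS}, got {self.series_kind!r}"
            )
        if self.data.ndim != 4:
            raise ShapeError(f"series data must be 4-D, got shape {self.data.shape}")
        if tuple(self.data.shape[:3]) != self.geometry.grid_shape:
            raise ShapeError(
                f"data grid {self.data.shape[:3]} does not match geometry "
                f"{self.geometry.grid_shape}"
            )
        if self.axis_tags.ndim != 1 or len(self.axis_tags) != self.data.shape[3]:
            raise ShapeError(
                f"{len(self.axis_tags)} axis tags for {self.data.shape[3]} volumes"
            )
        if self.series_kind in ("saturation_recovery", "dynamic"):
            if np.any(np.diff(self.axis_tags) <= 0):
                raise ConfigurationError(
                    f"{self.series_kind} axis tags must be strictly increasing"
                )
        finite = self.data[np.isfinite(self.data)]
        if finite.size and finite.min() < 0:
            raise ValueError("signal values must be >= 0")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class AcquisitionParams:
    """Sequence parameters needed for signal-to-concentration conversion.

    ``relaxivity_r1`` is the contrast agent's longitudinal relaxivity in
    L·mmol⁻¹·s⁻¹ (gadobutrol at 1.5 T defaults to 5.0, configurable — the
    value is assay-specific configuration, not a fit parameter).
    """

    flip_angle_deg: float = 16.0
    tr_ms: float = 2.63
    te_ms: float = 0.81
    relaxivity_r1: float = 5.0
    baseline_frame_count: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.flip_angle_deg < 90:
            raise ValueError("flip angle must be in (0, 90) degrees")
        if self.tr_ms <= 0:
            raise ValueError("TR must be > 0")
        if self.relaxivity_r1 <= 0:
            raise ValueError("relaxivity must be > 0")
        if self.baseline_frame_count < 1:
            raise ValueError("baseline_frame_count must be >= 1")


@dataclass
class ParameterMap:
    """Per-voxel scalar map (T1, ADC or iAUC60) with a validity mask."""

    values: np.ndarray
    units: str
    valid_mask: np.ndarray
    map_kind: str
    geometry: VoxelGeometry | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.ndim != 3:
            raise ShapeError("parameter map must be 3-D")
        if self.values.shape != self.valid_mask.shape:
            raise ShapeError("values and valid_mask shapes differ")
        if self.map_kind not in MAP_UNITS:
            raise ConfigurationError(f"unknown map kind {self.map_kind!r}")
        if self.units != MAP_UNITS[self.map_kind]:
            raise ConfigurationError(
                f"units {self.units!r} inconsistent with map kind {self.map_kind!r} "
                f"(expected {MAP_UNITS[self.map_kind]!r})"
            )
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("values must be finite wherever valid_mask is true")

    @classmethod
    def from_values(
        cls, values: np.ndarray, map_kind: str, valid_mask: np.ndarray | None = None,
        geometry: VoxelGeometry | None = None,
    ) -> "ParameterMap":
        values = np.asarray(values, dtype=float)
        if valid_mask is None:
            valid_mask = np.isfinite(values)
        return cls(values=values, units=MAP_UNITS[map_kind], valid_mask=valid_mask,
                   map_kind=map_kind, geometry=geometry)

    def masked_values(self) -> np.ndarray:
        """Values with invalid voxels replaced by NaN."""
        out = self.values.copy()
        out[~self.valid_mask] = np.nan
        return out


@dataclass
class RoiMask:
    """Binary tumour mask on a named reference grid."""

    mask: np.ndarray
    geometry: VoxelGeometry
    label: str = "tumour"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ShapeError("ROI mask must be 3-D")
        if tuple(self.mask.shape) != self.geometry.grid_shape:
            raise ShapeError(
                f"mask shape {self.mask.shape} does not match geometry "
                f"{self.geometry.grid_shape}"
            )
        if not self.mask.any():
            get_logger().warning("ROI %r is empty", self.label)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# sidecar + NIfTI I/O

def read_sidecar(path: str | Path, required: Sequence[str] = ()) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"sidecar not found: {path}")
    with open(path) as fh:
        meta = json.load(fh)
    missing = [k for k in required if k not in meta]
    if missing:
        raise ConfigurationError(f"sidecar {path} missing keys: {missing}")
    return meta


def _geometry_from_img(img: nib.Nifti1Image) -> VoxelGeometry:
    zooms = img.header.get_zooms()[:3]
    return VoxelGeometry(tuple(float(z) for z in zooms), tuple(int(s) for s in img.shape[:3]))


def read_image_series(path: str | Path, sidecar: str | Path) -> ImageSeries:
    """Load a 4-D NIfTI plus its JSON sidecar into an :class:`ImageSeries`.

    The sidecar must provide ``axis_tags`` and ``series_kind``; a tag count
    that disagrees with the 4th-dimension extent is rejected.
    """
    meta = read_sidecar(sidecar, required=("axis_tags", "series_kind"))
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        raise ShapeError(f"{path}: expected a 4-D series, got a 3-D volume")
    if data.ndim != 4:
        raise ShapeError(f"{path}: expected 4-D data, got {data.ndim}-D")
    return ImageSeries(
        data=data,
        geometry=_geometry_from_img(img),
        axis_tags=np.asarray(meta["axis_tags"], dtype=float),
        series_kind=meta["series_kind"],
    )


def write_image_series(series: ImageSeries, path: str | Path,
                       sidecar: str | Path | None = None,
                       extra_meta: dict | None = None) -> None:
    img = nib.Nifti1Image(series.data.astype(np.float64), series.geometry.affine())
    img.header.set_zooms(series.geometry.voxel_size_mm + (1.0,))
    nib.save(img, str(path))
    if sidecar is not None:
        meta = {
            "axis_tags": [float(t) for t in series.axis_tags],
            "series_kind": series.series_kind,
        }
        if extra_meta:
            meta.update(extra_meta)
        with open(sidecar, "w") as fh:
            json.dump(meta, fh, indent=1)


def write_parameter_map(pmap: ParameterMap, path: str | Path,
                        sidecar: str | Path | None = None) -> None:
    """Write a parameter map as NIfTI; invalid voxels become NaN on disk."""
    geometry = pmap.geometry
    if geometry is None:
        geometry = VoxelGeometry((1.0, 1.0, 1.0), pmap.values.shape)
    img = nib.Nifti1Image(pmap.masked_values().astype(np.float64), geometry.affine())
    img.header.set_zooms(geometry.voxel_size_mm)
    nib.save(img, str(path))
    if sidecar is None:
        sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii.gz
        sidecar = Path(str(sidecar) + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"map_kind": pmap.map_kind, "units": pmap.units}, fh, indent=1)


def read_parameter_map(path: str | Path, sidecar: str | Path | None = None) -> ParameterMap:
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    if sidecar is None:
        candidate = Path(str(path)).with_suffix("").with_suffix("")
        sidecar = Path(str(candidate) + ".json")
    meta = read_sidecar(sidecar, required=("map_kind", "units"))
    return ParameterMap(
        values=values,
        units=meta["units"],
        valid_mask=np.isfinite(values),
        map_kind=meta["map_kind"],
        geometry=_geometry_from_img(img),
    )


def write_roi_mask(roi: RoiMask, path: str | Path) -> None:
    img = nib.Nifti1Image(roi.mask.astype(np.uint8), roi.geometry.affine())
    img.header.set_zooms(roi.geometry.voxel_size_mm)
    nib.save(img, str(path))


def read_roi_mask(path: str | Path, label: str = "tumour") -> RoiMask:
    img = nib.load(str(path))
    mask = np.asarray(img.dataobj) > 0
    return RoiMask(mask=mask, geometry=_geometry_from_img(img), label=label)
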
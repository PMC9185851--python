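"""Tumour ROI handling: grid transfer, in-plane erosion, volume, summaries.

ROIs are outlined on the anatomical T2-weighted reference and transferred to
the functional grids by nearest-neighbour resampling. Before summary
statistics are taken the mask is eroded in-plane by one pixel (3x3
4-connected cross, slice by slice) to suppress partial-volume voxels at the
tumour edge; tumour volume is computed on the uneroded outline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import GeometryError, ParameterMap, RoiMask, VoxelGeometry, get_logger

__all__ = ["RoiSummary", "EmptyRoiError", "transfer_roi", "erode_roi",
           "roi_volume_cm3", "summarise_roi"]

log = get_logger(__name__)

# 2-D 4-connected cross, applied per slice ("in-plane by one pixel")
_CROSS_2D = ndimage.generate_binary_structure(2, 1)


class EmptyRoiError(ValueError):
    """Raised when a summary is requested over zero valid voxels."""


@dataclass
class RoiSummary:
    """Whole-ROI median / interquartile summary of one parameter map."""

    median: float
    iqr_low: float   # 25th percentile
    iqr_high: float  # 75th percentile
    n_voxels: int
    volume_cm3: float


def transfer_roi(roi: RoiMask, target_geometry: VoxelGeometry,
                 offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> RoiMask:
    """Nearest-neighbour resampling of a binary mask onto another grid.

    Both grids are assumed corner-aligned in a shared physical frame (the
    study acquires all series over the same field of view); a field-of-view
    mismatch beyond one source voxel raises :class:`GeometryError`.
    ``offset_mm`` applies a rigid translation of the target frame relative
    to the source, standing in for landmark-based realignment.
    """
    src = roi.geometry
    if src == target_geometry:
        return RoiMask(roi.mask.copy(), target_geometry, roi.label)
    for es, et, vs in zip(src.extent_mm, target_geometry.extent_mm, src.voxel_size_mm):
        if abs(es - et) > vs + 1e-6:
            raise GeometryError(
                f"field of view mismatch: source {src.extent_mm} vs "
                f"target {target_geometry.extent_mm}"
            )
    out = np.zeros(target_geometry.grid_shape, dtype=bool)
    idx = [None] * 3
    for ax in range(3):
        centres = (np.arange(target_geometry.grid_shape[ax]) + 0.5) \
            * target_geometry.voxel_size_mm[ax] + offset_mm[ax]
        src_idx = np.floor(centres / src.voxel_size_mm[ax]).astype(int)
        idx[ax] = np.clip(src_idx, 0, src.grid_shape[ax] - 1)
        # remember which targets fell outside the source grid
        idx[ax] = np.where((src_idx < 0) | (src_idx >= src.grid_shape[ax]), -1, idx[ax])
    ii, jj, kk = np.meshgrid(idx[0], idx[1], idx[2], indexing="ij")
    inside = (ii >= 0) & (jj >= 0) & (kk >= 0)
    out[inside] = roi.mask[ii[inside], jj[inside], kk[inside]]
    return RoiMask(out, target_geometry, roi.label)


def erode_roi(roi: RoiMask) -> RoiMask:
    """One-pixel in-plane erosion, slice by slice, 4-connected.

    The result is always a subset of the input; an empty result is allowed
    (and logged) — single-voxel or thread-like ROIs vanish.
    """
    eroded = np.zeros_like(roi.mask)
    for z in range(roi.mask.shape[2]):
        eroded[:, :, z] = ndimage.binary_erosion(
            roi.mask[:, :, z], structure=_CROSS_2D, border_value=0)
    if roi.mask.any() and not eroded.any():
        log.warning("ROI %r empty after erosion", roi.label)
    return RoiMask(eroded, roi.geometry, roi.label)


def roi_volume_cm3(roi: RoiMask) -> float:
    """Tumour volume from voxel count and the known voxel size."""
    return roi.n_voxels * roi.geometry.voxel_volume_mm3 / 1000.0


def summarise_roi(pmap: ParameterMap, roi: RoiMask) -> RoiSummary:
    """Median and interquartile range over the valid in-ROI voxels.

    Percentiles use linear interpolation between order statistics (the
    type-7 convention, numpy's default). Raises :class:`EmptyRoiError` when
    no valid voxel lies inside the ROI.
    """
    if pmap.values.shape != roi.mask.shape:
        raise GeometryError("ROI grid does not match map grid")
    sel = roi.mask & pmap.valid_mask
    vals = pmap.values[sel]
    if vals.size == 0:
        raise EmptyRoiError(f"no valid voxels in ROI {roi.label!r}")
    q25, q50, q75 = np.percentile(vals, [25.0, 50.0, 75.0])
    geom = pmap.geometry if pmap.geometry is not None else roi.geometry
    return RoiSummary(
        median=float(q50), iqr_low=float(q25), iqr_high=float(q75),
        n_voxels=int(vals.size),
        volume_cm3=float(vals.size * geom.voxel_volume_mm3 / 1000.0),
    )
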
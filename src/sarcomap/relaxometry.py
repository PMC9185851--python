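"""Saturation-recovery T1 mapping.

The forward model is the ideal two-parameter saturation-recovery signal

    S(TI) = S0 * (1 - exp(-TI / T1))

fitted voxel-by-voxel by bounded nonlinear least squares over the acquired
saturation delays TI. Voxels whose peak signal falls below a configurable
floor (a fraction of the volume's 99th-percentile signal) are skipped, and
voxels that fail to converge or pin against the T1 bounds are marked
invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core import ImageSeries, ParameterMap, get_logger

__all__ = ["SrFitOptions", "SrFitResult", "sr_signal", "fit_t1_voxel", "fit_t1_map"]

log = get_logger(__name__)


@dataclass(frozen=True)
class SrFitOptions:
    """Controls for the per-voxel T1 fit.

    ``signal_floor_frac`` is relative to the 99th percentile of the series'
    maximum-over-TI image; ``bounds_margin`` is the relative distance from a
    T1 bound below which an estimate is treated as pinned (hence invalid).
    """

    t1_bounds_ms: tuple[float, float] = (10.0, 10000.0)
    t1_init_ms: float = 1000.0
    signal_floor_frac: float = 0.05
    max_iter: int = 200
    xtol: float = 1e-10
    bounds_margin: float = 1e-3


@dataclass
class SrFitResult:
    """Per-voxel saturation-recovery fit outcome."""

    t1_ms: float
    s0: float
    residual_norm: float
    converged: bool


def sr_signal(t1_ms: float, s0: float, tis_ms: np.ndarray) -> np.ndarray:
    """Ideal saturation-recovery signal at the given saturation delays.

    Strictly increasing in TI and bounded by ``s0``.
    """
    tis_ms = np.asarray(tis_ms, dtype=float)
    if t1_ms <= 0:
        raise ValueError(f"T1 must be > 0, got {t1_ms}")
    if tis_ms.size == 0 or np.any(tis_ms <= 0):
        raise ValueError("TIs must be non-empty and > 0")
    return s0 * (1.0 - np.exp(-tis_ms / t1_ms))


def fit_t1_voxel(signal: np.ndarray, tis_ms: np.ndarray,
                 options: SrFitOptions = SrFitOptions()) -> SrFitResult:
    """Bounded nonlinear least-squares fit of (T1, S0) for one voxel."""
    signal = np.asarray(signal, dtype=float)
    tis_ms = np.asarray(tis_ms, dtype=float)
    lo, hi = options.t1_bounds_ms
    s0_init = max(float(signal.max()), 1e-12)

    def resid(theta):
        t1, s0 = theta
        return s0 * (1.0 - np.exp(-tis_ms / t1)) - signal

    def jac(theta):
        t1, s0 = theta
        e = np.exp(-tis_ms / t1)
        return np.column_stack([-s0 * e * tis_ms / t1**2, 1.0 - e])

    sol = least_squares(
        resid, x0=[options.t1_init_ms, s0_init], jac=jac,
        bounds=([lo, 0.0], [hi, np.inf]),
        xtol=options.xtol, ftol=options.xtol, gtol=None,
        max_nfev=options.max_iter * 2,
    )
    t1, s0 = sol.x
    pinned = (t1 - lo) < options.bounds_margin * lo or (hi - t1) < options.bounds_margin * hi
    return SrFitResult(
        t1_ms=float(t1), s0=float(s0),
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success) and not pinned,
    )


def fit_t1_map(series: ImageSeries, options: SrFitOptions = SrFitOptions(),
               roi_mask: np.ndarray | None = None
               ) -> tuple[ParameterMap, dict[str, np.ndarray]]:
    """Pixel-by-pixel T1 map from a saturation-recovery series.

    Returns the T1 :class:`ParameterMap` (ms) together with auxiliary maps
    (``s0``, ``residual_norm``, ``converged``). Requires at least 3 TIs.
    ``roi_mask`` optionally restricts the fit to a subset of voxels.
    """
    if series.series_kind != "saturation_recovery":
        raise ValueError(f"expected saturation_recovery series, got {series.series_kind}")
    if series.n_volumes < 3:
        raise ValueError("T1 fitting needs at least 3 saturation delays")

    tis = series.axis_tags
    data = series.data
    shape = data.shape[:3]
    peak = data.max(axis=3)
    floor = options.signal_floor_frac * np.percentile(peak, 99.0)
    candidates = peak > floor
    if roi_mask is not None:
        candidates &= np.asarray(roi_mask, dtype=bool)

    t1 = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    resid = np.full(shape, np.nan)
    conv = np.zeros(shape, dtype=bool)

    idx = np.argwhere(candidates)
    for ix, iy, iz in idx:
        res = fit_t1_voxel(data[ix, iy, iz, :], tis, options)
        t1[ix, iy, iz] = res.t1_ms
        s0[ix, iy, iz] = res.s0
        resid[ix, iy, iz] = res.residual_norm
        conv[ix, iy, iz] = res.converged

    valid = conv.copy()
    t1_out = np.where(valid, t1, np.nan)
    n_fit, n_valid = len(idx), int(valid.sum())
    if n_fit:
        log.info("T1 fit: %d voxels attempted, %d valid", n_fit, n_valid)
    pmap = ParameterMap.from_values(t1_out, "T1", valid_mask=valid,
                                    geometry=series.geometry)
    return pmap, {"s0": s0, "residual_norm": resid, "converged": conv}
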
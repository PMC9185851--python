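"""Mono-exponential ADC mapping from multi-b diffusion-weighted series.

The signal model is S(b) = S0 * exp(-b * D). ADC is reported in
10^-6 mm^2/s throughout (so D = 1000 here means 1.0 x 10^-3 mm^2/s). The
default estimator is a weighted log-linear least-squares fit (weights equal
to squared signal, which makes the log-domain fit first-order equivalent to
nonlinear least squares in the signal domain); a direct nonlinear fit is
provided for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import ImageSeries, ParameterMap, get_logger

__all__ = ["AdcFitOptions", "AdcFitResult", "adc_signal", "fit_adc_voxel_nonlinear",
           "fit_adc_map"]

log = get_logger(__name__)

ADC_SCALE = 1e-6  # package ADC unit in mm^2/s


@dataclass(frozen=True)
class AdcFitOptions:
    """``bvals_use``: 'all' or an explicit subset of b-values to fit."""

    bvals_use: str | tuple[float, ...] = "all"


@dataclass
class AdcFitResult:
    adc: float  # 10^-6 mm^2/s
    s0: float
    r_squared: float


def adc_signal(adc: float, s0: float, bvals: np.ndarray) -> np.ndarray:
    """Mono-exponential DWI signal; ``adc`` in 10^-6 mm^2/s, b in s/mm^2."""
    bvals = np.asarray(bvals, dtype=float)
    if adc < 0:
        raise ValueError(f"ADC must be >= 0, got {adc}")
    if np.any(bvals < 0):
        raise ValueError("b-values must be >= 0")
    return s0 * np.exp(-bvals * adc * ADC_SCALE)


def _select_bvals(tags: np.ndarray, options: AdcFitOptions) -> np.ndarray:
    if options.bvals_use == "all":
        return np.ones(len(tags), dtype=bool)
    wanted = np.asarray(options.bvals_use, dtype=float)
    sel = np.isin(tags, wanted)
    if sel.sum() != len(wanted):
        raise ValueError(f"requested b-values {wanted} not all present in {tags}")
    return sel


def fit_adc_voxel_nonlinear(signal: np.ndarray, bvals: np.ndarray) -> AdcFitResult:
    """Direct nonlinear least squares in the signal domain (cross-check path)."""
    signal = np.asarray(signal, dtype=float)
    bvals = np.asarray(bvals, dtype=float)
    s0_init = max(float(signal[np.argmin(bvals)]), 1e-12)
    # log-linear start
    y = np.log(np.clip(signal, 1e-12, None))
    slope = np.polyfit(bvals, y, 1)[0]
    d_init = max(-slope, 1e-12)

    def resid(theta):
        d, s0 = theta
        return s0 * np.exp(-bvals * d) - signal

    sol = least_squares(resid, x0=[d_init, s0_init],
                        bounds=([0.0, 0.0], [np.inf, np.inf]), xtol=1e-12, ftol=1e-12)
    d, s0 = sol.x
    pred = s0 * np.exp(-bvals * d)
    ss_res = float(np.sum((signal - pred) ** 2))
    ss_tot = float(np.sum((signal - signal.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return AdcFitResult(adc=float(d / ADC_SCALE), s0=float(s0),
                        r_squared=float(np.clip(r2, 0.0, 1.0)))


def fit_adc_map(series: ImageSeries, options: AdcFitOptions = AdcFitOptions()
                ) -> ParameterMap:
    """Weighted log-linear ADC map (10^-6 mm^2/s) over the selected b-values.

    Weights are the squared signals, compensating the log transform's noise
    amplification at high b. Voxels with any nonpositive signal at a fitted
    b-value are masked invalid rather than clipped, as are (noise-driven)
    negative ADC estimates.
    """
    if series.series_kind != "diffusion":
        raise ValueError(f"expected diffusion series, got {series.series_kind}")
    sel = _select_bvals(series.axis_tags, options)
    bvals = series.axis_tags[sel]
    if len(np.unique(bvals)) < 2:
        raise ValueError("ADC fitting needs at least 2 distinct b-values")

    data = series.data[..., sel]
    shape = data.shape[:3]
    flat = data.reshape(-1, len(bvals))
    positive = np.all(flat > 0, axis=1)

    adc = np.full(flat.shape[0], np.nan)
    valid = np.zeros(flat.shape[0], dtype=bool)
    if positive.any():
        s = flat[positive]
        y = np.log(s)
        w = s ** 2
        # weighted straight-line fit y = a + b*bval, vectorised over voxels
        sw = w.sum(axis=1)
        swx = (w * bvals).sum(axis=1)
        swy = (w * y).sum(axis=1)
        swxx = (w * bvals**2).sum(axis=1)
        swxy = (w * bvals * y).sum(axis=1)
        denom = sw * swxx - swx**2
        slope = (sw * swxy - swx * swy) / denom
        d = -slope / ADC_SCALE
        # exact zero decay (constant signal) is valid ADC=0; negatives are noise
        d[np.abs(d) < 1e-9] = 0.0
        adc[positive] = d
        valid[positive] = d >= 0.0

    adc = adc.reshape(shape)
    valid = valid.reshape(shape)
    adc_out = np.where(valid, adc, np.nan)
    log.info("ADC fit: %d voxels valid of %d", int(valid.sum()), flat.shape[0])
    return ParameterMap.from_values(adc_out, "ADC", valid_mask=valid,
                                    geometry=series.geometry)
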
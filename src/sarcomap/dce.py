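"""Dynamic contrast-enhanced MRI: concentration conversion and iAUC60.

Signal is converted to gadolinium concentration through the spoiled
gradient-echo (SPGR) steady-state equation

    S = M0 * sin(a) * (1 - E1) / (1 - E1 * cos(a)),   E1 = exp(-TR / T1)

with per-voxel M0 calibrated from the pre-injection baseline signal and the
baseline T1 map, and the contrast agent acting through

    R1(t) = R1(0) + r1 * C(t).

The inversion for E1 is closed-form (monotone rational function), so the
conversion is exact up to floating point. The semi-quantitative perfusion
metric is the initial area under the concentration curve over the first
60 s from bolus arrival, by trapezoidal integration with the final partial
interval linearly interpolated to exactly 60 s. T2* attenuation is
neglected (TE is sub-millisecond for the dynamic sequence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AcquisitionParams, ImageSeries, ParameterMap, RoiMask, get_logger

__all__ = [
    "EnhancementCurve", "spgr_signal", "concentration_to_signal",
    "signal_to_concentration", "detect_bolus_arrival", "compute_iauc60",
    "iauc60_map",
]

log = get_logger(__name__)


@dataclass
class EnhancementCurve:
    """A sampled concentration-time curve with its bolus-arrival index."""

    times_s: np.ndarray
    concentration_mM: np.ndarray
    bolus_arrival_index: int

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.concentration_mM = np.asarray(self.concentration_mM, dtype=float)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times_s.shape != self.concentration_mM.shape:
            raise ValueError("times and concentrations must align")
        if not np.all(np.isfinite(self.concentration_mM)):
            raise ValueError("concentrations must be finite")
        if not 0 <= self.bolus_arrival_index < len(self.times_s):
            raise ValueError("bolus_arrival_index out of range")


def spgr_signal(t1_ms, m0, flip_angle_deg: float, tr_ms: float):
    """Spoiled gradient-echo steady-state signal. Accepts arrays for t1/m0."""
    if not 0 < flip_angle_deg < 90:
        raise ValueError(f"flip angle must be in (0, 90), got {flip_angle_deg}")
    if tr_ms <= 0:
        raise ValueError("TR must be > 0")
    t1_ms = np.asarray(t1_ms, dtype=float)
    if np.any(t1_ms <= 0):
        raise ValueError("T1 must be > 0")
    a = np.deg2rad(flip_angle_deg)
    e1 = np.exp(-tr_ms / t1_ms)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def _invert_spgr_e1(s_norm, cos_a):
    """Solve S/(M0 sin a) = (1-E1)/(1-E1 cos a) for E1 (closed form)."""
    return (1.0 - s_norm) / (1.0 - s_norm * cos_a)


def concentration_to_signal(conc_mM, t10_ms, m0, acq: AcquisitionParams):
    """Forward model: concentration -> dynamic SPGR signal (for simulation)."""
    conc_mM = np.asarray(conc_mM, dtype=float)
    r1_s = 1000.0 / np.asarray(t10_ms, dtype=float) + acq.relaxivity_r1 * conc_mM
    t1_eff_ms = 1000.0 / r1_s
    return spgr_signal(t1_eff_ms, m0, acq.flip_angle_deg, acq.tr_ms)


def signal_to_concentration(
    dynamic: ImageSeries, t10_map: ParameterMap, acq: AcquisitionParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert a dynamic series to a 4-D concentration array (mM).

    M0 is calibrated per voxel from the mean of the first
    ``acq.baseline_frame_count`` (pre-injection) frames and the baseline T1.
    Returns ``(concentration, valid_mask)``; voxels lacking a valid baseline
    T1, with nonpositive baseline signal, or whose signal exceeds the SPGR
    saturation ceiling at any frame are masked.
    """
    if dynamic.series_kind != "dynamic":
        raise ValueError(f"expected dynamic series, got {dynamic.series_kind}")
    if tuple(dynamic.data.shape[:3]) != t10_map.values.shape:
        raise ValueError("T10 map grid does not match dynamic series grid")
    nb = acq.baseline_frame_count
    if dynamic.n_volumes <= nb:
        raise ValueError("dynamic series shorter than baseline window")

    a = np.deg2rad(acq.flip_angle_deg)
    sin_a, cos_a = np.sin(a), np.cos(a)
    data = dynamic.data
    baseline = data[..., :nb].mean(axis=3)
    t10 = t10_map.values

    valid = t10_map.valid_mask & (baseline > 0) & (t10 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e10 = np.exp(-acq.tr_ms / t10)
        f10 = sin_a * (1.0 - e10) / (1.0 - e10 * cos_a)
        m0 = baseline / f10
        s_norm = data / (m0 * sin_a)[..., None]
        e1 = _invert_spgr_e1(s_norm, cos_a)
        ok = valid[..., None] & (e1 > 0) & (e1 <= 1.0)
        r1 = np.where(ok, -np.log(np.where(ok, e1, 1.0)) / (acq.tr_ms / 1000.0), np.nan)
        conc = (r1 - (1000.0 / t10)[..., None]) / acq.relaxivity_r1
    voxel_ok = valid & np.all(np.isfinite(conc), axis=3)
    conc[~voxel_ok] = np.nan
    return conc, voxel_ok


def detect_bolus_arrival(curve_mM: np.ndarray, baseline_frame_count: int,
                         k_sigma: float = 3.0, consecutive: int = 2,
                         min_delta_mM: float = 1e-6) -> int:
    """First frame where concentration exceeds baseline noise persistently.

    Threshold is ``max(k_sigma * sd(baseline), min_delta_mM)`` above the
    baseline mean, required for ``consecutive`` successive frames; the
    absolute floor keeps detection meaningful on noiseless input.
    """
    c = np.asarray(curve_mM, dtype=float)
    nb = baseline_frame_count
    if nb >= len(c):
        raise ValueError("baseline window covers the whole curve")
    base_mean = float(c[:nb].mean())
    thresh = base_mean + max(k_sigma * float(c[:nb].std()), min_delta_mM)
    above = c > thresh
    for i in range(nb, len(c) - consecutive + 1):
        if above[i:i + consecutive].all():
            return i
    raise ValueError("no bolus arrival detected")


def compute_iauc60(curve: EnhancementCurve, window_s: float = 60.0) -> float:
    """Trapezoidal area under C(t) over the first 60 s from bolus arrival.

    The last partial sampling interval is linearly interpolated so the
    integral covers exactly ``window_s`` seconds; a curve that does not span
    the window raises a coverage error.
    """
    t = curve.times_s
    c = curve.concentration_mM
    i0 = curve.bolus_arrival_index
    t_end = t[i0] + window_s
    if t[-1] < t_end:
        raise ValueError(
            f"curve ends at {t[-1]:.2f}s, before arrival+{window_s:.0f}s = {t_end:.2f}s"
        )
    inside = t <= t_end
    tt = t[inside][i0:]
    cc = c[inside][i0:]
    if tt[-1] < t_end:
        c_end = float(np.interp(t_end, t, c))
        tt = np.append(tt, t_end)
        cc = np.append(cc, c_end)
    return float(np.trapezoid(cc, tt))


def iauc60_map(
    dynamic: ImageSeries, t10_map: ParameterMap, acq: AcquisitionParams,
    roi: RoiMask | None = None, arrival: str | int = "auto",
    window_s: float = 60.0,
) -> ParameterMap:
    """Voxel-wise iAUC60 map (mmol*s/L) from a dynamic series.

    Bolus arrival is detected once on the mean curve over the ROI (or over
    all convertible voxels when no ROI is given) and applied to every voxel;
    pass ``arrival=<frame index>`` to fix it manually.
    """
    frame_times = dynamic.axis_tags
    conc, voxel_ok = signal_to_concentration(dynamic, t10_map, acq)
    if roi is not None:
        voxel_ok = voxel_ok & roi.mask

    shape = conc.shape[:3]
    values = np.full(shape, np.nan)
    if not voxel_ok.any():
        log.warning("iAUC60: no convertible voxels")
        return ParameterMap.from_values(values, "iAUC60", valid_mask=voxel_ok,
                                        geometry=dynamic.geometry)

    flat = conc[voxel_ok]  # (n_voxels, n_frames)
    if arrival == "auto":
        mean_curve = flat.mean(axis=0)
        i0 = detect_bolus_arrival(mean_curve, acq.baseline_frame_count)
    else:
        i0 = int(arrival)
        if not 0 <= i0 < dynamic.n_volumes:
            raise ValueError(f"arrival frame {i0} out of range")

    t_end = frame_times[i0] + window_s
    if frame_times[-1] < t_end:
        raise ValueError("dynamic series does not span 60 s beyond bolus arrival")
    inside = frame_times <= t_end
    tt = frame_times[inside][i0:]
    cc = flat[:, inside][:, i0:]
    if tt[-1] < t_end:
        # linear interpolation to exactly arrival+60 s
        j = np.searchsorted(frame_times, t_end)
        t_lo, t_hi = frame_times[j - 1], frame_times[j]
        w = (t_end - t_lo) / (t_hi - t_lo)
        c_end = (1 - w) * flat[:, j - 1] + w * flat[:, j]
        tt = np.append(tt, t_end)
        cc = np.column_stack([cc, c_end])
    values[voxel_ok] = np.trapezoid(cc, tt, axis=1)
    return ParameterMap.from_values(values, "iAUC60", valid_mask=voxel_ok,
                                    geometry=dynamic.geometry)
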
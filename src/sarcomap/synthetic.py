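"""Digital phantoms and synthetic cohorts with known ground truth.

Every input the analysis pipeline consumes can be generated here:

* per patient-visit image bundles — a multi-TI saturation-recovery stack, a
  multi-b diffusion stack and a 150-frame dynamic series at 1.75 s
  resolution (the trial acquisition geometry), built from an ellipsoidal
  tumour phantom whose compartments have known T1, ADC and enhancement
  curves, with optional Gaussian or Rician noise;
* summary-level cohorts — per patient-visit ROI medians plus histology
  covariates drawn from a Gaussian copula hitting a configurable target
  Pearson correlation matrix, with multiplicative visit effects and a
  configurable fraction of patients missing the final visit;
* qPCR Ct tables whose hypoxia scores reproduce the cohort's latent scores
  up to configurable cycle noise (a synthetic placeholder panel ships; the
  real assay's gene list is configuration).

Everything is deterministic under a fixed seed.

Enhancement curves are gamma-variate, C(t) = A*(tau/(ab))^a * exp(a-tau/b)
for tau = t - arrival (peak concentration A at tau = ab): the pipeline's
only dynamic quantity is an integral over the first minute, which needs a
realistic curve shape but no tracer-kinetic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (AcquisitionParams, ImageSeries, ParameterMap, RoiMask,
                   VoxelGeometry, get_logger, write_image_series, write_roi_mask)
from .dce import concentration_to_signal
from .diffusion import adc_signal
from .relaxometry import sr_signal

__all__ = [
    "DEFAULT_TI_MS", "DEFAULT_SRTFE_TR_MS", "DEFAULT_BVALS", "DYNAMIC_DT_S",
    "N_DYNAMICS", "SIGNATURE_GENES", "CONTROL_GENES", "COHORT_VARS",
    "GammaVariate", "Compartment", "PhantomSpec", "PhantomBundle", "CohortSpec",
    "CohortBundle", "gamma_variate_curve", "fine_grid_iauc60", "rician_sigma_for_snr",
    "generate_phantom", "default_correlation_targets", "generate_cohort",
    "generate_ct_table", "write_phantom_bundle", "write_cohort_dataset",
]

log = get_logger(__name__)

# trial acquisition geometry
DEFAULT_TI_MS = (37.0, 100.0, 250.0, 1000.0, 2500.0, 3900.0)
DEFAULT_SRTFE_TR_MS = (64.0, 142.0, 292.0, 1050.0, 2550.0, 3950.0)
DEFAULT_BVALS = (0.0, 50.0, 100.0, 150.0, 200.0, 500.0, 1000.0)
DYNAMIC_DT_S = 1.75
N_DYNAMICS = 150
DEFAULT_ACQ = AcquisitionParams()

# synthetic placeholder panel: the assay's 24-gene signature + 2 controls are
# configuration data, not code; these names exist only for testing
SIGNATURE_GENES = tuple(f"HYP{i:02d}" for i in range(1, 25))
CONTROL_GENES = ("CTRL1", "CTRL2")

COHORT_VARS = ["t1", "adc", "iauc60", "cd31", "ki67", "hif", "hs"]

# physiologic plausibility bounds for phantom compartments
T1_RANGE_MS = (200.0, 3000.0)
ADC_RANGE = (100.0, 3500.0)


@dataclass(frozen=True)
class GammaVariate:
    """Gamma-variate enhancement curve; ``peak_mM`` is the peak
    concentration, reached ``alpha*beta_s`` seconds after arrival."""

    peak_mM: float = 1.0
    alpha: float = 2.0
    beta_s: float = 12.0
    arrival_s: float = 21.0


def gamma_variate_curve(times_s: np.ndarray, gv: GammaVariate) -> np.ndarray:
    t = np.asarray(times_s, dtype=float)
    tau = t - gv.arrival_s
    tp = gv.alpha * gv.beta_s  # time-to-peak
    with np.errstate(invalid="ignore"):
        c = gv.peak_mM * (np.maximum(tau, 0.0) / tp) ** gv.alpha \
            * np.exp(gv.alpha - np.maximum(tau, 0.0) / gv.beta_s)
    c[tau <= 0] = 0.0
    return c


def fine_grid_iauc60(gv: GammaVariate, window_s: float = 60.0,
                     dt_s: float = 0.001) -> float:
    """Reference iAUC60 of a gamma-variate curve on a fine time grid."""
    t = np.arange(gv.arrival_s, gv.arrival_s + window_s + dt_s / 2, dt_s)
    return float(np.trapezoid(gamma_variate_curve(t, gv), t))


def rician_sigma_for_snr(s0: float, snr: float) -> float:
    return s0 / snr


@dataclass(frozen=True)
class Compartment:
    name: str
    t1_ms: float
    adc: float  # 10^-6 mm^2/s
    s0: float = 1.0
    enhancement: GammaVariate | None = None


@dataclass
class PhantomSpec:
    """Ellipsoidal tumour phantom on an otherwise empty (air) grid.

    ``compartments`` are applied from the outside in: the first fills the
    tumour ellipsoid, each subsequent one fills an ellipsoid shrunk by
    ``core_fraction`` of the previous semi-axes (rim/core nesting).
    """

    geometry: VoxelGeometry = field(
        default_factory=lambda: VoxelGeometry((3.9, 3.9, 5.0), (64, 64, 20)))
    tumour_centre_vox: tuple[float, float, float] | None = None
    tumour_semiaxes_vox: tuple[float, float, float] = (18.0, 14.0, 7.0)
    core_fraction: float = 0.55
    compartments: tuple[Compartment, ...] = (
        Compartment("rim", t1_ms=1200.0, adc=1600.0, s0=1.0,
                    enhancement=GammaVariate(peak_mM=1.2)),
        Compartment("core", t1_ms=900.0, adc=1100.0, s0=1.0,
                    enhancement=GammaVariate(peak_mM=0.4)),
    )
    noise_model: str = "none"
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if not self.compartments:
            raise ValueError("at least one compartment required")
        for c in self.compartments:
            if not T1_RANGE_MS[0] <= c.t1_ms <= T1_RANGE_MS[1]:
                raise ValueError(f"{c.name}: T1 {c.t1_ms} outside {T1_RANGE_MS} ms")
            if not ADC_RANGE[0] <= c.adc <= ADC_RANGE[1]:
                raise ValueError(f"{c.name}: ADC {c.adc} outside {ADC_RANGE}")


@dataclass
class PhantomBundle:
    sr: ImageSeries
    dwi: ImageSeries
    dce: ImageSeries
    roi: RoiMask
    truth_t1: ParameterMap
    truth_adc: ParameterMap
    truth_iauc60: ParameterMap
    labels: np.ndarray  # 0 = background, k = compartment k
    acq: AcquisitionParams


def _compartment_labels(spec: PhantomSpec) -> np.ndarray:
    shape = spec.geometry.grid_shape
    centre = spec.tumour_centre_vox or tuple((s - 1) / 2.0 for s in shape)
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    labels = np.zeros(shape, dtype=int)
    axes = np.asarray(spec.tumour_semiaxes_vox, dtype=float)
    for k in range(len(spec.compartments)):
        scaled = axes * spec.core_fraction ** k
        r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, scaled))
        labels[r2 <= 1.0] = k + 1
    return labels


def _apply_noise(signal: np.ndarray, spec: PhantomSpec,
                 rng: np.random.Generator) -> np.ndarray:
    if spec.noise_model == "none" or spec.noise_sigma == 0.0:
        return signal
    if spec.noise_model == "gaussian":
        return np.clip(signal + rng.normal(0.0, spec.noise_sigma, signal.shape), 0, None)
    # magnitude-image (Rician) noise: |signal + complex Gaussian|
    re = signal + rng.normal(0.0, spec.noise_sigma, signal.shape)
    im = rng.normal(0.0, spec.noise_sigma, signal.shape)
    return np.hypot(re, im)


def generate_phantom(spec: PhantomSpec, visit: int = 1,
                     acq: AcquisitionParams = DEFAULT_ACQ,
                     ti_ms=DEFAULT_TI_MS, bvals=DEFAULT_BVALS,
                     n_dynamics: int = N_DYNAMICS,
                     dt_s: float = DYNAMIC_DT_S) -> PhantomBundle:
    """Forward-simulate one patient-visit image bundle with known truth.

    The same seed (and visit) always yields bit-identical data; the visit
    index only salts the noise stream, so per-visit parameter changes are
    expressed through the spec itself.
    """
    labels = _compartment_labels(spec)
    shape = spec.geometry.grid_shape
    rng = np.random.default_rng([int(spec.seed), int(visit)])

    t1_true = np.full(shape, np.nan)
    adc_true = np.full(shape, np.nan)
    iauc_true = np.full(shape, np.nan)
    s0_vol = np.zeros(shape)
    times = np.arange(n_dynamics, dtype=float) * dt_s

    sr = np.zeros(shape + (len(ti_ms),))
    dwi = np.zeros(shape + (len(bvals),))
    dce = np.zeros(shape + (n_dynamics,))

    for k, comp in enumerate(spec.compartments, start=1):
        m = labels == k
        if not m.any():
            continue
        t1_true[m] = comp.t1_ms
        adc_true[m] = comp.adc
        s0_vol[m] = comp.s0
        sr[m] = sr_signal(comp.t1_ms, comp.s0, np.asarray(ti_ms))
        dwi[m] = adc_signal(comp.adc, comp.s0, np.asarray(bvals))
        gv = comp.enhancement
        if gv is not None:
            conc = gamma_variate_curve(times, gv)
            iauc_true[m] = fine_grid_iauc60(gv)
        else:
            conc = np.zeros_like(times)
            iauc_true[m] = 0.0
        dce[m] = concentration_to_signal(conc, comp.t1_ms, comp.s0, acq)

    sr = _apply_noise(sr, spec, rng)
    dwi = _apply_noise(dwi, spec, rng)
    dce = _apply_noise(dce, spec, rng)

    geom = spec.geometry
    tumour = labels > 0
    return PhantomBundle(
        sr=ImageSeries(sr, geom, np.asarray(ti_ms), "saturation_recovery"),
        dwi=ImageSeries(dwi, geom, np.asarray(bvals), "diffusion"),
        dce=ImageSeries(dce, geom, times, "dynamic"),
        roi=RoiMask(tumour, geom, "tumour"),
        truth_t1=ParameterMap.from_values(t1_true, "T1", geometry=geom),
        truth_adc=ParameterMap.from_values(adc_true, "ADC", geometry=geom),
        truth_iauc60=ParameterMap.from_values(iauc_true, "iAUC60", geometry=geom),
        labels=labels, acq=acq,
    )


# ---------------------------------------------------------------------------
# summary-level cohort generation

def default_correlation_targets() -> pd.DataFrame:
    """Default target Pearson matrix over (t1, adc, iauc60, cd31, ki67, hif, hs).

    The three strong imaging-histology associations of the study design
    (iAUC60-HS -0.64, ADC-HS +0.63, ADC-Ki67 -0.66) are embedded exactly;
    the remaining cross-cells among those four variables are filled with
    Markov-tree path products (iAUC60 -- HS -- ADC -- Ki67), which is the
    minimal completion that keeps the matrix positive definite. All other
    variables are uncorrelated by default.
    """
    R = pd.DataFrame(np.eye(7), index=COHORT_VARS, columns=COHORT_VARS)

    def setr(a, b, v):
        R.loc[a, b] = R.loc[b, a] = v

    setr("iauc60", "hs", -0.64)
    setr("adc", "hs", 0.63)
    setr("adc", "ki67", -0.66)
    setr("iauc60", "adc", -0.64 * 0.63)
    setr("hs", "ki67", 0.63 * -0.66)
    setr("iauc60", "ki67", -0.64 * 0.63 * -0.66)
    return R


#: marginal (mean, sd) used to map latent normals to physiologic scales
DEFAULT_MARGINALS = {
    "t1": (1100.0, 200.0),      # ms
    "adc": (1400.0, 300.0),     # 10^-6 mm^2/s
    "iauc60": (10.0, 3.0),      # mmol*s/L
    "cd31": (20.0, 6.0),        # vessel score, %
    "ki67": (30.0, 10.0),       # proliferation score, %
    "hif": (15.0, 5.0),         # HIF score, %
    "hs": (0.0, 1.5),           # log2 units
}

#: multiplicative per-visit shifts: T1 drops mid-treatment, ADC drops at the
#: post-treatment visit (following the study's Results; flip the ADC entry
#: above 1 to emulate the opposite direction reported in its Discussion)
DEFAULT_VISIT_EFFECTS = {
    "t1": {2: 0.85, 3: 0.95},
    "adc": {3: 0.80},
    "iauc60": {},
}


@dataclass
class CohortSpec:
    n_patients: int = 12
    visit_effects: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_VISIT_EFFECTS.items()})
    correlation_targets: pd.DataFrame = field(
        default_factory=default_correlation_targets)
    marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    missing_visit3_fraction: float = 0.25
    caix_positive_fraction: float = 0.5
    volume_median_cm3: float = 29.0
    volume_log_sd: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        R = np.asarray(self.correlation_targets, dtype=float)
        if R.shape != (7, 7) or not np.allclose(R, R.T) \
                or not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation_targets must be symmetric 7x7 with unit diagonal")
        eig = np.linalg.eigvalsh(R)
        if eig.min() < -1e-10:
            Rn = _nearest_psd(R)
            raise ValueError(
                "correlation_targets not positive semi-definite "
                f"(min eigenvalue {eig.min():.4f}); nearest PSD suggestion:\n{Rn}")
        for f in (self.missing_visit3_fraction, self.caix_positive_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")


def _nearest_psd(R: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(R)
    Rp = (v * np.maximum(w, 1e-8)) @ v.T
    d = np.sqrt(np.diag(Rp))
    return Rp / np.outer(d, d)


@dataclass
class CohortBundle:
    table: pd.DataFrame           # per (patient, visit) summary rows
    truth: dict                   # latent values, targets, applied effects
    phantom_specs: dict | None = None  # (patient, visit) -> PhantomSpec


def generate_cohort(spec: CohortSpec, image_level: bool = False,
                    phantom_geometry: VoxelGeometry | None = None) -> CohortBundle:
    """Draw a synthetic three-visit cohort at summary level.

    Latent patient vectors come from a Gaussian copula with the target
    correlation matrix; marginals are affine maps to physiologic scales, so
    the target Pearson correlations are preserved exactly in expectation.
    Visit effects multiply the affected parameter at the affected visit in
    every patient. ``round(n * missing_visit3_fraction)`` patients lack the
    third visit (imaging NaN, flagged). With ``image_level=True`` a
    per-(patient, visit) :class:`PhantomSpec` dictionary is also returned,
    with uniform single-compartment tumours carrying the latent values.
    """
    rng = np.random.default_rng(int(spec.seed))
    n = spec.n_patients
    R = np.asarray(spec.correlation_targets, dtype=float)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(7))
    z = rng.standard_normal((n, 7)) @ L.T
    latent = pd.DataFrame(
        {v: spec.marginals[v][0] + spec.marginals[v][1] * z[:, i]
         for i, v in enumerate(COHORT_VARS)},
        index=[f"P{i + 1:02d}" for i in range(n)])
    latent["volume_cm3"] = spec.volume_median_cm3 * np.exp(
        rng.normal(0.0, spec.volume_log_sd, n))

    n_missing = int(round(spec.missing_visit3_fraction * n))
    missing3 = set(rng.choice(latent.index.to_numpy(), size=n_missing, replace=False))

    n_pos = int(round(spec.caix_positive_fraction * n))
    pos_ids = set(latent["hs"].nlargest(n_pos).index)  # CAIX tracks hypoxia

    rows = []
    for pid, row in latent.iterrows():
        for visit in (1, 2, 3):
            miss = visit == 3 and pid in missing3
            eff = {p: spec.visit_effects.get(p, {}).get(visit, 1.0)
                   for p in ("t1", "adc", "iauc60")}
            rows.append({
                "patient": pid, "visit": visit,
                "t1_median": np.nan if miss else row["t1"] * eff["t1"],
                "adc_median": np.nan if miss else row["adc"] * eff["adc"],
                "iauc60_median": np.nan if miss else row["iauc60"] * eff["iauc60"],
                "volume_cm3": np.nan if miss else row["volume_cm3"],
                "cd31_score": row["cd31"], "ki67_score": row["ki67"],
                "hif_score": row["hif"], "hypoxia_score": row["hs"],
                "caix_positive": pid in pos_ids,
                "visit_missing": miss,
            })
    table = pd.DataFrame(rows)

    phantom_specs = None
    if image_level:
        geom = phantom_geometry or VoxelGeometry((3.9, 3.9, 5.0), (32, 32, 10))
        phantom_specs = {}
        unit_iauc = fine_grid_iauc60(GammaVariate(peak_mM=1.0))
        for pid, row in latent.iterrows():
            for visit in (1, 2, 3):
                if visit == 3 and pid in missing3:
                    continue
                eff = {p: spec.visit_effects.get(p, {}).get(visit, 1.0)
                       for p in ("t1", "adc", "iauc60")}
                t1 = float(np.clip(row["t1"] * eff["t1"], *T1_RANGE_MS))
                adc = float(np.clip(row["adc"] * eff["adc"], *ADC_RANGE))
                peak = max(row["iauc60"] * eff["iauc60"], 0.0) / unit_iauc
                comp = Compartment("tumour", t1_ms=t1, adc=adc, s0=1.0,
                                   enhancement=GammaVariate(peak_mM=peak))
                phantom_specs[(pid, visit)] = PhantomSpec(
                    geometry=geom,
                    tumour_semiaxes_vox=(10.0, 8.0, 3.5),
                    compartments=(comp,), core_fraction=1.0,
                    noise_model="none", noise_sigma=0.0,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )

    truth = {
        "latent": latent,
        "correlation_targets": spec.correlation_targets.copy(),
        "visit_effects": {k: dict(v) for k, v in spec.visit_effects.items()},
        "missing_visit3": sorted(missing3),
        "caix_positive": sorted(pos_ids),
    }
    return CohortBundle(table=table, truth=truth, phantom_specs=phantom_specs)


# ---------------------------------------------------------------------------
# Ct table generation

def generate_ct_table(hs_by_sample: pd.Series,
                      signature_genes=SIGNATURE_GENES,
                      control_genes=CONTROL_GENES,
                      seed: int = 0, noise_sd_cycles: float = 0.25,
                      control_mean_ct: tuple[float, ...] = (21.0, 23.0),
                      gene_offset_span: float = 2.0) -> pd.DataFrame:
    """Ct table (genes x samples) whose hypoxia score recovers the latent HS.

    Signature gene g of a sample with latent score ``hs`` is placed at
    Ct_g = mean(control Ct) - (hs + offset_g) + noise, with per-gene
    offsets symmetric about zero (median exactly zero), so at zero noise
    the median normalised expression equals ``hs`` exactly.
    """
    if len(control_genes) != len(control_mean_ct):
        raise ValueError("one plate mean per control gene required")
    sig = list(signature_genes)
    if len(sig) % 2 != 0:
        raise ValueError("signature size must be even for a symmetric offset set")
    rng = np.random.default_rng(int(seed))
    offsets = np.linspace(-gene_offset_span, gene_offset_span, len(sig))
    ref = float(np.mean(control_mean_ct))

    data = {}
    for sample, hs in hs_by_sample.items():
        ct_ctrl = np.asarray(control_mean_ct, dtype=float) \
            + rng.normal(0.0, noise_sd_cycles, len(control_genes))
        # normalisation subtracts the realised control mean; centre signature
        # rows on it so control noise does not bias the score
        ct_sig = ct_ctrl.mean() - (hs + offsets) \
            + rng.normal(0.0, noise_sd_cycles, len(sig))
        data[sample] = np.concatenate([ct_sig, ct_ctrl])
    return pd.DataFrame(data, index=sig + list(control_genes))


# ---------------------------------------------------------------------------
# file-level dataset writers (inputs for the pipeline CLI)

def write_phantom_bundle(bundle: PhantomBundle, out_dir: str | Path,
                         prefix: str = "phantom") -> dict:
    """Write one phantom's series, sidecars and ROI to NIfTI/JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    acq_meta = {
        "flip_angle_deg": bundle.acq.flip_angle_deg, "tr_ms": bundle.acq.tr_ms,
        "te_ms": bundle.acq.te_ms, "relaxivity_r1": bundle.acq.relaxivity_r1,
        "baseline_frame_count": bundle.acq.baseline_frame_count,
    }
    for name, series, extra in (
            ("sr", bundle.sr, {"srtfe_tr_ms": list(DEFAULT_SRTFE_TR_MS)}),
            ("dwi", bundle.dwi, {}),
            ("dce", bundle.dce, acq_meta)):
        nii = out / f"{prefix}_{name}.nii.gz"
        sidecar = out / f"{prefix}_{name}.json"
        write_image_series(series, nii, sidecar, extra_meta=extra)
        paths[name] = str(nii)
        paths[f"{name}_sidecar"] = str(sidecar)
    roi_path = out / f"{prefix}_roi.nii.gz"
    write_roi_mask(bundle.roi, roi_path)
    paths["roi"] = str(roi_path)
    return paths


def write_cohort_dataset(spec: CohortSpec, out_dir: str | Path,
                         phantom_geometry: VoxelGeometry | None = None,
                         ct_noise_sd_cycles: float = 0.25) -> dict:
    """Materialise a full image-level cohort on disk: per patient-visit
    NIfTI bundles, a histology CSV (scores + hypoxia score from a generated
    Ct table), a Ct table CSV, a panel YAML and a pipeline manifest.

    Returns ``{"manifest": path, "truth": dict, "bundle": CohortBundle}``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(spec, image_level=True,
                             phantom_geometry=phantom_geometry)
    latent = cohort.truth["latent"]

    manifest: dict = {"patients": {}}
    for (pid, visit), pspec in cohort.phantom_specs.items():
        bundle = generate_phantom(pspec, visit=visit)
        paths = write_phantom_bundle(bundle, out / pid, prefix=f"v{visit}")
        manifest["patients"].setdefault(pid, {"visits": {}})
        manifest["patients"][pid]["visits"][visit] = paths

    ct = generate_ct_table(latent["hs"], seed=spec.seed + 1,
                           noise_sd_cycles=ct_noise_sd_cycles)
    ct_path = out / "ct_table.csv"
    ct.to_csv(ct_path, index_label="gene")
    panel_path = out / "panel.yaml"
    with open(panel_path, "w") as fh:
        yaml.safe_dump({"signature_genes": list(SIGNATURE_GENES),
                        "control_genes": list(CONTROL_GENES)}, fh)

    caix_pos = set(cohort.truth["caix_positive"])
    histology = pd.DataFrame({
        "patient": latent.index,
        "cd31_score": latent["cd31"].to_numpy(),
        "ki67_score": latent["ki67"].to_numpy(),
        "hif_score": latent["hif"].to_numpy(),
        "caix_positive": [p in caix_pos for p in latent.index],
    })
    hist_path = out / "histology.csv"
    histology.to_csv(hist_path, index=False)

    manifest["histology"] = str(hist_path)
    manifest["ct_table"] = str(ct_path)
    manifest["panel"] = str(panel_path)
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh)
    return {"manifest": str(manifest_path), "truth": cohort.truth, "bundle": cohort}
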
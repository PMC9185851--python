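# sarcomap

Quantitative multiparametric MRI (mpMRI) biomarkers for soft-tissue sarcoma
under neoadjuvant radiotherapy, as a tested, reusable pipeline. Soft-tissue
sarcomas barely shrink during pre-operative radiotherapy even when they
respond pathologically, so size-based response criteria fail; functional
imaging — tissue T1, water diffusivity (ADC) and contrast-agent uptake
(iAUC60) — tracked over three visits (before, during and after
radiotherapy) and correlated against histology of the resected tumour is a
candidate replacement. This package implements that analysis end to end for
imaging scientists and trial analysts:

* **T1 mapping** — voxel-wise bounded nonlinear least-squares fit of the
  saturation-recovery signal `S(TI) = S0·(1 − e^(−TI/T1))` over a multi-TI
  stack (TI = 37…3900 ms).
* **ADC mapping** — weighted log-linear fit of the mono-exponential decay
  `S(b) = S0·e^(−b·ADC)` over seven b-values (0…1000 s/mm²), reported in
  10⁻⁶ mm²/s.
* **DCE-MRI** — closed-form inversion of the spoiled gradient-echo signal
  equation `S = M0·sin α·(1 − E1)/(1 − E1·cos α)` to gadolinium
  concentration via `R1(t) = R1(0) + r1·C(t)`, then the initial area under
  the concentration curve over the first 60 s from bolus arrival
  (trapezoidal, mmol·s/L).
* **ROI statistics** — nearest-neighbour mask transfer between grids,
  one-pixel in-plane erosion, tumour volume from the known voxel size, and
  median/IQR summaries over the tumour.
* **Hypoxia score** — per-sample median of control-normalised log2
  expression over a 24-gene qPCR hypoxia signature,
  `HS = median_g[−(Ct_g − mean(Ct_controls))]`, the control mean being the
  log of the geometric mean of the endogenous-control expression.
* **Cohort statistics** — Wilcoxon signed-rank visit comparisons (exact
  null for small n), Pearson r with t-distribution p-values between imaging
  and histology, Mann–Whitney U stratification by CAIX status; two-sided
  p-values, no multiplicity correction.
* **Synthetic data** — digital ellipsoid phantoms (Rician noise, trial
  acquisition geometry) and Gaussian-copula cohorts with configurable
  imaging–histology correlations, so every stage can be validated against
  known ground truth.

## Worked example

```python
import numpy as np
from sarcomap import fit_t1_map, fit_adc_map, iauc60_map, erode_roi, summarise_roi
from sarcomap.synthetic import PhantomSpec, generate_phantom
from sarcomap.core import VoxelGeometry

spec = PhantomSpec(geometry=VoxelGeometry((3.9, 3.9, 5.0), (24, 24, 6)),
                   tumour_semiaxes_vox=(8, 6, 2.5), seed=7)
bundle = generate_phantom(spec)                      # SR + DWI + DCE + ROI

t1_map, _ = fit_t1_map(bundle.sr, roi_mask=bundle.roi.mask)
adc_map = fit_adc_map(bundle.dwi)
ia_map = iauc60_map(bundle.dce, t1_map, bundle.acq, roi=bundle.roi)

roi = erode_roi(bundle.roi)
for name, pmap in [("T1", t1_map), ("ADC", adc_map), ("iAUC60", ia_map)]:
    s = summarise_roi(pmap, roi)
    print(f"{name}: median {s.median:.1f} ({pmap.units}), "
          f"IQR {s.iqr_low:.1f}-{s.iqr_high:.1f}, n={s.n_voxels}")
```

prints

```
T1: median 1200.0 (ms), IQR 1200.0-1200.0, n=352
ADC: median 1600.0 (1e-6 mm^2/s), IQR 1600.0-1600.0, n=352
iAUC60: median 47.2 (mmol*s/L), IQR 47.2-47.2, n=352
```

The default phantom nests a low-diffusivity, weakly enhancing core
(T1 = 900 ms, ADC = 1100) inside a rim (T1 = 1200 ms, ADC = 1600, peak
enhancement 1.2 mM); at this small matrix the rim holds the whole-ROI
median, and on noiseless data the fitted values reproduce the compartment
ground truth exactly (hence the collapsed IQRs). The iAUC60 median, 47.2
mmol·s/L, is the trapezoidal integral of the rim's gamma-variate
concentration curve over the first minute of enhancement.

A command-line interface mirrors the library (`sarcomap t1map`, `adcmap`,
`iauc`, `roi-stats`, `hypoxia-score`, `cohort-stats`, `simulate`, `run`);
`sarcomap run --manifest cohort.yaml --out results/` processes a whole
cohort and writes `cohort.csv`, `table3.csv` (the imaging-vs-histology
correlation grid), `visit_tests.csv` and `caix_stratification.csv`.

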
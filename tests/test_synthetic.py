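import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sarcomap import (VoxelGeometry, default_correlation_targets, fit_adc_map,
                      fit_t1_map, generate_cohort, generate_ct_table,
                      generate_phantom, iauc60_map)
from sarcomap.hypoxia import ExpressionTable, score_all_samples
from sarcomap.synthetic import (CONTROL_GENES, SIGNATURE_GENES, CohortSpec,
                                Compartment, GammaVariate, PhantomSpec,
                                fine_grid_iauc60, rician_sigma_for_snr)


class TestPhantom:
    def test_noiseless_pipeline_recovers_ground_truth(self, small_phantom_spec):
        b = generate_phantom(small_phantom_spec)
        t1_map, _ = fit_t1_map(b.sr, roi_mask=b.roi.mask)
        m = b.roi.mask & t1_map.valid_mask
        assert m.sum() == b.roi.n_voxels
        np.testing.assert_allclose(t1_map.values[m], b.truth_t1.values[m], rtol=1e-6)

        adc_map = fit_adc_map(b.dwi)
        np.testing.assert_allclose(adc_map.values[b.roi.mask],
                                   b.truth_adc.values[b.roi.mask], rtol=1e-9)

        imap = iauc60_map(b.dce, t1_map, b.acq, roi=b.roi)
        m2 = b.roi.mask & imap.valid_mask
        # detection-window offset and 1.75 s sampling keep this within a few %
        np.testing.assert_allclose(imap.values[m2], b.truth_iauc60.values[m2],
                                   rtol=0.03)

    def test_same_seed_bit_identical(self, small_phantom_spec, tmp_path):
        from dataclasses import replace
        from sarcomap.synthetic import write_phantom_bundle
        spec = replace(small_phantom_spec, noise_model="rician", noise_sigma=0.02)
        b1 = generate_phantom(spec)
        b2 = generate_phantom(spec)
        assert np.array_equal(b1.sr.data, b2.sr.data)
        assert np.array_equal(b1.dce.data, b2.dce.data)
        # byte-identical uncompressed NIfTI payloads
        from sarcomap.core import write_image_series
        p1, p2 = tmp_path / "a.nii", tmp_path / "b.nii"
        write_image_series(b1.dwi, p1)
        write_image_series(b2.dwi, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_visit_different_noise(self, small_phantom_spec):
        from dataclasses import replace
        spec = replace(small_phantom_spec, noise_model="gaussian", noise_sigma=0.02)
        assert not np.array_equal(generate_phantom(spec, visit=1).sr.data,
                                  generate_phantom(spec, visit=2).sr.data)

    def test_out_of_range_compartment_rejected(self, small_geometry):
        with pytest.raises(ValueError, match="T1"):
            PhantomSpec(geometry=small_geometry,
                        compartments=(Compartment("x", t1_ms=50.0, adc=1000.0),))
        with pytest.raises(ValueError, match="ADC"):
            PhantomSpec(geometry=small_geometry,
                        compartments=(Compartment("x", t1_ms=1000.0, adc=5000.0),))

    def test_rician_background_matches_closed_form(self):
        """Background (zero-signal) magnitude noise is Rayleigh(sigma): the
        Rician distribution at zero underlying signal."""
        sigma = rician_sigma_for_snr(1.0, 50.0)
        spec = PhantomSpec(
            geometry=VoxelGeometry((3.9, 3.9, 5.0), (48, 48, 8)),
            tumour_semiaxes_vox=(8.0, 6.0, 2.0),
            compartments=(Compartment("t", t1_ms=1000.0, adc=1500.0),),
            core_fraction=1.0, noise_model="rician", noise_sigma=sigma, seed=11)
        b = generate_phantom(spec)
        bg = b.sr.data[~b.roi.mask][:, 0].ravel()
        bg = bg[:100_000]
        assert bg.size >= 10_000
        d, _ = sps.kstest(bg, sps.rayleigh(scale=sigma).cdf)
        assert d < 0.02


class TestCohort:
    def test_zero_targets_give_near_zero_sample_correlations(self):
        R = pd.DataFrame(np.eye(7), index=default_correlation_targets().index,
                         columns=default_correlation_targets().columns)
        spec = CohortSpec(n_patients=10_000, correlation_targets=R, seed=4)
        latent = generate_cohort(spec).truth["latent"]
        sample_r = latent[list(R.index)].corr().to_numpy()
        off = sample_r[~np.eye(7, dtype=bool)]
        assert np.abs(off).max() < 0.03

    def test_target_correlation_hit_within_fisher_interval(self):
        spec = CohortSpec(n_patients=10_000, seed=9)
        latent = generate_cohort(spec).truth["latent"]
        r = latent["iauc60"].corr(latent["hs"])
        z = np.arctanh(-0.64)
        lo, hi = np.tanh(z - 2.576 / np.sqrt(10_000 - 3)), \
            np.tanh(z + 2.576 / np.sqrt(10_000 - 3))
        assert lo < r < hi

    def test_missing_visit3_count_exact(self):
        spec = CohortSpec(n_patients=12, missing_visit3_fraction=0.25, seed=1)
        bundle = generate_cohort(spec)
        assert len(bundle.truth["missing_visit3"]) == 3
        t = bundle.table
        miss = t[(t.visit == 3) & t.visit_missing]
        assert len(miss) == 3 and miss["t1_median"].isna().all()

    def test_visit_effect_signs_in_every_patient(self):
        bundle = generate_cohort(CohortSpec(n_patients=12, seed=2))
        wide_t1 = bundle.table.pivot(index="patient", columns="visit",
                                     values="t1_median")
        assert (wide_t1[2] < wide_t1[1]).all()
        wide_adc = bundle.table.pivot(index="patient", columns="visit",
                                      values="adc_median").dropna()
        assert (wide_adc[3] < wide_adc[1]).all()

    def test_non_psd_targets_rejected_with_suggestion(self):
        R = default_correlation_targets()
        R.loc["t1", "hs"] = R.loc["hs", "t1"] = 0.99
        R.loc["t1", "iauc60"] = R.loc["iauc60", "t1"] = 0.99
        R.loc["iauc60", "hs"] = R.loc["hs", "iauc60"] = -0.99
        with pytest.raises(ValueError, match="nearest PSD"):
            CohortSpec(correlation_targets=R)

    def test_determinism(self):
        b1 = generate_cohort(CohortSpec(seed=33))
        b2 = generate_cohort(CohortSpec(seed=33))
        pd.testing.assert_frame_equal(b1.table, b2.table)

    def test_default_targets_embed_study_cells(self):
        R = default_correlation_targets()
        assert R.loc["iauc60", "hs"] == -0.64
        assert R.loc["adc", "hs"] == 0.63
        assert R.loc["adc", "ki67"] == -0.66
        assert np.linalg.eigvalsh(R.to_numpy()).min() > 0


class TestCtTable:
    def _score(self, ct):
        table = ExpressionTable(ct, list(SIGNATURE_GENES), list(CONTROL_GENES))
        return score_all_samples(table)

    def test_zero_noise_reproduces_latent_scores_exactly(self):
        hs = pd.Series({"A": -1.3, "B": 0.0, "C": 2.4})
        ct = generate_ct_table(hs, seed=0, noise_sd_cycles=0.0)
        scores = self._score(ct)
        np.testing.assert_allclose(scores[hs.index], hs, atol=1e-12)

    def test_plate_shift_leaves_scores_unchanged(self):
        hs = pd.Series({"A": 0.7, "B": -0.2})
        ct = generate_ct_table(hs, seed=1, noise_sd_cycles=0.3)
        s0 = self._score(ct)
        s1 = self._score(ct + 2.5)
        pd.testing.assert_series_equal(s0, s1)

    def test_noise_propagation_consistent_with_median_of_24(self):
        """Score RMSE under cycle noise matches a direct Monte-Carlo of the
        same median-of-24 construction."""
        rng = np.random.default_rng(5)
        n = 1000
        sd = 0.25
        hs = pd.Series(0.0, index=[f"S{i}" for i in range(n)])
        scores = self._score(generate_ct_table(hs, seed=6, noise_sd_cycles=sd))
        rmse = float(np.sqrt(np.mean(scores**2)))
        # independent oracle: signature rows are centred on the realised
        # control mean, so control noise cancels and the score is the median
        # of the 24 per-gene offsets plus iid cycle noise
        offsets = np.linspace(-2, 2, 24)
        oracle = float(np.std(np.median(
            offsets + rng.normal(0, sd, (20_000, 24)), axis=1)))
        assert rmse == pytest.approx(oracle, rel=0.15)

    def test_panel_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="even"):
            generate_ct_table(pd.Series({"A": 0.0}),
                              signature_genes=("G1", "G2", "G3"))
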
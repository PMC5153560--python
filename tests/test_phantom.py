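"""Phantom cohort generator: masks, intensity model, clinical links."""

import numpy as np
import pytest
from scipy import stats as sps

from conftest import make_record
from striatex import (
    ClinicalRecord,
    PhantomParams,
    clinical_frame,
    laterality_index,
    make_masks,
    mean_roi_uptake,
    normalize_to_reference,
    read_cohort,
    simulate_cohort,
    simulate_subject,
    texture_for_region,
    write_cohort,
)


class TestMasks:
    def test_mirror_symmetry_of_voxel_counts(self, default_masks):
        assert default_masks["putamen_L"].sum() == default_masks["putamen_R"].sum()
        assert default_masks["caudate_L"].sum() == default_masks["caudate_R"].sum()

    def test_striatal_masks_pairwise_disjoint(self, default_masks):
        names = ["caudate_L", "caudate_R", "putamen_L", "putamen_R"]
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                assert not np.any(default_masks[a] & default_masks[b])

    def test_occipital_disjoint_from_striatum(self, default_masks):
        occ = default_masks["occipital"]
        for name in ("caudate_L", "caudate_R", "putamen_L", "putamen_R"):
            assert not np.any(occ & default_masks[name])

    def test_region_volumes_near_anatomical_targets(self, default_masks, default_params):
        vox_mm3 = default_params.spacing_mm**3
        caud_cm3 = default_masks["caudate_L"].sum() * vox_mm3 / 1000
        put_cm3 = default_masks["putamen_L"].sum() * vox_mm3 / 1000
        assert 1.0 < caud_cm3 < 2.0
        assert 3.0 < put_cm3 < 5.0

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="exceeds the grid"):
            make_masks(PhantomParams(grid_shape=(16, 16, 16)))


class TestSimulateSubject:
    def test_zero_severity_is_left_right_symmetric(self, default_params, default_masks):
        params = PhantomParams(**{**default_params.to_dict(), "noise_sd": 0.0})
        vol = simulate_subject(params, make_record(0.0), masks=default_masks,
                               rng=np.random.default_rng(0))
        s = mean_roi_uptake(vol, default_masks)
        assert s.mean_raw["putamen_L"] == pytest.approx(s.mean_raw["putamen_R"], abs=1e-9)
        assert s.mean_raw["caudate_L"] == pytest.approx(s.mean_raw["caudate_R"], abs=1e-9)

    def test_asymmetry_ratio_at_full_severity(self, default_params, default_masks):
        """More-affected putamen mean = (1 - asymmetry) x less-affected one."""
        params = PhantomParams(**{**default_params.to_dict(), "noise_sd": 0.0})
        _, truth = simulate_subject(
            params, make_record(1.0), masks=default_masks,
            rng=np.random.default_rng(0), return_truth=True,
        )
        assert truth["putamen_L"] / truth["putamen_R"] == pytest.approx(0.7, abs=1e-9)

    def test_analytic_means_recovered_without_noise_or_smoothing(self, default_masks, default_params):
        params = PhantomParams(
            **{**default_params.to_dict(), "noise_sd": 0.0, "fwhm_mm": 1e-6}
        )
        vol, truth = simulate_subject(
            params, make_record(0.6), masks=default_masks,
            rng=np.random.default_rng(3), return_truth=True,
        )
        measured = mean_roi_uptake(vol, default_masks)
        for region, expected in truth.items():
            assert measured.mean_raw[region] == pytest.approx(expected, rel=1e-6), region

    def test_intensity_variance_grows_with_gradient_steepness(self, default_params):
        variances = []
        for steep in (0.01, 0.03, 0.05):
            params = PhantomParams(
                **{**default_params.to_dict(), "noise_sd": 0.0, "patchiness": 0.0,
                   "lesion_fraction_max": 0.0, "gradient_steepness": steep}
            )
            masks = make_masks(params)
            vol = simulate_subject(params, make_record(0.8), masks=masks,
                                   rng=np.random.default_rng(4))
            variances.append(vol.data[masks["putamen_R"]].var())
        assert variances[0] <= variances[1] <= variances[2]

    def test_severity_sweep_monotone_trends(self, default_params, default_masks):
        """Noise-free sweep: putamen uptake strictly falls, caudate contrast
        trends up (Spearman) with a clear endpoint increase."""
        params = PhantomParams(**{**default_params.to_dict(), "noise_sd": 0.0})
        sweep = np.linspace(0.0, 1.0, 6)
        uptake, contrast = [], []
        for s in sweep:
            vol = simulate_subject(params, make_record(float(s)), masks=default_masks,
                                   rng=np.random.default_rng(5))
            su = normalize_to_reference(mean_roi_uptake(vol, default_masks))
            uptake.append(su.mean_normalized["putamen_L"])
            contrast.append(texture_for_region(vol, default_masks, "caudate_L").contrast)
        assert all(a > b for a, b in zip(uptake, uptake[1:]))
        rho = sps.spearmanr(sweep, contrast).statistic
        assert rho >= 0.7
        assert contrast[-1] > contrast[0] * 1.3

    def test_invalid_severity_rejected(self):
        with pytest.raises(ValueError):
            ClinicalRecord("X", "PD", 10, 5, 10, 28, 60, latent_severity=1.5)


class TestCohort:
    def test_counts_and_determinism(self, small_params):
        cohort = simulate_cohort(small_params, n_pd=5, n_hc=3)
        assert len(cohort.volumes) == 8
        assert len(cohort.records) == 8
        assert sum(r.group == "PD" for r in cohort.records) == 5
        again = simulate_cohort(small_params, n_pd=5, n_hc=3)
        assert clinical_frame(cohort.records).to_csv() == clinical_frame(again.records).to_csv()
        np.testing.assert_array_equal(cohort.volumes[0].data, again.volumes[0].data)

    def test_severity_drives_updrs(self):
        params = PhantomParams(seed=11)
        rng = np.random.default_rng(11)
        # clinical link only: draw scores via the cohort generator
        from striatex.phantom import _simulate_clinical

        records = _simulate_clinical(params, 85, 0, rng)
        sev = np.array([r.latent_severity for r in records])
        updrs = np.array([r.updrs3 for r in records])
        assert np.corrcoef(sev, updrs)[0, 1] > 0.8

    def test_clinical_invariants_hold(self, tiny_cohort):
        cohort, _, clin = tiny_cohort
        pd_rows = clin[clin.group == "PD"]
        hc_rows = clin[clin.group == "HC"]
        assert (hc_rows.latent_severity == 0).all()
        assert (pd_rows.dd_sympt_months >= pd_rows.dd_diag_months).all()
        assert clin.moca.between(0, 30).all()

    def test_hc_laterality_small(self, default_params, default_masks):
        """Healthy phantoms: putamen laterality well below the PD scale."""
        lats = []
        for seed in range(20):
            vol = simulate_subject(
                default_params, make_record(0.0, subject_id=f"HC{seed}"),
                masks=default_masks, rng=np.random.default_rng(100 + seed),
            )
            su = normalize_to_reference(mean_roi_uptake(vol, default_masks))
            lats.append(laterality_index(su.mean_normalized["putamen_R"],
                                         su.mean_normalized["putamen_L"]))
        assert np.mean(lats) < 0.02

    def test_write_read_round_trip(self, tmp_path, tiny_cohort):
        cohort, _, _ = tiny_cohort
        manifest = write_cohort(cohort, tmp_path / "cohort")
        back = read_cohort(manifest)
        assert len(back.volumes) == len(cohort.volumes)
        for va, vb in zip(cohort.volumes, back.volumes):
            a = mean_roi_uptake(va, cohort.masks).mean_raw
            b = mean_roi_uptake(vb, back.masks).mean_raw
            for region in a:
                assert a[region] == pytest.approx(b[region], abs=1e-12)

    def test_manifest_and_clinical_schema(self, tmp_path, tiny_cohort):
        import yaml
        import pandas as pd

        cohort, _, _ = tiny_cohort
        manifest_path = write_cohort(cohort, tmp_path / "c2")
        with open(manifest_path) as fh:
            manifest = yaml.safe_load(fh)
        assert len(manifest["subjects"]) == len(cohort.records)
        clin = pd.read_csv(manifest["clinical_csv"])
        for col in ("subject_id", "group", "updrs3", "dd_diag_months",
                    "dd_sympt_months", "moca", "age"):
            assert col in clin.columns
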
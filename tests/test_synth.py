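import numpy as np
import pytest

from conedose import GammaCriteria, ValidationError, gamma_1d
from conedose.pdd import extract_pdd_metrics, normalize_pdd
from conedose.profile import extract_profile_metrics
from conedose.reference_data import OUTPUT_FACTORS, PROFILE_SHAPE_MM
from conedose.synth import (
    BeamModelParams,
    GenerationError,
    NoiseModel,
    PddShape,
    ProfileShape,
    gen_pdd,
    gen_plane,
    gen_profile,
)


class TestGenPdd:
    def test_r50_calibration_hits_reference_beam_quality(self):
        # 10x10 reference field beam quality at SSD 100 cm
        curve = gen_pdd(BeamModelParams(pdd=PddShape(r50_mm=25.06)))
        m = extract_pdd_metrics(curve)
        assert m.r50_mm == pytest.approx(25.06, abs=0.02)

    def test_surface_dose_parameter(self):
        curve = gen_pdd(BeamModelParams(pdd=PddShape(surface_percent=80.0,
                                                     buildup_scale_mm=5.0)))
        norm = normalize_pdd(curve)
        assert norm.doses[0] == pytest.approx(80.0, abs=0.5)

    def test_same_seed_bit_identical_different_seed_not(self):
        p = lambda s: BeamModelParams(pdd=PddShape(),
                                      noise=NoiseModel(relative_sd=0.02, seed=s))
        a, b = gen_pdd(p(42)), gen_pdd(p(42))
        c = gen_pdd(p(43))
        assert np.array_equal(a.doses, b.doses)
        assert not np.array_equal(a.doses, c.doses)

    def test_max_dose_scaling(self):
        curve = gen_pdd(BeamModelParams(pdd=PddShape(), max_dose=0.685))
        assert curve.doses.max() == pytest.approx(0.685, abs=1e-12)

    def test_impossible_calibration_raises(self):
        with pytest.raises((GenerationError, ValidationError)):
            gen_pdd(BeamModelParams(pdd=PddShape(r50_mm=25.0, r100_mm=24.0)))


class TestGenProfile:
    def test_fwhm_and_penumbra_calibration(self):
        # fixed-cone 2 cm in-plane shape: FWHM 22.7 mm, penumbra ~7.5 mm
        params = BeamModelParams(
            profile=ProfileShape(half_width_mm=11.35, penumbra_mm=7.5))
        curve = gen_profile(params, depth_mm=9.99)
        m = extract_profile_metrics(curve)
        assert m.fwhm_mm == pytest.approx(22.7, abs=0.1)
        mean_pen = 0.5 * (m.penumbra_left_mm + m.penumbra_right_mm)
        assert mean_pen == pytest.approx(7.5, abs=0.05)

    def test_sharp_edge_limit(self):
        params = BeamModelParams(profile=ProfileShape(half_width_mm=10.0,
                                                      edge_scale_mm=0.05))
        curve = gen_profile(params, depth_mm=14.0, grid_step_mm=0.01)
        m = extract_profile_metrics(curve)
        assert m.fwhm_mm == pytest.approx(20.0, abs=0.02)
        assert m.penumbra_right_mm < 0.2

    def test_undersampled_penumbra_warns(self):
        params = BeamModelParams(profile=ProfileShape(half_width_mm=10.0,
                                                      edge_scale_mm=0.5))
        with pytest.warns(UserWarning, match="under-sampled"):
            gen_profile(params, depth_mm=14.0, grid_step_mm=1.0)

    def test_plane_central_cut_equals_profile(self):
        params = BeamModelParams(profile=ProfileShape(half_width_mm=10.0))
        prof = gen_profile(params, depth_mm=14.0, grid_step_mm=1.0)
        plane = gen_plane(params, depth_mm=14.0, grid_step_mm=1.0)
        center_row = plane.values[plane.shape[0] // 2]
        assert np.allclose(center_row, prof.doses, atol=1e-9)


class TestNoiseEffect:
    def test_gamma_pass_rate_non_increasing_in_noise(self):
        """Averaged over 20 seeds, adding measurement noise can only hurt the
        1%/1mm agreement with the noiseless curve."""
        base = gen_pdd(BeamModelParams(pdd=PddShape()))
        ref = normalize_pdd(base)
        crit = GammaCriteria(dose_percent=1, dta_mm=1)
        mean_rates = []
        for sd in (0.002, 0.01, 0.03):
            rates = []
            for seed in range(20):
                noisy = gen_pdd(BeamModelParams(
                    pdd=PddShape(), noise=NoiseModel(relative_sd=sd, seed=seed)))
                rates.append(gamma_1d(ref, normalize_pdd(noisy), crit).pass_rate_percent)
            mean_rates.append(np.mean(rates))
        assert mean_rates[0] >= mean_rates[1] >= mean_rates[2]
        assert mean_rates[2] < 100.0


class TestStudyDataset:
    def test_metric_targets_hit(self, study_dataset):
        """Spot-check calibrated targets across the paired dataset."""
        m = extract_pdd_metrics(study_dataset.pdds[("cutout", 2.0, 100.0)])
        assert m.r50_mm == pytest.approx(23.19, abs=0.02)
        assert m.r100_mm == pytest.approx(9.01, abs=0.02)
        pm = extract_profile_metrics(study_dataset.profiles[("fixed_cone", 2.0, "inplane")])
        fwhm, pen_l, pen_r = PROFILE_SHAPE_MM[("fixed_cone", 2.0, "inplane")]
        assert pm.fwhm_mm == pytest.approx(fwhm, abs=0.1)
        assert 0.5 * (pm.penumbra_left_mm + pm.penumbra_right_mm) == pytest.approx(
            0.5 * (pen_l + pen_r), abs=0.05)

    def test_outputs_encode_benchmark_ofs(self, study_dataset):
        for (fld, ssd), (of_c, of_fc, _, _) in OUTPUT_FACTORS.items():
            ref_max = study_dataset.reference_pdds[ssd].doses.max()
            c_max = study_dataset.pdds[("cutout", fld, ssd)].doses.max()
            fc_max = study_dataset.pdds[("fixed_cone", fld, ssd)].doses.max()
            assert c_max / ref_max == pytest.approx(of_c, abs=1e-9)
            assert fc_max / ref_max == pytest.approx(of_fc, abs=1e-9)

    def test_broader_cone_profiles(self, study_dataset):
        """Fixed-cone profiles are broader than the cutout's at every field."""
        for fld in (2.0, 3.0, 4.0, 5.0):
            for plane in ("inplane", "crossplane"):
                mc = extract_profile_metrics(study_dataset.profiles[("cutout", fld, plane)])
                mf = extract_profile_metrics(
                    study_dataset.profiles[("fixed_cone", fld, plane)])
                assert mf.fwhm_mm > mc.fwhm_mm
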
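import numpy as np
import pytest
from scipy.special import erfinv

from conedose import ScanCurve, ScanMeta, extract_profile_metrics, normalize_profile
from conedose.profile import FieldSizeUndefinedError
from conedose.synth import BeamModelParams, ProfileShape, gen_profile

from oracles import crossing_oracle


def erf_profile_curve(half_width, edge_scale, step=0.1, tilt=0.0):
    from scipy.special import erf

    x = np.round(np.arange(-(half_width + 25), half_width + 25 + step / 2, step), 10)
    u = edge_scale * np.sqrt(2)
    d = 50.0 * (erf((x + half_width) / u) - erf((x - half_width) / u))
    d = d * (1 + tilt * x)
    return ScanCurve(x, np.maximum(d, 0.0), axis="crossplane",
                     meta=ScanMeta(depth_mm=14.0))


class TestFwhm:
    def test_ideal_rectangle(self, rect_profile):
        m = extract_profile_metrics(rect_profile)
        assert m.fwhm_mm == pytest.approx(20.0, abs=0.15)

    def test_erf_edge_fwhm_at_nominal_width(self):
        # the 50% point of an erf edge sits at the nominal aperture edge
        m = extract_profile_metrics(erf_profile_curve(10.0, 3.0))
        assert m.fwhm_mm == pytest.approx(20.0, abs=0.05)

    def test_never_below_50_raises(self):
        x = np.linspace(-20, 20, 41)
        d = np.full(41, 90.0) + np.cos(x / 20)
        with pytest.raises(FieldSizeUndefinedError):
            extract_profile_metrics(ScanCurve(x, d, axis="inplane",
                                              meta=ScanMeta(depth_mm=14.0)))

    @pytest.mark.parametrize("width", [10.0, 16.0, 21.0, 27.0])
    def test_generator_round_trip(self, width):
        """Generated FWHM recovered within 0.1 mm at 0.1 mm sampling,
        noiseless, across the study's field-size span."""
        params = BeamModelParams(profile=ProfileShape(half_width_mm=width / 2))
        curve = gen_profile(params, depth_mm=14.0, grid_step_mm=0.1)
        m = extract_profile_metrics(curve)
        assert m.fwhm_mm == pytest.approx(width, abs=0.1)


class TestPenumbra:
    def test_erf_edge_penumbra_matches_dense_oracle(self):
        curve = erf_profile_curve(10.0, 3.0)
        m = extract_profile_metrics(curve)
        norm = normalize_profile(curve, mode="cax")
        x80 = crossing_oracle(norm.positions, norm.doses, 80.0, "right")
        x20 = crossing_oracle(norm.positions, norm.doses, 20.0, "right")
        assert m.penumbra_right_mm == pytest.approx(x20 - x80, abs=0.01)
        # single-edge closed form: 2*sqrt(2)*erfinv(0.6)*s, valid when the
        # edges are well separated
        closed = 2 * np.sqrt(2) * erfinv(0.6) * 3.0
        assert m.penumbra_right_mm == pytest.approx(closed, rel=0.02)

    def test_sharp_edge_limit(self):
        m = extract_profile_metrics(erf_profile_curve(10.0, 0.05, step=0.01))
        assert m.fwhm_mm == pytest.approx(20.0, abs=0.02)
        assert m.penumbra_right_mm < 0.15

    def test_tail_never_reaches_20_percent(self):
        x = np.linspace(-30, 30, 121)
        d = np.where(np.abs(x) <= 10, 100.0, 30.0)  # floor above 20%
        with pytest.warns(UserWarning, match="penumbra"):
            m = extract_profile_metrics(ScanCurve(x, d, axis="inplane",
                                                  meta=ScanMeta(depth_mm=14.0)))
        assert m.penumbra_left_mm is None and m.penumbra_right_mm is None
        assert m.fwhm_mm == pytest.approx(20.0, abs=1.0)


class TestSymmetryProperties:
    def test_mirroring_swaps_penumbras(self):
        curve = erf_profile_curve(10.0, 2.0, tilt=0.004)
        m = extract_profile_metrics(curve)
        mirrored = ScanCurve(-curve.positions[::-1], curve.doses[::-1],
                             axis=curve.axis, meta=curve.meta)
        mm = extract_profile_metrics(mirrored)
        assert mm.penumbra_left_mm == pytest.approx(m.penumbra_right_mm, abs=1e-9)
        assert mm.penumbra_right_mm == pytest.approx(m.penumbra_left_mm, abs=1e-9)
        assert mm.fwhm_mm == pytest.approx(m.fwhm_mm, abs=1e-9)

    def test_dose_scaling_invariance(self):
        curve = erf_profile_curve(10.0, 3.0)
        scaled = curve.with_doses(curve.doses * 3.0)
        m1, m2 = extract_profile_metrics(curve), extract_profile_metrics(scaled)
        assert m2.fwhm_mm == m1.fwhm_mm
        assert m2.penumbra_left_mm == m1.penumbra_left_mm


class TestNormalizeProfile:
    def test_symmetric_profile_modes_agree(self):
        curve = erf_profile_curve(10.0, 3.0)
        a = normalize_profile(curve, mode="cax")
        b = normalize_profile(curve, mode="max")
        assert np.allclose(a.doses, b.doses, rtol=1e-6)

    def test_tilted_profile_modes_differ_by_tilt(self):
        curve = erf_profile_curve(10.0, 3.0, tilt=0.01)
        cax = normalize_profile(curve, mode="cax")
        mx = normalize_profile(curve, mode="max")
        cax_ref = np.interp(0.0, curve.positions, curve.doses)
        peak = curve.doses.max()
        assert peak > cax_ref
        assert np.allclose(cax.doses / mx.doses, peak / cax_ref)

    def test_no_central_sample_rejected(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(Exception):
            normalize_profile(ScanCurve(x, [1, 2, 2, 1], axis="inplane",
                                        meta=ScanMeta(depth_mm=10.0)), mode="cax")
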
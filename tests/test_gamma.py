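import numpy as np
import pytest

from conedose import (
    DoseGrid,
    GammaCriteria,
    ScanCurve,
    ScanMeta,
    ValidationError,
    gamma_1d,
    gamma_2d,
)

from oracles import brute_gamma_1d, brute_gamma_2d


def depth_curve(doses, step=1.0):
    z = step * np.arange(len(doses))
    return ScanCurve(z, doses, axis="depth")


def circular_plane(radius_mm=10.0, edge_mm=3.0, extent_mm=20.0, spacing=1.0,
                   scale=100.0):
    from scipy.special import erf

    ax = np.arange(-extent_mm, extent_mm + spacing / 2, spacing)
    r = np.hypot(ax[:, None], ax[None, :])
    u = edge_mm * np.sqrt(2)
    vals = 0.5 * (erf((r + radius_mm) / u) - erf((r - radius_mm) / u))
    vals = scale * vals / vals.max()
    return DoseGrid(vals, spacing_mm=(spacing, spacing),
                    origin_mm=(float(ax[0]), float(ax[0])))


class TestIdentityAndClosedForms:
    def test_identity_curve_gamma_zero(self):
        doses = 100.0 * np.exp(-0.5 * ((np.arange(50) - 20) / 8.0) ** 2)
        c = depth_curve(doses)
        res = gamma_1d(c, c, GammaCriteria(dose_percent=2, dta_mm=2))
        assert res.pass_rate_percent == 100.0
        assert np.allclose(res.gamma_values, 0.0)

    def test_uniform_offset_of_exact_dose_criterion(self):
        """A flat distribution offset by exactly the dose criterion gives
        gamma = 1 everywhere (the spatial search cannot help on a flat field)."""
        ref = depth_curve(np.full(40, 100.0))
        ev = depth_curve(np.full(40, 102.0))
        res = gamma_1d(ref, ev, GammaCriteria(dose_percent=2, dta_mm=2))
        assert np.allclose(res.gamma_values, 1.0, atol=1e-6)

    def test_ramp_shifted_by_exact_dta(self):
        """Steep constant-gradient ramp shifted by exactly the DTA: the
        closed-form optimum is beta/sqrt(1+beta^2) with beta = g*dta/dose_tol,
        approaching 1 for steep gradients."""
        step, g, dta = 0.1, 10.0, 2.0
        x = np.arange(0.0, 60.0 + step / 2, step)
        ref = ScanCurve(x, 10.0 + g * x, axis="depth")
        ev = ScanCurve(x, 10.0 + g * np.clip(x - dta, 0, None), axis="depth")
        crit = GammaCriteria(dose_percent=2, dta_mm=dta,
                             normalization="global_prescribed",
                             prescribed_dose=100.0, low_dose_cutoff_percent=0.0,
                             step_fraction=0.02)
        res = gamma_1d(ref, ev, crit)
        beta = g * dta / 2.0  # dose tolerance = 2% of 100
        expected = beta / np.hypot(1.0, beta)
        interior = (ref.positions > 10) & (ref.positions < 50)
        interior_gamma = res.gamma_values[interior]  # cutoff=0 keeps all points
        assert np.allclose(interior_gamma, expected, atol=5e-3)
        assert np.allclose(interior_gamma, 1.0, atol=0.01)

    def test_identical_planes_pass_100(self):
        plane = circular_plane()
        res = gamma_2d(plane, plane, GammaCriteria(dose_percent=3, dta_mm=3))
        assert res.pass_rate_percent == 100.0
        assert np.nanmax(res.gamma_map) == 0.0


class TestOracleEquivalence:
    def test_1d_matches_brute_force(self):
        rng = np.random.default_rng(11)
        z = np.arange(0.0, 40.0, 0.5)
        ref_d = 100 / (1 + np.exp((z - 25) / 3.0)) * (1 - 0.3 * np.exp(-z / 5))
        ev_d = ref_d * (1 + rng.normal(0, 0.01, z.size))
        ref = ScanCurve(z, ref_d, axis="depth")
        ev = ScanCurve(z, np.maximum(ev_d, 0), axis="depth")
        crit = GammaCriteria(dose_percent=2, dta_mm=2, step_fraction=0.004)
        res = gamma_1d(ref, ev, crit)
        _, brute = brute_gamma_1d(z, ref_d, z, ev.doses, 2, 2)
        assert res.gamma_values.shape == brute.shape
        assert np.max(np.abs(res.gamma_values - brute)) < 0.01

    def test_2d_scaled_plane_matches_brute_force(self):
        """A plane against itself scaled by 1.05 at 3%/3mm: in-field points
        fail with gamma ~ 5/3; the windowed search equals the exhaustive
        all-pairs oracle within 0.01."""
        ref = circular_plane(radius_mm=10.0, edge_mm=2.5, extent_mm=18.0,
                             spacing=1.0)
        ev = DoseGrid(ref.values * 1.05, spacing_mm=ref.spacing_mm,
                      origin_mm=ref.origin_mm)
        # search step 0.05 mm divides the 1 mm grid spacing, so the windowed
        # implementation and the global exhaustive oracle sample identical
        # candidate lattices and differences isolate the search shortcuts
        crit = GammaCriteria(dose_percent=3, dta_mm=3, step_fraction=0.05 / 3,
                             search_radius_factor=2.0)
        res = gamma_2d(ref, ev, crit)
        in_field = ref.values >= 0.999 * ref.values.max()  # flat plateau only
        assert np.nanmin(res.gamma_map[in_field]) > 1.0
        center = res.gamma_map[ref.shape[0] // 2, ref.shape[1] // 2]
        assert center == pytest.approx(5.0 / 3.0, abs=0.02)
        brute = brute_gamma_2d(ref.axis_coords(), ref.values,
                               ev.axis_coords(), ev.values, 3, 3,
                               dense_step=0.05,
                               gamma_bound=res.gamma_values + 0.05)
        assert brute.shape == res.gamma_values.shape
        assert np.max(np.abs(res.gamma_values - brute)) < 0.01


class TestProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_pass_rate_monotone_in_criteria_1d(self, seed):
        rng = np.random.default_rng(100 + seed)
        z = np.arange(0.0, 40.0, 0.5)
        ref_d = 100 / (1 + np.exp((z - 22 - rng.uniform(-2, 2)) / 3.0))
        ev_d = np.maximum(ref_d * (1 + rng.normal(0, 0.02, z.size)), 0)
        ref, ev = ScanCurve(z, ref_d, axis="depth"), ScanCurve(z, ev_d, axis="depth")
        rates = [
            gamma_1d(ref, ev, GammaCriteria(dose_percent=p, dta_mm=d)).pass_rate_percent
            for p, d in ((1, 1), (2, 2), (3, 3))
        ]
        assert rates[0] <= rates[1] <= rates[2]

    def test_gamma_asymmetry(self):
        z = np.arange(0.0, 40.0, 0.5)
        ref_d = 100 / (1 + np.exp((z - 25) / 3.0))
        ev_d = 100 / (1 + np.exp((z - 25) / 2.0))
        a = gamma_1d(ScanCurve(z, ref_d, axis="depth"),
                     ScanCurve(z, ev_d, axis="depth"),
                     GammaCriteria(dose_percent=1, dta_mm=1))
        b = gamma_1d(ScanCurve(z, ev_d, axis="depth"),
                     ScanCurve(z, ref_d, axis="depth"),
                     GammaCriteria(dose_percent=1, dta_mm=1))
        assert abs(a.gamma_values.mean() - b.gamma_values.mean()) > 1e-3

    def test_low_dose_cutoff_reduces_points(self):
        z = np.arange(0.0, 40.0, 0.5)
        d = 100 / (1 + np.exp((z - 20) / 2.0))
        c = ScanCurve(z, d, axis="depth")
        all_pts = gamma_1d(c, c, GammaCriteria(dose_percent=2, dta_mm=2,
                                               low_dose_cutoff_percent=0.0))
        cut = gamma_1d(c, c, GammaCriteria(dose_percent=2, dta_mm=2,
                                           low_dose_cutoff_percent=10.0))
        assert cut.n_evaluated < all_pts.n_evaluated == z.size

    def test_cutoff_excluding_everything_rejected(self):
        c = depth_curve(np.full(10, 1.0))
        with pytest.raises(ValidationError):
            gamma_1d(c, c, GammaCriteria(dose_percent=2, dta_mm=2,
                                         low_dose_cutoff_percent=150.0))

    def test_disjoint_ranges_rejected(self):
        a = ScanCurve([0, 1, 2, 3], [1, 2, 3, 4], axis="depth")
        b = ScanCurve([10, 11, 12, 13], [1, 2, 3, 4], axis="depth")
        with pytest.raises(ValidationError):
            gamma_1d(a, b, GammaCriteria(dose_percent=2, dta_mm=2))
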
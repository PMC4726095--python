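"""Amassed-profile math: alpha factor, inversion, Stokes buoyancy, flow rate."""

import numpy as np
import pytest

from xpiv import (
    AmassedProfileModel,
    StokesParams,
    VelocityField,
    alpha,
    amassed_profile,
    buoyancy_correct,
    fit_profile,
    flow_rate,
    stokes_terminal_velocity,
)


def mc_chord_alpha(xi, k, n=200_000, seed=0):
    """Monte-Carlo chord average of u(r)/V_max at offset xi (brute-force oracle)."""
    rng = np.random.default_rng(seed)
    ell = np.sqrt(1.0 - xi * xi)
    eta = rng.uniform(0.0, ell, size=n)
    r = np.sqrt(xi * xi + eta * eta)
    return float(np.mean(1.0 - r ** k))


class TestAlpha:
    @pytest.mark.parametrize("k", [1.0, 2.0, 3.31, 5.0, 8.0])
    def test_centerline_closed_form(self, k):
        # axial chord: alpha(0, K) = K / (K + 1)
        assert alpha(0.0, k) == pytest.approx(k / (k + 1.0), abs=1e-6)
        assert alpha(0.0, k, method="adaptive") == pytest.approx(k / (k + 1.0), abs=1e-6)

    @pytest.mark.parametrize("xi", [0.0, 0.3, 0.5, 0.8, 0.95])
    def test_parabolic_closed_form(self, xi):
        assert alpha(xi, 2.0) == pytest.approx((2.0 / 3.0) * (1 - xi * xi), abs=1e-6)

    def test_plug_flow_limit(self):
        assert alpha(0.0, 1e6) > 0.999

    def test_wall_and_outside_return_zero(self):
        assert alpha(1.0, 3.0) == 0.0
        assert alpha(np.array([0.5, 1.2]), 3.0)[1] == 0.0

    def test_monotone_decreasing_in_xi_and_bounded(self):
        xi = np.linspace(0.0, 0.99, 50)
        for k in (1.0, 2.0, 5.0):
            a = alpha(xi, k)
            assert np.all(np.diff(a) < 0)
            assert np.all((a >= 0) & (a <= 1))

    @pytest.mark.parametrize("xi", [0.0, 0.25, 0.5, 0.75, 0.9])
    @pytest.mark.parametrize("k", [1.0, 2.0, 3.31, 5.0, 8.0])
    def test_quadrature_matches_monte_carlo_chord_oracle(self, xi, k):
        mc = mc_chord_alpha(xi, k)
        assert alpha(xi, k) == pytest.approx(mc, rel=3e-3, abs=3e-4)

    def test_fixed_and_adaptive_quadrature_agree(self):
        xi = np.linspace(0, 0.95, 12)
        fixed = alpha(xi, 3.31)
        adaptive = alpha(xi, 3.31, method="adaptive")
        assert np.allclose(fixed, adaptive, atol=1e-8)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            alpha(0.5, 0.5)
        with pytest.raises(ValueError):
            alpha(-0.1, 2.0)


class TestAmassedProfile:
    def test_center_and_wall_values(self):
        v = amassed_profile(np.array([0.0, 500.0, -500.0]), 50.0, 3.0, 500.0)
        assert v[0] == pytest.approx(50.0 * 3.0 / 4.0)
        assert v[1] == pytest.approx(0.0, abs=1e-12)
        assert v[2] == pytest.approx(0.0, abs=1e-12)

    def test_zero_outside_lumen_with_center_offset(self):
        # station at |800 - 200| = 600 um from the axis lies outside R = 500 um
        v = amassed_profile(np.array([800.0, 300.0]), 50.0, 2.0, 500.0, x0=200.0)
        assert v[0] == 0.0
        assert v[1] == pytest.approx(50.0 * alpha(100.0 / 500.0, 2.0))


class TestFitProfile:
    @staticmethod
    def samples(v_max=30.0, k=3.31, r=500.0, x0=600.0, n=25, span=0.95):
        x = np.linspace(x0 - span * r, x0 + span * r, n)
        return x, amassed_profile(x, v_max, k, r, x0)

    def test_noiseless_recovery_at_blood_like_k(self):
        x, v = self.samples(k=3.31)
        fit = fit_profile(x, v, radius=500.0)
        assert abs(fit.k - 3.31) < 0.01
        assert fit.v_max == pytest.approx(30.0, rel=1e-3)
        assert fit.x0 == pytest.approx(600.0, abs=1.0)

    def test_parabolic_ground_truth(self):
        x, v = self.samples(k=2.0)
        fit = fit_profile(x, v, radius=500.0)
        assert 1.95 <= fit.k <= 2.05

    def test_noisy_recovery_90_percent_within_10pct(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(50):
            x, v = self.samples(k=3.31)
            noisy = v * (1.0 + 0.03 * rng.standard_normal(v.shape))
            fit = fit_profile(x, noisy, radius=500.0)
            if abs(fit.k - 3.31) / 3.31 <= 0.10:
                hits += 1
        assert hits >= 45

    def test_free_radius_recovered_from_full_span(self):
        x, v = self.samples(k=3.0, span=0.99, n=41)
        fit = fit_profile(x, v, radius=None)
        assert fit.r == pytest.approx(500.0, rel=0.02)
        assert fit.k == pytest.approx(3.0, rel=0.02)

    def test_too_few_or_too_narrow_samples_rejected(self):
        x, v = self.samples(n=5)
        with pytest.raises(ValueError):
            fit_profile(x, v, radius=500.0)
        x, v = self.samples(span=0.25)
        with pytest.raises(ValueError, match="60%"):
            fit_profile(x, v, radius=500.0)

    def test_results_object_summary_and_prediction(self):
        x, v = self.samples()
        res = AmassedProfileModel(x, v, radius=500.0).fit()
        text = res.summary()
        assert "v_max" in text and "mL/min" in text
        assert np.allclose(res.predict(x), v, atol=0.15)
        assert res.fit.q_ml_min == pytest.approx(
            flow_rate(res.v_max, res.k, 500.0), rel=1e-9
        )
        assert res.bse["v_max"] >= 0.0


class TestStokes:
    def test_neutral_buoyancy_gives_zero(self):
        assert stokes_terminal_velocity(
            StokesParams(rho_particle=1060.0, rho_fluid=1060.0)
        ) == 0.0

    def test_quadratic_diameter_scaling(self):
        v1 = stokes_terminal_velocity(StokesParams(diameter_um=10.0))
        v2 = stokes_terminal_velocity(StokesParams(diameter_um=20.0))
        assert v2 == pytest.approx(4.0 * v1)

    def test_co2_bubble_worked_example(self):
        # 13.3 um CO2 bubble in blood: ~0.043 mm/s terminal rise velocity
        v_t = stokes_terminal_velocity(
            StokesParams(diameter_um=13.3, rho_fluid=1060.0, rho_particle=1.8,
                         viscosity=2.4e-3, gravity=9.81)
        )
        assert v_t == pytest.approx(0.043, rel=0.05)

    def test_invalid_viscosity(self):
        with pytest.raises(ValueError):
            StokesParams(viscosity=0.0)


def physical_field(u_mms, v_mms):
    shape = u_mms.shape
    return VelocityField(
        x_px=np.arange(shape[1], dtype=float), y_px=np.arange(shape[0], dtype=float),
        u=u_mms / 1.8994, v=v_mms / 1.8994,
        pc=np.full(shape, 0.9), sr=np.full(shape, 0.2),
        valid=np.ones(shape, bool), n_pairs=np.ones(shape, int),
        pixel_pitch=1.8994, frame_rate=1000.0,
        u_mms=u_mms, v_mms=v_mms,
    )


class TestBuoyancy:
    def test_zero_terminal_velocity_is_identity(self):
        f = physical_field(np.full((4, 4), 10.0), np.zeros((4, 4)))
        out = buoyancy_correct(f, 0.0)
        assert np.allclose(out.u_mms, f.u_mms)
        assert np.allclose(out.v_mms, f.v_mms)

    def test_rise_component_subtracted(self):
        # 10 mm/s upward flow (negative row direction); bubbles rise at 0.043
        f = physical_field(np.zeros((4, 4)), np.full((4, 4), -10.0))
        out = buoyancy_correct(f, 0.043, gravity_direction=(1.0, 0.0))
        assert np.allclose(out.v_mms, -9.957)
        # correction below 0.5% of the mean speed
        assert 0.043 / 10.0 < 0.005

    def test_pixel_units_rejected(self):
        f = physical_field(np.ones((4, 4)), np.ones((4, 4)))
        f.u_mms = None
        with pytest.raises(ValueError, match="physical"):
            buoyancy_correct(f, 0.043)


class TestFlowRate:
    def test_poiseuille_closed_form(self):
        q = flow_rate(50.0, 2.0, 500.0)
        expected = (50e-3) * np.pi * (500e-6) ** 2 * 0.5 * 6e7
        assert q == pytest.approx(expected, rel=1e-12)
        assert q == pytest.approx(1.178, abs=5e-4)

    def test_plug_flow_limit(self):
        assert flow_rate(50.0, 1e9, 500.0) == pytest.approx(
            (50e-3) * np.pi * (500e-6) ** 2 * 6e7, rel=1e-6
        )

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            flow_rate(10.0, 2.0, -5.0)
        with pytest.raises(ValueError):
            flow_rate(10.0, 0.5, 100.0)
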
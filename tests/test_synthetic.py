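import numpy as np
import pytest
from hypothesis import given, strategies as st

import rheonmr as rn
from rheonmr.synthetic import CouetteSolverError


class TestStressProfile:
    def test_direct_evaluation(self):
        geo = rn.CouetteGeometry(inner_radius=10e-3, outer_radius=11e-3, height=50e-3)
        sigma = rn.stress_profile(1.0e-3, geo, [10.5e-3])
        assert sigma[0] == pytest.approx(
            1.0e-3 / (2 * np.pi * (10.5e-3) ** 2 * 50e-3), rel=1e-12
        )
        assert sigma[0] == pytest.approx(28.87, abs=0.01)

    def test_zero_torque(self, geometry):
        r = np.linspace(geometry.inner_radius, geometry.outer_radius, 5)
        assert np.all(rn.stress_profile(0.0, geometry, r) == 0.0)

    @given(torque=st.floats(1e-6, 1.0))
    def test_inner_outer_ratio(self, torque):
        geo = rn.CouetteGeometry()
        s = rn.stress_profile(torque, geo, [geo.inner_radius, geo.outer_radius])
        assert s[0] / s[1] == pytest.approx(
            (geo.outer_radius / geo.inner_radius) ** 2, rel=1e-12
        )
        assert s[0] > s[1]

    def test_outside_gap_rejected(self, geometry):
        with pytest.raises(ValueError):
            rn.stress_profile(1e-3, geometry, [geometry.outer_radius + 1e-4])


class TestCouetteForwardSolve:
    def test_newtonian_closed_form(self, geometry):
        """tau0=0, n=1 must match the analytic Couette velocity pointwise."""
        omega = 0.5
        sol = rn.couette_forward_solve(geometry, rn.HBParams(0.0, 1.0, 1.0), omega)
        r = sol.profile.r
        ri, ro = geometry.inner_radius, geometry.outer_radius
        v_exact = omega * (ro**2 / r - r) * ri**2 / (ro**2 - ri**2)
        np.testing.assert_allclose(sol.profile.v, v_exact, atol=1e-12 * omega * ri)
        assert sol.yield_radius is None

    def test_zero_rotation(self, geometry):
        hb = rn.HBParams(100.0, 30.0, 0.47)
        sol = rn.couette_forward_solve(geometry, hb, 0.0)
        assert np.all(sol.profile.v == 0.0)
        assert sol.at_yield_limit
        assert sol.torque == pytest.approx(
            2 * np.pi * geometry.inner_radius**2 * geometry.height * 100.0
        )

    def test_torque_consistency(self, geometry):
        """sigma(Ri) * 2 pi Ri^2 H equals the returned torque."""
        hb = rn.HBParams(80.0, 30.0, 0.47)
        sol = rn.couette_forward_solve(geometry, hb, 0.5)
        sigma_i = rn.stress_profile(sol.torque, geometry, [geometry.inner_radius])[0]
        back = sigma_i * 2 * np.pi * geometry.inner_radius**2 * geometry.height
        assert back == pytest.approx(sol.torque, rel=1e-8)

    def test_no_slip_at_rotor(self, geometry):
        omega = 0.5
        sol = rn.couette_forward_solve(geometry, rn.HBParams(50.0, 30.0, 0.47), omega)
        assert sol.profile.v[0] == pytest.approx(omega * geometry.inner_radius, rel=1e-9)

    def test_shear_localization(self, geometry):
        """Large yield stress confines flow to an inner band; outer band arrested."""
        hb = rn.HBParams(800.0, 30.0, 0.47)
        sol = rn.couette_forward_solve(geometry, hb, 0.1)
        assert sol.yield_radius is not None
        assert geometry.inner_radius < sol.yield_radius < geometry.outer_radius
        arrested = sol.profile.r > sol.yield_radius
        assert arrested.sum() >= 2
        np.testing.assert_allclose(sol.profile.v[arrested], 0.0, atol=1e-15)
        # stress at the yield radius equals the yield stress
        s_ry = rn.stress_profile(sol.torque, geometry, [sol.yield_radius])[0]
        assert s_ry == pytest.approx(800.0, rel=1e-9)


class TestNoise:
    def test_sigma_zero_identity(self, geometry):
        sol = rn.couette_forward_solve(geometry, rn.HBParams(0.0, 1.0, 1.0), 0.5)
        out = rn.noisy_profile(sol.profile, rn.NoiseSpec(sigma=0.0, seed=3))
        np.testing.assert_array_equal(out.v, sol.profile.v)

    def test_seed_determinism(self, geometry):
        sol = rn.couette_forward_solve(geometry, rn.HBParams(0.0, 1.0, 1.0), 0.5)
        spec = rn.NoiseSpec(sigma=1e-4, seed=42)
        a = rn.noisy_profile(sol.profile, spec)
        b = rn.noisy_profile(sol.profile, spec)
        np.testing.assert_array_equal(a.v, b.v)
        c = rn.noisy_profile(sol.profile, rn.NoiseSpec(sigma=1e-4, seed=43))
        assert np.any(a.v != c.v)

    def test_additive_sigma_statistics(self):
        rng_values = np.zeros(20000)
        spec = rn.NoiseSpec(sigma=0.01, seed=5)
        out = spec.apply(rng_values)
        assert np.std(out) == pytest.approx(0.01, rel=0.05)

    def test_multiplicative_fraction(self):
        values = np.full(20000, 50.0)
        out = rn.NoiseSpec("multiplicative-gaussian", 0.02, seed=6).apply(values)
        assert np.std(out / values - 1.0) == pytest.approx(0.02, rel=0.05)


class TestSKMSeries:
    def test_limits_and_half_decay(self):
        p = rn.SKMParams(80.1, 44.0, 0.012)
        assert p.tau0(0.0) == pytest.approx(80.1)
        assert p.tau0(1e12) == pytest.approx(44.0, rel=1e-9)
        # at ks*t = 1 the decaying part has halved: (80.1-44)/2 + 44
        assert p.tau0(1.0 / 0.012) == pytest.approx(62.05)

    @given(st.floats(0.0, 1e4), st.floats(0.0, 1e4))
    def test_monotone_noiseless(self, t1, t2):
        p = rn.SKMParams(271.0, 182.0, 0.11)
        lo, hi = sorted([t1, t2])
        assert p.tau0(lo) >= p.tau0(hi)

    def test_seeded_series(self):
        p = rn.SKMParams(80.1, 44.0, 0.012)
        t = np.linspace(0, 500, 20)
        spec = rn.NoiseSpec("multiplicative-gaussian", 0.05, seed=11)
        a = rn.skm_series(p, t, spec)
        b = rn.skm_series(p, t, spec)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(rn.skm_series(p, t), p.tau0(t))


class TestDT2Signal:
    def test_single_component_separable(self, pgse_dt2):
        t = 2.2e-3 * np.arange(1, 65)
        ds = rn.dt2_signal([(2.0, 9e-10, 0.15)], pgse_dt2, t)
        lnS = np.log(ds.signal)
        expected = np.log(2.0) - np.outer(pgse_dt2.b_values(), np.full(t.size, 9e-10)) \
            - t[None, :] / 0.15
        np.testing.assert_allclose(lnS, expected, rtol=1e-10)

    def test_amplitude_normalization(self, pgse_dt2):
        t = 2.2e-3 * np.arange(1, 9)
        comps = [(0.4, 9e-10, 0.15), (0.6, 4e-12, 0.08)]
        ds = rn.dt2_signal(comps, pgse_dt2, t)
        # extrapolated S(g=0, t=0) is the amplitude sum
        b = pgse_dt2.b_values()
        s00 = sum(a for a, _, _ in comps)
        back = sum(a * np.exp(-b[0] * D) * np.exp(-t[0] / T2) for a, D, T2 in comps)
        assert ds.signal[0, 0] == pytest.approx(back, rel=1e-12)
        assert ds.signal[0, 0] < s00

    def test_bi_exponential_cpmg_trace(self, pgse_dt2):
        """The weakest-gradient echo train is (nearly) the bi-exponential CPMG decay."""
        t = 2.2e-3 * np.arange(1, 257)
        comps = [(0.4, 9e-10, 0.15), (0.6, 4e-12, 0.08)]
        ds = rn.dt2_signal(comps, pgse_dt2, t)
        b0 = pgse_dt2.b_values()[0]
        expected = 0.4 * np.exp(-b0 * 9e-10) * np.exp(-t / 0.15) \
            + 0.6 * np.exp(-b0 * 4e-12) * np.exp(-t / 0.08)
        np.testing.assert_allclose(ds.signal[0], expected, rtol=1e-12)

    def test_rejects_bad_components(self, pgse_dt2):
        with pytest.raises(ValueError):
            rn.dt2_signal([(0.0, 9e-10, 0.15)], pgse_dt2, [2.2e-3])
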
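import numpy as np
import pytest
from scipy.optimize import nnls

import rheonmr as rn
from rheonmr.dt2 import (
    ILT2D,
    build_kernels,
    default_d_grid,
    default_t2_grid,
    detect_peaks,
    _fista_nonneg,
)

ECHOES_64 = 2.2e-3 * np.arange(1, 65)


def small_dataset(pgse8, components, noise=None):
    return rn.dt2_signal(components, pgse8, 2.2e-3 * np.arange(1, 9), noise=noise)


@pytest.fixture(scope="module")
def pgse8():
    return rn.PGSEParams(tuple(np.linspace(0.1, 6.6, 8)), 1e-3, 0.2)


class TestKernels:
    def test_zero_encoding_rows_are_ones(self):
        pg = rn.PGSEParams(tuple([0.0, 1.0, 3.0]), 1e-3, 0.2)
        ds = rn.dt2_signal([(1.0, 9e-10, 0.15)], pg, [0.0, 1e-3, 1e-2])
        K1, K2 = build_kernels(ds, default_d_grid(16), default_t2_grid(16))
        np.testing.assert_array_equal(K1[0], 1.0)  # g = 0
        np.testing.assert_array_equal(K2[0], 1.0)  # t = 0

    def test_non_log_spaced_grid_rejected(self, pgse8):
        ds = small_dataset(pgse8, [(1.0, 9e-10, 0.15)])
        with pytest.raises(ValueError, match="log-spaced"):
            build_kernels(ds, np.linspace(1e-13, 1e-8, 16), default_t2_grid(16))


class TestILT2D:
    def test_single_component_concentrates_on_grid(self, pgse_dt2):
        """A noiseless on-grid exponential pair reconstructs within one cell.

        Needs the full 256-echo train: a shorter window cannot pin T2 values
        beyond its own length and the mass smears along the T2 axis.
        """
        Dg, Tg = default_d_grid(32), default_t2_grid(32)
        D0, T20 = Dg[22], Tg[20]
        ds = rn.dt2_signal([(1.0, D0, T20)], pgse_dt2, 2.2e-3 * np.arange(1, 257))
        est = ILT2D(D_grid=Dg, T2_grid=Tg, reg_weight=1e-6, max_iter=40000,
                    tol=1e-12).fit(ds)
        i0, j0 = 22, 20
        window = est.F_[i0 - 1:i0 + 2, j0 - 1:j0 + 2]
        assert window.sum() >= 0.95 * est.F_.sum()

    def test_total_mass_conserved(self, pgse_dt2):
        """Map mass matches the extrapolated S(g=0, t=0) amplitude within 2%."""
        ds = rn.dt2_signal([(0.7, 9e-10, 0.15), (0.5, 4e-12, 0.08)],
                           pgse_dt2, ECHOES_64)
        est = ILT2D(D_grid=default_d_grid(32), T2_grid=default_t2_grid(32),
                    reg_weight=1e-6, max_iter=40000, tol=1e-12).fit(ds)
        assert est.F_.sum() == pytest.approx(1.2, rel=0.02)

    def test_compressed_equals_bruteforce_nnls(self, pgse8):
        """SVD-compressed FISTA solve == uncompressed NNLS on an 8x8 instance."""
        ds = small_dataset(pgse8, [(1.0, 9e-10, 0.15), (0.8, 4e-12, 0.08)])
        Dg = np.logspace(-13, -8, 8)
        Tg = np.logspace(-3, np.log10(3.0), 8)
        K1, K2 = build_kernels(ds, Dg, Tg)
        lam = 1e-2
        A = np.kron(K2, K1)
        augmented = np.vstack([A, np.sqrt(lam) * np.eye(64)])
        rhs = np.concatenate([ds.signal.flatten(order="F"), np.zeros(64)])
        x, _ = nnls(augmented, rhs)
        F_oracle = x.reshape(8, 8, order="F")
        est = ILT2D(D_grid=Dg, T2_grid=Tg, reg_weight=lam, sv_threshold=1e-13,
                    max_iter=200000, tol=1e-14).fit(ds)
        assert np.abs(est.F_ - F_oracle).max() < 1e-6

    def test_axis_reordering_invariance(self, pgse_dt2):
        """Permuting gradient rows and echo columns with their axes leaves the
        solution mass unchanged (the program is permutation-invariant)."""
        ds = rn.dt2_signal([(1.0, 9e-10, 0.15)], pgse_dt2, ECHOES_64)
        kw = dict(D_grid=default_d_grid(16), T2_grid=default_t2_grid(16),
                  reg_weight=1e-4, max_iter=40000, tol=1e-12)
        est = ILT2D(**kw).fit(ds)
        # reverse echo order (gradients must stay ascending for the dataclass,
        # so permute the echo dimension, which the solver never sorts)
        perm = np.arange(ECHOES_64.size)[::-1]
        ds_perm = rn.DT2Dataset(
            gradient_strengths=ds.gradient_strengths,
            echo_times=ds.echo_times[perm],
            signal=ds.signal[:, perm],
            pgse=ds.pgse,
        )
        est_perm = ILT2D(**kw).fit(ds_perm)
        assert abs(est.F_.sum() - est_perm.F_.sum()) < 1e-6 * est.F_.sum()
        np.testing.assert_allclose(est_perm.F_, est.F_, atol=1e-8 * est.F_.max())

    def test_peak_height_decreases_with_regularization(self, pgse_dt2):
        ds = rn.dt2_signal([(1.0, 9e-10, 0.15)], pgse_dt2, ECHOES_64)
        heights = []
        for lam in [1e-6, 1e-4, 1e-2, 1.0]:
            est = ILT2D(D_grid=default_d_grid(16), T2_grid=default_t2_grid(16),
                        reg_weight=lam, max_iter=30000, tol=1e-11).fit(ds)
            heights.append(est.F_.max())
        assert all(a >= b * (1 - 1e-9) for a, b in zip(heights, heights[1:]))

    def test_discrepancy_principle_residual(self, pgse_dt2):
        """Auto-selected lambda leaves a residual within 2x the injected noise."""
        comps = [(0.6, 9e-10, 0.15), (0.4, 4e-12, 0.08)]
        clean = rn.dt2_signal(comps, pgse_dt2, ECHOES_64)
        sigma = clean.signal.max() / 500
        ds = rn.dt2_signal(comps, pgse_dt2, ECHOES_64,
                           noise=rn.NoiseSpec(sigma=sigma, seed=9))
        est = ILT2D(D_grid=default_d_grid(32), T2_grid=default_t2_grid(32)).fit(ds)
        # tail-based noise estimate recovers the injected level, and the
        # residual at lambda_auto stays within 2x the full noise norm
        assert est.noise_sigma_ == pytest.approx(sigma, rel=0.5)
        assert est.residual_ <= 2.0 * sigma * np.sqrt(ds.signal.size)

    def test_empty_signal_gives_empty_map(self, pgse_dt2):
        ds = rn.DT2Dataset(
            gradient_strengths=pgse_dt2.g,
            echo_times=ECHOES_64,
            signal=np.zeros((32, 64)),
            pgse=pgse_dt2,
        )
        est = ILT2D().fit(ds)
        assert est.F_.sum() == 0.0
        assert "empty-signal" in est.flags_


class TestPeaks:
    def _map_two(self, pgse_dt2):
        comps = [(0.4, 9e-10, 0.15), (0.6, 4e-12, 0.08)]
        clean = rn.dt2_signal(comps, pgse_dt2, 2.2e-3 * np.arange(1, 257))
        ds = rn.dt2_signal(comps, pgse_dt2, 2.2e-3 * np.arange(1, 257),
                           noise=rn.NoiseSpec(sigma=clean.signal.max() / 500, seed=7))
        return rn.ilt2d(ds)

    def test_water_is_high_diffusivity_component(self, pgse_dt2):
        m = self._map_two(pgse_dt2)
        assert len(m.peaks) >= 2
        D_w, T2_w, mass = rn.extract_water_peak(m)
        assert D_w > 1e-10  # free-water-like mobility
        assert 0.05 < T2_w < 0.5
        assert mass == pytest.approx(0.4, rel=0.15)

    def test_single_component_map_returns_it(self, pgse_dt2):
        ds = rn.dt2_signal([(1.0, 9e-10, 0.15)], pgse_dt2, ECHOES_64)
        m = rn.ilt2d(ds, D_grid=default_d_grid(32), T2_grid=default_t2_grid(32),
                     reg_weight=1e-5)
        D_w, _, mass = rn.extract_water_peak(m)
        assert D_w == pytest.approx(9e-10, rel=0.3)
        assert mass == pytest.approx(m.total_mass, rel=0.05)

    def test_equal_d_tie_breaks_by_mass(self):
        """Two regions at the same D coordinate: the heavier one wins."""
        Dg, Tg = default_d_grid(16), default_t2_grid(16)
        F = np.zeros((16, 16))
        F[8, 3] = 1.0   # light region
        F[8, 12] = 3.0  # heavy region, same D row
        peaks = detect_peaks(F, Dg, Tg)
        m = rn.DT2Map(Dg, Tg, F, 0.0, peaks=peaks)
        _, T2_w, mass = rn.extract_water_peak(m)
        assert mass == pytest.approx(3.0)
        assert T2_w == pytest.approx(Tg[12])

    def test_no_peaks_raises(self):
        m = rn.DT2Map(default_d_grid(8), default_t2_grid(8), np.zeros((8, 8)), 0.0)
        with pytest.raises(ValueError, match="peak"):
            rn.extract_water_peak(m)


class TestCalibrationAndLength:
    def test_collinear_exact(self):
        c = np.array([1.0, 2.0, 3.0, 4.0])
        cal = rn.t2_concentration_fit(c, 0.3 - 0.02 * c)
        assert cal.slope == pytest.approx(-0.02, rel=1e-9)
        assert cal.intercept == pytest.approx(0.3, rel=1e-9)
        assert cal.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_t2_zero_slope(self):
        cal = rn.t2_concentration_fit([1.0, 2.0, 3.0], [0.2, 0.2, 0.2])
        assert cal.slope == 0.0

    def test_noisy_slope_recovered(self):
        rng = np.random.default_rng(2)
        c = np.linspace(0.5, 5.0, 12)
        t2 = 0.3 - 0.02 * c + 0.002 * rng.standard_normal(c.size)
        cal = rn.t2_concentration_fit(c, t2)
        assert cal.slope == pytest.approx(-0.02, rel=0.15)
        assert cal.r_squared > 0.9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            rn.t2_concentration_fit([1.0, 2.0], [0.1, 0.2])

    def test_diffusion_length(self):
        assert rn.diffusion_length(9e-10, 0.2) == pytest.approx(19.0e-6, rel=0.01)
        assert rn.diffusion_length(9e-10, 0.0) == 0.0
        assert rn.diffusion_length(9e-10, 0.8) == pytest.approx(
            2 * rn.diffusion_length(9e-10, 0.2)
        )
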
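"""OS-EM update properties, post-filter and the dual-isotope orchestration."""

import numpy as np
import pytest

import dualspect as d
from dualspect.mcscatter import McConfig
from dualspect.reconstruct import (ReconConfig, SelfScatterProvider,
                                   ZeroScatter, gaussian_postfilter, osem,
                                   reconstruct_dual)


def _ball_system(n=32, n_views=16, with_mu=True):
    idx = np.arange(n) - (n - 1) / 2
    xx, yy, zz = np.meshgrid(idx, idx, idx, indexing="ij")
    r2 = xx ** 2 + yy ** 2 + zz ** 2
    act = np.where(r2 < 8 ** 2, 1.0, 0.0).astype(np.float32)
    mu = None
    if with_mu:
        mu = d.AttenuationMap(
            np.where(r2 < 12 ** 2, 0.15, 0.0).astype(np.float32), 6.6, 140.0)
    geo = d.Geometry.circular(n_views=n_views, orbit_radius_mm=200.0,
                              detector_shape=(n, n), pixel_mm=6.6)
    col = d.CollimatorModel()
    eff = float(d.window_acceptance(140.0, d.TC_WINDOW, 0.099))
    system = d.SpectSystem(geo, mu, col, 140.0, 6.6, efficiency=eff)
    return act, mu, geo, col, system


def _proj(system, geo, x):
    return d.ProjectionSet(system.forward(x), np.asarray(geo.angles_deg),
                           geo.orbit_radius_mm, geo.pixel_mm)


class TestOsem:
    def test_kl_fit_monotone_on_noise_free_data(self):
        act, mu, geo, col, system = _ball_system()
        proj = _proj(system, geo, act)
        cfg = ReconConfig(iterations=8, subsets=4, scatter_update_iters=0,
                          postfilter_fwhm_cm=0.0)
        _, log = osem(proj, mu, geo, col, cfg)
        kl = [entry["kl_fit"] for entry in log]
        assert all(a >= b - 1e-9 for a, b in zip(kl, kl[1:]))

    def test_uniform_fixed_point(self):
        act, mu, geo, col, system = _ball_system()
        x0 = np.ones(act.shape, np.float32)
        proj = _proj(system, geo, x0)
        cfg = ReconConfig(iterations=1, subsets=4, scatter_update_iters=0,
                          postfilter_fwhm_cm=0.0)
        vol, _ = osem(proj, mu, geo, col, cfg)
        infield = vol.values > 0
        np.testing.assert_allclose(vol.values[infield], 1.0, rtol=1e-5)

    def test_zero_provider_equals_plain_osem(self):
        act, mu, geo, col, system = _ball_system()
        proj = _proj(system, geo, act)
        cfg = ReconConfig(iterations=3, subsets=4, scatter_update_iters=2,
                          postfilter_fwhm_cm=0.0, compute_fit=False)
        a, _ = osem(proj, mu, geo, col, cfg, scatter_provider=None)
        b, _ = osem(proj, mu, geo, col, cfg, scatter_provider=ZeroScatter())
        assert np.array_equal(a.values, b.values)

    def test_no_updates_means_provider_never_called(self):
        act, mu, geo, col, system = _ball_system()
        proj = _proj(system, geo, act)
        calls = []

        def provider(x, iteration, shape):
            calls.append(iteration)
            return np.zeros(shape, np.float32)

        cfg = ReconConfig(iterations=3, subsets=4, scatter_update_iters=0,
                          postfilter_fwhm_cm=0.0, compute_fit=False)
        a, _ = osem(proj, mu, geo, col, cfg, scatter_provider=provider)
        assert calls == []
        b, _ = osem(proj, mu, geo, col, cfg)
        assert np.array_equal(a.values, b.values)

    def test_scatter_update_schedule(self):
        act, mu, geo, col, system = _ball_system()
        proj = _proj(system, geo, act)
        calls = []

        def provider(x, iteration, shape):
            calls.append(iteration)
            return np.zeros(shape, np.float32)

        cfg = ReconConfig(iterations=6, subsets=4, scatter_update_iters=2,
                          postfilter_fwhm_cm=0.0, compute_fit=False)
        _, log = osem(proj, mu, geo, col, cfg, scatter_provider=provider)
        # iteration 1 runs scatter-free; updates fire at iterations 2..3
        assert calls == [2, 3]
        assert [e["scatter_updated"] for e in log] == [False, True, True,
                                                       False, False, False]

    def test_one_subset_matches_reference_mlem(self):
        """OS-EM with a single subset is classical MLEM; compare against an
        independently coded MLEM loop on a tiny problem."""
        act, mu, geo, col, system = _ball_system(n=16, n_views=8)
        proj = _proj(system, geo, act)
        cfg = ReconConfig(iterations=5, subsets=1, scatter_update_iters=0,
                          postfilter_fwhm_cm=0.0, compute_fit=False)
        vol, _ = osem(proj, mu, geo, col, cfg)

        y = proj.data
        eps = 1e-10 * float(y.mean(dtype=np.float64))
        sens = system.sensitivity()
        infield = sens > 0
        x = np.ones(act.shape, np.float32)
        x *= float(y.sum(dtype=np.float64)) / float(
            system.forward(x).sum(dtype=np.float64))
        for _ in range(5):
            ratio = y / (system.forward(x) + eps)
            upd = system.backward(ratio)
            x = np.where(infield, x * upd / np.maximum(sens, 1e-20),
                         x).astype(np.float32)
        np.testing.assert_allclose(vol.values, x, rtol=1e-10, atol=1e-12)

    def test_non_negativity_preserved(self):
        act, mu, geo, col, system = _ball_system()
        rng = np.random.default_rng(0)
        noisy = rng.poisson(system.forward(act) * 50.0).astype(np.float32)
        proj = d.ProjectionSet(noisy, np.asarray(geo.angles_deg), 200.0, 6.6)
        cfg = ReconConfig(iterations=3, subsets=4, scatter_update_iters=0,
                          compute_fit=False)
        vol, log = osem(proj, mu, geo, col, cfg)
        assert np.all(vol.values >= 0)
        assert len(log) == cfg.iterations

    def test_negative_projections_rejected(self):
        act, mu, geo, col, system = _ball_system()
        bad = _proj(system, geo, act)
        bad.data[0, 0, 0] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            osem(bad, mu, geo, col, ReconConfig())

    def test_subsets_must_divide_views(self):
        act, mu, geo, col, system = _ball_system()
        proj = _proj(system, geo, act)
        with pytest.raises(ValueError, match="divide"):
            osem(proj, mu, geo, col, ReconConfig(subsets=5))


class TestPostfilter:
    def test_zero_fwhm_is_identity(self):
        v = np.random.default_rng(0).uniform(0, 1, (16, 16, 16))
        np.testing.assert_array_equal(gaussian_postfilter(v, 0.0, 6.6), v)

    def test_interior_totals_preserved(self):
        v = np.zeros((32, 32, 32), np.float32)
        v[12:20, 12:20, 12:20] = 1.0
        out = gaussian_postfilter(v, 0.9, 6.6)
        assert out.sum() == pytest.approx(v.sum(), rel=1e-3)

    def test_delta_kernel_fwhm(self):
        from scipy.optimize import curve_fit
        v = np.zeros((33, 33, 33), np.float32)
        v[16, 16, 16] = 1.0
        out = gaussian_postfilter(v, 0.9, 3.0)  # 3 mm voxels resolve the kernel
        profile = out[:, 16, 16].astype(np.float64)
        xs = (np.arange(33) - 16) * 3.0

        def gauss(x, a, sig):
            return a * np.exp(-0.5 * (x / sig) ** 2)

        popt, _ = curve_fit(gauss, xs, profile, p0=(profile.max(), 4.0))
        assert abs(popt[1]) * 2.3548 == pytest.approx(9.0, rel=0.03)


class TestDualReconstruction:
    def test_zero_tc_equals_single_isotope_tl(self, ball_phantom):
        act, mu_map = ball_phantom
        geo = d.Geometry.circular(n_views=16, orbit_radius_mm=200.0,
                                  detector_shape=(32, 32), pixel_mm=6.6)
        col = d.CollimatorModel()
        eff = float(d.window_acceptance(72.0, d.TL_WINDOW, 0.099))
        system = d.SpectSystem(geo, mu_map, col, 72.0, 6.6, efficiency=eff)
        tl_proj = d.ProjectionSet(system.forward(act.values),
                                  np.asarray(geo.angles_deg), 200.0, 6.6)
        tc_proj = tl_proj.copy_with(np.zeros_like(tl_proj.data))
        mc = McConfig(photons=2_000, seed=5)
        cfg = ReconConfig(iterations=2, subsets=4, scatter_update_iters=1,
                          mc=mc, compute_fit=False)
        dual = reconstruct_dual(tc_proj, tl_proj, mu_map, geo, col, cfg,
                                McConfig(photons=2_000, seed=6), cfg)
        provider = SelfScatterProvider(mu_map, d.TL201, d.TL_WINDOW, geo, col,
                                       mc, resolution_frac=0.099)
        single, _ = osem(tl_proj, mu_map, geo, col, cfg, provider,
                         emission=d.TL201, window=d.TL_WINDOW)
        assert dual.downscatter.total() == 0.0
        assert np.array_equal(dual.tl.values, single.values)

    def test_fixed_seed_reproducible(self, ball_phantom):
        act, mu_map = ball_phantom
        geo = d.Geometry.circular(n_views=16, orbit_radius_mm=200.0,
                                  detector_shape=(32, 32), pixel_mm=6.6)
        col = d.CollimatorModel()
        system = d.SpectSystem(geo, mu_map, col, 140.0, 6.6)
        proj = d.ProjectionSet(system.forward(act.values),
                               np.asarray(geo.angles_deg), 200.0, 6.6)
        cfg = ReconConfig(iterations=2, subsets=4, scatter_update_iters=1,
                          mc=McConfig(photons=2_000, seed=3), compute_fit=False)
        runs = [reconstruct_dual(proj, proj, mu_map, geo, col, cfg,
                                 McConfig(photons=2_000, seed=4), cfg)
                for _ in range(2)]
        assert np.array_equal(runs[0].tc.values, runs[1].tc.values)
        assert np.array_equal(runs[0].tl.values, runs[1].tl.values)
        assert np.array_equal(runs[0].downscatter.data,
                              runs[1].downscatter.data)

    def test_mismatched_geometries_rejected(self, ball_phantom):
        act, mu_map = ball_phantom
        geo = d.Geometry.circular(n_views=8, orbit_radius_mm=200.0,
                                  detector_shape=(32, 32), pixel_mm=6.6)
        a = d.ProjectionSet(np.ones((8, 32, 32), np.float32),
                            np.asarray(geo.angles_deg), 200.0, 6.6)
        b = d.ProjectionSet(np.ones((8, 16, 16), np.float32),
                            np.asarray(geo.angles_deg), 200.0, 3.3)
        with pytest.raises(ValueError, match="share geometry"):
            reconstruct_dual(a, b, mu_map, geo, d.CollimatorModel(),
                             ReconConfig(), McConfig(), ReconConfig())
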
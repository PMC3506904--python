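"""Phantom voxelisation, noise model and study simulation contracts."""

import numpy as np
import pytest

import dualspect as d
from dualspect.phantom import (ORGAN_IDS, CardiacPhantom, DefectSpec,
                               PhantomSpec, StudySpec)


class TestCardiacPhantom:
    def test_organ_concentration_ratios(self, cardiac_phantom):
        ph = cardiac_phantom
        organs = ph.organs
        ant = ph.defect_mask("anterior")
        myo = (organs == ORGAN_IDS["myocardium"]) & ~ant \
            & ~ph.defect_mask("septal")
        liver = organs == ORGAN_IDS["liver"]
        assert ph.tc.values[liver].max() / ph.tc.values[myo].max() == 0.5
        assert ph.tc.values[ant].max() == pytest.approx(
            0.2 * ph.tc.values[myo].max())

    def test_defect_reversibility(self, cardiac_phantom):
        # Phantom 3: anterior defect irreversible (both volumes), septal
        # reversible (Tl only)
        sept = cardiac_phantom.defect_mask("septal")
        assert np.all(cardiac_phantom.tl.values[sept] == pytest.approx(20.0))
        assert np.all(cardiac_phantom.tc.values[sept] == pytest.approx(180.0))

    def test_organ_labels_partition(self, cardiac_phantom):
        # labels are a single grid, so exclusivity holds by construction;
        # check the builder rejects overlapping geometry instead
        spec = d.cardiac_phantom_spec(3)
        spec.geometry["liver"]["center"] = spec.geometry["heart"]["center"]
        with pytest.raises(ValueError, match="overlap"):
            d.build_cardiac_phantom(spec)

    def test_activity_conservation(self, cardiac_phantom):
        """Total Tl activity equals sum(concentration x voxel count)."""
        ph = cardiac_phantom
        conc = {"myocardium": 50.0, "ventricle": 3.0, "lung": 2.0,
                "liver": 3.0, "background": 3.0}
        defects = np.zeros(ph.organs.shape, bool)
        expected = 0.0
        for spec, mask in ph.defect_masks:
            defects |= mask
            expected += spec.fraction * conc["myocardium"] * mask.sum()
        for organ, c in conc.items():
            expected += c * ((ph.organs == ORGAN_IDS[organ]) & ~defects).sum()
        assert ph.tl.total() == pytest.approx(expected, rel=1e-6)

    def test_attenuation_ordering(self, cardiac_phantom):
        mu = cardiac_phantom.mu_map
        lab = cardiac_phantom.mu_map.labels
        lung = mu.mu[lab == 2].max()
        soft = mu.mu[lab == 1].max()
        bone = mu.mu[lab == 3].max()
        assert lung < soft < bone

    def test_zero_activities_zero_volumes(self):
        spec = d.cardiac_phantom_spec(3)
        spec.activities = {"tc": {}, "tl": {}}
        ph = d.build_cardiac_phantom(spec)
        assert ph.tc.total() == 0 and ph.tl.total() == 0

    def test_wall_thickness_must_be_positive(self):
        spec = d.cardiac_phantom_spec(3)
        spec.geometry["heart"]["wall_mm"] = -1.0
        with pytest.raises(ValueError, match="wall"):
            d.build_cardiac_phantom(spec)


class TestJaszczakPhantom:
    def test_concentrations_from_compartment_totals(self):
        ph = d.build_jaszczak_phantom(d.jaszczak_phantom_spec())
        organs = ph.organs
        ant = ph.defect_mask("anterior")
        myo = (organs == ORGAN_IDS["myocardium"]) & ~ant \
            & ~ph.defect_mask("inferior")
        voxel_cm3 = (ph.voxel_mm / 10.0) ** 3
        n_myo = ((organs == ORGAN_IDS["myocardium"])
                 & ~ant & ~ph.defect_mask("inferior")).sum()
        # Tl defect/myocardium concentration ratio follows the compartment
        # totals scaled by compartment volumes
        c_myo = ph.tl.values[myo].max()
        c_def = ph.tl.values[ant].max()
        expected = (0.04 / (ant.sum() * voxel_cm3)) / (8.18 / (n_myo * voxel_cm3))
        assert c_def / c_myo == pytest.approx(expected, rel=1e-5)
        # anterior defect is reversible: absent from the Tc volume
        assert np.all(ph.tc.values[ant] == ph.tc.values[myo].max())

    def test_total_activity_matches_compartments(self):
        ph = d.build_jaszczak_phantom(d.jaszczak_phantom_spec())
        voxel_cm3 = (ph.voxel_mm / 10.0) ** 3
        assert ph.tl.total() * voxel_cm3 == pytest.approx(
            8.18 + 0.34 + 0.04 + 0.04, rel=1e-4)

    def test_uniform_cylinder_conservation(self):
        spec = PhantomSpec(
            grid=(32, 32, 32), voxel_mm=6.6,
            geometry={"cylinder": {"radius": 80.0, "half_height": 80.0}},
            activities={"tl": {"background": 5.0}, "tc": {}},
            activity_mode="per_voxel",
        )
        ph = d.build_jaszczak_phantom(spec)
        n = (ph.organs == ORGAN_IDS["background"]).sum()
        assert ph.tl.total() == pytest.approx(5.0 * n)

    def test_degenerate_cylinder_rejected(self):
        spec = d.jaszczak_phantom_spec()
        spec.geometry["cylinder"]["radius"] = 0.0
        with pytest.raises(ValueError, match="radius"):
            d.build_jaszczak_phantom(spec)


class TestDefectSpec:
    @pytest.mark.parametrize("kwargs", [
        {"sector": "apex", "fraction": 0.2},
        {"sector": "anterior", "fraction": 1.5},
        {"sector": "anterior", "fraction": 0.2, "extent_deg": 0.0},
        {"sector": "anterior", "fraction": 0.2, "isotopes": "xx"},
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DefectSpec(**kwargs)


class TestPoissonNoise:
    def _uniform(self, value=5.0):
        data = np.full((16, 32, 32), value, np.float32)
        return d.ProjectionSet(data, np.arange(16) * 22.5, 200.0, 6.6)

    def test_fano_factor_near_one(self):
        proj = self._uniform()
        target = 100.0 * proj.data.size
        noisy = d.add_poisson_noise(proj, target, seed=5)
        mean = noisy.data.mean()
        var = noisy.data.var()
        assert 0.9 < var / mean < 1.1
        assert noisy.total() == pytest.approx(target, rel=0.01)

    def test_unit_scale_when_target_equals_total(self):
        proj = self._uniform()
        noisy = d.add_poisson_noise(proj, proj.total(), seed=1)
        assert noisy.meta["count_scale_factor"] == pytest.approx(1.0)

    def test_seed_reproducibility(self):
        proj = self._uniform()
        a = d.add_poisson_noise(proj, 1e5, seed=9)
        b = d.add_poisson_noise(proj, 1e5, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_all_zero_input_rejected(self):
        zeros = self._uniform(0.0)
        with pytest.raises(ValueError, match="all-zero"):
            d.add_poisson_noise(zeros, 1e5, seed=0)


class TestCollapse:
    def test_factor_two_preserves_totals(self):
        rng = np.random.default_rng(0)
        proj = d.ProjectionSet(rng.uniform(0, 10, (4, 128, 128)),
                               np.arange(4) * 90.0, 250.0, 3.3)
        out = d.collapse_projections(proj, 2)
        assert out.data.shape == (4, 64, 64)
        assert out.total() == pytest.approx(proj.total(), rel=1e-6)
        assert out.pixel_mm == pytest.approx(6.6)

    def test_factor_one_identity(self):
        proj = d.ProjectionSet(np.ones((2, 16, 16)), [0.0, 90.0], 200.0, 6.6)
        assert d.collapse_projections(proj, 1) is proj

    def test_uniform_view_scales_by_factor_squared(self):
        proj = d.ProjectionSet(np.full((1, 16, 16), 3.0), [0.0], 200.0, 6.6)
        out = d.collapse_projections(proj, 2)
        assert np.all(out.data == 12.0)


def _ball_as_phantom(ball_phantom, tc_scale=1.0):
    act, mu_map = ball_phantom
    tc = act.copy_with(act.values * tc_scale)
    return CardiacPhantom(tc, act, mu_map, np.zeros(act.shape, np.int8), (),
                          PhantomSpec(grid=act.shape, voxel_mm=act.voxel_mm))


@pytest.fixture(scope="module")
def small_study():
    return StudySpec(n_views=16, orbit_radius_mm=200.0,
                     detector_shape=(32, 32), pixel_mm=6.6,
                     tc_counts=2e5, tl_dual_counts=2e5, tl_pure_counts=5e4)


class TestSimulateStudy:
    def test_zero_tc_means_no_crosstalk(self, ball_phantom, small_study):
        ph = _ball_as_phantom(ball_phantom, tc_scale=0.0)
        sim = d.simulate_study(ph, small_study,
                               mc_config=d.McConfig(photons=20_000, seed=3),
                               seed=3)
        np.testing.assert_array_equal(sim.expected_tl_dual.data,
                                      sim.expected_tl_pure.data)
        assert sim.downscatter.total() == 0.0

    def test_downscatter_adds_counts(self, ball_phantom, small_study):
        ph = _ball_as_phantom(ball_phantom, tc_scale=4.0)
        sim = d.simulate_study(ph, small_study,
                               mc_config=d.McConfig(photons=20_000, seed=4),
                               seed=4)
        assert sim.downscatter.total() > 0
        assert (sim.expected_tl_dual.total()
                > sim.expected_tl_pure.total())

    def test_fixed_seed_bitwise_reproducible(self, ball_phantom, small_study):
        ph = _ball_as_phantom(ball_phantom)
        kwargs = dict(mc_config=d.McConfig(photons=20_000, seed=7), seed=7)
        a = d.simulate_study(ph, small_study, **kwargs)
        b = d.simulate_study(ph, small_study, **kwargs)
        for x, y in ((a.tc, b.tc), (a.tl_dual, b.tl_dual),
                     (a.tl_pure, b.tl_pure)):
            assert np.array_equal(x.data, y.data)

    def test_window_totals_hit_targets(self, ball_phantom, small_study):
        ph = _ball_as_phantom(ball_phantom)
        sim = d.simulate_study(ph, small_study,
                               mc_config=d.McConfig(photons=20_000, seed=8),
                               seed=8)
        assert sim.tc.total() == pytest.approx(2e5, rel=0.02)
        assert sim.tl_dual.total() == pytest.approx(2e5, rel=0.02)
        assert sim.tl_pure.total() == pytest.approx(5e4, rel=0.02)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            StudySpec(tc_window=d.EnergyWindow(100.0, 0.5),
                      tl_window=d.EnergyWindow(95.0, 0.5))
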
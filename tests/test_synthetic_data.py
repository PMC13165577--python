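"""Forward phantom physics and the deterministic chip renderer."""

import numpy as np
import pytest

from hemoflow import synthetic_data as syn
from hemoflow.chip_model import DomainError


class TestDeliveredHematocrit:
    def test_no_sedimentation_is_constant(self):
        blood = syn.SyntheticBloodModel(sed_amplitude=0.0)
        sched = (("on", 100.0),)
        assert syn.delivered_hematocrit(0.0, sched, blood) == blood.hct0
        assert syn.delivered_hematocrit(99.0, sched, blood) == blood.hct0

    def test_starts_at_hct0(self):
        blood = syn.SyntheticBloodModel(sed_amplitude=0.3)
        assert syn.delivered_hematocrit(0.0, (("on", 10.0),), blood) \
            == pytest.approx(blood.hct0)

    def test_off_period_accelerates_sedimentation(self):
        # oracle: evaluate the sedimentation clock for both schedules by hand
        blood = syn.SyntheticBloodModel(sed_amplitude=0.3, sed_tau_s=600.0,
                                        stasis_kappa=4.0)
        t = 1500.0
        with_off = (("on", 100.0), ("off", 1200.0), ("on", 1000.0))
        all_on = (("on", 3000.0),)
        h_off = syn.delivered_hematocrit(t, with_off, blood)
        h_on = syn.delivered_hematocrit(t, all_on, blood)
        assert h_off > h_on
        s_expected = 100.0 + 1200.0 * 4.0 + 200.0
        expected = blood.hct0 * (1 + blood.aggregability * 0.3
                                 * (1 - np.exp(-s_expected / 600.0)))
        assert h_off == pytest.approx(expected, rel=1e-12)

    def test_capped_at_080(self):
        blood = syn.SyntheticBloodModel(hct0=0.7, sed_amplitude=0.5,
                                        sed_tau_s=1.0)
        assert syn.delivered_hematocrit(1e4, (("on", 1e5),), blood) == 0.8


class TestPhantomViscosity:
    def test_cell_free_limit_is_medium_viscosity(self):
        assert syn.phantom_viscosity(0.0, 0.0) == pytest.approx(1.0)
        assert syn.phantom_viscosity(0.0, 20.0) == pytest.approx(2.5)

    def test_monotone_in_hct_and_dextran(self):
        assert syn.phantom_viscosity(0.5, 10.0) > syn.phantom_viscosity(0.3, 10.0)
        assert syn.phantom_viscosity(0.5, 20.0) > syn.phantom_viscosity(0.5, 10.0)

    def test_domain_error_near_packing(self):
        with pytest.raises(DomainError):
            syn.phantom_viscosity(0.99, 0.0)


class TestAggregationDeficit:
    def test_zero_aggregability_and_zero_dextran(self):
        assert syn.phantom_aggregation_deficit(0.5, 20.0, 0.0, 10.0) == 0.0
        assert syn.phantom_aggregation_deficit(0.5, 0.0, 1.0, 10.0) == 0.0

    def test_dextran_response_peaks_at_15(self):
        vals = {c: syn.phantom_aggregation_deficit(0.5, c, 1.0, 10.0)
                for c in (5.0, 10.0, 15.0, 20.0)}
        assert max(vals, key=vals.get) == 15.0

    def test_decreasing_in_shear_and_bounded(self):
        lo = syn.phantom_aggregation_deficit(0.5, 15.0, 1.0, 10.0)
        hi = syn.phantom_aggregation_deficit(0.5, 15.0, 1.0, 500.0)
        assert 0 < hi < lo <= 0.5


class TestRenderBurst:
    def _state(self, **kw):
        base = dict(t_s=0.0, delivering=True, hct=0.0, mu_b_cP=1.0,
                    alpha_b=0.5, u_mc_mm_s=2.0, u_ac_mm_s=0.1, ai_target=0.0)
        base.update(kw)
        return syn.TriggerState(**base)

    def test_noiseless_blank_channels_at_background(self, geometry):
        settings = syn.RenderSettings(particle_density_mm2=0.0)
        frames = syn.render_burst(self._state(), geometry, settings,
                                  np.random.default_rng(0))
        assert (frames[0][geometry.roi_mc.rows, :] == 220).all()
        assert (frames[0][geometry.roi_ac.rows, :] == 220).all()

    def test_interface_row_is_quantized_alpha(self, geometry):
        settings = syn.RenderSettings(particle_density_mm2=0.0)
        alpha = 0.485
        frames = syn.render_burst(self._state(hct=0.5, alpha_b=alpha),
                                  geometry, settings, np.random.default_rng(0))
        vc = frames[0][geometry.roi_vc.rows, :]
        col = vc[:, 0]
        n_blood = int((col < 220).sum())
        assert n_blood == round(alpha * geometry.width_px)

    def test_burst_frames_differ_only_by_particle_motion(self, geometry):
        settings = syn.RenderSettings()
        frames = syn.render_burst(self._state(u_mc_mm_s=0.0, u_ac_mm_s=0.0),
                                  geometry, settings, np.random.default_rng(1))
        np.testing.assert_array_equal(frames[0], frames[1])
        moving = syn.render_burst(self._state(u_mc_mm_s=10.0, u_ac_mm_s=0.0),
                                  geometry, settings, np.random.default_rng(1))
        assert (moving[0] != moving[1]).any()
        # motion confined to the mc band
        outside = np.ones(geometry.frame_shape[0], dtype=bool)
        outside[geometry.roi_mc.rows] = False
        np.testing.assert_array_equal(moving[0][outside], moving[1][outside])

    def test_aliasing_warning_on_large_displacement(self, geometry):
        settings = syn.RenderSettings()
        with pytest.warns(RuntimeWarning, match="alias"):
            syn.render_burst(self._state(u_mc_mm_s=40.0), geometry, settings,
                             np.random.default_rng(0))


class TestGenerateDataset:
    def test_same_seed_bit_identical(self, geometry):
        scen = syn.SyntheticScenario(schedule=(("on", 5.0),), seed=9)
        blood = syn.SyntheticBloodModel()
        s1, m1 = syn.generate_dataset(scen, blood, geometry)
        s2, m2 = syn.generate_dataset(scen, blood, geometry)
        np.testing.assert_array_equal(s1, s2)
        assert m1.records == m2.records

    def test_control_blood_constant_interface(self, geometry):
        scen = syn.SyntheticScenario(q_b_ml_h=0.4, q_r_ml_h=0.8,
                                     schedule=(("on", 5.0),), seed=3)
        blood = syn.SyntheticBloodModel(cdex_mg_ml=0.0, aggregability=0.0,
                                        sed_amplitude=0.0)
        _, manifest = syn.generate_dataset(scen, blood, geometry)
        alphas = {r["alpha_b"] for r in manifest.records}
        assert len(alphas) == 1

    def test_dextran_blood_viscosity_strictly_increases(self, geometry):
        scen = syn.SyntheticScenario(q_b_ml_h=0.4, q_r_ml_h=1.8,
                                     schedule=(("on", 8.0),), seed=3)
        blood = syn.SyntheticBloodModel(cdex_mg_ml=20.0, sed_amplitude=0.2)
        _, manifest = syn.generate_dataset(scen, blood, geometry)
        mus = [r["mu_b_cP"] for r in manifest.records]
        assert all(a < b for a, b in zip(mus, mus[1:]))

    def test_unreachable_interface_raises_actionable_error(self, geometry):
        scen = syn.SyntheticScenario(q_b_ml_h=0.4, q_r_ml_h=0.05,
                                     schedule=(("on", 2.0),), seed=1)
        blood = syn.SyntheticBloodModel(fixed_viscosity_cP=50.0)
        with pytest.raises(syn.GenerationError, match="[Aa]djust"):
            syn.generate_dataset(scen, blood, geometry)

    def test_off_triggers_have_zero_velocity_and_frozen_interface(self, geometry):
        scen = syn.SyntheticScenario(schedule=(("on", 4.0), ("off", 4.0)),
                                     seed=2)
        blood = syn.SyntheticBloodModel()
        _, manifest = syn.generate_dataset(scen, blood, geometry)
        on = [r for r in manifest.records if r["state"] == "on"]
        off = [r for r in manifest.records if r["state"] == "off"]
        assert all(r["u_mc_mm_s"] == 0.0 == r["u_ac_mm_s"] for r in off)
        assert all(r["alpha_b"] == on[-1]["alpha_b"] for r in off)

    def test_tiff_and_manifest_round_trip(self, geometry, tmp_path):
        import tifffile
        scen = syn.SyntheticScenario(schedule=(("on", 3.0),), seed=4)
        stack, manifest = syn.generate_dataset(
            scen, syn.SyntheticBloodModel(), geometry)
        tiff, mjson = tmp_path / "s.tif", tmp_path / "m.json"
        syn.save_dataset(stack, manifest, tiff, mjson)
        np.testing.assert_array_equal(tifffile.imread(tiff), stack)
        loaded = syn.GroundTruthManifest.from_json(mjson)
        assert loaded.records == manifest.records
        assert loaded.seed == manifest.seed
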
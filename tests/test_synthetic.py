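"""Generator ground-truth, determinism and embedded-association checks."""

import numpy as np
import pytest

import fire_dynamics as fd
from fire_dynamics import BurnEvent, SceneConfig
from fire_dynamics.synthetic import BASE_REFLECTANCE, generate_annual_series


def scar_dnbr(config, year):
    pre, post, truth = fd.generate_scene(config)
    d = fd.delta_nbr(fd.nbr(pre[year]), fd.nbr(post[year]))
    return d, truth


class TestSceneGeneration:
    def test_unburned_band_structure(self):
        pre, post, _ = fd.generate_scene(SceneConfig(seed=11))
        stack = pre[2001]
        noise_sd = np.hypot(0.01, 0.003)  # surface + epoch components
        for band, mean in BASE_REFLECTANCE.items():
            vals = stack.band(band)
            assert np.all(vals >= 0) and np.all(vals <= 1)
            assert abs(vals.mean() - mean) < 3 * noise_sd / np.sqrt(vals.size)
            assert 0.5 * noise_sd < vals.std() < 2.0 * noise_sd

    def test_fixed_seed_bit_identical(self, small_scene):
        pre1, post1, _ = fd.generate_scene(small_scene)
        pre2, post2, _ = fd.generate_scene(small_scene)
        for year in small_scene.years:
            for band in BASE_REFLECTANCE:
                assert np.array_equal(pre1[year].band(band),
                                      pre2[year].band(band))
                assert np.array_equal(post1[year].band(band),
                                      post2[year].band(band))

    def test_planted_severity_recovered_within_tolerance(self, small_scene):
        d, truth = scar_dnbr(small_scene, 2003)
        for ev in small_scene.burn_events:
            if ev.year != 2003:
                continue
            fp = ev.footprint(small_scene.shape)
            assert np.all(np.abs(d.values[fp] - ev.severity_dnbr) <= 0.01)

    def test_hs_event_yields_hs_class(self):
        cfg = SceneConfig(seed=5, years=(2001, 2002, 2003, 2004),
                          burn_events=(BurnEvent(2002, 3, 3, 4, 4, "HS", 0.70),))
        d, truth = scar_dnbr(cfg, 2002)
        fp = truth.burn_masks[2002]
        assert np.all((d.values[fp] >= 0.69) & (d.values[fp] <= 0.71))
        codes = fd.classify_severity(d, cfg.scheme).codes
        assert np.all(codes[fp] == cfg.scheme.code("HS"))

    def test_no_burn_events_dnbr_below_noise_bound(self):
        cfg = SceneConfig(seed=13, years=(2001, 2002, 2003, 2004))
        pre, post, _ = fd.generate_scene(cfg)
        for year in cfg.years:
            d = fd.delta_nbr(fd.nbr(pre[year]), fd.nbr(post[year]))
            assert np.abs(d.values).max() < 0.05
            codes = fd.classify_severity(d, cfg.scheme).codes
            assert np.all(codes == cfg.scheme.code("UN"))

    def test_class_map_matches_ground_truth_on_footprints(self, small_scene):
        pre, post, truth = fd.generate_scene(small_scene)
        for year in small_scene.years:
            d = fd.delta_nbr(fd.nbr(pre[year]), fd.nbr(post[year]))
            codes = fd.classify_severity(d, small_scene.scheme).codes
            fp = truth.burn_masks[year]
            assert np.array_equal(codes[fp], truth.burn_classes[year][fp])

    def test_overlapping_footprints_rejected(self):
        cfg = SceneConfig(
            seed=1, years=(2001, 2002, 2003, 2004),
            burn_events=(BurnEvent(2002, 2, 2, 4, 4, "MLS", 0.30),
                         BurnEvent(2002, 4, 4, 4, 4, "MHS", 0.50)))
        with pytest.raises(ValueError, match="overlap"):
            fd.generate_scene(cfg)

    def test_out_of_bounds_footprint_rejected(self):
        cfg = SceneConfig(
            seed=1, years=(2001, 2002, 2003, 2004),
            burn_events=(BurnEvent(2002, 14, 14, 4, 4, "MLS", 0.30),))
        with pytest.raises(ValueError, match="bounds"):
            fd.generate_scene(cfg)

    def test_severity_outside_class_interval_rejected(self):
        with pytest.raises(ValueError, match="interval"):
            fd.generate_scene(SceneConfig(
                seed=1, years=(2001, 2002, 2003, 2004),
                burn_events=(BurnEvent(2002, 2, 2, 4, 4, "HS", 0.30),)))

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            SceneConfig(grid_rows=4)
        with pytest.raises(ValueError):
            SceneConfig(years=(2003, 2002, 2004, 2005))
        with pytest.raises(ValueError):
            SceneConfig(pixel_area_ha=0.0)


class TestAnnualSeries:
    def test_four_coupled_series(self):
        out = generate_annual_series(SceneConfig(seed=2))
        assert set(out) == {"precipitation", "foci", "gpp", "co2_flux"}
        for s in out.values():
            assert len(s) == 22

    def test_precipitation_matches_configured_moments(self):
        # aggregate over replicate scenes; per-scene spread is configured sd
        vals = np.concatenate([
            generate_annual_series(SceneConfig(seed=s))["precipitation"].values
            for s in range(60)])
        assert abs(vals.mean() - 1300.0) < 25.0
        assert abs(vals.std() - 300.0) < 30.0

    def test_fewer_than_four_years_rejected(self):
        with pytest.raises(ValueError, match="4 years"):
            generate_annual_series(SceneConfig(seed=0, years=(2001, 2002, 2003)))

    def test_negative_coupling_yields_negative_correlation(self):
        neg = 0
        for s in range(200):
            out = generate_annual_series(SceneConfig(seed=s))
            r = np.corrcoef(out["foci"].values,
                            out["precipitation"].values)[0, 1]
            neg += r < 0
        assert neg / 200 >= 0.99

    def test_zero_coupling_correlation_centred_at_zero(self):
        rs = []
        for s in range(300):
            out = generate_annual_series(SceneConfig(seed=s, foci_coupling=0.0))
            rs.append(np.corrcoef(out["foci"].values,
                                  out["precipitation"].values)[0, 1])
        # mean of r over replicates ~ N(0, 1/sqrt(300*21))
        assert abs(np.mean(rs)) < 0.05

    def test_gpp_co2_coupling_negative(self):
        neg = 0
        for s in range(100):
            out = generate_annual_series(SceneConfig(seed=s))
            neg += np.corrcoef(out["gpp"].values,
                               out["co2_flux"].values)[0, 1] < 0
        assert neg == 100

    def test_planted_step_shifts_gpp_level(self):
        base = generate_annual_series(SceneConfig(seed=9))
        step = generate_annual_series(
            SceneConfig(seed=9, gpp_change_year=2012, gpp_step=0.006))
        years = base["gpp"].years
        diff = step["gpp"].values - base["gpp"].values
        assert np.allclose(diff[years < 2012], 0.0)
        assert np.allclose(diff[years >= 2012], 0.006)

    def test_expected_foci_recorded_in_truth(self):
        cfg = SceneConfig(seed=4, years=(2001, 2002, 2003, 2004, 2005))
        _, _, truth = fd.generate_scene(cfg)
        for year, lam in truth.expected_foci.items():
            assert lam > 0
        assert set(truth.precipitation) == set(cfg.years)
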
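"""The scenario generator: landscape, berry field, sugar, movement, bundle."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import special

from berryforage.grid import HABITAT_CLASSES
from berryforage.synthetic import (
    DAY_CENTER,
    DEFAULT_BERRY_PARAMS,
    DEFAULT_SUGAR_PARAMS,
    BerryFieldParams,
    LandscapeConfig,
    MovementParams,
    ScenarioConfig,
    SugarParams,
    berry_expectation_surface,
    gen_landscape,
    gen_sugar,
    make_scenario,
    rtruncnb,
    sample_plot_counts,
    sample_used_available,
    simulate_bear,
    write_scenario,
)
from berryforage.trajectory import fix_success_rate


class TestLandscape:
    def test_habitat_shares_near_targets(self):
        cfg = LandscapeConfig()
        grid = gen_landscape(cfg, np.random.default_rng(0))
        hab = grid.layers["habitat"]
        for cls, target in cfg.habitat_shares.items():
            share = np.mean(hab == HABITAT_CLASSES.index(cls))
            assert share == pytest.approx(target, abs=0.03)

    def test_single_habitat_config_uniform(self):
        cfg = LandscapeConfig(habitat_shares={"bog": 1.0}, n_rows=30, n_cols=30)
        grid = gen_landscape(cfg, np.random.default_rng(1))
        assert (grid.layers["habitat"] == HABITAT_CLASSES.index("bog")).all()

    def test_shares_must_sum_to_one(self):
        cfg = LandscapeConfig(habitat_shares={"bog": 0.5, "clearcut": 0.4})
        with pytest.raises(ValueError, match="sum to 1"):
            gen_landscape(cfg, np.random.default_rng(0))

    def test_layer_ranges(self):
        grid = gen_landscape(LandscapeConfig(), np.random.default_rng(2))
        elev = grid.layers["elevation"]
        assert elev.min() >= 200.0 and elev.max() <= 600.0
        ndvi = grid.layers["ndvi"]
        assert ndvi.min() >= -1.0 and ndvi.max() <= 0.86
        assert grid.layers["slope"].min() >= 0.0

    def test_same_seed_identical_grids(self):
        a = gen_landscape(LandscapeConfig(n_rows=40, n_cols=40), np.random.default_rng(5))
        b = gen_landscape(LandscapeConfig(n_rows=40, n_cols=40), np.random.default_rng(5))
        for name in a.layers:
            np.testing.assert_array_equal(a.layers[name], b.layers[name])


class TestBerryField:
    def _covariates(self, rng, n=20000, habitat="mature_forest"):
        return pd.DataFrame(
            {
                "habitat": habitat,
                "elevation": np.full(n, 400.0),
                "ndvi": np.full(n, 0.45),
                "ordinal_day": np.full(n, DAY_CENTER),
            }
        )

    def test_impossible_occurrence_gives_all_zero(self, rng):
        par = BerryFieldParams(
            name="none", intercept_occ=-60.0, habitat_occ={}, elevation_occ=0,
            ndvi_occ=0, day_occ=0, intercept_abn=1.0, habitat_abn={},
            elevation_abn=0, ndvi_abn=0, day_abn=0, theta=1.0,
        )
        counts = sample_plot_counts(self._covariates(rng, 2000), par, rng)
        assert (counts == 0).all()

    def test_positive_mean_matches_truncated_nb_closed_form(self, rng):
        mu, theta = 6.0, 1.2
        draws = rtruncnb(np.full(200_000, mu), theta, rng)
        assert draws.min() >= 1
        p0 = (theta / (theta + mu)) ** theta
        expected = mu / (1.0 - p0)
        assert draws.mean() == pytest.approx(expected, rel=0.01)

    def test_species_counts_essentially_uncorrelated(self, rng):
        cov = self._covariates(rng, 8000)
        bb = sample_plot_counts(cov, DEFAULT_BERRY_PARAMS["bilberry"], rng)
        lb = sample_plot_counts(cov, DEFAULT_BERRY_PARAMS["lingonberry"], rng)
        r = np.corrcoef(bb, lb)[0, 1]
        assert abs(r) < 0.05

    def test_default_day_trend_signs(self):
        bb = DEFAULT_BERRY_PARAMS["bilberry"]
        lb = DEFAULT_BERRY_PARAMS["lingonberry"]
        assert bb.day_occ < 0 and bb.day_abn < 0
        assert lb.day_occ > 0 and lb.day_abn > 0

    def test_expectation_surface_positive_and_finite(self, small_grid):
        surf = berry_expectation_surface(small_grid, DEFAULT_BERRY_PARAMS["bilberry"])
        assert np.isfinite(surf).all() and (surf >= 0).all()


class TestSugar:
    def test_zero_noise_equals_linear_predictor(self, rng):
        par = SugarParams(intercept=10.0, plottype=0.5, ndvi=0.0, day=0.0, resid_sd=0.0)
        cov = pd.DataFrame(
            {"plottype": [0, 1], "ndvi": 0.45, "ordinal_day": DAY_CENTER}
        )
        tss = gen_sugar(cov, par, rng)
        np.testing.assert_allclose(tss, [10.0, 10.5])

    def test_default_species_means(self, rng):
        # balanced used/available mix at the covariate centres
        n = 60000
        cov = pd.DataFrame(
            {
                "plottype": np.tile([0, 1], n // 2),
                "ndvi": np.full(n, 0.45),
                "ordinal_day": np.full(n, DAY_CENTER),
            }
        )
        bb = gen_sugar(cov, DEFAULT_SUGAR_PARAMS["bilberry"], rng)
        lb = gen_sugar(cov, DEFAULT_SUGAR_PARAMS["lingonberry"], rng)
        assert bb.mean() == pytest.approx(8.48, abs=0.03)
        assert lb.mean() == pytest.approx(12.04, abs=0.03)

    def test_plot_type_effect_lingonberry_only(self):
        assert DEFAULT_SUGAR_PARAMS["bilberry"].plottype == 0.0
        assert DEFAULT_SUGAR_PARAMS["lingonberry"].plottype > 0.0


class TestMovement:
    def test_transition_rows_validated(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MovementParams(transition=((0.5, 0.4, 0.0), (0.1, 0.8, 0.1), (0.2, 0.2, 0.6)))

    def test_fix_failure_rate_near_8_percent(self):
        grid = gen_landscape(LandscapeConfig(n_rows=60, n_cols=60), np.random.default_rng(0))
        surf = berry_expectation_surface(grid, DEFAULT_BERRY_PARAMS["bilberry"])
        rates = []
        rng = np.random.default_rng(3)
        for b in range(6):
            tr = simulate_bear(grid, surf, MovementParams(), f"B{b}",
                               pd.Timestamp("2014-08-07"), 14, rng)
            rates.append(fix_success_rate(tr))
        assert np.mean(rates) == pytest.approx(0.92, abs=0.01)

    def test_zero_attraction_is_unselective(self):
        # with w=0 the bilberry expectation at foraging-state fixes matches
        # the landscape average within sampling noise
        rng = np.random.default_rng(4)
        grid = gen_landscape(LandscapeConfig(n_rows=80, n_cols=80), rng)
        surf = berry_expectation_surface(grid, DEFAULT_BERRY_PARAMS["bilberry"])
        mp = MovementParams(attraction=0.0, fix_fail_prob=0.0)
        vals = []
        for b in range(4):
            tr = simulate_bear(grid, surf, mp, f"B{b}", pd.Timestamp("2014-08-07"), 21, rng)
            for f in tr.fixes:
                r, c = grid.cell_index(f.x, f.y)
                vals.append(surf[r, c])
        landscape_mean = surf.mean()
        assert np.mean(vals) == pytest.approx(landscape_mean, rel=0.25)

    def test_attraction_concentrates_on_berry_rich_cells(self):
        rng = np.random.default_rng(5)
        grid = gen_landscape(LandscapeConfig(n_rows=80, n_cols=80), rng)
        surf = berry_expectation_surface(grid, DEFAULT_BERRY_PARAMS["bilberry"])

        def mean_val(w, seed):
            r = np.random.default_rng(seed)
            mp = MovementParams(attraction=w, fix_fail_prob=0.0)
            tr = simulate_bear(grid, surf, mp, "B", pd.Timestamp("2014-08-07"), 21, r)
            vals = [surf[grid.cell_index(f.x, f.y)] for f in tr.fixes]
            return np.mean(vals)

        assert mean_val(2.0, 11) > mean_val(0.0, 11)


class TestScenarioBundle:
    def test_round_trips_through_readers(self, tmp_path):
        cfg = ScenarioConfig(
            landscape=LandscapeConfig(n_rows=50, n_cols=50), n_days=7, n_random_plots=60
        )
        scn = make_scenario(cfg, seed=7)
        write_scenario(scn, tmp_path / "scn")
        from berryforage.grid import read_landscape
        from berryforage.io import read_plots, read_telemetry

        tracks = read_telemetry(tmp_path / "scn" / "telemetry.csv")
        assert len(tracks) == scn.config.n_bears
        assert len(tracks[0]) == 7 * 48
        grid = read_landscape(tmp_path / "scn" / "grid")
        np.testing.assert_array_equal(grid.layers["habitat"], scn.grid.layers["habitat"])
        plots = read_plots(tmp_path / "scn" / "foraging_plots.csv")
        assert len(plots) == len(scn.foraging_plots)

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = ScenarioConfig(
            landscape=LandscapeConfig(n_rows=40, n_cols=40), n_days=5, n_random_plots=40
        )
        for d in ("a", "b"):
            write_scenario(make_scenario(cfg, seed=11), tmp_path / d)
        for name in ("telemetry.csv", "foraging_plots.csv", "random_plots.csv",
                     "ground_truth.json", "grid/habitat.asc"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_ground_truth_records_generating_coefficients(self, tmp_path):
        cfg = ScenarioConfig(
            landscape=LandscapeConfig(n_rows=40, n_cols=40), n_days=5, n_random_plots=40
        )
        scn = make_scenario(cfg, seed=2)
        write_scenario(scn, tmp_path / "scn")
        truth = json.loads((tmp_path / "scn" / "ground_truth.json").read_text())
        assert truth["berry"]["bilberry"]["day_occ"] == cfg.berry["bilberry"].day_occ
        assert truth["seed"] == 2
        # regeneration from (config, seed) reproduces the same truth
        again = make_scenario(cfg, seed=2)
        assert again.ground_truth["bear_effects"] == scn.ground_truth["bear_effects"]


class TestUsedAvailableGenerator:
    def test_counts_respect_explicit_plot_type_effect(self, rng):
        from dataclasses import replace

        # covariate effects zeroed so the marginal occurrence difference is
        # exactly the conditional plot-type coefficient (logit links do not
        # marginalise over varying covariates otherwise)
        par = replace(
            DEFAULT_BERRY_PARAMS["bilberry"], plottype_occ=2.0, plottype_abn=0.0,
            patch_sd_occ=0.0, patch_sd_abn=0.0, re_sd_occ=0.0, re_sd_abn=0.0,
            habitat_occ={}, elevation_occ=0.0, ndvi_occ=0.0, day_occ=0.0,
        )
        df = sample_used_available(par, n_foraging=4000, n_random=4000, rng=rng)
        occ_f = (df.loc[df.plottype == 1, "count_bilberry"] >= 1).mean()
        occ_r = (df.loc[df.plottype == 0, "count_bilberry"] >= 1).mean()
        assert special.logit(occ_f) - special.logit(occ_r) == pytest.approx(2.0, abs=0.25)

    def test_centred_columns_present(self, rng):
        df = sample_used_available(DEFAULT_BERRY_PARAMS["bilberry"], rng=rng)
        assert {"elevation_c", "ndvi_c", "day_c"} <= set(df.columns)
        assert df["day_c"].abs().max() <= 15
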
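"""Synthetic-data generator: structure, invariants and Monte-Carlo checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import occuscale as oc
from occuscale.simulate import ConfigError


class TestLandscape:
    def test_pixel_count_and_lattice(self):
        land = oc.make_landscape(oc.LandscapeConfig(extent_km=(40, 40)), seed=0)
        assert land.n_pixels == 400  # (40/2)^2
        # centres on a regular 2-km lattice
        assert np.allclose(sorted(land.pixels["x_km"].unique()), np.arange(1, 40, 2))
        lo, hi = oc.LandscapeConfig().elevation_range_m
        assert land.pixels["elevation_m"].between(lo, hi).all()

    def test_single_region_degenerate(self):
        land = oc.make_landscape(oc.LandscapeConfig(n_regions=1), seed=0)
        assert land.pixels["region_id"].nunique() == 1

    def test_determinism(self):
        a = oc.make_landscape(oc.LandscapeConfig(), seed=7)
        b = oc.make_landscape(oc.LandscapeConfig(), seed=7)
        pd.testing.assert_frame_equal(a.pixels, b.pixels)

    def test_regions_and_topo_units_cut_across(self):
        land = oc.make_landscape(oc.LandscapeConfig(n_regions=2, n_topo_units=2), seed=0)
        # every (region, topo unit) combination occurs: the partitions cross
        combos = land.pixels.groupby(["region_id", "topo_unit_id"]).size()
        assert len(combos) == 4

    @pytest.mark.parametrize(
        "kwargs", [{"extent_km": (-10, 40)}, {"n_regions": 0}, {"extent_km": (41, 40)}]
    )
    def test_config_errors(self, kwargs):
        with pytest.raises(ConfigError):
            oc.make_landscape(oc.LandscapeConfig(**kwargs), seed=0)


class TestSpeciesPool:
    def test_endemics_confined_to_one_region(self):
        land = oc.make_landscape(oc.LandscapeConfig(n_regions=2), seed=1)
        pool = oc.make_species_pool(
            land, oc.SpeciesConfig(n_species=40, endemic_fraction=1.0), seed=1
        )
        region_of = land.pixels.set_index("pixel_id")["region_id"]
        spans = pool.ranges.assign(region=region_of.loc[pool.ranges["pixel_id"]].to_numpy())
        assert (spans.groupby("species_id")["region"].nunique() == 1).all()

    def test_pool_size_and_invariants(self, landscape, pool):
        assert pool.n_species == 30
        sp = pool.species
        assert (sp["elev_min_m"] < sp["elev_max_m"]).all()
        assert (pool.ranges.groupby("species_id").size() >= 1).all()
        for name in ("forest_dependency", "diet_invert", "range_restricted"):
            assert set(np.unique(pool.traits[name])) <= {-1.0, 1.0}

    def test_ranges_are_contiguous(self, landscape, pool):
        # 4-neighbour connectivity on the pixel lattice
        s = landscape.pixel_size_km
        ny = int(round(landscape.extent_km[1] / s))
        for sid in pool.species["species_id"].head(10):
            pix = set(pool.range_pixels(sid))
            seen = {next(iter(pix))}
            frontier = list(seen)
            while frontier:
                q = frontier.pop()
                for step in (ny, -ny, 1, -1):
                    n = q + step
                    if n in pix and n not in seen:
                        seen.add(n)
                        frontier.append(n)
            assert seen == pix, f"range of species {sid} is not contiguous"

    def test_trait_moments_match_config(self):
        land = oc.make_landscape(oc.LandscapeConfig(extent_km=(20, 20)), seed=2)
        n = 5000
        pool = oc.make_species_pool(land, oc.SpeciesConfig(n_species=n), seed=2)
        # binary trait: P(+1) = 0.5 -> mean 0, SE = 2*sqrt(p(1-p)/n)
        m = pool.traits["forest_dependency"].mean()
        assert abs(m - 0.0) < 3 * 2 * np.sqrt(0.25 / n)
        # continuous trait: mean 0 sd 1
        x = pool.traits["log_mass"]
        assert abs(x.mean()) < 3 / np.sqrt(n)
        assert abs(x.std() - 1.0) < 3 / np.sqrt(2 * n)
        # rarer binary trait
        p_hat = (pool.traits["range_restricted"] > 0).mean()
        assert abs(p_hat - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)

    def test_empty_landscape_rejected(self, landscape):
        with pytest.raises(ConfigError):
            oc.make_species_pool(landscape, oc.SpeciesConfig(n_species=0), seed=0)


class TestSamplingDesign:
    def test_cluster_structure_and_spacing(self, design):
        per_cluster = design.points.groupby("cluster_id").size()
        assert per_cluster.between(2, 3).all()
        for _, grp in design.points.groupby("cluster_id"):
            xy = grp[["x_km", "y_km"]].to_numpy()
            for i in range(len(xy)):
                for j in range(i + 1, len(xy)):
                    assert np.hypot(*(xy[i] - xy[j])) >= 0.2

    def test_forest_pasture_pairing(self):
        # on a gentle landscape the pairing constraints are always satisfiable
        land = oc.make_landscape(
            oc.LandscapeConfig(elevation_range_m=(0.0, 150.0)), seed=3
        )
        des = oc.make_sampling_design(land, oc.DesignConfig(n_cluster_pairs=15), seed=3)
        cl = des.clusters
        for k in range(0, len(cl), 2):
            f, p = cl.iloc[k], cl.iloc[k + 1]
            assert {f["land_use"], p["land_use"]} == {"forest", "pasture"}
            assert np.hypot(f["x_km"] - p["x_km"], f["y_km"] - p["y_km"]) < 22.0

    def test_visit_schedule(self, design):
        v = design.visits
        assert set(v["visit_index"]) == {1, 2, 3, 4}
        assert v.groupby("point_id").size().eq(4).all()

    def test_survey_minutes(self):
        assert oc.total_survey_minutes(3357) == 33570.0


class TestTruthSimulation:
    def _flat_params(self, **over):
        p = oc.OccupancyParams.default()
        p.coef = {k: 0.0 for k in p.coef}
        p.trait_coef = {}
        p.lu_trait_coef = {}
        p.b_d2r = 0.0
        p.re_sd = {k: 0.0 for k in p.re_sd}
        for k, v in over.items():
            p.coef[k] = v
        return p

    def test_null_model_gives_half(self, landscape, pool, design):
        truth = oc.simulate_truth(landscape, pool, design, self._flat_params(), seed=0)
        assert np.allclose(truth.units["psi"], 0.5)

    def test_land_use_coding_identity(self, landscape, pool, design):
        beta = 0.8
        truth = oc.simulate_truth(
            landscape, pool, design, self._flat_params(land_use=beta), seed=0
        )
        u = truth.units
        logit = np.log(u["psi"] / (1 - u["psi"]))
        forest = logit[u["lu"] > 0].iloc[0]
        pasture = logit[u["lu"] < 0].iloc[0]
        assert forest - pasture == pytest.approx(2 * beta)

    def test_missing_coefficient_named(self, landscape, pool, design):
        from occuscale.truth import MissingCoefficientError

        with pytest.raises(MissingCoefficientError, match="land_use"):
            oc.OccupancyParams(coef={"intercept": 0.0}, re_sd={})

    def test_z_is_bernoulli_of_psi(self, truth):
        # aggregate Monte-Carlo check: sum(z) ~ Poisson-binomial(sum psi)
        psi = truth.units["psi"].to_numpy()
        z = truth.units["z"].to_numpy()
        se = np.sqrt(np.sum(psi * (1 - psi)))
        assert abs(z.sum() - psi.sum()) < 3 * se

    def test_z_replicates_at_one_point(self):
        # repeated simulation of a single unit's latent state (micro study)
        land = oc.make_landscape(oc.LandscapeConfig(extent_km=(10, 10)), seed=5)
        pool = oc.make_species_pool(land, oc.SpeciesConfig(n_species=3), seed=5)
        des = oc.make_sampling_design(land, oc.DesignConfig(n_cluster_pairs=2), seed=5)
        params = self._flat_params(intercept=0.7)
        feats = None
        hits = []
        for s in range(300):
            t = oc.simulate_truth(land, pool, des, params, seed=s, features=feats)
            feats = t.features  # reuse the (deterministic) covariates
            hits.append(t.units["z"].iloc[0])
        p_true = 1 / (1 + np.exp(-0.7))
        se = np.sqrt(p_true * (1 - p_true) / 300)
        assert abs(np.mean(hits) - p_true) < 3 * se

    def test_determinism(self, landscape, pool, design):
        a = oc.simulate_truth(landscape, pool, design, oc.OccupancyParams.default(), seed=9)
        b = oc.simulate_truth(landscape, pool, design, oc.OccupancyParams.default(), seed=9)
        pd.testing.assert_frame_equal(a.units, b.units)


class TestDetectionSimulation:
    def test_no_false_positives(self, truth, detections):
        absent = truth.units.loc[truth.units["z"] == 0, ["species_id", "point_id"]]
        merged = absent.merge(detections, on=["species_id", "point_id"])
        assert (merged["y"] == 0).all()

    def test_certain_detection_when_present(self, landscape, pool, design):
        params = oc.OccupancyParams.default()
        params.coef["intercept"] = 20.0  # z = 1 everywhere retained
        params.re_sd = {k: 0.0 for k in params.re_sd}
        truth = oc.simulate_truth(landscape, pool, design, params, seed=0)
        det_params = oc.DetectionParams.default()
        det_params.coef = {"intercept": 25.0, "time_after_sunrise": 0.0, "land_use": 0.0}
        det_params.obs_effects = np.zeros(3)
        det_params.trait_coef = {}
        det_params.re_sd = {k: 0.0 for k in det_params.re_sd}
        det = oc.simulate_detections(truth, design, det_params, seed=1)
        assert (det["y"] == 1).all()

    def test_detection_frequency_matches_p(self, truth, detections):
        # among occupied units, y ~ Bernoulli(p_true) aggregated over visits
        occ = truth.units.loc[truth.units["z"] == 1, ["species_id", "point_id"]]
        sub = occ.merge(detections, on=["species_id", "point_id"])
        p = sub["p_true"].to_numpy()
        se = np.sqrt(np.sum(p * (1 - p)))
        assert abs(sub["y"].sum() - p.sum()) < 3 * se

    def test_conditional_independence_of_visits(self, landscape, pool, design):
        # constant p, all z = 1: visit pairs should be independent (chi-square)
        params = oc.OccupancyParams.default()
        params.coef["intercept"] = 20.0
        params.re_sd = {k: 0.0 for k in params.re_sd}
        truth = oc.simulate_truth(landscape, pool, design, params, seed=4)
        det_params = oc.DetectionParams.default()
        det_params.coef = {"intercept": 0.0, "time_after_sunrise": 0.0, "land_use": 0.0}
        det_params.obs_effects = np.zeros(3)
        det_params.trait_coef = {}
        det_params.re_sd = {k: 0.0 for k in det_params.re_sd}
        det = oc.simulate_detections(truth, design, det_params, seed=5)
        wide = det.pivot_table(
            index=["species_id", "point_id"], columns="visit_index", values="y"
        )
        table = pd.crosstab(wide[1], wide[2])
        _, pval, _, _ = stats.chi2_contingency(table)
        assert pval > 0.01

    def test_unknown_point_rejected(self, truth, design):
        bad = design.visits.copy()
        bad.loc[0, "point_id"] = 10_000
        bad_design = oc.SamplingDesign(design.clusters, design.points, bad)
        with pytest.raises(ValueError, match="unknown point"):
            oc.simulate_detections(truth, bad_design, oc.DetectionParams.default(), seed=0)

    def test_determinism(self, truth, design):
        a = oc.simulate_detections(truth, design, oc.DetectionParams.default(), seed=6)
        b = oc.simulate_detections(truth, design, oc.DetectionParams.default(), seed=6)
        pd.testing.assert_frame_equal(a, b)
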
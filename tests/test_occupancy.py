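"""Occupancy model: likelihood, gradients, fitting, prediction."""

import numpy as np
import pytest

import occuscale as oc
from occuscale.occupancy import (
    OccupancyModel,
    cluster_averaged_psi,
    marginal_loglik_point,
    monotonic_effect,
    n_cluster_subcells,
)


def brute_force_loglik(psi, p, y):
    """Enumeration oracle: sum over the latent state z in {0, 1}."""
    p = np.atleast_1d(p)
    y = np.atleast_1d(y)
    like_z1 = psi * np.prod(np.where(y > 0, p, 1 - p))
    like_z0 = (1 - psi) * (0.0 if (y > 0).any() else 1.0)
    return np.log(like_z1 + like_z0)


class TestMonotonicEffect:
    def test_endpoints(self):
        zeta = np.array([0.2, 0.3, 0.5])
        assert monotonic_effect(0, 2.0, zeta) == 0.0
        assert monotonic_effect(3, 2.0, zeta) == pytest.approx(2.0)

    def test_monotone_decreasing_for_negative_scale(self):
        zeta = np.array([0.1, 0.4, 0.2, 0.3])
        vals = monotonic_effect(np.arange(5), -1.5, zeta)
        assert (np.diff(vals) <= 0).all()

    def test_simplex_violation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            monotonic_effect(1, 1.0, [0.5, 0.6])


class TestMarginalLoglik:
    def test_worked_examples(self):
        assert marginal_loglik_point(0.5, [0.5, 0.5], [1, 0]) == pytest.approx(np.log(0.125))
        assert marginal_loglik_point(0.5, [0.5] * 4, [0] * 4) == pytest.approx(np.log(0.53125))

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            J = rng.integers(1, 5)
            psi = rng.uniform(0.01, 0.99)
            p = rng.uniform(0.01, 0.99, J)
            y = rng.integers(0, 2, J).astype(float)
            assert marginal_loglik_point(psi, p, y) == pytest.approx(
                brute_force_loglik(psi, p, y), abs=1e-12
            )

    def test_no_visits_rejected(self):
        with pytest.raises(ValueError, match="visit"):
            marginal_loglik_point(0.5, [], [])


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, detections, truth, pool, design):
        m = OccupancyModel.from_tables(
            detections, truth.features, pool, design, spec=oc.ModelSpec()
        )
        rng = np.random.default_rng(1)
        theta = 0.1 * rng.standard_normal(m.layout.size)
        _, g = m.neg_log_post(theta)
        eps = 1e-6
        for j in rng.choice(m.layout.size, 30, replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += eps
            tm[j] -= eps
            num = (m.neg_log_post(tp, grad=False) - m.neg_log_post(tm, grad=False)) / (2 * eps)
            assert num == pytest.approx(g[j], rel=1e-4, abs=1e-6)

    def test_model_loglik_equals_unitwise_oracle(self, fitted):
        # the vectorized likelihood agrees with the per-unit marginal formula
        m = fitted.model
        d = m.design
        parts = m.layout.unpack(fitted.theta_map)
        eta_psi, eta_p, _ = m._etas(parts)
        psi = 1 / (1 + np.exp(-eta_psi))
        p = 1 / (1 + np.exp(-eta_p))
        total = 0.0
        for u in range(d.n_units):
            sel = d.visit_unit == u
            total += marginal_loglik_point(psi[u], p[sel], d.y[sel])
        assert m.loglike(fitted.theta_map) == pytest.approx(total, rel=1e-10)


class TestFitting:
    def _null_data(self):
        land = oc.make_landscape(oc.LandscapeConfig(extent_km=(20, 20)), seed=21)
        pool = oc.make_species_pool(land, oc.SpeciesConfig(n_species=15), seed=21)
        des = oc.make_sampling_design(land, oc.DesignConfig(n_cluster_pairs=8), seed=21)
        params = oc.OccupancyParams.default()
        params.coef = {k: 0.0 for k in params.coef}
        params.trait_coef = {}
        params.lu_trait_coef = {}
        params.b_d2r = 0.0
        params.re_sd = {k: 0.0 for k in params.re_sd}
        truth = oc.simulate_truth(land, pool, des, params, seed=22)
        dp = oc.DetectionParams.default()
        dp.coef = {"intercept": 0.0, "time_after_sunrise": 0.0, "land_use": 0.0}
        dp.obs_effects = np.zeros(3)
        dp.trait_coef = {}
        dp.re_sd = {k: 0.0 for k in dp.re_sd}
        det = oc.simulate_detections(truth, des, dp, seed=23)
        return land, pool, des, truth, det

    def test_null_recovery(self):
        land, pool, des, truth, det = self._null_data()
        m = OccupancyModel.from_tables(det, truth.features, pool, des,
                                       spec=oc.ModelSpec.reduced())
        res = m.fit(method="laplace", n_draws=100, seed=24)
        s = res.summary()
        fixed = s[s["term"].str.startswith(("psi:", "p:"))]
        # every coefficient within 3 posterior SDs of its generating value 0
        assert (fixed["map"].abs() <= 3 * fixed["sd"] + 1e-6).all()

    def test_seeded_fit_is_deterministic(self, detections, truth, pool, design):
        spec = oc.ModelSpec.reduced()
        a = OccupancyModel.from_tables(detections, truth.features, pool, design, spec=spec).fit(
            n_draws=20, seed=31
        )
        b = OccupancyModel.from_tables(detections, truth.features, pool, design, spec=spec).fit(
            n_draws=20, seed=31
        )
        np.testing.assert_array_equal(a.theta_map, b.theta_map)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_map_only_mode(self, detections, truth, pool, design):
        res = OccupancyModel.from_tables(
            detections, truth.features, pool, design, spec=oc.ModelSpec.reduced()
        ).fit(method="map", seed=1)
        assert res.draws is None
        with pytest.raises(ValueError, match="MAP-only"):
            res.param_draws("beta_psi")

    def test_diagnostics_reported_for_every_parameter(self, fitted):
        d = fitted.diagnostics()
        assert len(d) == fitted.model.layout.size
        assert d["rhat"].notna().all()
        assert d["flagged"].dtype == bool

    def test_emcee_backend_small_model(self):
        land, pool, des, truth, det = self._null_data()
        spec = oc.ModelSpec(
            occ_traits=(), det_traits=(), include_mono_d2r=False,
            include_elevation=False, occ_random=("sp_intercept",), det_random=(),
        )
        m = OccupancyModel.from_tables(det, truth.features, pool, des, spec=spec)
        res = m.fit(method="emcee", n_draws=50, seed=7, emcee_steps=120, emcee_burn=60)
        res2 = m.fit(method="emcee", n_draws=50, seed=7, emcee_steps=120, emcee_burn=60)
        assert res.draws.shape == (50, m.layout.size)
        np.testing.assert_array_equal(res.draws, res2.draws)

    def test_prior_pushforward_not_extreme(self, detections, truth, pool, design):
        # psi sampled under the priors alone should not pile up at 0/1
        m = OccupancyModel.from_tables(
            detections, truth.features, pool, design, spec=oc.ModelSpec.reduced()
        )
        rng = np.random.default_rng(3)
        re_scale = {f"lsd_occ_{t.name}": t.sd_prior_scale for t in m.design.occ_re}
        re_scale |= {f"lsd_det_{t.name}": t.sd_prior_scale for t in m.design.det_re}
        mass = []
        for _ in range(20):
            parts = {}
            for name, s in m.layout.blocks.items():
                size = s.stop - s.start
                if name == "beta_psi":
                    parts[name] = rng.normal(0, m.design.psi_prior_sd)
                elif name == "beta_p":
                    parts[name] = rng.normal(0, m.design.p_prior_sd)
                elif name.startswith("z_") or name == "u_d2r":
                    parts[name] = rng.standard_normal(size)
                elif name == "b_d2r":
                    parts[name] = rng.normal(0, m.design.spec.prior_sd_slope, 1)
                else:  # lsd: half-normal sd with the term's prior scale
                    parts[name] = np.log(
                        re_scale[name] * np.abs(rng.standard_normal(1)) + 1e-3
                    )
            eta_psi, _, _ = m._etas(parts)
            psi = 1 / (1 + np.exp(-eta_psi))
            mass.append(np.mean((psi > 0.01) & (psi < 0.99)))
        assert np.mean(mass) >= 0.9


class TestPrediction:
    def test_subcell_count(self):
        assert n_cluster_subcells(2.0, 0.5) == 16

    def test_cluster_averaging_degenerate(self, rng):
        eta = np.linspace(-3, 3, 7)
        out = cluster_averaged_psi(eta, 0.0, 16, rng)
        np.testing.assert_allclose(out, 1 / (1 + np.exp(-eta)))

    def test_cluster_averaging_approximates_logit_normal_mean(self, rng):
        # 16-sample average vs a high-resolution Monte-Carlo oracle
        etas = rng.uniform(-3, 3, 100)
        big = rng.standard_normal(200_000)
        err = []
        for eta in etas:
            approx = cluster_averaged_psi([eta], 1.0, 16, rng)[0]
            oracle = np.mean(1 / (1 + np.exp(-(eta + 1.0 * big))))
            err.append(approx - oracle)
        # averaged over the 100 pixels the 16-sample estimate is unbiased
        assert abs(np.mean(err)) < 0.02

    def test_cube_shape_bounds_and_clipping(self, fitted, landscape, pool):
        cube = fitted.predict_cube(landscape, pool, seed=5, n_draws=15)
        assert cube.dims == ("species", "pixel", "scenario", "draw")
        assert list(cube["scenario"].values) == ["forest", "pasture"]
        v = cube.values
        assert (v >= 0).all() and (v <= 1).all()
        # clipped species-pixel pairs are exactly zero in every draw/scenario
        from occuscale.biogeo import point_features

        pts = landscape.pixels.rename(columns={"pixel_id": "point_id"})[
            ["point_id", "x_km", "y_km", "elevation_m"]
        ]
        feats = point_features(pts, pool, landscape)
        dropped = feats[~feats["retained"]]
        sp_in = dropped["species_id"].isin(cube["species"].values)
        sel = dropped[sp_in].head(50)
        for _, r in sel.iterrows():
            assert float(cube.sel(species=r["species_id"], pixel=r["point_id"]).max()) == 0.0

    def test_unknown_scenario_rejected(self, fitted, landscape, pool):
        with pytest.raises(ValueError, match="scenario"):
            fitted.predict_cube(landscape, pool, scenarios=("savanna",))

    def test_prediction_seeded(self, fitted, landscape, pool):
        a = fitted.predict_cube(landscape, pool, seed=9, n_draws=5)
        b = fitted.predict_cube(landscape, pool, seed=9, n_draws=5)
        assert (a.values == b.values).all()
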
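"""Generalized dissimilarity models: dissimilarities, I-splines, fitting,
Bayesian bootstrap and detection correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import occuscale as oc
from occuscale import gdm as gd
from occuscale.biogeo import site_pair_table


def line_sites(n=30, length=100.0, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "site_id": np.arange(n),
            "x_km": np.linspace(0, length, n),
            "y_km": 0.0,
            "elevation_m": rng.uniform(0, 1000, n),
            "mountain_range": 0,
            "divide_side": 0,
        }
    )


def turnover_presence(n_sites=30, n_species=60, width=15, step=1.5):
    """Communities slide along the species axis with site position."""
    pres = np.zeros((n_sites, n_species))
    for i in range(n_sites):
        lo = int(i * step)
        pres[i, lo : lo + width] = 1
    return pd.DataFrame(pres, index=pd.Index(np.arange(n_sites), name="site_id"))


class TestDissimilarities:
    def test_identical_and_disjoint(self):
        pres = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]],
            index=pd.Index([0, 1, 2], name="site_id"),
        )
        pairs = gd.pair_dissimilarities(pres)
        p01 = pairs[(pairs.site_i == 0) & (pairs.site_j == 1)].iloc[0]
        p02 = pairs[(pairs.site_i == 0) & (pairs.site_j == 2)].iloc[0]
        assert p01["sorensen"] == 0.0 and p01["simpson"] == 0.0
        assert p02["sorensen"] == 1.0 and p02["simpson"] == 1.0

    def test_abc_formula(self):
        pres = pd.DataFrame(
            [[1, 1, 1, 0], [1, 1, 0, 1]], index=pd.Index([0, 1], name="site_id")
        )
        row = gd.pair_dissimilarities(pres).iloc[0]
        assert (row["a"], row["b"], row["c"]) == (2, 1, 1)
        assert row["sorensen"] == pytest.approx(1 / 3)
        assert row["simpson"] == pytest.approx(1 / 3)

    def test_simpson_never_exceeds_sorensen(self, rng):
        pres = pd.DataFrame(
            (rng.random((25, 40)) < 0.3).astype(float),
            index=pd.Index(np.arange(25), name="site_id"),
        )
        pairs = gd.pair_dissimilarities(pres)
        assert (pairs["simpson"] <= pairs["sorensen"] + 1e-12).all()

    def test_empty_community_convention(self):
        pres = pd.DataFrame(
            [[1, 1], [0, 0]], index=pd.Index([0, 1], name="site_id")
        )
        pairs = gd.pair_dissimilarities(pres)
        assert pairs["d"].iloc[0] == 1.0 and pairs["empty_pair"].iloc[0]


class TestISplines:
    def test_endpoint_values(self):
        knots = (0.0, 3.0, 10.0)
        np.testing.assert_allclose(gd.ispline_basis(0.0, knots), [[0, 0, 0]][0])
        np.testing.assert_allclose(gd.ispline_basis(10.0, knots), [[1, 1, 1]][0])

    def test_bounded_unit_interval(self):
        B = gd.ispline_basis(np.linspace(-5, 15, 200), (0.0, 3.0, 10.0))
        assert (B >= 0).all() and (B <= 1).all()

    @given(
        a=st.floats(-100, 100),
        dm=st.floats(0.5, 100),
        db=st.floats(0.5, 100),
    )
    def test_monotone_on_grid_for_random_knots(self, a, dm, db):
        knots = (a, a + dm, a + dm + db)
        x = np.linspace(a - 1, a + dm + db + 1, 1000)
        B = gd.ispline_basis(x, knots)
        assert (np.diff(B, axis=0) >= -1e-12).all()

    def test_degenerate_knots_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            gd.ispline_basis(1.0, (0.0, 0.0, 1.0))


class TestGDMFit:
    def _fitted(self, noise=0.0, seed=0):
        sites = line_sites()
        pres = turnover_presence()
        pairs = gd.pair_dissimilarities(pres)
        pairs = pairs.merge(site_pair_table(sites), on=["site_i", "site_j"])
        model = gd.GDM.from_tables(
            pairs, sites, site_predictors=("elevation_m",), pair_predictors=("geo_km",)
        )
        return model, model.fit()

    def test_intercept_only_prediction(self):
        # identical sites: all predictors 0 -> predicted d = 1 - exp(-a0)
        sites = line_sites(n=10, length=0.0)
        sites["elevation_m"] = 500.0
        rng = np.random.default_rng(1)
        pres = pd.DataFrame(
            (rng.random((10, 20)) < 0.5).astype(float),
            index=pd.Index(np.arange(10), name="site_id"),
        )
        pairs = gd.pair_dissimilarities(pres)
        pairs = pairs.merge(site_pair_table(sites), on=["site_i", "site_j"])
        model = gd.GDM.from_tables(
            pairs, sites, site_predictors=("elevation_m",), pair_predictors=("geo_km",)
        )
        fit = model.fit()
        np.testing.assert_allclose(fit.fitted, 1.0 - np.exp(-fit.intercept), rtol=1e-9)

    def test_coefficients_nonnegative(self):
        _, fit = self._fitted()
        assert fit.intercept >= 0
        for w in fit.coefs.values():
            assert (w >= 0).all()

    def test_partial_distance_properties(self):
        model, fit = self._fitted()
        assert fit.partial_distance("geo_km", 40.0, 40.0) == 0.0
        p = fit._predictor("geo_km")
        top = fit.partial_distance("geo_km", p.knots[0], p.knots[2])
        assert top == pytest.approx(np.sum(fit.coefs["geo_km"]))
        curve = fit.curve("geo_km", n=500)
        assert (np.diff(curve["partial"]) >= -1e-12).all()
        with pytest.raises(KeyError, match="unknown predictor"):
            fit.partial_distance("precip", 0, 1)

    def test_generate_and_refit_recovery(self):
        # simulate d from a known GDM and recover the partial curve
        rng = np.random.default_rng(3)
        n = 60
        x = rng.uniform(0, 10, n)
        i, j = np.triu_indices(n, k=1)
        knots = (0.0, 5.0, 10.0)
        w_true = np.array([0.5, 0.3, 0.2])
        B = gd.ispline_basis(x, knots)
        f = B @ w_true
        eta = 0.1 + np.abs(f[i] - f[j])
        d = np.clip(1 - np.exp(-eta) + rng.normal(0, 0.02, len(i)), 0, 1)
        pset = gd.PredictorSet(
            pair_i=i, pair_j=j,
            predictors=[gd.Predictor("x", "site", x, knots)],
        )
        fit = gd.GDM(d, pset).fit()
        grid = np.linspace(0, 10, 101)
        true_curve = gd.ispline_basis(grid, knots) @ w_true
        est_curve = fit.f("x", grid)
        rms = np.sqrt(np.mean((est_curve - true_curve) ** 2))
        assert rms <= 0.05

    def test_invalid_dissimilarities_rejected(self):
        pset = gd.PredictorSet(
            pair_i=np.array([0]), pair_j=np.array([1]),
            predictors=[gd.Predictor("x", "site", np.array([0.0, 1.0]), (0.0, 0.5, 1.0))],
        )
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            gd.GDM(np.array([1.4]), pset)


class TestBayesianBootstrap:
    def test_weights_and_determinism(self):
        sites = line_sites(n=15)
        pres = turnover_presence(n_sites=15)
        pairs = gd.pair_dissimilarities(pres)
        pairs = pairs.merge(site_pair_table(sites), on=["site_i", "site_j"])
        model = gd.GDM.from_tables(
            pairs, sites, site_predictors=("elevation_m",), pair_predictors=("geo_km",)
        )
        ens = model.bootstrap(n=25, seed=9)
        assert ens.n_replicates == 25
        np.testing.assert_allclose(ens.site_weights.sum(axis=1), 1.0)
        assert (ens.site_weights >= 0).all()
        ens2 = model.bootstrap(n=25, seed=9)
        for a, b in zip(ens.fits, ens2.fits):
            assert a.intercept == b.intercept
            for k in a.coefs:
                np.testing.assert_array_equal(a.coefs[k], b.coefs[k])

    def test_curve_band_contains_mean(self):
        sites = line_sites(n=15)
        pres = turnover_presence(n_sites=15)
        pairs = gd.pair_dissimilarities(pres)
        pairs = pairs.merge(site_pair_table(sites), on=["site_i", "site_j"])
        model = gd.GDM.from_tables(pairs, sites, site_predictors=(),
                                   pair_predictors=("geo_km",))
        band = model.bootstrap(n=30, seed=1).curve_band("geo_km")
        assert ((band["lo"] <= band["mean"] + 1e-9)
                & (band["mean"] <= band["hi"] + 1e-9)).all()


class TestConditionalPresence:
    def test_detection_forces_presence(self, rng):
        z = gd.conditional_presence(
            np.array([0.2]), np.array([[0.9, 0.9]]), np.array([[1.0, 0.0]]), rng
        )
        assert z[0] == 1

    def test_bayes_rule_oracle(self):
        # psi=0.5, p=0.5, J=2, no detections -> P(z=1 | y=0) = 0.125/0.625
        rng = np.random.default_rng(0)
        n = 40_000
        z = gd.conditional_presence(
            np.full(n, 0.5), np.full((n, 2), 0.5), np.zeros((n, 2)), rng
        )
        expected = 0.125 / 0.625
        assert z.mean() == pytest.approx(expected, abs=3 * np.sqrt(expected * 0.8 / n))

    def test_perfect_detection_limit(self, rng):
        z = gd.conditional_presence(
            np.full(500, 0.5), np.full((500, 3), 1.0 - 1e-12), np.zeros((500, 3)), rng
        )
        assert z.sum() == 0

    def test_nan_padding_ignored(self, rng):
        p = np.array([[0.5, np.nan], [0.5, 0.5]])
        y = np.array([[0.0, np.nan], [0.0, 0.0]])
        psi = np.array([0.5, 0.5])
        rng1 = np.random.default_rng(1)
        z = gd.conditional_presence(psi, p, y, rng1)
        assert set(np.unique(z)) <= {0, 1}


class TestDetectionCorrectedGDM:
    def test_runs_and_respects_draw_budget(self, fitted, design, landscape):
        sites = oc.biogeo.synthetic_barrier_labels(landscape, design.points)
        forest_pts = sites.loc[sites["land_use"] == "forest", "site_id"].to_numpy()
        ens = gd.detection_corrected_gdm(
            fitted, forest_pts, sites,
            site_predictors=("elevation_m",), pair_predictors=("geo_km",),
            n_draws=6, seed=3,
        )
        assert ens.n_replicates == 6
        for f in ens.fits:
            assert f.intercept >= 0
        with pytest.raises(ValueError, match="draws"):
            gd.detection_corrected_gdm(
                fitted, forest_pts, sites, n_draws=10_000, seed=0
            )


class TestHomogenizationFlattening:
    def test_pasture_distance_curve_flatter_than_forest(self):
        # forest communities turn over with distance; pasture communities
        # are a shared subset everywhere
        sites = line_sites(n=24)
        forest = turnover_presence(n_sites=24)
        pasture = pd.DataFrame(
            np.tile(forest.iloc[0].to_numpy(), (24, 1)),
            index=forest.index,
        )
        rng = np.random.default_rng(5)
        flip = rng.random(pasture.shape) < 0.02  # small site-level noise
        pasture = pd.DataFrame(
            np.abs(pasture.to_numpy() - flip), index=forest.index
        )
        heights = {}
        for name, pres in (("forest", forest), ("pasture", pasture)):
            pairs = gd.pair_dissimilarities(pres)
            pairs = pairs.merge(site_pair_table(sites), on=["site_i", "site_j"])
            model = gd.GDM.from_tables(
                pairs, sites, site_predictors=(), pair_predictors=("geo_km",)
            )
            heights[name] = model.bootstrap(n=100, seed=7).total_heights("geo_km")
        flatter = heights["pasture"] < heights["forest"]
        assert flatter.mean() >= 0.95
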
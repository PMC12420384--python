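"""Generalized dissimilarity modelling of community turnover.

A GDM regresses pairwise compositional dissimilarity ``d`` on transformed
predictor differences through a negative-exponential link:

    d_hat = 1 - exp(-eta),   eta = a0 + sum_j f_j,

where each predictor contributes either ``|f_j(x_i) - f_j(x_j)|`` (site
predictors such as elevation or precipitation) or ``f_j(d_ij)`` (pairwise
predictors such as geographic or barrier distance), and every ``f_j`` is a
non-negative combination of three monotone I-spline basis functions with
knots at the predictor's minimum, median and maximum.  Non-negative
coefficients make every partial response monotone non-decreasing and keep
``d_hat`` in [0, 1).

Uncertainty comes from the Bayesian bootstrap: per replicate, site weights
are drawn from a flat Dirichlet, propagated to pairs by
product-and-renormalize, and the GDM is refitted.  The detection-corrected
variant replaces observed communities with latent-state draws from a
fitted occupancy model (one bootstrap replicate per posterior draw).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from ._util import check_seed, rng_for

__all__ = [
    "pair_dissimilarities",
    "ispline_basis",
    "PredictorSet",
    "GDM",
    "GDMResults",
    "GDMEnsemble",
    "conditional_presence",
    "detection_corrected_gdm",
]

logger = logging.getLogger(__name__)

N_BOOTSTRAP = 400


# ---------------------------------------------------------------------------
# Dissimilarities
# ---------------------------------------------------------------------------

def pair_dissimilarities(presence: pd.DataFrame, metric: str = "sorensen") -> pd.DataFrame:
    """All unordered site pairs with Sorensen and Simpson dissimilarities.

    ``presence`` is a site x species table of 0/1 presences (sites in the
    index).  Sorensen = (b+c)/(2a+b+c); Simpson = min(b,c)/(a+min(b,c)),
    the turnover component of Sorensen.  Pairs involving a site with no
    species take dissimilarity 1 by convention and are flagged.
    """
    if metric not in ("sorensen", "simpson"):
        raise ValueError(f"unknown dissimilarity metric {metric!r}")
    M = presence.to_numpy(dtype=float)
    sites = presence.index.to_numpy()
    A = M @ M.T                       # shared species
    rich = M.sum(axis=1)
    i, j = np.triu_indices(len(sites), k=1)
    a = A[i, j]
    b = rich[i] - a
    c = rich[j] - a
    mn = np.minimum(b, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        sor = np.where(2 * a + b + c > 0, (b + c) / (2 * a + b + c), 1.0)
        sim = np.where(a + mn > 0, mn / (a + mn), 1.0)
    empty = (rich[i] == 0) | (rich[j] == 0)
    if empty.any():
        logger.warning("%d pairs involve an empty community (d = 1 convention)", int(empty.sum()))
        sor = np.where(empty, 1.0, sor)
        sim = np.where(empty, 1.0, sim)
    return pd.DataFrame(
        {
            "site_i": sites[i],
            "site_j": sites[j],
            "a": a,
            "b": b,
            "c": c,
            "sorensen": sor,
            "simpson": sim,
            "empty_pair": empty,
            "d": sor if metric == "sorensen" else sim,
        }
    )


# ---------------------------------------------------------------------------
# I-splines
# ---------------------------------------------------------------------------

def ispline_basis(x, knots) -> np.ndarray:
    """Order-2 (piecewise-quadratic) I-spline basis with three functions.

    ``knots = (min, median, max)`` must be strictly increasing.  Each basis
    is 0 at or below the minimum knot, 1 at or above the maximum, and
    monotone non-decreasing in between.
    """
    a, m, b = (float(k) for k in knots)
    if not a < m < b:
        raise ValueError(f"knots must be strictly increasing, got {knots}")
    x = np.asarray(x, dtype=float)
    out = np.empty(x.shape + (3,))
    # basis 1: knots (a, a, m)
    out[..., 0] = np.where(
        x <= a, 0.0, np.where(x >= m, 1.0, 1.0 - (m - x) ** 2 / (m - a) ** 2)
    )
    # basis 2: knots (a, m, b)
    mid_lo = (x - a) ** 2 / ((b - a) * (m - a))
    mid_hi = 1.0 - (b - x) ** 2 / ((b - a) * (b - m))
    out[..., 1] = np.where(
        x <= a, 0.0, np.where(x >= b, 1.0, np.where(x <= m, mid_lo, mid_hi))
    )
    # basis 3: knots (m, b, b)
    out[..., 2] = np.where(
        x <= m, 0.0, np.where(x >= b, 1.0, (x - m) ** 2 / (b - m) ** 2)
    )
    return out


def _default_knots(values: np.ndarray) -> tuple[float, float, float]:
    lo, med, hi = np.min(values), np.median(values), np.max(values)
    if not lo < med < hi:  # degenerate spread: nudge the median
        med = lo + (hi - lo) / 2 if hi > lo else lo + 1.0
        hi = max(hi, med + 1e-9)
    return float(lo), float(med), float(hi)


@dataclass
class Predictor:
    """One GDM predictor: ``kind`` is "site" (site values, pair contribution
    |f(x_i)-f(x_j)|) or "pair" (pairwise distances, contribution f(d))."""

    name: str
    kind: str
    values: np.ndarray
    knots: tuple[float, float, float]


@dataclass
class PredictorSet:
    """Predictors aligned to a fixed pair list (site_i/site_j indices)."""

    pair_i: np.ndarray
    pair_j: np.ndarray
    predictors: list

    @property
    def names(self) -> list:
        return [p.name for p in self.predictors]


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class GDM:
    """Generalized dissimilarity model for one habitat stratum.

    Built from a pair table of dissimilarities and a predictor set; ``fit``
    minimizes the (weighted) squared error of the negative-exponential link
    under non-negativity constraints, statsmodels-style returning a
    :class:`GDMResults`.
    """

    def __init__(self, d: np.ndarray, predictors: PredictorSet):
        self.d = np.asarray(d, dtype=float)
        if ((self.d < 0) | (self.d > 1)).any():
            raise ValueError("dissimilarities must lie in [0, 1]")
        self.predictors = predictors
        self._B = self._pair_basis()

    @classmethod
    def from_tables(
        cls,
        pairs: pd.DataFrame,
        sites: pd.DataFrame,
        site_predictors=("elevation_m",),
        pair_predictors=("geo_km",),
        response: str = "d",
    ) -> "GDM":
        """Build from a pair table (site_i, site_j, dissimilarity and pair
        distances) plus a site table carrying the site-level predictors."""
        site_ids = sites["site_id"].to_numpy()
        pos = pd.Series(np.arange(len(site_ids)), index=site_ids)
        pi = pos.loc[pairs["site_i"]].to_numpy()
        pj = pos.loc[pairs["site_j"]].to_numpy()
        preds = []
        for name in site_predictors:
            v = sites[name].to_numpy(dtype=float)
            preds.append(Predictor(name, "site", v, _default_knots(v)))
        for name in pair_predictors:
            v = pairs[name].to_numpy(dtype=float)
            preds.append(Predictor(name, "pair", v, _default_knots(v)))
        pset = PredictorSet(pair_i=pi, pair_j=pj, predictors=preds)
        return cls(pairs[response].to_numpy(dtype=float), pset)

    def _pair_basis(self) -> np.ndarray:
        """Per-pair basis matrix (n_pairs, 3 * n_predictors), non-negative."""
        cols = []
        ps = self.predictors
        for p in ps.predictors:
            if p.kind == "site":
                Bi = ispline_basis(p.values, p.knots)
                cols.append(np.abs(Bi[ps.pair_i] - Bi[ps.pair_j]))
            elif p.kind == "pair":
                cols.append(ispline_basis(p.values, p.knots))
            else:
                raise ValueError(f"unknown predictor kind {p.kind!r}")
        return np.concatenate(cols, axis=1)

    def fit(self, weights: np.ndarray | None = None) -> "GDMResults":
        """Weighted non-negative least squares under the 1-exp(-eta) link."""
        B = self._B
        n, k = B.shape
        w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        w = w / w.sum() * n
        d = self.d

        def obj(theta):
            eta = theta[0] + B @ theta[1:]
            ex = np.exp(-eta)
            r = (1.0 - ex) - d
            val = np.sum(w * r**2)
            g_eta = 2.0 * w * r * ex
            return val, np.concatenate([[g_eta.sum()], B.T @ g_eta])

        x0 = np.full(1 + k, 0.1)
        res = optimize.minimize(
            obj,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * (1 + k),
            options={"maxiter": 500},
        )
        theta = res.x
        eta = theta[0] + B @ theta[1:]
        fitted = 1.0 - np.exp(-eta)
        rms = float(np.sqrt(np.mean(w / n * (fitted - d) ** 2) * n))
        coefs = {
            p.name: theta[1 + 3 * i : 4 + 3 * i]
            for i, p in enumerate(self.predictors.predictors)
        }
        return GDMResults(
            model=self,
            intercept=float(theta[0]),
            coefs=coefs,
            fitted=fitted,
            rms=rms,
            converged=bool(res.success),
        )

    # -- Bayesian bootstrap --------------------------------------------------

    def bootstrap(self, n: int = N_BOOTSTRAP, seed: int = 0) -> "GDMEnsemble":
        """Bayesian bootstrap: flat-Dirichlet site weights per replicate,
        mapped to pair weights by product-and-renormalize, one refit each."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = rng_for(check_seed(seed), "gdm-bootstrap")
        ps = self.predictors
        n_sites = int(max(ps.pair_i.max(), ps.pair_j.max())) + 1
        fits = []
        site_w = rng.dirichlet(np.ones(n_sites), size=n)
        for r in range(n):
            wpair = site_w[r, ps.pair_i] * site_w[r, ps.pair_j]
            wpair = wpair / wpair.sum()
            fits.append(self.fit(weights=wpair))
        return GDMEnsemble(model=self, fits=fits, site_weights=site_w)


@dataclass
class GDMResults:
    """One fitted GDM: non-negative spline coefficients per predictor."""

    model: GDM
    intercept: float
    coefs: dict
    fitted: np.ndarray
    rms: float
    converged: bool

    def _predictor(self, name: str) -> Predictor:
        for p in self.model.predictors.predictors:
            if p.name == name:
                return p
        raise KeyError(f"unknown predictor {name!r}")

    def f(self, name: str, x) -> np.ndarray:
        """Partial transform f_j(x) (monotone non-decreasing from 0)."""
        p = self._predictor(name)
        return ispline_basis(x, p.knots) @ self.coefs[name]

    def partial_distance(self, name: str, x1, x2) -> np.ndarray:
        """Partial ecological distance |f_j(x1) - f_j(x2)|."""
        return np.abs(self.f(name, x1) - self.f(name, x2))

    def curve(self, name: str, n: int = 101) -> pd.DataFrame:
        """Partial-distance curve f_j(x) - f_j(min) along the gradient."""
        p = self._predictor(name)
        grid = np.linspace(p.knots[0], p.knots[2], n)
        y = self.f(name, grid)
        return pd.DataFrame({"x": grid, "partial": y - y[0]})

    def total_height(self, name: str) -> float:
        """f_j(max) - f_j(min) = sum of the spline coefficients."""
        return float(np.sum(self.coefs[name]))

    def predict(self, B_row=None) -> np.ndarray:
        return self.fitted if B_row is None else 1.0 - np.exp(
            -(self.intercept + B_row @ np.concatenate(list(self.coefs.values())))
        )

    def summary(self) -> pd.DataFrame:
        rows = [{"term": "intercept", "coef": self.intercept}]
        for name, w in self.coefs.items():
            for i, wi in enumerate(w):
                rows.append({"term": f"{name}[{i}]", "coef": wi})
            rows.append({"term": f"{name}:total", "coef": float(np.sum(w))})
        return pd.DataFrame(rows)


@dataclass
class GDMEnsemble:
    """Bootstrap (or posterior) ensemble of GDM fits."""

    model: GDM
    fits: list
    site_weights: np.ndarray | None = None

    @property
    def n_replicates(self) -> int:
        return len(self.fits)

    def curve_band(self, name: str, n: int = 101, ci: float = 0.9) -> pd.DataFrame:
        p = self.fits[0]._predictor(name)
        grid = np.linspace(p.knots[0], p.knots[2], n)
        curves = np.stack([f.f(name, grid) - f.f(name, grid[:1]) for f in self.fits])
        a = (1 - ci) / 2
        return pd.DataFrame(
            {
                "x": grid,
                "mean": curves.mean(axis=0),
                "lo": np.quantile(curves, a, axis=0),
                "hi": np.quantile(curves, 1 - a, axis=0),
            }
        )

    def total_heights(self, name: str) -> np.ndarray:
        return np.array([f.total_height(name) for f in self.fits])

    def plot_curve(self, name: str, ax=None, ci: float = 0.9, **kwargs):
        """Partial-distance curve along one gradient with its CI ribbon."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        band = self.curve_band(name, ci=ci)
        ax.fill_between(band["x"], band["lo"], band["hi"], alpha=0.25, **kwargs)
        ax.plot(band["x"], band["mean"], **kwargs)
        ax.set_xlabel(name)
        ax.set_ylabel("partial ecological distance")
        return ax


# ---------------------------------------------------------------------------
# Detection correction
# ---------------------------------------------------------------------------

def conditional_presence(psi, p_visits, y_visits, rng) -> np.ndarray:
    """Sample the latent state given the detection history.

    ``z = 1`` with certainty where any visit detected the species;
    otherwise Bernoulli with the conditional probability
    ``psi * prod(1-p_j) / (psi * prod(1-p_j) + 1 - psi)``.

    ``psi``: (n_units,); ``p_visits``/``y_visits``: (n_units, J) arrays
    (NaN-padded columns allowed for units with fewer visits).
    """
    psi = np.asarray(psi, dtype=float)
    p = np.asarray(p_visits, dtype=float)
    y = np.asarray(y_visits, dtype=float)
    detected = np.nansum(y, axis=1) > 0
    with np.errstate(invalid="ignore"):
        prod_miss = np.nanprod(np.where(np.isnan(p), 1.0, 1.0 - p), axis=1)
    num = psi * prod_miss
    cond = num / (num + 1.0 - psi)
    z = rng.random(len(psi)) < cond
    return np.where(detected, 1, z.astype(int))


def detection_corrected_gdm(
    results,
    stratum_points: np.ndarray,
    sites: pd.DataFrame,
    site_predictors=("elevation_m",),
    pair_predictors=("geo_km",),
    response: str = "sorensen",
    n_draws: int = N_BOOTSTRAP,
    seed: int = 0,
) -> GDMEnsemble:
    """Detection-corrected GDM ensemble from a fitted occupancy model.

    For each of ``n_draws`` posterior draws, the latent presence of every
    modelled species-point unit is sampled conditional on its detection
    history, the pairwise dissimilarities of the resulting communities are
    computed for the given stratum's points, and a single Bayesian-bootstrap
    replicate is fitted — so occupancy-model uncertainty and sampling
    uncertainty propagate together.
    """
    seed = check_seed(seed)
    d = results.model.design
    if results.n_draws < n_draws:
        raise ValueError(
            f"requested {n_draws} draws but the fit holds only {results.n_draws}"
        )
    psi_draws, p_draws = results.unit_posteriors(n_draws=n_draws)

    units = d.units[["species_id", "point_id"]].reset_index(drop=True)
    # visit rows grouped by unit; pad to rectangular (n_units, Jmax)
    order = np.argsort(d.visit_unit, kind="stable")
    vu = d.visit_unit[order]
    counts = np.bincount(vu, minlength=len(units))
    Jmax = counts.max()
    col = np.concatenate([np.arange(c) for c in counts])
    y_pad = np.full((len(units), Jmax), np.nan)
    y_pad[vu, col] = d.y[order]

    in_stratum = units["point_id"].isin(stratum_points).to_numpy()
    species = np.sort(units["species_id"].unique())
    spos = pd.Series(np.arange(len(species)), index=species)
    ppos = pd.Series(np.arange(len(stratum_points)), index=stratum_points)

    fits = []
    ens_model = None
    for r in range(n_draws):
        rng = rng_for(seed, f"detcorr-{r}")
        p_pad = np.full((len(units), Jmax), np.nan)
        p_pad[vu, col] = p_draws[r][order]
        z = conditional_presence(psi_draws[r], p_pad, y_pad, rng)
        pres = np.zeros((len(stratum_points), len(species)))
        sel = in_stratum & (z == 1)
        pres[
            ppos.loc[units.loc[sel, "point_id"]].to_numpy(),
            spos.loc[units.loc[sel, "species_id"]].to_numpy(),
        ] = 1.0
        presence = pd.DataFrame(pres, index=pd.Index(stratum_points, name="site_id"))
        pairs = pair_dissimilarities(presence, metric=response)
        pair_meta = sites  # site table carries coordinates / barrier labels
        from .biogeo import site_pair_table

        geo = site_pair_table(pair_meta[pair_meta["site_id"].isin(stratum_points)])
        pairs = pairs.merge(geo, on=["site_i", "site_j"], how="left")
        gdm = GDM.from_tables(
            pairs,
            pair_meta[pair_meta["site_id"].isin(stratum_points)],
            site_predictors=site_predictors,
            pair_predictors=pair_predictors,
            response="d",
        )
        ens_model = gdm
        n_sites = len(stratum_points)
        sw = rng.dirichlet(np.ones(n_sites))
        wpair = sw[gdm.predictors.pair_i] * sw[gdm.predictors.pair_j]
        fits.append(gdm.fit(weights=wpair / wpair.sum()))
    return GDMEnsemble(model=ens_model, fits=fits, site_weights=None)
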
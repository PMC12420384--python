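"""Biogeographically constrained multi-species occupancy model.

The model marginalizes the latent presence state out of the likelihood:
for a species-point unit with occupancy probability ``psi`` and per-visit
detection probabilities ``p_j`` given detection history ``y_j``,

    L = psi * prod_j p_j^y_j (1-p_j)^(1-y_j)  +  (1-psi) * 1{sum_j y_j = 0}.

``logit(psi)`` is a linear predictor over elevation (linear and quadratic,
with a lowland-minimum modifier), a monotonic ordinal effect of
distance-to-range, land use, species traits and land-use x trait
interactions, plus crossed Gaussian random effects (species, family,
species x cluster, species x subregion intercepts; species elevation
slopes; species and family land-use slopes).  ``logit(p)`` carries
observer, time-after-sunrise, land-use and trait terms with species-level
random effects.  All priors are zero-centred Gaussians; random-effect SDs
carry half-Normal priors and the distance-to-range simplex a
uniform-on-the-simplex (softmax-Gaussian) prior.

Fitting follows the statsmodels convention: :class:`OccupancyModel` is
built from data tables, ``fit()`` returns an :class:`OccupancyResults`
carrying the MAP estimate, posterior draws (Laplace approximation around
the mode, or an affine-invariant ensemble sampler for small models),
convergence diagnostics and a ``summary()`` table.  Random effects are
parameterized non-centred (effect = sd * z, z ~ N(0,1)), which keeps the
joint mode well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import linalg, optimize

from ._util import check_seed, expit, log_expit, rng_for, softmax, spawn_seed
from .biogeo import (
    ModelSpec,
    OccDesign,
    build_design,
    clip_pairs,
    d2r_levels,
    point_features,
    psi_fixed_matrix,
)
from .simulate import Landscape, SpeciesPool, SamplingDesign, subregion_ids

__all__ = [
    "monotonic_effect",
    "marginal_loglik_point",
    "cluster_averaged_psi",
    "n_cluster_subcells",
    "OccupancyModel",
    "OccupancyResults",
    "make_cube",
]

RHAT_FLAG_THRESHOLD = 1.02


def n_cluster_subcells(pixel_size_km: float = 2.0, cluster_scale_km: float = 0.5) -> int:
    """Number of cluster-scale sub-cells per prediction pixel.

    One 2-km pixel contains sixteen 500-m cells, each at the spatial grain
    of a sampling cluster; pixel predictions average the cluster random
    effect over this many independent samples.
    """
    n = (pixel_size_km / cluster_scale_km) ** 2
    return int(round(n))


def cluster_averaged_psi(eta, cluster_sd: float, n_samples: int, rng) -> np.ndarray:
    """Occupancy averaged over the cluster-level random effect.

    For each linear predictor value, draws ``n_samples`` independent
    cluster effects ~ N(0, cluster_sd), inverse-logits each, and averages
    on the probability scale (a Monte-Carlo logit-normal mean, one sample
    per cluster-scale sub-cell of the pixel).  With ``cluster_sd == 0``
    this is exactly ``expit(eta)``.
    """
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    if cluster_sd == 0:
        return expit(eta)
    clus = cluster_sd * rng.standard_normal((len(eta), n_samples))
    return expit(eta[:, None] + clus).mean(axis=1)


def monotonic_effect(k, b: float, zeta) -> np.ndarray:
    """Monotonic ordinal effect: ``b * sum_{l<=k} zeta_l``.

    ``zeta`` is a simplex of per-level increments, so the contribution runs
    monotonically from 0 (level 0) to ``b`` (top level), with the sign of
    ``b`` setting the direction.
    """
    z = np.asarray(zeta, dtype=float)
    if (z < -1e-12).any() or abs(z.sum() - 1.0) > 1e-8:
        raise ValueError("zeta must be non-negative and sum to 1")
    k = np.asarray(k)
    if (k < 0).any() or (k > len(z)).any():
        raise ValueError(f"bin index out of range 0..{len(z)}")
    cum = np.concatenate([[0.0], np.cumsum(z)])
    return b * cum[k]


def marginal_loglik_point(psi, p, y) -> float:
    """Marginal occupancy log-likelihood for one species-point unit.

    ``p`` and ``y`` are the per-visit detection probabilities and binary
    outcomes.  The latent state is marginalized analytically.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if p.size == 0:
        raise ValueError("no visits: J must be >= 1")
    if p.shape != y.shape:
        raise ValueError("p and y must have the same length")
    psi = float(psi)
    with np.errstate(divide="ignore"):
        logq = np.where(y > 0, np.log(p), np.log1p(-p)).sum()
    if (y > 0).any():
        return float(np.log(psi) + logq)
    return float(np.logaddexp(np.log(psi) + logq, np.log1p(-psi)))


# ---------------------------------------------------------------------------
# Parameter layout
# ---------------------------------------------------------------------------

class ParameterLayout:
    """Maps named parameter blocks to slices of one flat vector."""

    def __init__(self, design: OccDesign):
        self.blocks: dict[str, slice] = {}
        pos = 0

        def add(name, size):
            nonlocal pos
            self.blocks[name] = slice(pos, pos + size)
            pos += size

        add("beta_psi", design.X_psi.shape[1])
        if design.d2r_level is not None:
            add("b_d2r", 1)
            add("u_d2r", design.n_d2r_levels - 1)
        add("beta_p", design.X_p.shape[1])
        for t in design.occ_re:
            add(f"z_occ_{t.name}", t.n_levels)
        for t in design.det_re:
            add(f"z_det_{t.name}", t.n_levels)
        for t in design.occ_re:
            add(f"lsd_occ_{t.name}", 1)
        for t in design.det_re:
            add(f"lsd_det_{t.name}", 1)
        self.size = pos

    def unpack(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        return {k: theta[s] for k, s in self.blocks.items()}

    def pack(self, parts: dict[str, np.ndarray]) -> np.ndarray:
        theta = np.zeros(self.size)
        for k, s in self.blocks.items():
            theta[s] = parts[k]
        return theta


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class OccupancyModel:
    """Multi-species occupancy model over an assembled design.

    Use :meth:`from_tables` to go straight from the detection, feature,
    pool and design tables (clipping applied on the way in), or construct
    from a pre-built :class:`~occuscale.biogeo.OccDesign`.
    """

    def __init__(self, design: OccDesign):
        self.design = design
        self.layout = ParameterLayout(design)
        d = design
        self._det_unit = np.bincount(d.visit_unit, weights=d.y, minlength=d.n_units) > 0

    @classmethod
    def from_tables(
        cls,
        detections: pd.DataFrame,
        features: pd.DataFrame,
        pool: SpeciesPool,
        design: SamplingDesign,
        spec: ModelSpec | None = None,
    ) -> "OccupancyModel":
        if "retained" not in features.columns:
            raise ValueError("features must carry a 'retained' column (run point_features)")
        retained, _ = clip_pairs(features)
        return cls(build_design(detections, retained, pool, design, spec=spec))

    # -- linear predictors --------------------------------------------------

    def _etas(self, parts):
        d = self.design
        eta_psi = d.X_psi @ parts["beta_psi"]
        zeta = None
        if d.d2r_level is not None:
            zeta = softmax(parts["u_d2r"])
            cum = np.concatenate([[0.0], np.cumsum(zeta)])
            eta_psi = eta_psi + parts["b_d2r"][0] * cum[d.d2r_level]
        for t in d.occ_re:
            sd = np.exp(parts[f"lsd_occ_{t.name}"][0])
            eta_psi = eta_psi + sd * parts[f"z_occ_{t.name}"][t.index] * t.cov
        eta_p = d.X_p @ parts["beta_p"]
        for t in d.det_re:
            sd = np.exp(parts[f"lsd_det_{t.name}"][0])
            eta_p = eta_p + sd * parts[f"z_det_{t.name}"][t.index] * t.cov
        return eta_psi, eta_p, zeta

    def loglike(self, theta: np.ndarray) -> float:
        """Marginal log-likelihood (latent state summed out), no priors."""
        parts = self.layout.unpack(np.asarray(theta, dtype=float))
        eta_psi, eta_p, _ = self._etas(parts)
        return float(self._loglike_from_etas(eta_psi, eta_p)[0].sum())

    def _loglike_from_etas(self, eta_psi, eta_p):
        d = self.design
        log_psi = log_expit(eta_psi)
        log_1mpsi = log_expit(-eta_psi)
        sgn = 1.0 - 2.0 * d.y  # +1 for y=0, -1 for y=1
        logq = log_expit(-sgn * eta_p)  # log p when y=1, log(1-p) when y=0
        logQ = np.bincount(d.visit_unit, weights=logq, minlength=d.n_units)
        ll_det = log_psi + logQ
        ll = np.where(self._det_unit, ll_det, np.logaddexp(ll_det, log_1mpsi))
        return ll, logQ

    # -- posterior density and gradient -------------------------------------

    def neg_log_post(self, theta: np.ndarray, grad: bool = True):
        """Negative log posterior and (optionally) its analytic gradient."""
        d = self.design
        theta = np.asarray(theta, dtype=float)
        parts = self.layout.unpack(theta)
        eta_psi, eta_p, zeta = self._etas(parts)
        ll, logQ = self._loglike_from_etas(eta_psi, eta_p)
        lp = ll.sum()

        # priors
        b = parts["beta_psi"]
        lp += -0.5 * np.sum((b / d.psi_prior_sd) ** 2)
        bp = parts["beta_p"]
        lp += -0.5 * np.sum((bp / d.p_prior_sd) ** 2)
        if d.d2r_level is not None:
            lp += -0.5 * (parts["b_d2r"][0] / d.spec.prior_sd_slope) ** 2
            lp += -0.5 * np.sum(parts["u_d2r"] ** 2)
        for side, terms in (("occ", d.occ_re), ("det", d.det_re)):
            for t in terms:
                z = parts[f"z_{side}_{t.name}"]
                l = parts[f"lsd_{side}_{t.name}"][0]
                sd = np.exp(l)
                lp += -0.5 * np.sum(z**2)
                lp += -0.5 * (sd / t.sd_prior_scale) ** 2 + l  # half-Normal + Jacobian

        if not grad:
            return -lp

        # -- gradient ---------------------------------------------------
        psi = expit(eta_psi)
        det = self._det_unit
        # weight of the occupied branch for undetected units
        log_1mpsi = log_expit(-eta_psi)
        log_psi = log_expit(eta_psi)
        ll_undet = np.logaddexp(log_psi + logQ, log_1mpsi)
        w = np.exp(log_psi + logQ - ll_undet)  # P(z=1 | y=0)
        g_eta_psi = np.where(det, 1.0 - psi, w * (1.0 - psi) - (1.0 - w) * psi)
        omega = np.where(det, 1.0, w)
        p = expit(eta_p)
        g_eta_p = omega[d.visit_unit] * (d.y - p)

        g = np.zeros_like(theta)
        L = self.layout.blocks
        g[L["beta_psi"]] = d.X_psi.T @ g_eta_psi - b / d.psi_prior_sd**2
        g[L["beta_p"]] = d.X_p.T @ g_eta_p - bp / d.p_prior_sd**2
        if d.d2r_level is not None:
            cum = np.concatenate([[0.0], np.cumsum(zeta)])
            bb = parts["b_d2r"][0]
            g[L["b_d2r"]] = np.sum(g_eta_psi * cum[d.d2r_level]) - bb / d.spec.prior_sd_slope**2
            # d eta / d zeta_l = b * 1{l <= k}; accumulate tail sums over levels
            s = np.bincount(d.d2r_level, weights=g_eta_psi, minlength=d.n_d2r_levels)
            tail = np.cumsum(s[::-1])[::-1]
            g_zeta = bb * tail[1:]
            u = parts["u_d2r"]
            g[L["u_d2r"]] = zeta * (g_zeta - np.dot(zeta, g_zeta)) - u
        for side, terms, g_eta in (("occ", d.occ_re, g_eta_psi), ("det", d.det_re, g_eta_p)):
            for t in terms:
                z = parts[f"z_{side}_{t.name}"]
                l = parts[f"lsd_{side}_{t.name}"][0]
                sd = np.exp(l)
                acc = np.bincount(t.index, weights=g_eta * t.cov, minlength=t.n_levels)
                g[L[f"z_{side}_{t.name}"]] = sd * acc - z
                g[L[f"lsd_{side}_{t.name}"]] = (
                    sd * np.dot(z, acc) - (sd / t.sd_prior_scale) ** 2 + 1.0
                )
        return -lp, -g

    # -- fitting ------------------------------------------------------------

    def _initial(self, rng) -> np.ndarray:
        theta = 0.01 * rng.standard_normal(self.layout.size)
        for name, s in self.layout.blocks.items():
            if name.startswith("lsd_"):
                theta[s] = np.log(0.3)
        return theta

    def fit(
        self,
        method: str = "laplace",
        n_draws: int = 200,
        seed: int = 0,
        maxiter: int = 1000,
        hessian_step: float = 1e-4,
        emcee_steps: int = 800,
        emcee_burn: int = 400,
    ) -> "OccupancyResults":
        """Fit the model and return results with tagged posterior draws.

        ``method`` is one of ``"map"`` (mode only, no draws), ``"laplace"``
        (mode plus Gaussian draws from the local curvature) or ``"emcee"``
        (affine-invariant ensemble sampler initialized at the mode; only
        sensible for small parameter counts).
        """
        seed = check_seed(seed)
        rng = rng_for(seed, "fit-init")
        theta0 = self._initial(rng)
        val0 = self.neg_log_post(theta0, grad=False)
        if not np.isfinite(val0):
            raise FloatingPointError("non-finite posterior density at initialization")

        res = optimize.minimize(
            self.neg_log_post,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "maxcor": 25},
        )
        theta_hat = res.x
        converged = bool(res.success)
        if not converged:
            warnings.warn(f"MAP optimization did not fully converge: {res.message}")

        draws = None
        if method == "laplace":
            draws = self._laplace_draws(theta_hat, n_draws, seed, hessian_step)
        elif method == "emcee":
            draws = self._emcee_draws(theta_hat, n_draws, seed, emcee_steps, emcee_burn)
        elif method != "map":
            raise ValueError(f"unknown fit method {method!r}")

        return OccupancyResults(
            model=self,
            theta_map=theta_hat,
            draws=draws,
            converged=converged,
            optimizer_message=str(res.message),
            method=method,
        )

    def _hessian(self, theta: np.ndarray, step: float) -> np.ndarray:
        """Finite-difference Hessian from the analytic gradient (central)."""
        n = len(theta)
        H = np.empty((n, n))
        for j in range(n):
            h = step * max(1.0, abs(theta[j]))
            tp = theta.copy()
            tp[j] += h
            tm = theta.copy()
            tm[j] -= h
            _, gp = self.neg_log_post(tp)
            _, gm = self.neg_log_post(tm)
            H[:, j] = (gp - gm) / (2 * h)
        return 0.5 * (H + H.T)

    def _laplace_draws(self, theta_hat, n_draws, seed, step) -> np.ndarray:
        H = self._hessian(theta_hat, step)
        jitter = 0.0
        eye = np.eye(len(theta_hat))
        for _ in range(8):
            try:
                c, low = linalg.cho_factor(H + jitter * eye, lower=False)
                break
            except linalg.LinAlgError:
                jitter = max(jitter * 10, 1e-8)
        else:
            raise linalg.LinAlgError("Hessian could not be regularized to positive definite")
        rng = rng_for(seed, "laplace-draws")
        xi = rng.standard_normal((n_draws, len(theta_hat)))
        # x ~ N(0, H^-1): solve R x = xi for upper Cholesky R (H = R'R)
        dev = linalg.solve_triangular(c, xi.T, lower=low).T
        return theta_hat + dev

    def _emcee_draws(self, theta_hat, n_draws, seed, steps, burn) -> np.ndarray:
        import emcee

        ndim = len(theta_hat)
        nwalkers = max(2 * ndim + 2, 8)
        rng = rng_for(seed, "emcee")
        p0 = theta_hat + 0.01 * rng.standard_normal((nwalkers, ndim))

        def logp(th):
            return -self.neg_log_post(th, grad=False)

        sampler = emcee.EnsembleSampler(nwalkers, ndim, logp)
        sampler.random_state = np.random.RandomState(spawn_seed(seed, "emcee-state")).get_state()
        sampler.run_mcmc(p0, steps, progress=False)
        chain = sampler.get_chain(discard=burn, flat=True)
        idx = rng.choice(len(chain), size=n_draws, replace=len(chain) < n_draws)
        return chain[idx]


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class OccupancyResults:
    """Fitted occupancy model: MAP estimate, posterior draws, diagnostics."""

    model: OccupancyModel
    theta_map: np.ndarray
    draws: np.ndarray | None
    converged: bool
    optimizer_message: str
    method: str
    _diag: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def layout(self) -> ParameterLayout:
        return self.model.layout

    @property
    def n_draws(self) -> int:
        return 0 if self.draws is None else len(self.draws)

    def param_map(self, block: str) -> np.ndarray:
        return self.theta_map[self.layout.blocks[block]]

    def param_draws(self, block: str) -> np.ndarray:
        if self.draws is None:
            raise ValueError("fit was MAP-only; no posterior draws available")
        return self.draws[:, self.layout.blocks[block]]

    # -- diagnostics ---------------------------------------------------------

    def diagnostics(self, n_chains: int = 4) -> pd.DataFrame:
        """Split R-hat and bulk ESS per scalar parameter (via ArviZ).

        Draws are folded into ``n_chains`` pseudo-chains.  Parameters with
        R-hat >= 1.02 are flagged (not failed).
        """
        if self._diag is not None:
            return self._diag
        import arviz as az

        if self.draws is None:
            raise ValueError("no draws to diagnose (MAP-only fit)")
        n = (self.n_draws // n_chains) * n_chains
        arr = self.draws[:n].reshape(n_chains, n // n_chains, -1)
        names = []
        for blk, s in self.layout.blocks.items():
            size = s.stop - s.start
            names += [blk if size == 1 else f"{blk}[{i}]" for i in range(size)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(az.convert_to_dataset(arr))["x"].values
            ess = az.ess(az.convert_to_dataset(arr))["x"].values
        self._diag = pd.DataFrame(
            {"parameter": names, "rhat": rhat, "bulk_ess": ess,
             "flagged": rhat >= RHAT_FLAG_THRESHOLD}
        )
        return self._diag

    # -- summary -------------------------------------------------------------

    def summary(self) -> pd.DataFrame:
        """Fixed effects and random-effect SDs: MAP, posterior sd and 90% CI."""
        rows = []
        for blk, s in self.layout.blocks.items():
            if blk.startswith("z_"):
                continue
            vals_map = self.theta_map[s]
            if blk.startswith("lsd_"):
                vals_map = np.exp(vals_map)
            dr = None
            if self.draws is not None:
                dr = self.draws[:, s]
                if blk.startswith("lsd_"):
                    dr = np.exp(dr)
            if blk == "beta_psi":
                labels = [f"psi:{c}" for c in self.model.design.psi_colnames]
            elif blk == "beta_p":
                labels = [f"p:{c}" for c in self.model.design.p_colnames]
            elif blk.startswith("lsd_"):
                labels = ["sd:" + blk[4:]]
            else:
                labels = [blk if s.stop - s.start == 1 else f"{blk}[{i}]"
                          for i in range(s.stop - s.start)]
            for i, lab in enumerate(labels):
                row = {"term": lab, "map": vals_map[i]}
                if dr is not None:
                    row.update(
                        sd=dr[:, i].std(),
                        q5=np.quantile(dr[:, i], 0.05),
                        q95=np.quantile(dr[:, i], 0.95),
                    )
                rows.append(row)
        return pd.DataFrame(rows)

    # -- species-level effects ----------------------------------------------

    def species_land_use_effects(self) -> pd.Series:
        """Total species-level land-use effect (fixed + trait + random slope),
        on the logit scale, at MAP."""
        d = self.model.design
        beta = dict(zip(d.psi_colnames, self.param_map("beta_psi")))
        species = d.meta["species_levels"]
        eff = np.full(len(species), beta.get("land_use", 0.0))
        # trait contributions to the land-use response
        sp_first = d.units.drop_duplicates("species_id").set_index("species_id")
        X = d.X_psi[
            d.units.drop_duplicates("species_id").index.to_numpy()
        ]
        for i, c in enumerate(d.psi_colnames):
            if c.startswith("lu_x_"):
                # column value is lu * trait; divide out the lu code
                lu = sp_first["lu"].to_numpy()
                eff = eff + beta[c] * (X[:, i] / lu)
        for t in d.occ_re:
            if t.name == "sp_lu":
                sd = np.exp(self.param_map("lsd_occ_sp_lu")[0])
                eff = eff + sd * self.param_map("z_occ_sp_lu")
        return pd.Series(eff, index=pd.Index(species, name="species_id"))

    # -- per-unit posteriors (for detection-corrected analyses) --------------

    def unit_posteriors(self, n_draws: int | None = None):
        """Per-draw psi for every unit and p for every visit row.

        Returns (psi: (n_draws, n_units), p: (n_draws, n_visit_rows)).
        """
        if self.draws is None:
            raise ValueError("needs posterior draws")
        dr = self.draws if n_draws is None else self.draws[:n_draws]
        psis, ps = [], []
        for th in dr:
            parts = self.layout.unpack(th)
            eta_psi, eta_p, _ = self.model._etas(parts)
            psis.append(expit(eta_psi))
            ps.append(expit(eta_p))
        return np.array(psis), np.array(ps)

    # -- prediction -----------------------------------------------------------

    def predict_cube(
        self,
        landscape: Landscape,
        pool: SpeciesPool,
        seed: int = 0,
        n_draws: int | None = None,
        n_cluster_samples: int | None = None,
        scenarios=("forest", "pasture"),
        pixel_features: pd.DataFrame | None = None,
        batch_pixels: int = 4096,
    ) -> xr.DataArray:
        """Posterior occupancy for hypothetical all-forest / all-pasture pixels.

        For every retained species-pixel pair and every draw, the linear
        predictor combines the fixed effects, the species/family random
        effects fitted to the data, a subregion effect freshly sampled from
        its fitted distribution (shared within each 20-km subregion), and
        ``n_cluster_samples`` (default sixteen, one per 500-m sub-cell)
        independent cluster effects averaged on the probability scale.
        Clipped pairs get occupancy 0.
        """
        for sc in scenarios:
            if sc not in ("forest", "pasture"):
                raise ValueError(f"unknown scenario {sc!r}")
        if self.draws is None:
            raise ValueError("prediction requires posterior draws")
        d = self.model.design
        spec = d.spec
        ncs = n_cluster_samples or n_cluster_subcells(landscape.pixel_size_km)
        dr = self.draws if n_draws is None else self.draws[:n_draws]
        rng = rng_for(check_seed(seed), "predict")

        px = landscape.pixels
        if pixel_features is None:
            pts = px.rename(columns={"pixel_id": "point_id"})[
                ["point_id", "x_km", "y_km", "elevation_m"]
            ]
            pixel_features = point_features(pts, pool, landscape)
        feats = pixel_features[pixel_features["retained"]].reset_index(drop=True)

        species = d.meta["species_levels"]
        sp_pos = pd.Series(np.arange(len(species)), index=species)
        feats = feats[feats["species_id"].isin(sp_pos.index)].reset_index(drop=True)
        px_ids = px["pixel_id"].to_numpy()
        px_pos = pd.Series(np.arange(len(px_ids)), index=px_ids)

        units = feats[["species_id", "point_id", "std_elevation", "distance_to_range_km"]].copy()
        units = units.rename(columns={"point_id": "pixel_id"})
        sp_tab = pool.species.set_index("species_id")
        units["family_id"] = sp_tab.loc[units["species_id"], "family_id"].to_numpy()
        units["lowmin"] = np.where(
            sp_tab.loc[units["species_id"], "elev_min_m"].to_numpy() <= 0.0, -1.0, 1.0
        )
        xs = px.set_index("pixel_id").loc[units["pixel_id"], "x_km"].to_numpy()
        ys = px.set_index("pixel_id").loc[units["pixel_id"], "y_km"].to_numpy()
        sub_ids = subregion_ids(xs, ys, spec.subregion_scale_km)
        sub_codes, sub_levels = pd.factorize(sub_ids, sort=True)
        usp = sp_pos.loc[units["species_id"]].to_numpy()
        upx = px_pos.loc[units["pixel_id"]].to_numpy()
        # species x subregion index for fresh subregion effects
        spsub_codes, spsub_levels = pd.factorize(
            usp.astype(np.int64) * (len(sub_levels) + 1) + sub_codes, sort=True
        )

        # family index aligned with model families
        fam_all = sorted(pool.species["family_id"].unique())
        fam_pos = pd.Series(np.arange(len(fam_all)), index=fam_all)
        ufam = fam_pos.loc[units["family_id"]].to_numpy()

        lv = None
        if d.d2r_level is not None:
            lv = d2r_levels(units["distance_to_range_km"].to_numpy(), d.n_d2r_levels)

        occ_names = [t.name for t in d.occ_re]
        e = units["std_elevation"].to_numpy()

        cube = np.zeros((len(species), len(px_ids), len(scenarios), len(dr)), dtype=np.float32)
        L = self.layout.blocks
        for di, th in enumerate(dr):
            parts = self.layout.unpack(th)
            beta = parts["beta_psi"]
            # species-level random effects common to both scenarios
            eta_re = np.zeros(len(units))
            for t in d.occ_re:
                sd = np.exp(parts[f"lsd_occ_{t.name}"][0])
                z = parts[f"z_occ_{t.name}"]
                if t.name == "sp_intercept":
                    eta_re += sd * z[usp]
                elif t.name == "fam_intercept":
                    eta_re += sd * z[ufam] if t.n_levels == len(fam_all) else 0.0
                elif t.name == "sp_elev":
                    eta_re += sd * z[usp] * e
            sd_sub = (
                np.exp(parts["lsd_occ_sp_subregion"][0]) if "sp_subregion" in occ_names else 0.0
            )
            sd_clu = (
                np.exp(parts["lsd_occ_sp_cluster"][0]) if "sp_cluster" in occ_names else 0.0
            )
            sub_eff = sd_sub * rng.standard_normal(len(spsub_levels))
            eta_re = eta_re + sub_eff[spsub_codes]
            mono = 0.0
            if lv is not None:
                zeta = softmax(parts["u_d2r"])
                cum = np.concatenate([[0.0], np.cumsum(zeta)])
                mono = parts["b_d2r"][0] * cum[lv]
            for si, sc in enumerate(scenarios):
                lu = 1.0 if sc == "forest" else -1.0
                units["lu"] = lu
                X, _, _ = psi_fixed_matrix(units, pool, spec)
                eta = X @ beta + eta_re + mono
                for t in d.occ_re:
                    sd = np.exp(parts[f"lsd_occ_{t.name}"][0])
                    z = parts[f"z_occ_{t.name}"]
                    if t.name == "sp_lu":
                        eta = eta + sd * z[usp] * lu
                    elif t.name == "fam_lu":
                        eta = eta + sd * z[ufam] * lu
                if sd_clu > 0:
                    psi = np.zeros(len(units))
                    for start in range(0, len(units), batch_pixels):
                        sl = slice(start, min(start + batch_pixels, len(units)))
                        psi[sl] = cluster_averaged_psi(eta[sl], sd_clu, ncs, rng)
                else:
                    psi = expit(eta)
                cube[usp, upx, si, di] = psi.astype(np.float32)

        return xr.DataArray(
            cube,
            dims=("species", "pixel", "scenario", "draw"),
            coords={
                "species": species,
                "pixel": px_ids,
                "scenario": list(scenarios),
                "draw": np.arange(len(dr)),
            },
            name="occupancy",
        )


def make_cube(psi_forest, psi_pasture, species=None, pixels=None) -> xr.DataArray:
    """Assemble an occupancy cube from (species x pixel [x draw]) arrays.

    A convenience for analyses and tests that start from known occupancy
    probabilities rather than a fitted model.
    """
    pf = np.asarray(psi_forest, dtype=float)
    pp = np.asarray(psi_pasture, dtype=float)
    if pf.shape != pp.shape:
        raise ValueError("forest and pasture arrays must have equal shapes")
    if pf.ndim == 2:
        pf = pf[..., None]
        pp = pp[..., None]
    n_sp, n_px, n_dr = pf.shape
    data = np.stack([pf, pp], axis=2)
    return xr.DataArray(
        data,
        dims=("species", "pixel", "scenario", "draw"),
        coords={
            "species": np.arange(n_sp) if species is None else np.asarray(species),
            "pixel": np.arange(n_px) if pixels is None else np.asarray(pixels),
            "scenario": ["forest", "pasture"],
            "draw": np.arange(n_dr),
        },
        name="occupancy",
    )
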
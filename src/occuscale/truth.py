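"""Generative simulation of latent occupancy and detection histories.

The generator is the probabilistic twin of the occupancy model: a
logit-linear occupancy process with elevation, distance-to-range, land-use,
trait and interaction terms plus crossed random effects, and a Bernoulli
per-visit detection process with observer, time-of-day, land-use and trait
terms.  It is implemented independently of the model-matrix assembly in
:mod:`occuscale.biogeo` so that parameter-recovery tests compare two
separate code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import check_seed, expit, rng_for
from .biogeo import d2r_levels, point_features, clip_pairs
from .simulate import Landscape, SpeciesPool, SamplingDesign, subregion_ids

__all__ = [
    "OccupancyParams",
    "DetectionParams",
    "TruthSet",
    "simulate_truth",
    "simulate_detections",
]


class MissingCoefficientError(KeyError):
    """A required generative coefficient was not supplied."""


OCC_COEF_NAMES = (
    "intercept",
    "elev",
    "elev2",
    "elev_x_lowmin",
    "elev2_x_lowmin",
    "land_use",
)
OCC_RE_NAMES = (
    "sp_intercept",
    "fam_intercept",
    "sp_elev",
    "sp_lu",
    "fam_lu",
    "sp_cluster",
    "sp_subregion",
)
DET_RE_NAMES = ("sp_intercept", "fam_intercept", "sp_obs", "sp_time", "sp_lu", "fam_lu")


def _require(mapping: dict, keys, what: str):
    missing = [k for k in keys if k not in mapping]
    if missing:
        raise MissingCoefficientError(f"missing {what} term(s): {missing}")


@dataclass
class OccupancyParams:
    """Coefficients of the occupancy linear predictor.

    ``coef`` must contain every fixed-effect term (intercept, elevation
    linear/quadratic, their lowland-minimum modifiers, land use);
    ``trait_coef``/``lu_trait_coef`` hold main effects and land-use
    interactions per trait name; ``re_sd`` holds every random-effect SD.
    ``b_d2r`` scales the monotonic distance-to-range effect over the
    ordinal bins; ``zeta`` is the simplex of per-bin increments (equal
    increments when None).
    """

    coef: dict
    trait_coef: dict = field(default_factory=dict)
    lu_trait_coef: dict = field(default_factory=dict)
    b_d2r: float = 0.0
    zeta: np.ndarray | None = None
    n_d2r_bins: int = 8
    re_sd: dict = field(default_factory=dict)

    def __post_init__(self):
        _require(self.coef, OCC_COEF_NAMES, "occupancy coefficient")
        _require(self.re_sd, OCC_RE_NAMES, "occupancy random-effect SD")
        if self.zeta is None:
            self.zeta = np.full(self.n_d2r_bins - 1, 1.0 / (self.n_d2r_bins - 1))
        self.zeta = np.asarray(self.zeta, dtype=float)
        if len(self.zeta) != self.n_d2r_bins - 1:
            raise ValueError("zeta must have n_d2r_bins - 1 components")
        if (self.zeta < 0).any() or abs(self.zeta.sum() - 1.0) > 1e-8:
            raise ValueError("zeta must be a simplex (non-negative, summing to 1)")

    @classmethod
    def default(cls, trait_names=("forest_dependency", "log_mass")) -> "OccupancyParams":
        """Reference generative conditions for the synthetic avifauna.

        Land-use effect 0.75 (occupancy higher in forest on average) with
        strong interspecific variation (SD 1.0) so the community contains
        both winners and losers; a hump-shaped elevational response; an
        out-of-range occupancy decline of 2 logits across the
        distance-to-range bins; spatial (cluster, subregion) random-effect
        SDs of 0.75 reflecting high small-scale heterogeneity.
        """
        return cls(
            coef={
                "intercept": -0.5,
                "elev": 0.0,
                "elev2": -1.0,
                "elev_x_lowmin": 0.0,
                "elev2_x_lowmin": 0.25,
                "land_use": 0.75,
            },
            trait_coef={t: -0.25 for t in trait_names},
            lu_trait_coef={t: 0.5 for t in trait_names},
            b_d2r=-2.0,
            re_sd={
                "sp_intercept": 1.25,
                "fam_intercept": 0.5,
                "sp_elev": 0.5,
                "sp_lu": 1.0,
                "fam_lu": 0.5,
                "sp_cluster": 0.75,
                "sp_subregion": 0.75,
            },
        )


@dataclass
class DetectionParams:
    """Coefficients of the per-visit detection linear predictor."""

    coef: dict                      # intercept, time_after_sunrise, land_use
    obs_effects: np.ndarray         # additive effect per observer id
    trait_coef: dict = field(default_factory=dict)
    re_sd: dict = field(default_factory=dict)

    def __post_init__(self):
        _require(self.coef, ("intercept", "time_after_sunrise", "land_use"), "detection coefficient")
        _require(self.re_sd, DET_RE_NAMES, "detection random-effect SD")
        self.obs_effects = np.asarray(self.obs_effects, dtype=float)

    @classmethod
    def default(cls, n_observers: int = 3, trait_names=("log_mass",)) -> "DetectionParams":
        """Reference detection conditions: per-visit detection probability
        around 0.3 for an average present species, declining through the
        morning, with moderate observer and species heterogeneity."""
        rngless = np.linspace(-0.3, 0.3, n_observers) if n_observers > 1 else np.zeros(1)
        return cls(
            coef={"intercept": -0.8, "time_after_sunrise": -0.3, "land_use": 0.2},
            obs_effects=rngless - rngless.mean(),
            trait_coef={t: 0.25 for t in trait_names},
            re_sd={
                "sp_intercept": 1.0,
                "fam_intercept": 0.5,
                "sp_obs": 0.25,
                "sp_time": 0.25,
                "sp_lu": 0.5,
                "fam_lu": 0.25,
            },
        )


@dataclass
class TruthSet:
    """Latent state and generating parameters of one simulation.

    ``units`` has one row per retained species-point pair with the analytic
    occupancy probability ``psi`` and the realized latent state ``z``.
    ``re_occ`` maps random-effect term name -> pandas Series of level
    values (indexed by level key).
    """

    units: pd.DataFrame
    re_occ: dict
    params: OccupancyParams
    features: pd.DataFrame
    clip_report: dict
    pool: SpeciesPool | None = None

    @property
    def n_units(self) -> int:
        return len(self.units)

    def save(self, path) -> None:
        """Archive the generating parameters and latent state (npz)."""
        np.savez_compressed(
            path,
            psi=self.units["psi"].to_numpy(),
            z=self.units["z"].to_numpy(),
            species_id=self.units["species_id"].to_numpy(),
            point_id=self.units["point_id"].to_numpy(),
            **{f"re_{k}": v.to_numpy() for k, v in self.re_occ.items()},
        )


def _draw_re(levels, sd: float, rng) -> pd.Series:
    vals = rng.normal(0.0, sd, size=len(levels))
    return pd.Series(vals, index=pd.Index(levels))


def occupancy_linear_predictor(
    units: pd.DataFrame,
    pool: SpeciesPool,
    params: OccupancyParams,
    re_values: dict,
) -> np.ndarray:
    """Evaluate logit(psi) for unit rows given parameters and RE values.

    ``units`` needs species_id, std_elevation, distance_to_range_km,
    land-use code ``lu`` (+1 forest / -1 pasture), cluster_id,
    subregion_id, family_id, lowmin (+-1).
    """
    c = params.coef
    e = units["std_elevation"].to_numpy()
    lu = units["lu"].to_numpy()
    lowmin = units["lowmin"].to_numpy()
    eta = (
        c["intercept"]
        + c["elev"] * e
        + c["elev2"] * e**2
        + c["elev_x_lowmin"] * lowmin * e
        + c["elev2_x_lowmin"] * lowmin * e**2
        + c["land_use"] * lu
    )
    traits = pool.traits
    for t, b in params.trait_coef.items():
        tv = traits.loc[units["species_id"], t].to_numpy()
        eta = eta + b * tv
    for t, b in params.lu_trait_coef.items():
        tv = traits.loc[units["species_id"], t].to_numpy()
        eta = eta + b * lu * tv
    # monotonic distance-to-range effect
    lv = d2r_levels(units["distance_to_range_km"].to_numpy(), params.n_d2r_bins)
    cum = np.concatenate([[0.0], np.cumsum(params.zeta)])
    eta = eta + params.b_d2r * cum[lv]
    # random effects
    keys = {
        "sp_intercept": (units["species_id"], 1.0),
        "fam_intercept": (units["family_id"], 1.0),
        "sp_elev": (units["species_id"], e),
        "sp_lu": (units["species_id"], lu),
        "fam_lu": (units["family_id"], lu),
        "sp_cluster": (
            pd.MultiIndex.from_arrays([units["species_id"], units["cluster_id"]]),
            1.0,
        ),
        "sp_subregion": (
            pd.MultiIndex.from_arrays([units["species_id"], units["subregion_id"]]),
            1.0,
        ),
    }
    for name, (idx, cov) in keys.items():
        vals = re_values[name]
        eta = eta + vals.loc[idx].to_numpy() * cov
    return eta


def simulate_truth(
    landscape: Landscape,
    pool: SpeciesPool,
    design: SamplingDesign,
    params: OccupancyParams,
    seed: int,
    features: pd.DataFrame | None = None,
) -> TruthSet:
    """Simulate latent occupancy for every retained species-point pair.

    Biogeographic clipping is applied first; z is identically zero (and
    unrepresented) for clipped pairs.  ``z ~ Bernoulli(psi)`` independently
    across retained pairs.
    """
    rng = rng_for(check_seed(seed), "truth")
    if features is None:
        features = point_features(design.points, pool, landscape)
    retained, report = clip_pairs(features)

    units = retained[["species_id", "point_id", "std_elevation", "distance_to_range_km"]].copy()
    pts = design.points.set_index("point_id")
    sp = pool.species.set_index("species_id")
    units["lu"] = np.where(pts.loc[units["point_id"], "land_use"].to_numpy() == "forest", 1.0, -1.0)
    units["cluster_id"] = pts.loc[units["point_id"], "cluster_id"].to_numpy()
    units["subregion_id"] = subregion_ids(
        pts.loc[units["point_id"], "x_km"].to_numpy(),
        pts.loc[units["point_id"], "y_km"].to_numpy(),
    )
    units["family_id"] = sp.loc[units["species_id"], "family_id"].to_numpy()
    units["lowmin"] = np.where(sp.loc[units["species_id"], "elev_min_m"].to_numpy() <= 0.0, -1.0, 1.0)

    re_values = {}
    level_sets = {
        "sp_intercept": pd.Index(pool.species["species_id"]),
        "fam_intercept": pd.Index(sorted(pool.species["family_id"].unique())),
        "sp_elev": pd.Index(pool.species["species_id"]),
        "sp_lu": pd.Index(pool.species["species_id"]),
        "fam_lu": pd.Index(sorted(pool.species["family_id"].unique())),
        "sp_cluster": pd.MultiIndex.from_frame(
            units[["species_id", "cluster_id"]].drop_duplicates()
        ),
        "sp_subregion": pd.MultiIndex.from_frame(
            units[["species_id", "subregion_id"]].drop_duplicates()
        ),
    }
    for name, levels in level_sets.items():
        re_values[name] = _draw_re(levels, params.re_sd[name], rng)

    eta = occupancy_linear_predictor(units, pool, params, re_values)
    psi = expit(eta)
    z = (rng.random(len(units)) < psi).astype(int)
    units["psi"] = psi
    units["z"] = z
    return TruthSet(
        units=units.reset_index(drop=True),
        re_occ=re_values,
        params=params,
        features=features,
        clip_report=report,
        pool=pool,
    )


def simulate_detections(
    truth: TruthSet,
    design: SamplingDesign,
    det_params: DetectionParams,
    seed: int,
) -> pd.DataFrame:
    """Simulate the long detection table (one row per unit visit).

    ``y | z=1 ~ Bernoulli(p)`` with a logit-linear detection predictor;
    ``y = 0`` wherever ``z = 0`` (no false positives).  Returns a DataFrame
    with columns point_id, species_id, visit_index, y, observer_id,
    time_after_sunrise_h, land_use, date, p_true.
    """
    rng = rng_for(check_seed(seed), "detections")
    units = truth.units
    visits = design.visits
    unknown = set(visits["point_id"]) - set(design.points["point_id"])
    if unknown:
        raise ValueError(f"visits reference unknown point ids: {sorted(unknown)[:5]}")

    rows = units[["species_id", "point_id", "family_id", "lu", "z"]].copy()
    rows["unit_index"] = np.arange(len(rows))
    long = rows.merge(visits, on="point_id", how="inner")

    time_std = (
        long["time_after_sunrise_h"] - visits["time_after_sunrise_h"].mean()
    ) / max(visits["time_after_sunrise_h"].std(ddof=0), 1e-12)
    c = det_params.coef
    n_obs_cfg = len(det_params.obs_effects)
    obs = long["observer_id"].to_numpy()
    if obs.max() >= n_obs_cfg:
        raise ValueError(
            f"observer id {obs.max()} outside configured obs_effects (length {n_obs_cfg})"
        )
    eta = (
        c["intercept"]
        + det_params.obs_effects[obs]
        + c["time_after_sunrise"] * time_std.to_numpy()
        + c["land_use"] * long["lu"].to_numpy()
    )
    for t, b in det_params.trait_coef.items():
        if truth.pool is None:
            raise MissingCoefficientError(
                f"detection trait {t!r} requires the TruthSet to carry its species pool"
            )
        eta = eta + b * truth.pool.traits.loc[long["species_id"], t].to_numpy()

    # random effects
    rsd = det_params.re_sd
    sp_levels = pd.Index(sorted(units["species_id"].unique()))
    fam_levels = pd.Index(sorted(units["family_id"].unique()))
    spobs_levels = pd.MultiIndex.from_frame(
        long[["species_id", "observer_id"]].drop_duplicates()
    )
    re = {
        "sp_intercept": (_draw_re(sp_levels, rsd["sp_intercept"], rng), long["species_id"], 1.0),
        "fam_intercept": (_draw_re(fam_levels, rsd["fam_intercept"], rng), long["family_id"], 1.0),
        "sp_obs": (
            _draw_re(spobs_levels, rsd["sp_obs"], rng),
            pd.MultiIndex.from_frame(long[["species_id", "observer_id"]]),
            1.0,
        ),
        "sp_time": (_draw_re(sp_levels, rsd["sp_time"], rng), long["species_id"], time_std.to_numpy()),
        "sp_lu": (_draw_re(sp_levels, rsd["sp_lu"], rng), long["species_id"], long["lu"].to_numpy()),
        "fam_lu": (_draw_re(fam_levels, rsd["fam_lu"], rng), long["family_id"], long["lu"].to_numpy()),
    }
    for name, (vals, idx, cov) in re.items():
        eta = eta + vals.loc[idx].to_numpy() * cov

    p = expit(eta)
    y = ((rng.random(len(long)) < p) & (long["z"].to_numpy() == 1)).astype(int)
    out = long[
        ["point_id", "species_id", "visit_index", "observer_id", "time_after_sunrise_h", "date"]
    ].copy()
    out["land_use"] = np.where(long["lu"].to_numpy() > 0, "forest", "pasture")
    out["y"] = y
    out["p_true"] = p
    return out.reset_index(drop=True)
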
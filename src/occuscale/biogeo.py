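"""Biogeographic covariates, clipping rules and model matrices.

Three covariates are bespoke to this analysis and computed here:

* **species-standardized elevation** — site elevation linearly rescaled per
  species so its elevational limits map to -1 and +1;
* **distance-to-range** — signed distance (km) from a site to the nearest
  edge of the species' mapped range, negative inside the range, computed
  only against range within the site's topographic unit (ranges isolated by
  a major topographic barrier do not count);
* **barrier distances** — valley- and mountain-barrier separations between
  site pairs, used as dissimilarity predictors.

Biogeographic clipping removes species-site pairs that are implausible on
range (distance-to-range >= 160 km), elevation (standardized elevation
outside (-3, 3)) or season grounds; only retained pairs enter the occupancy
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .simulate import Landscape, SpeciesPool, SamplingDesign, subregion_ids

__all__ = [
    "std_elevation",
    "distance_to_range",
    "point_features",
    "clip_pairs",
    "valley_barrier",
    "mountain_barrier",
    "site_pair_table",
    "ModelSpec",
    "OccDesign",
    "build_design",
    "NO_RANGE_IN_UNIT",
]

#: Sentinel distance (km) for species with no mapped range in the site's
#: topographic unit; always removed by clipping.
NO_RANGE_IN_UNIT = np.inf

D2R_CLIP_KM = 160.0
STD_ELEV_BOUND = 3.0
MOUNTAIN_CEILING_M = 4100.0


def std_elevation(elevation_m, species_min_m, species_max_m):
    """Species-standardized elevation: -1 at the species' minimum, +1 at its
    maximum, linear and unbounded outside."""
    emin = np.asarray(species_min_m, dtype=float)
    emax = np.asarray(species_max_m, dtype=float)
    if np.any(emax <= emin):
        raise ValueError("degenerate elevational range: species_max_m must exceed species_min_m")
    return -1.0 + 2.0 * (np.asarray(elevation_m, dtype=float) - emin) / (emax - emin)


def distance_to_range(
    points: pd.DataFrame,
    pool: SpeciesPool,
    landscape: Landscape,
    species_ids=None,
) -> pd.DataFrame:
    """Signed distance-to-range (km) for every species-point combination.

    Positive outside the range (distance to the nearest in-unit range
    pixel), negative inside (distance to the nearest in-unit pixel outside
    the range, i.e. to the range edge).  When the species has no range in
    the point's topographic unit the sentinel ``NO_RANGE_IN_UNIT`` (inf) is
    returned; those pairs are later removed by clipping.

    ``points`` needs columns point_id, x_km, y_km.  The point's topographic
    unit is that of its containing pixel.
    """
    px = landscape.pixels
    if species_ids is None:
        species_ids = pool.species["species_id"].to_numpy()
    species_ids = np.asarray(species_ids)
    unknown = set(species_ids) - set(pool.species["species_id"])
    if unknown:
        raise KeyError(f"unknown species ids: {sorted(unknown)[:5]}")

    # topographic unit of each point, via its containing pixel
    s = landscape.pixel_size_km
    nx = int(round(landscape.extent_km[0] / s))
    ny = int(round(landscape.extent_km[1] / s))
    ii = np.clip((points["x_km"].to_numpy() / s).astype(int), 0, nx - 1)
    jj = np.clip((points["y_km"].to_numpy() / s).astype(int), 0, ny - 1)
    pt_pixel = ii * ny + jj
    topo_of_pixel = px.set_index("pixel_id")["topo_unit_id"]
    pt_topo = topo_of_pixel.loc[pt_pixel].to_numpy()

    ranges = pool.ranges.merge(
        px[["pixel_id", "topo_unit_id", "x_km", "y_km"]], on="pixel_id", how="left"
    )
    in_range_lookup = set(zip(ranges["species_id"].to_numpy(), ranges["pixel_id"].to_numpy()))

    pts_xy = points[["x_km", "y_km"]].to_numpy()
    out_frames = []
    for unit, pidx in pd.Series(np.arange(len(points))).groupby(pt_topo):
        pidx = pidx.to_numpy()
        unit_px = px[px["topo_unit_id"] == unit]
        unit_xy = unit_px[["x_km", "y_km"]].to_numpy()
        unit_ids = unit_px["pixel_id"].to_numpy()
        unit_ranges = ranges[ranges["topo_unit_id"] == unit]
        by_species = dict(list(unit_ranges.groupby("species_id")))
        for sp in species_ids:
            grp = by_species.get(sp)
            d = np.full(len(pidx), NO_RANGE_IN_UNIT)
            if grp is not None and len(grp):
                in_ids = set(grp["pixel_id"].to_numpy())
                tree_in = cKDTree(grp[["x_km", "y_km"]].to_numpy())
                d_in, _ = tree_in.query(pts_xy[pidx])
                out_mask = np.array([pid not in in_ids for pid in unit_ids])
                if out_mask.any():
                    tree_out = cKDTree(unit_xy[out_mask])
                    d_out, _ = tree_out.query(pts_xy[pidx])
                else:  # species occupies the entire unit
                    d_out = np.full(len(pidx), max(landscape.extent_km))
                inside = np.array([(sp, int(pp)) in in_range_lookup for pp in pt_pixel[pidx]])
                d = np.where(inside, -d_out, d_in)
            out_frames.append(
                pd.DataFrame(
                    {
                        "species_id": sp,
                        "point_id": points["point_id"].to_numpy()[pidx],
                        "distance_to_range_km": d,
                        "topo_unit_id": unit,
                    }
                )
            )
    out = pd.concat(out_frames, ignore_index=True)
    return out.sort_values(["species_id", "point_id"], ignore_index=True)


def _in_season(species: pd.DataFrame, dates) -> np.ndarray:
    """Seasonal availability; residents are always available."""
    if dates is None:
        return np.ones(len(species), dtype=bool)
    res = species["resident"].to_numpy(dtype=bool)
    start = species["season_start"].to_numpy()
    end = species["season_end"].to_numpy()
    d = np.asarray(dates, dtype=float)
    return res | ((d >= start) & (d <= end))


def point_features(
    points: pd.DataFrame,
    pool: SpeciesPool,
    landscape: Landscape,
    dates=None,
    d2r_clip_km: float = D2R_CLIP_KM,
    elev_bound: float = STD_ELEV_BOUND,
) -> pd.DataFrame:
    """Full species x point feature table with retention flags.

    Columns: species_id, point_id, distance_to_range_km, std_elevation,
    in_season, retained.  ``dates`` optionally gives one representative
    survey date per point for seasonal gating (off by default: synthetic
    pools are all-resident).
    """
    feats = distance_to_range(points, pool, landscape)
    sp = pool.species.set_index("species_id")
    emin = sp.loc[feats["species_id"], "elev_min_m"].to_numpy()
    emax = sp.loc[feats["species_id"], "elev_max_m"].to_numpy()
    elev_pt = points.set_index("point_id")["elevation_m"]
    e = elev_pt.loc[feats["point_id"]].to_numpy()
    feats["std_elevation"] = std_elevation(e, emin, emax)

    # seasonal gating: `dates` is a representative survey day-of-year
    season_by_species = pd.Series(
        _in_season(pool.species, dates), index=pool.species["species_id"]
    )
    feats["in_season"] = season_by_species.loc[feats["species_id"]].to_numpy()
    feats["retained"] = (
        (feats["distance_to_range_km"] < d2r_clip_km)
        & (feats["std_elevation"] > -elev_bound)
        & (feats["std_elevation"] < elev_bound)
        & feats["in_season"]
    )
    return feats


def clip_pairs(
    features: pd.DataFrame,
    d2r_clip_km: float = D2R_CLIP_KM,
    elev_bound: float = STD_ELEV_BOUND,
) -> tuple[pd.DataFrame, dict]:
    """Apply biogeographic clipping; return retained pairs and removal counts.

    A pair is retained iff distance-to-range < 160 km, standardized
    elevation lies in (-3, 3), and the pair is in season.  Idempotent and
    order-independent.
    """
    fail_d2r = ~(features["distance_to_range_km"] < d2r_clip_km)
    fail_elev = ~(
        (features["std_elevation"] > -elev_bound) & (features["std_elevation"] < elev_bound)
    )
    fail_season = ~features["in_season"].astype(bool)
    keep = ~(fail_d2r | fail_elev | fail_season)
    counts = {
        "n_pairs": int(len(features)),
        "removed_distance": int(fail_d2r.sum()),
        "removed_elevation": int(fail_elev.sum()),
        "removed_season": int(fail_season.sum()),
        "retained": int(keep.sum()),
    }
    out = features.loc[keep].copy()
    out["retained"] = True
    return out, counts


# ---------------------------------------------------------------------------
# Barrier covariates (GDM predictors)
# ---------------------------------------------------------------------------

def valley_barrier(range_i, range_j, elev_i_m, elev_j_m):
    """Valley-barrier separation between two sites, in metres.

    Zero for sites on the same mountain range (no valley isolates them);
    otherwise the elevation of the lower site — valley barriers matter
    increasingly for higher-elevation faunas.
    """
    ri, rj = np.asarray(range_i), np.asarray(range_j)
    if np.any(pd.isna(ri)) or np.any(pd.isna(rj)):
        raise ValueError("missing mountain-range label")
    lower = np.minimum(np.asarray(elev_i_m, dtype=float), np.asarray(elev_j_m, dtype=float))
    return np.where(ri == rj, 0.0, lower)


def mountain_barrier(side_i, side_j, elev_i_m, elev_j_m, ceiling_m: float = MOUNTAIN_CEILING_M):
    """Mountain-barrier separation between two sites, in metres.

    Zero for sites on the same side of the main cordilleran divide;
    otherwise ``ceiling_m`` (default 4,100 m, the highest elevation sampled)
    minus the elevation of the higher site, floored at zero — mountain
    barriers matter increasingly for lower-elevation faunas.
    """
    si, sj = np.asarray(side_i), np.asarray(side_j)
    if np.any(pd.isna(si)) or np.any(pd.isna(sj)):
        raise ValueError("missing divide-side label")
    higher = np.maximum(np.asarray(elev_i_m, dtype=float), np.asarray(elev_j_m, dtype=float))
    return np.where(si == sj, 0.0, np.maximum(ceiling_m - higher, 0.0))


def synthetic_barrier_labels(landscape: Landscape, points: pd.DataFrame) -> pd.DataFrame:
    """Attach synthetic mountain-range and divide-side labels to points.

    On the synthetic landscape the topographic unit of a point stands in
    for its mountain range, and the west/east half of the extent for the
    side of the main cordilleran divide.  Returns a copy of ``points`` with
    site_id, mountain_range, divide_side and annual_precip_mm columns.
    """
    px = landscape.pixels
    s = landscape.pixel_size_km
    nx = int(round(landscape.extent_km[0] / s))
    ny = int(round(landscape.extent_km[1] / s))
    ii = np.clip((points["x_km"].to_numpy() / s).astype(int), 0, nx - 1)
    jj = np.clip((points["y_km"].to_numpy() / s).astype(int), 0, ny - 1)
    pix = px.set_index("pixel_id").loc[ii * ny + jj]
    out = points.copy()
    out["site_id"] = out["point_id"].to_numpy()
    out["mountain_range"] = pix["topo_unit_id"].to_numpy()
    out["divide_side"] = (points["x_km"].to_numpy() < landscape.extent_km[0] / 2).astype(int)
    out["annual_precip_mm"] = pix["annual_precip_mm"].to_numpy()
    return out


def site_pair_table(sites: pd.DataFrame, ceiling_m: float = MOUNTAIN_CEILING_M) -> pd.DataFrame:
    """All unordered site pairs with geographic and barrier distances.

    ``sites`` needs columns site_id, x_km, y_km, elevation_m and the labels
    mountain_range and divide_side; optional annual_precip_mm is carried
    into the pair table as the per-site values.
    """
    n = len(sites)
    i, j = np.triu_indices(n, k=1)
    s = sites.reset_index(drop=True)
    out = pd.DataFrame(
        {
            "site_i": s["site_id"].to_numpy()[i],
            "site_j": s["site_id"].to_numpy()[j],
            "geo_km": np.hypot(
                s["x_km"].to_numpy()[i] - s["x_km"].to_numpy()[j],
                s["y_km"].to_numpy()[i] - s["y_km"].to_numpy()[j],
            ),
            "valley_m": valley_barrier(
                s["mountain_range"].to_numpy()[i],
                s["mountain_range"].to_numpy()[j],
                s["elevation_m"].to_numpy()[i],
                s["elevation_m"].to_numpy()[j],
            ),
            "mountain_m": mountain_barrier(
                s["divide_side"].to_numpy()[i],
                s["divide_side"].to_numpy()[j],
                s["elevation_m"].to_numpy()[i],
                s["elevation_m"].to_numpy()[j],
                ceiling_m=ceiling_m,
            ),
            "elev_i": s["elevation_m"].to_numpy()[i],
            "elev_j": s["elevation_m"].to_numpy()[j],
        }
    )
    if "annual_precip_mm" in s.columns:
        out["precip_i"] = s["annual_precip_mm"].to_numpy()[i]
        out["precip_j"] = s["annual_precip_mm"].to_numpy()[j]
    return out


# ---------------------------------------------------------------------------
# Model matrices
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Term selection and prior scales for the occupancy model.

    All binary predictors are coded -1/+1 (forest = +1) and continuous
    predictors standardized, so binary and continuous effects are on a
    common scale and prior pushforwards do not depend on reference-category
    choices.  Priors are zero-centred Gaussians: ``prior_sd_intercept`` for
    intercepts, ``prior_sd_slope`` for every slope, half-Normal
    ``prior_sd_re`` for random-effect standard deviations, and a
    uniform-on-the-simplex prior (softmax of iid Normals) for the
    distance-to-range monotonic simplex.
    """

    occ_traits: tuple[str, ...] = ("forest_dependency", "log_mass")
    det_traits: tuple[str, ...] = ("forest_dependency", "log_mass")
    include_elevation: bool = True
    include_lowland_split: bool = True
    include_mono_d2r: bool = True
    n_d2r_bins: int = 8
    occ_random: tuple[str, ...] = (
        "sp_intercept",
        "fam_intercept",
        "sp_elev",
        "sp_lu",
        "fam_lu",
        "sp_cluster",
        "sp_subregion",
    )
    det_random: tuple[str, ...] = (
        "sp_intercept",
        "fam_intercept",
        "sp_obs",
        "sp_time",
        "sp_lu",
        "fam_lu",
    )
    prior_sd_intercept: float = 1.0
    prior_sd_slope: float = 0.5
    prior_sd_re: float = 0.5
    #: per-term prior-scale overrides (keys are design-column or random-effect
    #: names).  The focal land-use contrast gets a wider prior than the
    #: nuisance slopes: forest-pasture occupancy contrasts in tropical birds
    #: are routinely of multi-logit magnitude, and the prior must not rule
    #: them out, whereas the summed pushforward of the many remaining terms
    #: must stay away from occupancy probabilities of exactly 0 or 1.
    prior_sd_overrides: dict = field(
        default_factory=lambda: {"land_use": 1.0, "sp_lu": 0.75}
    )
    subregion_scale_km: float = 20.0

    def prior_for(self, term: str, default: float) -> float:
        return float(self.prior_sd_overrides.get(term, default))

    @classmethod
    def reduced(cls, occ_traits=("forest_dependency",), det_traits=()) -> "ModelSpec":
        """A small spec for fast fitting: species/family intercepts and
        land-use slopes only, no spatial random effects."""
        return cls(
            occ_traits=tuple(occ_traits),
            det_traits=tuple(det_traits),
            include_mono_d2r=False,
            occ_random=("sp_intercept", "fam_intercept", "sp_lu"),
            det_random=("sp_intercept",),
        )


@dataclass
class RETerm:
    """One random-effect term: values of ``cov`` multiply the level effect."""

    name: str
    index: np.ndarray       # level index per row
    cov: np.ndarray         # multiplier per row (1.0 for intercepts)
    n_levels: int
    sd_prior_scale: float


@dataclass
class OccDesign:
    """Assembled model matrices for the occupancy model.

    Unit rows are retained species x point pairs; visit rows are units
    crossed with their visits (variable 2-4 per unit).
    """

    units: pd.DataFrame          # species_id, point_id (+ bookkeeping columns)
    X_psi: np.ndarray            # fixed occupancy design (n_units, P_psi)
    psi_colnames: list
    psi_prior_sd: np.ndarray
    d2r_level: np.ndarray | None  # ordinal level 0..K per unit (None if disabled)
    n_d2r_levels: int
    occ_re: list
    visit_unit: np.ndarray       # unit index per visit row
    y: np.ndarray                # detection outcome per visit row
    X_p: np.ndarray              # fixed detection design (n_visit_rows, P_p)
    p_colnames: list
    p_prior_sd: np.ndarray
    det_re: list
    spec: ModelSpec
    meta: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return len(self.units)


def _lu_code(land_use) -> np.ndarray:
    lu = np.asarray(land_use)
    known = np.isin(lu, ("forest", "pasture"))
    if not known.all():
        bad = sorted(set(lu[~known]))
        raise ValueError(f"unknown land-use label(s): {bad}")
    return np.where(lu == "forest", 1.0, -1.0)


def _binary_pm1(x) -> np.ndarray:
    """Remap a 0/1-coded binary column to -1/+1; pass -1/+1 through."""
    x = np.asarray(x, dtype=float)
    vals = set(np.unique(x))
    if vals <= {0.0, 1.0}:
        return 2.0 * x - 1.0
    return x


def _standardize(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def psi_fixed_matrix(units: pd.DataFrame, pool: SpeciesPool, spec: "ModelSpec"):
    """Fixed-effect occupancy design matrix for unit rows.

    ``units`` needs species_id, std_elevation, ``lu`` (+1 forest / -1
    pasture) and ``lowmin`` (+-1 lowland-minimum indicator).  Shared by
    model fitting and pixel prediction so both use identical columns.
    Returns (X, column names, prior SD vector).
    """
    e = units["std_elevation"].to_numpy()
    lu = units["lu"].to_numpy(dtype=float)
    lowmin = units["lowmin"].to_numpy(dtype=float)
    cols, names, prior = [], [], []

    def add(col, name, sd):
        cols.append(np.asarray(col, dtype=float))
        names.append(name)
        prior.append(spec.prior_for(name, sd))

    add(np.ones(len(units)), "intercept", spec.prior_sd_intercept)
    if spec.include_elevation:
        add(e, "elev", spec.prior_sd_slope)
        add(e**2, "elev2", spec.prior_sd_slope)
        if spec.include_lowland_split:
            add(lowmin * e, "elev_x_lowmin", spec.prior_sd_slope)
            add(lowmin * e**2, "elev2_x_lowmin", spec.prior_sd_slope)
    add(lu, "land_use", spec.prior_sd_slope)
    traits = pool.traits
    for t in spec.occ_traits:
        if t not in traits.columns:
            raise KeyError(f"occupancy trait {t!r} not in species pool traits")
        tv = _binary_pm1(traits.loc[units["species_id"], t].to_numpy())
        add(tv, f"trait_{t}", spec.prior_sd_slope)
        add(lu * tv, f"lu_x_{t}", spec.prior_sd_slope)
    return np.column_stack(cols), names, np.array(prior)


def d2r_levels(d2r_km, n_bins: int, clip_km: float = D2R_CLIP_KM) -> np.ndarray:
    """Ordinal distance-to-range level: ``n_bins`` equal-width bins over
    [-clip, clip] km, level 0 = deepest in range, level n_bins-1 = farthest
    out of range."""
    edges = np.linspace(-clip_km, clip_km, n_bins + 1)[1:-1]
    return np.digitize(np.asarray(d2r_km, dtype=float), edges)


def build_design(
    detections: pd.DataFrame,
    features: pd.DataFrame,
    pool: SpeciesPool,
    design: SamplingDesign,
    spec: ModelSpec | None = None,
) -> OccDesign:
    """Assemble occupancy and detection model matrices.

    ``detections`` is the long visit table (point_id, species_id,
    visit_index, y, observer_id, time_after_sunrise_h, land_use);
    ``features`` the clipped species-point feature table.  Clipping must
    already have been applied (rows with retained == False are dropped
    here, and any detection belonging to a clipped pair is an error).
    """
    spec = spec or ModelSpec()
    feats = features[features["retained"]].reset_index(drop=True)
    units = feats[["species_id", "point_id", "std_elevation", "distance_to_range_km"]].copy()

    pts = design.points.set_index("point_id")
    sp = pool.species.set_index("species_id")
    units["land_use"] = pts.loc[units["point_id"], "land_use"].to_numpy()
    units["cluster_id"] = pts.loc[units["point_id"], "cluster_id"].to_numpy()
    xs = pts.loc[units["point_id"], "x_km"].to_numpy()
    ys = pts.loc[units["point_id"], "y_km"].to_numpy()
    units["subregion_id"] = subregion_ids(xs, ys, spec.subregion_scale_km)
    units["family_id"] = sp.loc[units["species_id"], "family_id"].to_numpy()

    lu = _lu_code(units["land_use"])
    units["lu"] = lu
    units["lowmin"] = np.where(
        sp.loc[units["species_id"], "elev_min_m"].to_numpy() <= 0.0, -1.0, 1.0
    )
    X_psi, names, psi_prior = psi_fixed_matrix(units, pool, spec)
    e = units["std_elevation"].to_numpy()
    traits = pool.traits

    d2r_lv = None
    if spec.include_mono_d2r:
        d2r_lv = d2r_levels(units["distance_to_range_km"].to_numpy(), spec.n_d2r_bins)

    # grouping indices
    def codes(values):
        if isinstance(values, list):
            values = pd.Index(values)
        c, levels = pd.factorize(values, sort=True)
        return c.astype(np.int64), len(levels)

    sp_idx, n_sp = codes(units["species_id"])
    fam_idx, n_fam = codes(units["family_id"])
    clu_idx, n_clu = codes(list(zip(units["species_id"], units["cluster_id"])))
    sub_idx, n_sub = codes(list(zip(units["species_id"], units["subregion_id"])))
    units["_sp"] = sp_idx

    occ_terms_all = {
        "sp_intercept": RETerm("sp_intercept", sp_idx, np.ones(len(units)), n_sp, spec.prior_sd_re),
        "fam_intercept": RETerm("fam_intercept", fam_idx, np.ones(len(units)), n_fam, spec.prior_sd_re),
        "sp_elev": RETerm("sp_elev", sp_idx, e, n_sp, spec.prior_sd_re),
        "sp_lu": RETerm("sp_lu", sp_idx, lu, n_sp, spec.prior_sd_re),
        "fam_lu": RETerm("fam_lu", fam_idx, lu, n_fam, spec.prior_sd_re),
        "sp_cluster": RETerm("sp_cluster", clu_idx, np.ones(len(units)), n_clu, spec.prior_sd_re),
        "sp_subregion": RETerm("sp_subregion", sub_idx, np.ones(len(units)), n_sub, spec.prior_sd_re),
    }
    for t in occ_terms_all.values():
        t.sd_prior_scale = spec.prior_for(t.name, spec.prior_sd_re)
    occ_re = [occ_terms_all[k] for k in spec.occ_random]

    # ---- visit rows -------------------------------------------------------
    det = detections.copy()
    key = pd.MultiIndex.from_frame(units[["species_id", "point_id"]])
    unit_pos = pd.Series(np.arange(len(units)), index=key)
    det_key = pd.MultiIndex.from_frame(det[["species_id", "point_id"]])
    missing = ~det_key.isin(unit_pos.index)
    if missing.any():
        if det.loc[missing.to_numpy(), "y"].to_numpy().any():
            raise ValueError(
                "detections exist for species-point pairs removed by clipping"
            )
        det = det.loc[~missing.to_numpy()].reset_index(drop=True)
        det_key = pd.MultiIndex.from_frame(det[["species_id", "point_id"]])
    visit_unit = unit_pos.loc[det_key].to_numpy()
    order = np.argsort(visit_unit, kind="stable")
    det = det.iloc[order].reset_index(drop=True)
    visit_unit = visit_unit[order]

    y = det["y"].to_numpy(dtype=float)
    lu_v = _lu_code(det["land_use"])
    time_v = _standardize(det["time_after_sunrise_h"].to_numpy())
    obs_codes, n_obs = codes(det["observer_id"])

    dcols, dnames, dprior = [], [], []

    def addd(col, name, sd):
        dcols.append(np.asarray(col, dtype=float))
        dnames.append(name)
        dprior.append(spec.prior_for(name, sd))

    addd(np.ones(len(det)), "intercept", spec.prior_sd_intercept)
    # observer effects: sum-to-zero coding over n_obs levels
    for o in range(n_obs - 1):
        col = np.where(obs_codes == o, 1.0, np.where(obs_codes == n_obs - 1, -1.0, 0.0))
        addd(col, f"observer_{o}", spec.prior_sd_slope)
    addd(time_v, "time_after_sunrise", spec.prior_sd_slope)
    addd(lu_v, "land_use", spec.prior_sd_slope)
    for t in spec.det_traits:
        if t not in traits.columns:
            raise KeyError(f"detection trait {t!r} not in species pool traits")
        tv = _binary_pm1(traits.loc[det["species_id"], t].to_numpy())
        addd(tv, f"trait_{t}", spec.prior_sd_slope)
    X_p = np.column_stack(dcols)
    p_prior = np.array(dprior)

    vsp_idx = units["_sp"].to_numpy()[visit_unit]
    vfam_idx = fam_idx[visit_unit]
    spobs_idx, n_spobs = codes(list(zip(vsp_idx, obs_codes)))
    det_terms_all = {
        "sp_intercept": RETerm("sp_intercept", vsp_idx, np.ones(len(det)), n_sp, spec.prior_sd_re),
        "fam_intercept": RETerm("fam_intercept", vfam_idx, np.ones(len(det)), n_fam, spec.prior_sd_re),
        "sp_obs": RETerm("sp_obs", spobs_idx, np.ones(len(det)), n_spobs, spec.prior_sd_re),
        "sp_time": RETerm("sp_time", vsp_idx, time_v, n_sp, spec.prior_sd_re),
        "sp_lu": RETerm("sp_lu", vsp_idx, lu_v, n_sp, spec.prior_sd_re),
        "fam_lu": RETerm("fam_lu", vfam_idx, lu_v, n_fam, spec.prior_sd_re),
    }
    for t in det_terms_all.values():
        t.sd_prior_scale = spec.prior_for(t.name, spec.prior_sd_re)
    det_re = [det_terms_all[k] for k in spec.det_random]

    # every unit must have at least one visit row
    counts = np.bincount(visit_unit, minlength=len(units))
    if (counts == 0).any():
        raise ValueError(
            f"{int((counts == 0).sum())} retained species-point pairs have no visit rows"
        )

    return OccDesign(
        units=units,
        X_psi=X_psi,
        psi_colnames=names,
        psi_prior_sd=psi_prior,
        d2r_level=d2r_lv,
        n_d2r_levels=spec.n_d2r_bins,
        occ_re=occ_re,
        visit_unit=visit_unit,
        y=y,
        X_p=X_p,
        p_colnames=dnames,
        p_prior_sd=p_prior,
        det_re=det_re,
        spec=spec,
        meta={
            "n_species": n_sp,
            "n_families": n_fam,
            "species_levels": np.sort(units["species_id"].unique()),
        },
    )
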
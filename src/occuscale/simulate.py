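"""Synthetic landscapes, species pools and sampling designs.

The generator emulates the structure of a paired forest/pasture point-count
study spread across a biogeographically structured tropical landscape: a
regular 2-km pixel grid carrying elevation, topographic units and
biogeographic regions; a pool of species with contiguous geographic ranges,
elevational niches and traits; and clustered point-count sampling with
repeated visits by multiple observers.

Everything is deterministic given ``(config, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import check_seed, rng_for

__all__ = [
    "LandscapeConfig",
    "Landscape",
    "make_landscape",
    "TraitSpec",
    "SpeciesConfig",
    "SpeciesPool",
    "make_species_pool",
    "DesignConfig",
    "SamplingDesign",
    "make_sampling_design",
    "total_survey_minutes",
]


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

@dataclass
class LandscapeConfig:
    """Configuration of the gridded landscape.

    Attributes
    ----------
    extent_km : (width, height) of the study rectangle in km. Must be
        divisible by ``pixel_size_km``.
    pixel_size_km : edge length of the square pixels (2 km by default, the
        grain at which occupancy is predicted).
    n_regions : number of biogeographic regions; contiguous vertical strips.
    n_topo_units : number of topographic units; contiguous horizontal bands,
        so that units and regions cut across one another.
    elevation_range_m : (min, max) elevation after rescaling the ridge
        surface.
    n_ridges : number of Gaussian ridges summed to build the elevation
        surface.
    """

    extent_km: tuple[float, float] = (40.0, 40.0)
    pixel_size_km: float = 2.0
    n_regions: int = 2
    n_topo_units: int = 2
    elevation_range_m: tuple[float, float] = (0.0, 3500.0)
    n_ridges: int = 3
    precip_range_mm: tuple[float, float] = (1000.0, 4000.0)

    def validate(self) -> None:
        w, h = self.extent_km
        if w <= 0 or h <= 0:
            raise ConfigError(f"extent_km must be positive, got {self.extent_km}")
        if self.pixel_size_km <= 0:
            raise ConfigError("pixel_size_km must be positive")
        for name, v in (("width", w), ("height", h)):
            if abs(v / self.pixel_size_km - round(v / self.pixel_size_km)) > 1e-9:
                raise ConfigError(
                    f"extent {name} {v} km is not divisible by pixel size "
                    f"{self.pixel_size_km} km"
                )
        if self.n_regions < 1:
            raise ConfigError("n_regions must be >= 1")
        if self.n_topo_units < 1:
            raise ConfigError("n_topo_units must be >= 1")
        lo, hi = self.elevation_range_m
        if hi < lo:
            raise ConfigError("elevation_range_m must be (min, max) with max >= min")


@dataclass
class Landscape:
    """A regular grid of square pixels with elevation and spatial groupings.

    ``pixels`` columns: pixel_id, x_km, y_km (centres), elevation_m,
    topo_unit_id, region_id. Every pixel belongs to exactly one topographic
    unit and one biogeographic region.
    """

    pixels: pd.DataFrame
    pixel_size_km: float
    extent_km: tuple[float, float]

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    @property
    def regions(self) -> np.ndarray:
        return np.sort(self.pixels["region_id"].unique())

    @property
    def topo_units(self) -> np.ndarray:
        return np.sort(self.pixels["topo_unit_id"].unique())

    def to_csv(self, path) -> None:
        self.pixels.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, pixel_size_km: float = 2.0) -> "Landscape":
        px = pd.read_csv(path)
        w = px["x_km"].max() + pixel_size_km / 2
        h = px["y_km"].max() + pixel_size_km / 2
        return cls(pixels=px, pixel_size_km=pixel_size_km, extent_km=(w, h))


def _ridge_elevation(x, y, cfg: LandscapeConfig, rng) -> np.ndarray:
    """Sum of Gaussian ridges, rescaled to the configured elevation range.

    Each ridge is a line through a random point at a random orientation;
    elevation decays as a Gaussian of perpendicular distance, so montane
    crests and lowland basins coexist on one surface.
    """
    w, h = cfg.extent_km
    z = np.zeros_like(x, dtype=float)
    for _ in range(cfg.n_ridges):
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        theta = rng.uniform(0, np.pi)
        width = rng.uniform(0.1, 0.3) * max(w, h)
        amp = rng.uniform(0.5, 1.0)
        # perpendicular distance to the ridge line
        d = -(x - cx) * np.sin(theta) + (y - cy) * np.cos(theta)
        z += amp * np.exp(-0.5 * (d / width) ** 2)
    lo, hi = cfg.elevation_range_m
    zmin, zmax = z.min(), z.max()
    if zmax > zmin:
        z = (z - zmin) / (zmax - zmin)
    else:  # flat surface (e.g. n_ridges == 0)
        z = np.zeros_like(z)
    return lo + z * (hi - lo)


def make_landscape(config: LandscapeConfig, seed: int) -> Landscape:
    """Build a deterministic synthetic landscape.

    Biogeographic regions are contiguous vertical strips and topographic
    units are horizontal bands, so the two partitions cut across one
    another rather than sharing borders.
    """
    config.validate()
    rng = rng_for(check_seed(seed), "landscape")
    w, h = config.extent_km
    s = config.pixel_size_km
    nx, ny = int(round(w / s)), int(round(h / s))
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    ix, iy = ix.ravel(), iy.ravel()
    x = (ix + 0.5) * s
    y = (iy + 0.5) * s
    elev = _ridge_elevation(x, y, config, rng)
    region = np.minimum((ix * config.n_regions) // nx, config.n_regions - 1)
    topo = np.minimum((iy * config.n_topo_units) // ny, config.n_topo_units - 1)
    # annual precipitation: a smooth tilted-plane gradient across the extent
    plo, phi = config.precip_range_mm
    t = (x / w + y / h) / 2.0
    precip = plo + t * (phi - plo)
    px = pd.DataFrame(
        {
            "pixel_id": np.arange(nx * ny),
            "x_km": x,
            "y_km": y,
            "elevation_m": elev,
            "topo_unit_id": topo.astype(int),
            "region_id": region.astype(int),
            "annual_precip_mm": precip,
        }
    )
    return Landscape(pixels=px, pixel_size_km=s, extent_km=(float(w), float(h)))


# ---------------------------------------------------------------------------
# Species pool
# ---------------------------------------------------------------------------

@dataclass
class TraitSpec:
    """One species trait: binary traits take values -1/+1 with P(+1) = p;
    continuous traits are standard-normal (i.e. pre-standardized)."""

    name: str
    kind: str = "binary"  # "binary" | "continuous"
    p: float = 0.5        # binary: probability of +1
    mean: float = 0.0     # continuous
    sd: float = 1.0


DEFAULT_TRAITS = (
    TraitSpec("forest_dependency", "binary", p=0.5),
    TraitSpec("diet_invert", "binary", p=0.5),
    TraitSpec("log_mass", "continuous"),
    TraitSpec("elev_breadth", "continuous"),
    TraitSpec("range_restricted", "binary", p=0.3),
)


@dataclass
class SpeciesConfig:
    """Configuration of the synthetic species pool.

    ``endemic_fraction`` controls beta-diversity between regions: that
    fraction of species have ranges confined to a single biogeographic
    region. Ranges are contiguous pixel sets grown from a seed pixel.
    """

    n_species: int = 150
    n_families: int = 30
    endemic_fraction: float = 0.3
    range_size_mean_frac: float = 0.35   # mean range size as fraction of home region
    range_size_sd_log: float = 0.6
    elev_breadth_mean_m: float = 1500.0
    elev_breadth_sd_log: float = 0.4
    lowland_fraction: float = 0.4        # species with elevational minimum at 0
    traits: tuple[TraitSpec, ...] = DEFAULT_TRAITS
    migrant_fraction: float = 0.0        # default all-resident
    season_length_days: int = 180

    def validate(self) -> None:
        if self.n_species < 1:
            raise ConfigError("n_species must be >= 1")
        if not 0 <= self.endemic_fraction <= 1:
            raise ConfigError("endemic_fraction must be in [0, 1]")
        if self.n_families < 1:
            raise ConfigError("n_families must be >= 1")


@dataclass
class SpeciesPool:
    """Per-species ranges, elevational limits, traits and seasonality.

    ``species`` columns: species_id, family_id, elev_min_m, elev_max_m,
    resident (bool), season_start, season_end (day of year; NaN when
    resident). ``traits`` is indexed by species_id with one column per
    trait (binary traits coded -1/+1). ``ranges`` is a long table
    (species_id, pixel_id).
    """

    species: pd.DataFrame
    traits: pd.DataFrame
    ranges: pd.DataFrame

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)

    def range_pixels(self, species_id: int) -> np.ndarray:
        return self.ranges.loc[self.ranges["species_id"] == species_id, "pixel_id"].to_numpy()

    def to_json(self, path) -> None:
        payload = {
            "schema_version": 1,
            "species": self.species.to_dict(orient="list"),
            "traits": {
                "species_id": self.traits.index.tolist(),
                **{c: self.traits[c].tolist() for c in self.traits.columns},
            },
            "ranges": {
                str(sid): grp["pixel_id"].tolist()
                for sid, grp in self.ranges.groupby("species_id")
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "SpeciesPool":
        payload = json.loads(Path(path).read_text())
        species = pd.DataFrame(payload["species"])
        tr = payload["traits"]
        traits = pd.DataFrame(
            {k: v for k, v in tr.items() if k != "species_id"},
            index=pd.Index(tr["species_id"], name="species_id"),
        )
        rows = [
            (int(sid), int(p))
            for sid, pix in payload["ranges"].items()
            for p in pix
        ]
        ranges = pd.DataFrame(rows, columns=["species_id", "pixel_id"])
        return cls(species=species, traits=traits, ranges=ranges)


def _grow_range(start: int, allowed: np.ndarray, target: int, nx: int, ny: int,
                rng) -> np.ndarray:
    """Grow a contiguous pixel set by randomized breadth-first search on the
    4-neighbour lattice, restricted to ``allowed`` pixel ids."""
    allowed_set = set(int(a) for a in allowed)
    visited = {start}
    frontier = [start]
    out = [start]
    while frontier and len(out) < target:
        nxt = []
        rng.shuffle(frontier)
        for pid in frontier:
            i, j = divmod(pid, ny)
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                if 0 <= ii < nx and 0 <= jj < ny:
                    q = ii * ny + jj
                    if q in allowed_set and q not in visited:
                        visited.add(q)
                        nxt.append(q)
                        out.append(q)
                        if len(out) >= target:
                            return np.array(sorted(out))
        frontier = nxt
    return np.array(sorted(out))


def make_species_pool(landscape: Landscape, config: SpeciesConfig, seed: int) -> SpeciesPool:
    """Generate a species pool with contiguous ranges and configured traits.

    A ``endemic_fraction`` share of species is confined to one region
    (sampled uniformly); the rest may range over the whole landscape.
    Elevational niches are centred near the elevations available within the
    range so that species are not trivially clipped out of their own range.
    """
    config.validate()
    if landscape.n_pixels == 0:
        raise ConfigError("landscape has no pixels")
    rng = rng_for(check_seed(seed), "species")
    px = landscape.pixels
    s = landscape.pixel_size_km
    nx = int(round(landscape.extent_km[0] / s))
    ny = int(round(landscape.extent_km[1] / s))
    region_of = px.set_index("pixel_id")["region_id"]
    elev_of = px.set_index("pixel_id")["elevation_m"]
    region_ids = landscape.regions

    n = config.n_species
    endemic = rng.random(n) < config.endemic_fraction
    home_region = rng.choice(region_ids, size=n)

    range_rows = []
    elev_min = np.empty(n)
    elev_max = np.empty(n)
    for sp in range(n):
        if endemic[sp]:
            allowed = px.loc[px["region_id"] == home_region[sp], "pixel_id"].to_numpy()
        else:
            allowed = px["pixel_id"].to_numpy()
        target = max(
            1,
            int(
                len(allowed)
                * config.range_size_mean_frac
                * rng.lognormal(0.0, config.range_size_sd_log)
            ),
        )
        target = min(target, len(allowed))
        start = int(rng.choice(allowed))
        pix = _grow_range(start, allowed, target, nx, ny, rng)
        range_rows.append(pd.DataFrame({"species_id": sp, "pixel_id": pix}))
        # elevational niche anchored to elevations inside the range
        evals = elev_of.loc[pix].to_numpy()
        centre = float(rng.uniform(evals.min(), evals.max())) if len(evals) > 1 else float(evals[0])
        breadth = config.elev_breadth_mean_m * rng.lognormal(0.0, config.elev_breadth_sd_log)
        if rng.random() < config.lowland_fraction:
            elev_min[sp] = 0.0
            elev_max[sp] = max(centre + breadth / 2, 100.0)
        else:
            elev_min[sp] = max(centre - breadth / 2, 50.0)
            elev_max[sp] = elev_min[sp] + max(breadth, 100.0)

    ranges = pd.concat(range_rows, ignore_index=True)
    family = rng.integers(0, config.n_families, size=n)

    trait_cols = {}
    for t in config.traits:
        if t.kind == "binary":
            trait_cols[t.name] = np.where(rng.random(n) < t.p, 1.0, -1.0)
        elif t.kind == "continuous":
            trait_cols[t.name] = rng.normal(t.mean, t.sd, size=n)
        else:
            raise ConfigError(f"unknown trait kind {t.kind!r} for trait {t.name!r}")
    traits = pd.DataFrame(trait_cols, index=pd.Index(np.arange(n), name="species_id"))

    migrant = rng.random(n) < config.migrant_fraction
    start = rng.integers(1, 366 - config.season_length_days, size=n)
    species = pd.DataFrame(
        {
            "species_id": np.arange(n),
            "family_id": family.astype(int),
            "elev_min_m": elev_min,
            "elev_max_m": elev_max,
            "resident": ~migrant,
            "season_start": np.where(migrant, start, np.nan),
            "season_end": np.where(migrant, start + config.season_length_days, np.nan),
        }
    )
    return SpeciesPool(species=species, traits=traits, ranges=ranges)


# ---------------------------------------------------------------------------
# Sampling design
# ---------------------------------------------------------------------------

@dataclass
class DesignConfig:
    """Clustered, paired forest/pasture point-count design.

    Clusters come in forest/pasture pairs matched for elevation
    (< ``pair_max_elev_m`` difference) and proximity (< ``pair_max_km``).
    Each cluster holds ``points_per_cluster`` points spaced at least
    ``min_point_spacing_km`` apart; each point receives ``n_visits``
    ten-minute visits by one of ``n_observers`` observers.
    """

    n_cluster_pairs: int = 40
    points_per_cluster: int = 3
    n_visits: int = 4
    n_observers: int = 3
    min_point_spacing_km: float = 0.2
    pair_max_km: float = 21.0
    pair_max_elev_m: float = 200.0
    visit_minutes: float = 10.0
    max_time_after_sunrise_h: float = 5.0

    def validate(self) -> None:
        if self.n_cluster_pairs < 1:
            raise ConfigError("n_cluster_pairs must be >= 1")
        if not 2 <= self.points_per_cluster <= 3:
            raise ConfigError("points_per_cluster must be 2 or 3")
        if not 1 <= self.n_visits <= 4:
            raise ConfigError("n_visits must be in 1..4")
        if self.n_observers < 1:
            raise ConfigError("n_observers must be >= 1")


@dataclass
class SamplingDesign:
    """Tables of clusters, points and visits."""

    clusters: pd.DataFrame  # cluster_id, x_km, y_km, region_id, subregion_id, land_use
    points: pd.DataFrame    # point_id, cluster_id, x_km, y_km, elevation_m, land_use
    visits: pd.DataFrame    # point_id, visit_index, observer_id, time_after_sunrise_h, date

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_visits_total(self) -> int:
        return len(self.visits)

    def to_csv(self, points_path, visits_path, clusters_path=None) -> None:
        self.points.to_csv(points_path, index=False)
        self.visits.to_csv(visits_path, index=False)
        if clusters_path is not None:
            self.clusters.to_csv(clusters_path, index=False)


def total_survey_minutes(n_visits: int, minutes_per_visit: float = 10.0) -> float:
    """Total field-observation minutes for a count of point visits."""
    if n_visits < 0:
        raise ValueError("n_visits must be non-negative")
    return float(n_visits) * float(minutes_per_visit)


def subregion_ids(x_km, y_km, scale_km: float = 20.0) -> np.ndarray:
    """Axis-aligned square subregion ids at the given grid scale.

    Points are grouped into subregions by gridding their coordinates at the
    20-km scale (default); used for the spatial random effect.
    """
    gx = np.floor(np.asarray(x_km, dtype=float) / scale_km).astype(int)
    gy = np.floor(np.asarray(y_km, dtype=float) / scale_km).astype(int)
    # pair the two grid indices into a single id
    return gx * 100003 + gy


def _place_points(cx, cy, cfg: DesignConfig, rng, extent):
    """Points on a small ring around the cluster centre, >= 0.2 km apart."""
    r = max(cfg.min_point_spacing_km, 0.25)
    k = cfg.points_per_cluster
    phase = rng.uniform(0, 2 * np.pi)
    ang = phase + np.arange(k) * (2 * np.pi / k)
    x = np.clip(cx + r * np.cos(ang), 0.01, extent[0] - 0.01)
    y = np.clip(cy + r * np.sin(ang), 0.01, extent[1] - 0.01)
    return x, y


def make_sampling_design(landscape: Landscape, config: DesignConfig, seed: int) -> SamplingDesign:
    """Place paired forest/pasture clusters and schedule visits.

    Pasture partners are drawn from pixels within the pairing constraints of
    the forest cluster; when no pixel qualifies the nearest-in-elevation
    pixel within the distance bound is used.
    """
    config.validate()
    rng = rng_for(check_seed(seed), "design")
    px = landscape.pixels
    extent = landscape.extent_km

    cluster_rows = []
    point_rows = []
    cid = 0
    pid = 0
    forest_idx = rng.choice(len(px), size=config.n_cluster_pairs, replace=False)
    for fi in forest_idx:
        frow = px.iloc[fi]
        dx = px["x_km"] - frow["x_km"]
        dy = px["y_km"] - frow["y_km"]
        dist = np.hypot(dx, dy)
        delev = (px["elevation_m"] - frow["elevation_m"]).abs()
        ok = (dist < config.pair_max_km) & (delev < config.pair_max_elev_m) & (dist > 0)
        if ok.any():
            cand = np.flatnonzero(ok.to_numpy())
            pi = int(rng.choice(cand))
        else:  # fall back: closest elevation within the distance bound
            near = np.flatnonzero(((dist < config.pair_max_km) & (dist > 0)).to_numpy())
            pi = int(near[np.argmin(delev.to_numpy()[near])]) if len(near) else int(fi)
        for row, lu in ((frow, "forest"), (px.iloc[pi], "pasture")):
            r0 = max(config.min_point_spacing_km, 0.25) + 0.02
            cxj = float(np.clip(row["x_km"] + rng.uniform(-0.5, 0.5), r0, extent[0] - r0))
            cyj = float(np.clip(row["y_km"] + rng.uniform(-0.5, 0.5), r0, extent[1] - r0))
            cluster_rows.append(
                (cid, cxj, cyj, int(row["region_id"]), lu)
            )
            pxs, pys = _place_points(cxj, cyj, config, rng, extent)
            for xx, yy in zip(pxs, pys):
                # point elevation from the containing pixel
                s = landscape.pixel_size_km
                ii = min(int(xx // s), int(round(extent[0] / s)) - 1)
                jj = min(int(yy // s), int(round(extent[1] / s)) - 1)
                ny = int(round(extent[1] / s))
                elev = px.iloc[ii * ny + jj]["elevation_m"]
                point_rows.append((pid, cid, xx, yy, float(elev), lu))
                pid += 1
            cid += 1

    clusters = pd.DataFrame(
        cluster_rows, columns=["cluster_id", "x_km", "y_km", "region_id", "land_use"]
    )
    clusters["subregion_id"] = subregion_ids(clusters["x_km"], clusters["y_km"])
    points = pd.DataFrame(
        point_rows,
        columns=["point_id", "cluster_id", "x_km", "y_km", "elevation_m", "land_use"],
    )

    visit_rows = []
    base_date = 0
    for _, prow in points.iterrows():
        obs = int(rng.integers(0, config.n_observers))
        for v in range(1, config.n_visits + 1):
            visit_rows.append(
                (
                    int(prow["point_id"]),
                    v,
                    obs,
                    float(rng.uniform(0, config.max_time_after_sunrise_h)),
                    base_date + v,
                )
            )
    visits = pd.DataFrame(
        visit_rows,
        columns=["point_id", "visit_index", "observer_id", "time_after_sunrise_h", "date"],
    )
    return SamplingDesign(clusters=clusters, points=points, visits=visits)
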
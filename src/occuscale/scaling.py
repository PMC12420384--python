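"""Hexagon-grid scaling: beta-diversity versus excess regional loss.

The study area is tiled with regular hexagonal cells over a ladder of
nominal areas; each grid is randomly offset and rotated so no particular
alignment drives the results, and only cells at least 60% inside the study
area are kept.  Per cell and posterior draw, two numbers are computed:

* **multiplicative beta-diversity** — gamma richness of the cell's species
  pool divided by the mean alpha richness of its 2-km pixels (>= 1 by
  construction);
* **excess regional loss** — the log-ratio of the cell-scale percent
  decline (of the chosen sensitivity percentile) to the mean of its
  pixels' local percent declines; zero means regional equals local loss.

An ordinary-least-squares line of excess loss on beta-diversity is fitted
separately within each posterior draw (the regression is descriptive: the
grid covers the whole domain, so within-draw standard errors are not of
interest); uncertainty bands come from the spread of fitted lines across
draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
import shapely
from shapely.geometry import Polygon, box
from shapely import affinity

from ._util import check_seed, rng_for, spawn_seed
from .simulate import Landscape
from .sensitivity import (
    DEFAULT_TAU,
    decline_pct,
    species_pool_mask,
    species_sensitivity,
)

__all__ = [
    "DEFAULT_AREA_LADDER_KM2",
    "HexGrid",
    "make_hex_grid",
    "multiplicative_beta",
    "excess_regional_loss",
    "cell_records",
    "fit_scaling_regression",
    "regression_band",
    "plot_scaling",
    "scaling_analysis",
]

logger = logging.getLogger(__name__)

#: Nominal hexagon areas (km^2): six log-spaced regional scales.
DEFAULT_AREA_LADDER_KM2 = (290.0, 860.0, 2600.0, 7800.0, 23000.0, 70000.0)
MIN_OVERLAP = 0.6


@dataclass
class HexGrid:
    """One randomized hexagonal tiling clipped to the study area."""

    area_km2: float
    offset: tuple[float, float]
    rotation_deg: float
    cells: pd.DataFrame  # cell_id, polygon (shapely), overlap
    members: dict = field(default_factory=dict)  # cell_id -> np.ndarray of pixel ids

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_geojson_dict(self) -> dict:
        feats = []
        for _, row in self.cells.iterrows():
            feats.append(
                {
                    "type": "Feature",
                    "properties": {
                        "cell_id": int(row["cell_id"]),
                        "overlap": float(row["overlap"]),
                        "n_pixels": int(len(self.members[row["cell_id"]])),
                    },
                    "geometry": shapely.geometry.mapping(row["polygon"]),
                }
            )
        return {
            "type": "FeatureCollection",
            "properties": {
                "area_km2": self.area_km2,
                "rotation_deg": self.rotation_deg,
                "offset": list(self.offset),
            },
            "features": feats,
        }


def _hexagon(cx: float, cy: float, side: float) -> Polygon:
    ang = np.deg2rad(np.arange(6) * 60.0)
    return Polygon(np.column_stack([cx + side * np.cos(ang), cy + side * np.sin(ang)]))


def make_hex_grid(
    landscape: Landscape,
    area_km2: float,
    seed: int,
    min_overlap: float = MIN_OVERLAP,
    rotation_deg: float | None = None,
    offset: tuple[float, float] | None = None,
) -> HexGrid:
    """Tile the study area with hexagons of the given nominal area.

    The tiling is uniformly randomly offset (within one lattice cell) and
    rotated (within the 60-degree symmetry group) unless explicit values
    are given.  Pixels are assigned to the cell containing their centre, so
    cells of one grid never share pixels.  Cells overlapping the study
    rectangle by less than ``min_overlap`` are dropped; a grid whose cells
    are all dropped (area much larger than the study region) is returned
    empty and flagged in the log.
    """
    if area_km2 <= 0:
        raise ValueError("area_km2 must be positive")
    rng = rng_for(check_seed(seed), f"hexgrid-{area_km2}")
    side = np.sqrt(2.0 * area_km2 / (3.0 * np.sqrt(3.0)))
    w, h = landscape.extent_km
    cx0, cy0 = w / 2.0, h / 2.0
    rot = rng.uniform(0.0, 60.0) if rotation_deg is None else float(rotation_deg)
    # lattice pitch: flat-top hexagons at (1.5*s) x (sqrt(3)*s)
    dx, dy = 1.5 * side, np.sqrt(3.0) * side
    off = (
        (rng.uniform(0, dx), rng.uniform(0, dy)) if offset is None else tuple(map(float, offset))
    )

    # generate lattice covering the bounding circle of the extent
    radius = np.hypot(w, h) / 2.0 + 2.0 * side
    ni = int(np.ceil(radius / dx)) + 1
    nj = int(np.ceil(radius / dy)) + 1
    study = box(0.0, 0.0, w, h)
    theta = np.deg2rad(rot)
    ct, st = np.cos(theta), np.sin(theta)

    px = landscape.pixels
    pxx = px["x_km"].to_numpy()
    pxy = px["y_km"].to_numpy()
    # pixel coordinates in the (unrotated) grid frame
    gx = ct * (pxx - cx0) + st * (pxy - cy0) + cx0 - off[0]
    gy = -st * (pxx - cx0) + ct * (pxy - cy0) + cy0 - off[1]

    cells = []
    members = {}
    cid = 0
    for i in range(-ni, ni + 1):
        for j in range(-nj, nj + 1):
            hx = cx0 + i * dx
            hy = cy0 + (j + 0.5 * (i % 2)) * dy
            hex_grid_frame = _hexagon(hx, hy, side)
            # world frame: shift by offset then rotate about the extent centre
            poly = affinity.rotate(
                affinity.translate(hex_grid_frame, off[0], off[1]),
                rot,
                origin=(cx0, cy0),
            )
            if not poly.intersects(study):
                continue
            overlap = poly.intersection(study).area / poly.area
            if overlap < min_overlap:
                continue
            inside = shapely.contains_xy(hex_grid_frame, gx, gy)
            members[cid] = px["pixel_id"].to_numpy()[inside]
            cells.append((cid, poly, overlap))
            cid += 1
    if not cells:
        logger.warning(
            "hex grid at %.0f km^2 has no cells with overlap >= %.0f%%",
            area_km2,
            100 * min_overlap,
        )
        cells_df = pd.DataFrame(columns=["cell_id", "polygon", "overlap"])
    else:
        cells_df = pd.DataFrame(cells, columns=["cell_id", "polygon", "overlap"])
    return HexGrid(
        area_km2=float(area_km2),
        offset=off,
        rotation_deg=rot,
        cells=cells_df,
        members=members,
    )


def multiplicative_beta(
    cube: xr.DataArray, pixel_ids, tau: float = DEFAULT_TAU
) -> np.ndarray:
    """Gamma richness over mean pixel alpha richness, per draw.

    Gamma is the size of the cell-scope species pool (threshold tau);
    alpha_i the size of pixel i's local pool.  Cells whose mean alpha is
    zero yield NaN (skipped downstream with a warning).
    """
    pixel_ids = np.asarray(pixel_ids)
    if len(pixel_ids) == 0:
        raise ValueError("cell has no member pixels")
    sub = cube.sel(pixel=pixel_ids)
    gamma = species_pool_mask(sub, tau=tau).sum("species").values.astype(float)
    alpha = (sub.max("scenario") >= tau).sum("species").values.astype(float)  # (pixel, draw)
    alpha = np.atleast_2d(alpha)
    mean_alpha = alpha.mean(axis=0)
    out = np.where(mean_alpha > 0, gamma / np.where(mean_alpha > 0, mean_alpha, 1.0), np.nan)
    n_bad = int(np.isnan(out).sum())
    if n_bad:
        logger.warning("%d draws had zero mean alpha-richness in a cell", n_bad)
    return out


def _local_losses(sub: xr.DataArray, tau: float, q: float) -> np.ndarray:
    """Mean over member pixels of the local (single-pixel) percent decline."""
    f = sub.sel(scenario="forest").values  # (species, pixel, draw)
    p = sub.sel(scenario="pasture").values
    pool = np.maximum(f, p) >= tau  # local pool per pixel
    zero = 1e-9
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(p > zero, f / np.where(p > zero, p, 1.0), np.inf)
    n_px, n_dr = f.shape[1], f.shape[2]
    loss = np.full((n_px, n_dr), np.nan)
    for i in range(n_px):
        for d in range(n_dr):
            m = pool[:, i, d] & np.isfinite(s[:, i, d])
            if m.any():
                loss[i, d] = decline_pct(np.quantile(s[m, i, d], q))
    return np.nanmean(loss, axis=0)


def excess_regional_loss(
    cube: xr.DataArray,
    pixel_ids,
    tau: float = DEFAULT_TAU,
    q: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-ratio of cell-scale to mean local-scale percent decline, per draw.

    The cell-scale loss uses sensitivities summed over the cell's pixels
    and the cell's species pool; the local scale averages each member
    pixel's own percent decline.  Returns (excess, n_excluded_flags) where
    non-positive losses at either scale give NaN for that draw.
    """
    pixel_ids = np.asarray(pixel_ids)
    sub = cube.sel(pixel=pixel_ids)
    sens = species_sensitivity(sub)  # cell-scope S
    pool = species_pool_mask(sub, tau=tau)
    s = sens.transpose("species", "draw").values
    m = pool.transpose("species", "draw").values & np.isfinite(s)
    n_dr = s.shape[1]
    reg = np.full(n_dr, np.nan)
    for d in range(n_dr):
        if m[:, d].any():
            reg[d] = decline_pct(np.quantile(s[m[:, d], d], q))
    loc = _local_losses(sub, tau, q)
    with np.errstate(invalid="ignore", divide="ignore"):
        ok = (reg > 0) & (loc > 0)
        excess = np.where(ok, np.log(np.where(ok, reg, 1.0) / np.where(ok, loc, 1.0)), np.nan)
    return excess, ~ok


def cell_records(
    cube: xr.DataArray,
    grid: HexGrid,
    tau: float = DEFAULT_TAU,
    q: float = 0.5,
    draws=None,
) -> pd.DataFrame:
    """Per (cell, draw) records of beta-diversity and excess loss."""
    rows = []
    for cid, pix in grid.members.items():
        if len(pix) == 0:
            continue
        pix = np.asarray([p for p in pix if p in cube.indexes["pixel"]])
        if len(pix) == 0:
            continue
        sub_draws = np.asarray(cube["draw"]) if draws is None else np.asarray(draws)
        c = cube.sel(draw=sub_draws)
        beta = multiplicative_beta(c, pix, tau)
        excess, excluded = excess_regional_loss(c, pix, tau, q)
        for d, (b, e, x) in enumerate(zip(beta, excess, excluded)):
            rows.append((grid.area_km2, cid, sub_draws[d], b, e, bool(x), len(pix)))
    return pd.DataFrame(
        rows,
        columns=["area_km2", "cell_id", "draw", "beta", "excess", "excluded", "n_pixels"],
    )


def fit_scaling_regression(records: pd.DataFrame, min_cells: int = 3) -> pd.DataFrame:
    """Closed-form OLS of excess loss on beta-diversity, per draw.

    Draws with fewer than ``min_cells`` valid cells are skipped.  Returns
    (draw, slope, intercept, n_cells).
    """
    rows = []
    for d, grp in records.dropna(subset=["beta", "excess"]).groupby("draw"):
        if len(grp) < min_cells:
            logger.warning("draw %s skipped: only %d cells", d, len(grp))
            continue
        x = grp["beta"].to_numpy()
        y = grp["excess"].to_numpy()
        xm, ym = x.mean(), y.mean()
        sxx = np.sum((x - xm) ** 2)
        if sxx == 0:
            continue
        slope = np.sum((x - xm) * (y - ym)) / sxx
        rows.append((d, slope, ym - slope * xm, len(grp)))
    return pd.DataFrame(rows, columns=["draw", "slope", "intercept", "n_cells"])


def regression_band(fits: pd.DataFrame, x_grid, ci: float = 0.9) -> pd.DataFrame:
    """Pointwise CI of the fitted lines across draws."""
    x = np.asarray(x_grid, dtype=float)
    lines = fits["intercept"].to_numpy()[:, None] + fits["slope"].to_numpy()[:, None] * x[None, :]
    a = (1 - ci) / 2
    return pd.DataFrame(
        {
            "beta": x,
            "mean": lines.mean(axis=0),
            "lo": np.quantile(lines, a, axis=0),
            "hi": np.quantile(lines, 1 - a, axis=0),
        }
    )


def plot_scaling(records: pd.DataFrame, fits: pd.DataFrame, ax=None, ci: float = 0.9):
    """Cell records with the posterior band of the beta-excess line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ok = records.dropna(subset=["beta", "excess"])
    ax.scatter(ok["beta"], ok["excess"], s=6, alpha=0.3)
    if len(fits):
        grid = np.linspace(ok["beta"].min(), ok["beta"].max(), 50)
        band = regression_band(fits, grid, ci=ci)
        ax.fill_between(band["beta"], band["lo"], band["hi"], alpha=0.25, color="grey")
        ax.plot(band["beta"], band["mean"], color="black")
    ax.set_xlabel("multiplicative beta-diversity")
    ax.set_ylabel("log excess regional loss")
    return ax


def scaling_analysis(
    cube: xr.DataArray,
    landscape: Landscape,
    areas=DEFAULT_AREA_LADDER_KM2,
    tau: float = DEFAULT_TAU,
    q: float = 0.5,
    seed: int = 0,
    regrid_per_draw: bool = True,
) -> dict:
    """Full hexagon-scale analysis over an area ladder.

    With ``regrid_per_draw`` a fresh randomized grid is drawn for every
    posterior draw (one grid shared by all draws otherwise).  Returns
    ``{area: {"records": ..., "fits": ...}}``.
    """
    seed = check_seed(seed)
    out = {}
    draws = np.asarray(cube["draw"])
    for area in areas:
        recs = []
        if regrid_per_draw:
            for d in draws:
                grid = make_hex_grid(landscape, area, spawn_seed(seed, f"grid-{area}-{d}"))
                if grid.n_cells == 0:
                    continue
                recs.append(cell_records(cube, grid, tau, q, draws=[d]))
        else:
            grid = make_hex_grid(landscape, area, spawn_seed(seed, f"grid-{area}"))
            if grid.n_cells:
                recs.append(cell_records(cube, grid, tau, q))
        records = (
            pd.concat(recs, ignore_index=True)
            if recs
            else pd.DataFrame(
                columns=["area_km2", "cell_id", "draw", "beta", "excess", "excluded", "n_pixels"]
            )
        )
        out[area] = {"records": records, "fits": fit_scaling_regression(records)}
    return out
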
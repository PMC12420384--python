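"""Species sensitivity, thresholded species pools and multi-region pooling.

A species' **sensitivity** to habitat conversion over a set of pixels is
the ratio of its summed occupancy were every pixel forested to its summed
occupancy were every pixel pasture: S > 1 means the species loses from
conversion.  A scope's **species pool** at threshold tau is every species
whose occupancy reaches tau on at least one of the scope's pixels (in
either scenario).  Community response is summarized by the 25th, 50th and
75th percentiles of S over the pool, convertible to a percent decline
``100 * (1 - 1/Q)``.

The multi-region analysis asks how the community metric changes as
biogeographic regions are pooled: random region sequences are grown one
region at a time, the species pool is the union of the pooled regions'
pools, and the metric over that pool is compared with the metric over the
all-region pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from ._util import check_seed, rng_for

__all__ = [
    "species_sensitivity",
    "species_pool_mask",
    "pool_sizes",
    "community_metric",
    "decline_pct",
    "regional_relative_sensitivity",
    "pooling_trajectory",
    "PoolingTrajectory",
]

logger = logging.getLogger(__name__)

DEFAULT_TAU = 0.2
QUANTILES = (0.25, 0.5, 0.75)
#: pasture occupancy totals below this are treated as zero (infinite S)
ZERO_DENOM = 1e-9


def _select_pixels(cube: xr.DataArray, pixels) -> xr.DataArray:
    return cube if pixels is None else cube.sel(pixel=pixels)


def species_sensitivity(cube: xr.DataArray, pixels=None) -> xr.DataArray:
    """Forest:pasture sensitivity ratio per species and draw over a scope.

    ``S = sum_i psi_forest / sum_i psi_pasture`` over the scope's pixels.
    Species whose pasture total is (numerically) zero get ``S = inf`` and
    are excluded from community metrics; a count is logged.
    """
    sub = _select_pixels(cube, pixels)
    f = sub.sel(scenario="forest").sum("pixel")
    p = sub.sel(scenario="pasture").sum("pixel")
    with np.errstate(divide="ignore", invalid="ignore"):
        s = xr.where(p.values > ZERO_DENOM, f / p, np.inf)
    n_inf = int(np.isinf(np.asarray(s)).sum())
    if n_inf:
        logger.warning("%d species-draw sensitivities had zero pasture totals", n_inf)
    s.name = "sensitivity"
    return s


def species_pool_mask(cube: xr.DataArray, pixels=None, tau: float = DEFAULT_TAU) -> xr.DataArray:
    """Boolean (species, draw) mask: occupancy reaches ``tau`` on at least
    one of the scope's pixels, in either scenario."""
    if not 0 < tau < 1:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    sub = _select_pixels(cube, pixels)
    return (sub.max(["pixel", "scenario"]) >= tau).rename("in_pool")


def pool_sizes(cube: xr.DataArray, pixels=None, tau: float = DEFAULT_TAU) -> xr.DataArray:
    """Species-pool size (richness) per draw for a scope."""
    return species_pool_mask(cube, pixels, tau).sum("species").rename("richness")


def decline_pct(q_value) -> np.ndarray:
    """Percent decline implied by a sensitivity quantile: 100 * (1 - 1/Q)."""
    q = np.asarray(q_value, dtype=float)
    with np.errstate(divide="ignore"):
        return 100.0 * (1.0 - 1.0 / q)


def community_metric(sens: xr.DataArray, pool: xr.DataArray, q: float) -> pd.DataFrame:
    """Quantile of sensitivity over a species pool, per draw.

    Returns a DataFrame (draw, value, decline_pct, n_pool).  Draws whose
    pool is empty (or whose pooled sensitivities are all non-finite) get
    NaN and are reported.
    """
    s = sens.transpose("species", "draw").values
    m = pool.transpose("species", "draw").values
    finite = np.isfinite(s)
    mm = m & finite
    out = np.full(s.shape[1], np.nan)
    npool = mm.sum(axis=0)
    for d in range(s.shape[1]):
        if npool[d] > 0:
            out[d] = np.quantile(s[mm[:, d], d], q)
    n_empty = int((npool == 0).sum())
    if n_empty:
        logger.warning("%d draws had an empty species pool for this scope", n_empty)
    return pd.DataFrame(
        {
            "draw": np.asarray(sens["draw"]),
            "value": out,
            "decline_pct": decline_pct(out),
            "n_pool": npool,
        }
    )


def _metric_matrix(s: np.ndarray, masks: np.ndarray, q: float) -> np.ndarray:
    """Quantile of ``s`` (n_species,) under each row of boolean ``masks``."""
    with np.errstate(invalid="ignore"):
        arr = np.where(masks, s[None, :], np.nan)
        return np.nanquantile(arr, q, axis=1)


def regional_relative_sensitivity(
    cube: xr.DataArray,
    region_of_pixel: pd.Series,
    tau: float = DEFAULT_TAU,
    q: float = 0.5,
    n_draws: int | None = 100,
) -> pd.DataFrame:
    """Each region's community metric relative to the all-region metric.

    Sensitivities are computed over the full study area (all pixels); the
    region only selects which species enter the community via its pool.
    Values below one mean the region's community is less sensitive than the
    pooled community.  Returns (region, draw, metric, metric_study, ratio).
    """
    draws = np.asarray(cube["draw"])
    if n_draws is not None and n_draws < len(draws):
        draws = draws[:n_draws]
        cube = cube.sel(draw=draws)
    sens = species_sensitivity(cube)
    study_pool = species_pool_mask(cube, tau=tau)
    s = sens.transpose("species", "draw").values
    finite = np.isfinite(s)

    region_of_pixel = region_of_pixel.reindex(np.asarray(cube["pixel"]))
    rows = []
    study_vals = np.full(len(draws), np.nan)
    mstudy = study_pool.transpose("species", "draw").values & finite
    for d in range(len(draws)):
        if mstudy[:, d].any():
            study_vals[d] = np.quantile(s[mstudy[:, d], d], q)
    for region, grp in region_of_pixel.groupby(region_of_pixel):
        rp = grp.index.to_numpy()
        rpool = species_pool_mask(cube, pixels=rp, tau=tau)
        mr = rpool.transpose("species", "draw").values & finite
        for d in range(len(draws)):
            if mr[:, d].any():
                v = np.quantile(s[mr[:, d], d], q)
                rows.append((region, draws[d], v, study_vals[d], v / study_vals[d]))
            else:
                rows.append((region, draws[d], np.nan, study_vals[d], np.nan))
                logger.warning("region %s has an empty pool in draw %s", region, d)
    return pd.DataFrame(rows, columns=["region", "draw", "metric", "metric_study", "ratio"])


@dataclass
class PoolingTrajectory:
    """Mean and 90% CI of relative sensitivity versus number of pooled regions.

    ``summary`` columns: k, mean, lo, hi, pct_more_severe (the average
    percent by which the all-region metric exceeds the k-region metric).
    ``rel`` holds the per-draw sequence-averaged relative values
    (n_draws, R).
    """

    summary: pd.DataFrame
    rel: np.ndarray
    n_sequences: int
    q: float
    tau: float

    def plot(self, ax=None):
        """Mean relative sensitivity vs number of pooled regions, with CI."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.summary
        ax.errorbar(
            s["k"], s["mean"],
            yerr=[s["mean"] - s["lo"], s["hi"] - s["mean"]],
            fmt="o-", capsize=3,
        )
        ax.axhline(1.0, ls="--", color="grey")
        ax.set_xlabel("regions pooled (k)")
        ax.set_ylabel(f"relative sensitivity (q = {self.q})")
        return ax


def pooling_trajectory(
    cube: xr.DataArray,
    region_of_pixel: pd.Series,
    tau: float = DEFAULT_TAU,
    q: float = 0.5,
    n_sequences: int = 1000,
    n_draws: int | None = 100,
    seed: int = 0,
    ci: float = 0.9,
) -> PoolingTrajectory:
    """Relative community sensitivity as regions are sequentially pooled.

    Random region sequences each start from one region and add the rest in
    random order.  For each draw, sequence and k, the species pool is the
    union of the first k regions' pools, the metric is the q-quantile of
    the study-wide sensitivities restricted to that pool, and the relative
    value is that metric divided by the all-region metric (exactly 1 at
    k = R).  Relative values are averaged over sequences, then summarized
    across draws with a mean and a 90% interval.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    regions = np.asarray(sorted(region_of_pixel.unique()))
    R = len(regions)
    if R < 2:
        raise ValueError("pooling requires at least 2 regions")
    rng = rng_for(check_seed(seed), "pooling")

    draws = np.asarray(cube["draw"])
    if n_draws is not None and n_draws < len(draws):
        cube = cube.sel(draw=draws[:n_draws])
        draws = draws[:n_draws]
    sens = species_sensitivity(cube)
    s_all = sens.transpose("species", "draw").values
    finite = np.isfinite(s_all)
    region_of_pixel = region_of_pixel.reindex(np.asarray(cube["pixel"]))

    # per-region pools (R, n_species, n_draws)
    pools = np.stack(
        [
            species_pool_mask(cube, pixels=grp.index.to_numpy(), tau=tau)
            .transpose("species", "draw")
            .values
            for _, grp in region_of_pixel.groupby(region_of_pixel)
        ]
    )
    perms = np.stack([rng.permutation(R) for _ in range(n_sequences)])

    n_species, n_dr = s_all.shape
    rel = np.empty((n_dr, R))
    excess = np.empty((n_dr, R))  # pan-vs-pooled percent difference
    chunk = max(1, int(2e7 // (R * n_species)))
    for d in range(n_dr):
        s = s_all[:, d]
        pool_d = pools[:, :, d] & finite[None, :, d]
        full_mask = pool_d.any(axis=0)
        full_metric = np.quantile(s[full_mask], q) if full_mask.any() else np.nan
        acc = np.zeros(R)
        acc_inv = np.zeros(R)
        for start in range(0, n_sequences, chunk):
            pp = perms[start : start + chunk]
            cum = np.logical_or.accumulate(pool_d[pp], axis=1)  # (chunk, R, n_species)
            vals = _metric_matrix_3d(s, cum, q)
            acc += vals.sum(axis=0)
            acc_inv += (full_metric / vals - 1.0).sum(axis=0)
        rel[d] = (acc / n_sequences) / full_metric
        excess[d] = 100.0 * acc_inv / n_sequences
        # at k = R every sequence's union is the full pool: exactly 1 / 0
        rel[d, -1] = 1.0
        excess[d, -1] = 0.0
    alpha = (1 - ci) / 2
    summary = pd.DataFrame(
        {
            "k": np.arange(1, R + 1),
            "mean": rel.mean(axis=0),
            "lo": np.quantile(rel, alpha, axis=0),
            "hi": np.quantile(rel, 1 - alpha, axis=0),
            "pct_more_severe": excess.mean(axis=0),
        }
    )
    return PoolingTrajectory(summary=summary, rel=rel, n_sequences=n_sequences, q=q, tau=tau)


def _metric_matrix_3d(s: np.ndarray, masks: np.ndarray, q: float) -> np.ndarray:
    """Quantile of ``s`` under each mask of a (n_seq, R, n_species) stack."""
    with np.errstate(invalid="ignore", all="ignore"):
        arr = np.where(masks, s[None, None, :], np.nan)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanquantile(arr, q, axis=2)
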
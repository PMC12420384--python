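"""Shared fixtures: one small simulated study reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import occuscale as oc
from occuscale.occupancy import OccupancyModel

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def landscape():
    return oc.make_landscape(oc.LandscapeConfig(), seed=101)


@pytest.fixture(scope="session")
def pool(landscape):
    return oc.make_species_pool(landscape, oc.SpeciesConfig(n_species=30), seed=101)


@pytest.fixture(scope="session")
def design(landscape):
    return oc.make_sampling_design(landscape, oc.DesignConfig(n_cluster_pairs=10), seed=101)


@pytest.fixture(scope="session")
def truth(landscape, pool, design):
    return oc.simulate_truth(landscape, pool, design, oc.OccupancyParams.default(), seed=102)


@pytest.fixture(scope="session")
def detections(truth, design):
    return oc.simulate_detections(truth, design, oc.DetectionParams.default(), seed=103)


@pytest.fixture(scope="session")
def fitted(detections, truth, pool, design):
    """A small reduced-spec fit with Laplace draws, reused by several tests."""
    model = OccupancyModel.from_tables(
        detections, truth.features, pool, design, spec=oc.ModelSpec.reduced()
    )
    return model.fit(method="laplace", n_draws=120, seed=104)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_cube(rng, n_species=15, n_pixels=40, n_draws=4, pixels=None):
    """Uniform-random occupancy cube for brute-force oracle tests."""
    f = rng.uniform(0, 1, (n_species, n_pixels, n_draws))
    p = rng.uniform(0, 1, (n_species, n_pixels, n_draws))
    return oc.make_cube(f, p, pixels=pixels)


def homogenization_cube(n_pixels, per_pixel=2, n_shared=24, draws=20, noise=0.01, seed=0):
    """Pixel-disjoint forest endemics over a globally shared pasture pool.

    The shared (pasture-tolerant) species decline mildly with a graded
    spread of sensitivities; every pixel additionally hosts its own highly
    sensitive forest endemics.  Pooling pixels therefore raises both
    beta-diversity and the regional loss percentile together — the
    homogenization signature.
    """
    rng = np.random.default_rng(seed)
    n_sp = n_shared + n_pixels * per_pixel
    f = np.zeros((n_sp, n_pixels, draws))
    p = np.zeros((n_sp, n_pixels, draws))
    s_base = np.linspace(1.1, 2.0, n_shared)
    p[:n_shared] = 0.45
    f[:n_shared] = 0.45 * s_base[:, None, None]
    for i in range(n_pixels):
        sl = slice(n_shared + i * per_pixel, n_shared + (i + 1) * per_pixel)
        f[sl, i] = 0.8
        p[sl, i] = 0.05
    f += rng.normal(0, noise, f.shape)
    p += rng.normal(0, noise, p.shape)
    return oc.make_cube(np.clip(f, 0.01, 0.99), np.clip(p, 0.01, 0.99))
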
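"""Shared fixtures: toy stores with hand-checkable numbers and seeded
mid-sized simulations reused across test modules (session-scoped, since
simulation is the expensive part)."""

import numpy as np
import pytest

import cuedchoice as cc


@pytest.fixture(scope="session")
def toy_store() -> cc.SimilarityStore:
    """Four products with distinct, hand-readable similarity matrices."""
    catalog = ("A", "B", "C", "D")
    epi = np.array(
        [
            [1.0, 0.5, 0.25, 0.0],
            [0.5, 1.0, 0.25, 0.0],
            [0.25, 0.25, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    sem = np.array(
        [
            [1.0, 0.2, 0.1, 0.4],
            [0.2, 1.0, 0.3, 0.0],
            [0.1, 0.3, 1.0, 0.6],
            [0.4, 0.0, 0.6, 1.0],
        ]
    )
    hier = np.array(
        [
            [1.0, 0.8, 0.4, 0.0],
            [0.8, 1.0, 0.4, 0.0],
            [0.4, 0.4, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    return cc.SimilarityStore(
        catalog=catalog,
        matrices={"episodic": epi, "semantic": sem, "hierarchy": hier},
    )


@pytest.fixture(scope="session")
def small_config() -> cc.SimulationConfig:
    return cc.SimulationConfig(
        catalog_size=100,
        branching=(3, 3, 3, 2, 2),
        n_baskets=800,
        n_goals=120,
        n_recipes=20,
        goal_size=5,
        theme_size=4,
        embedding_dimension=40,
        n_shoppers=60,
        trip_length=(12, 25),
        seed=1234,
    )


@pytest.fixture(scope="session")
def small_sim(small_config) -> "cc.synthetic.SimulationResult":
    """A modest end-to-end simulation shared by analysis tests."""
    return cc.simulate(small_config)


def make_trips(store, betas, n_shoppers, trip_length, seed, **kwargs):
    """Trips from an existing store with pinned per-shopper weights."""
    betas = np.asarray(betas, dtype=float)
    if betas.ndim == 1:
        betas = np.tile(betas, (n_shoppers, 1))
    cfg = cc.SimulationConfig(
        catalog_size=len(store.catalog),
        n_shoppers=n_shoppers,
        trip_length=trip_length,
        true_betas=betas,
        seed=seed,
        **kwargs,
    )
    return cc.generate_trips(store, cfg)


@pytest.fixture(scope="session")
def null_trips(small_sim):
    """Trips with all attention weights zero: uniform random order."""
    trips, _ = make_trips(
        small_sim.store, [0.0, 0.0, 0.0], n_shoppers=200, trip_length=30, seed=77
    )
    return trips


@pytest.fixture(scope="session")
def hier_trips(small_sim):
    """Trips driven purely by hierarchical similarity (beta_hierarchy=10)."""
    trips, _ = make_trips(
        small_sim.store, [0.0, 0.0, 10.0], n_shoppers=120, trip_length=15, seed=78
    )
    return trips
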
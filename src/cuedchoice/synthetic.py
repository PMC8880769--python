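"""Synthetic taxonomies, basket corpora, and model-sampled shopping trips.

Every stage of the pipeline can be exercised against ground truth:

* :func:`generate_taxonomy` builds a random fixed-depth product hierarchy;
* :func:`generate_goals` / :func:`generate_baskets` plant goal-driven
  co-occurrence structure that is deliberately *not* reducible to the
  taxonomy (a configurable fraction of each goal's products comes from
  other branches — think chili peppers cueing coconut milk), so the
  episodic, semantic, and hierarchical representations stay separable;
* :func:`generate_trips` samples ordered choice sequences from the
  retrieval rule itself with known per-shopper attention weights, adds
  inter-response intervals from a linear model with Gaussian noise, and
  draws forgotten/removed error counts from Poisson laws whose log-means
  depend on the standardised true weights.

All randomness flows through ``numpy.random.default_rng`` seeded from the
configuration, so a fixed seed reproduces corpora and trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    NAV_METHODS,
    REPRESENTATIONS,
    BasketCorpus,
    InvalidConfigError,
    SimilarityStore,
    Taxonomy,
    TripLog,
)
from .retrieval import _log_strength, _stacked

__all__ = [
    "GoalLibrary",
    "IriParams",
    "ErrorLink",
    "SimulationConfig",
    "SimulationResult",
    "generate_taxonomy",
    "generate_goals",
    "generate_baskets",
    "generate_trips",
    "simulate",
]

#: Empirical navigation-method shares for simulated choices, proportional
#: to mean per-trip usage of search bar, category menu, special offers,
#: and the pre-checkout reminder in large online grocery datasets.
NAV_SHARES = {
    "search": 23.36,
    "category": 3.02,
    "offers": 1.55,
    "forgotten_rec": 0.322,
}


def generate_taxonomy(
    branching: Sequence[int] = (3, 3, 3, 3, 3),
    catalog_size: int = 300,
    seed: int = 0,
) -> Taxonomy:
    """Random product taxonomy with the given per-level branching factors.

    The tree has ``prod(branching)`` leaves. Products are spread over the
    leaves as evenly as possible (a random permutation of leaves is
    filled round-robin), so ``catalog_size`` may exceed or undershoot the
    leaf count; some leaves hold several products, some may be empty.
    """
    branching = tuple(int(b) for b in branching)
    if not branching or any(b < 1 for b in branching):
        raise InvalidConfigError("branching factors must all be positive")
    if catalog_size < 1:
        raise InvalidConfigError("catalog_size must be positive")
    rng = np.random.default_rng(seed)
    depth = len(branching)
    # enumerate leaf paths; node ids encode ancestry ("g2", "g2.0", ...)
    leaves: list[tuple[str, ...]] = [()]
    for b in branching:
        leaves = [path + (i,) for path in leaves for i in range(b)]
    leaf_paths = [
        tuple("g" + ".".join(str(c) for c in path[: l + 1]) for l in range(depth))
        for path in leaves
    ]
    order = rng.permutation(len(leaf_paths))
    width = len(str(catalog_size - 1))
    paths = {
        f"P{i:0{width}d}": leaf_paths[order[i % len(leaf_paths)]]
        for i in range(catalog_size)
    }
    return Taxonomy(depth=depth, paths=paths)


@dataclass(frozen=True)
class GoalLibrary:
    """Latent shopping goals: weighted product sets that co-occur in baskets."""

    goals: tuple[frozenset[str], ...]
    weights: np.ndarray
    cross_category_rate: float = 0.0

    def __post_init__(self) -> None:
        if len(self.goals) == 0:
            raise InvalidConfigError("goal library is empty")
        if any(len(g) < 2 for g in self.goals):
            raise InvalidConfigError("every goal needs at least 2 products")
        w = np.asarray(self.weights, dtype=float)
        if len(w) != len(self.goals) or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise InvalidConfigError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "weights", w)


def generate_goals(
    taxonomy: Taxonomy,
    n_goals: int = 240,
    goal_size: int = 6,
    cross_category_rate: float = 0.5,
    theme_size: int = 5,
    n_recipes: int = 30,
    seed: int = 0,
) -> GoalLibrary:
    """Sample latent goals with substitute *and* complement structure.

    The catalog is first partitioned into **themes** — small sets of
    substitutable products (different brands of the same thing). Themes
    are carved out of taxonomy branches, then a ``cross_category_rate``
    fraction of products is swapped between themes so that neither theme
    membership nor basket co-occurrence reduces to the taxonomy.

    **Recipes** are combinations of ``goal_size`` distinct themes —
    products that go together (a curry recipe pairs a pepper theme with a
    coconut-milk theme). Each of the ``n_goals`` returned goals
    instantiates a recipe by picking one concrete product per theme.

    The distinction matters for separability: products in the same theme
    share basket *contexts* without co-occurring (semantic overlap,
    recovered by the embedding), while products in the same recipe
    co-occur directly (episodic association). Cross-category swaps keep
    both distinct from hierarchical similarity.
    """
    if n_goals < 1 or goal_size < 2:
        raise InvalidConfigError("need n_goals >= 1 and goal_size >= 2")
    if theme_size < 1 or n_recipes < 1:
        raise InvalidConfigError("theme_size and n_recipes must be positive")
    rng = np.random.default_rng(seed)
    catalog = list(taxonomy.catalog)
    # order products by their full taxonomy path so consecutive chunks sit
    # in the same branch, then chunk into themes
    by_path = sorted(catalog, key=lambda p: taxonomy.paths[p])
    themes = [by_path[i : i + theme_size] for i in range(0, len(by_path), theme_size)]
    themes = [t for t in themes if t]
    # cross-category swaps: exchange members between random theme pairs
    n_swaps = int(round(cross_category_rate * len(catalog) / 2))
    for _ in range(n_swaps):
        a, b = rng.integers(len(themes)), rng.integers(len(themes))
        if a == b:
            continue
        ia, ib = rng.integers(len(themes[a])), rng.integers(len(themes[b]))
        themes[a][ia], themes[b][ib] = themes[b][ib], themes[a][ia]
    usable = [t for t in themes if len(t) >= 1]
    k = min(goal_size, len(usable))
    recipes = [
        rng.choice(len(usable), size=k, replace=False) for _ in range(n_recipes)
    ]
    goals = []
    for g in range(n_goals):
        recipe = recipes[g % n_recipes]
        members = {usable[t][rng.integers(len(usable[t]))] for t in recipe}
        while len(members) < 2:  # degenerate tiny catalogs
            members.add(catalog[rng.integers(len(catalog))])
        goals.append(frozenset(members))
    weights = np.full(len(goals), 1.0 / len(goals))
    return GoalLibrary(
        goals=tuple(goals), weights=weights, cross_category_rate=cross_category_rate
    )


def generate_baskets(
    taxonomy: Taxonomy,
    goals: GoalLibrary,
    n_baskets: int = 2000,
    goals_per_basket: int | tuple[int, int] = (1, 2),
    noise_rate: float = 0.1,
    seed: int = 0,
) -> BasketCorpus:
    """Unordered baskets as unions of sampled goals plus noise products.

    ``goals_per_basket`` is either a fixed count or an inclusive
    ``(low, high)`` range sampled uniformly per basket. ``noise_rate``
    adds that fraction (of the goal-driven basket size, rounded) of
    uniformly random catalog products so co-occurrence is not
    block-exact.
    """
    if n_baskets < 1:
        raise InvalidConfigError("n_baskets must be positive")
    catalog = list(taxonomy.catalog)
    known = set(catalog)
    for g in goals.goals:
        if not g <= known:
            raise InvalidConfigError("goal contains products outside the catalog")
    rng = np.random.default_rng(seed)
    lo, hi = (
        (goals_per_basket, goals_per_basket)
        if isinstance(goals_per_basket, int)
        else goals_per_basket
    )
    baskets = []
    for _ in range(n_baskets):
        k = int(rng.integers(lo, hi + 1))
        picks = rng.choice(len(goals.goals), size=k, replace=True, p=goals.weights)
        members: set[str] = set()
        for gi in picks:
            members |= goals.goals[gi]
        n_noise = int(round(noise_rate * len(members)))
        if n_noise > 0:
            members.update(rng.choice(catalog, size=n_noise, replace=True).tolist())
        baskets.append(frozenset(members))
    return BasketCorpus(baskets=tuple(baskets), catalog=tuple(sorted(known)))


@dataclass(frozen=True)
class IriParams:
    """Generative model of inter-response intervals (seconds).

    ``IRI_t = intercept - sum_k slope_k * S_k(prev, cur) + timestep_slope * t
    + Normal(0, sigma)`` — similar successors are retrieved faster, and
    responses slow as the trip wears on.
    """

    intercept: float = 30.0
    slopes: tuple[float, float, float] = (8.0, 8.0, 8.0)  # episodic, semantic, hierarchy
    timestep_slope: float = 0.15
    sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidConfigError("iri sigma must be >= 0")


@dataclass(frozen=True)
class ErrorLink:
    """Poisson log-link from standardised attention weights to error counts.

    ``count ~ Poisson(exp(intercept + sum_k coef_k * z(beta_k)))``.
    Default signs plant the qualitative pattern that episodic and
    hierarchical reliance reduce both error types while semantic reliance
    increases them (semantic retrieval surfaces substitutable rather than
    complementary products).
    """

    forgotten: dict = field(
        default_factory=lambda: {
            "intercept": 0.0,
            "episodic": -0.5,
            "semantic": 0.5,
            "hierarchy": -0.3,
        }
    )
    removed: dict = field(
        default_factory=lambda: {
            "intercept": 1.0,
            "episodic": -0.3,
            "semantic": 0.5,
            "hierarchy": -0.6,
        }
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full recipe for a synthetic study with known ground truth.

    Per-shopper true attention weights are drawn uniformly from
    ``beta_ranges`` unless ``true_betas`` pins them explicitly; the
    default ranges bracket the regime typically estimated on real
    shoppers (hierarchy dominant, semantic smallest).
    """

    catalog_size: int = 300
    branching: tuple[int, ...] = (3, 3, 3, 3, 3)
    n_goals: int = 240
    goal_size: int = 6
    theme_size: int = 5
    n_recipes: int = 30
    cross_category_rate: float = 0.5
    n_baskets: int = 2000
    goals_per_basket: int | tuple[int, int] = (1, 2)
    noise_rate: float = 0.1
    embedding_dimension: int = 50
    n_shoppers: int = 300
    trip_length: int | tuple[int, int] = 30
    beta_ranges: dict = field(
        default_factory=lambda: {
            "episodic": (0.0, 0.5),
            "semantic": (0.0, 0.2),
            "hierarchy": (0.0, 4.0),
        }
    )
    true_betas: np.ndarray | None = None  # (n_shoppers, 3) overrides beta_ranges
    iri: IriParams = field(default_factory=IriParams)
    error_link: ErrorLink = field(default_factory=ErrorLink)
    epsilon: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in [
            ("catalog_size", self.catalog_size),
            ("n_baskets", self.n_baskets),
            ("n_shoppers", self.n_shoppers),
            ("n_goals", self.n_goals),
        ]:
            if val < 1:
                raise InvalidConfigError(f"{name} must be positive")
        if self.epsilon <= 0:
            raise InvalidConfigError("epsilon must be > 0")
        tl = self.trip_length
        max_len = tl if isinstance(tl, int) else tl[1]
        if max_len > self.catalog_size:
            raise InvalidConfigError("trip_length cannot exceed catalog_size")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _draw_true_betas(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.true_betas is not None:
        betas = np.asarray(config.true_betas, dtype=float)
        if betas.shape != (config.n_shoppers, len(REPRESENTATIONS)):
            raise InvalidConfigError(
                "true_betas must have shape (n_shoppers, 3)"
            )
        if (betas < 0).any():
            raise InvalidConfigError("true betas must be >= 0")
        return betas
    lohi = np.array([config.beta_ranges[r] for r in REPRESENTATIONS])
    return rng.uniform(lohi[:, 0], lohi[:, 1], size=(config.n_shoppers, 3))


def _nav_probs() -> np.ndarray:
    w = np.array([NAV_SHARES[m] for m in NAV_METHODS])
    return w / w.sum()


def generate_trips(
    store: SimilarityStore, config: SimulationConfig
) -> tuple[TripLog, pd.DataFrame]:
    """Sample ordered trips from the retrieval rule with known weights.

    The first item of each trip is uniform over the catalog (it has no
    cue); each subsequent item is drawn from the retrieval probabilities
    over the not-yet-chosen catalog. Returns the trip log (with IRIs,
    navigation labels, and per-shopper error counts) and a frame of the
    true per-shopper attention weights.
    """
    missing = [r for r in REPRESENTATIONS if r not in store.names]
    if missing:
        raise InvalidConfigError(f"store lacks representations: {missing}")
    rng = np.random.default_rng(config.seed)
    n = len(store.catalog)
    betas = _draw_true_betas(config, rng)
    logS = _stacked(store, REPRESENTATIONS, config.epsilon, "product")
    sims = {r: store.matrices[r] for r in REPRESENTATIONS}
    nav_p = _nav_probs()
    ip = config.iri

    rows = []
    for s in range(config.n_shoppers):
        sid = f"S{s:05d}"
        T = (
            config.trip_length
            if isinstance(config.trip_length, int)
            else int(rng.integers(config.trip_length[0], config.trip_length[1] + 1))
        )
        if T > n:
            raise InvalidConfigError("trip_length exceeds catalog size")
        beta = betas[s]
        alive = np.ones(n, dtype=bool)
        current = int(rng.integers(n))
        alive[current] = False
        seq = [current]
        for _ in range(T - 1):
            scores = _log_strength(logS, beta, current, "product")
            w = np.where(alive, scores, -np.inf)
            w -= w.max()
            p = np.exp(w)
            p /= p.sum()
            current = int(rng.choice(n, p=p))
            alive[current] = False
            seq.append(current)
        navs = rng.choice(len(NAV_METHODS), size=T, p=nav_p)
        noise = rng.normal(0.0, ip.sigma, size=T)
        for t, idx in enumerate(seq, start=1):
            if t == 1:
                iri = np.nan
            else:
                prev = seq[t - 2]
                simsum = sum(
                    b * sims[r][prev, idx] for b, r in zip(ip.slopes, REPRESENTATIONS)
                )
                iri = ip.intercept - simsum + ip.timestep_slope * t + noise[t - 1]
            rows.append(
                {
                    "shopper_id": sid,
                    "timestep": t,
                    "product_id": store.catalog[idx],
                    "iri_seconds": iri,
                    "nav_method": NAV_METHODS[navs[t - 1]],
                }
            )

    trips = pd.DataFrame(rows)
    z = (betas - betas.mean(axis=0)) / np.where(betas.std(axis=0) > 0, betas.std(axis=0), 1.0)
    err_rows = []
    for s in range(config.n_shoppers):
        zz = dict(zip(REPRESENTATIONS, z[s]))
        counts = {}
        for kind in ("forgotten", "removed"):
            coefs = getattr(config.error_link, kind)
            eta = coefs["intercept"] + sum(coefs[r] * zz[r] for r in REPRESENTATIONS)
            counts[f"{kind}_count"] = int(rng.poisson(np.exp(eta)))
        err_rows.append({"shopper_id": f"S{s:05d}", **counts})
    errors = pd.DataFrame(err_rows)

    true = pd.DataFrame(betas, columns=[f"beta_{r}" for r in REPRESENTATIONS])
    true.insert(0, "shopper_id", [f"S{s:05d}" for s in range(config.n_shoppers)])
    return TripLog(trips=trips, shopper_errors=errors), true


@dataclass
class SimulationResult:
    """Everything a synthetic study produces, with ground truth attached."""

    taxonomy: Taxonomy
    goals: GoalLibrary
    corpus: BasketCorpus
    store: SimilarityStore
    trips: TripLog
    true_betas: pd.DataFrame
    config: SimulationConfig


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the full generative pipeline: taxonomy -> baskets -> store -> trips.

    Stage seeds are derived deterministically from ``config.seed`` so the
    whole study is reproducible from one integer.
    """
    from .representations import build_store

    base = int(config.seed)
    taxonomy = generate_taxonomy(config.branching, config.catalog_size, seed=base)
    goals = generate_goals(
        taxonomy,
        n_goals=config.n_goals,
        goal_size=config.goal_size,
        cross_category_rate=config.cross_category_rate,
        theme_size=config.theme_size,
        n_recipes=config.n_recipes,
        seed=base + 1,
    )
    corpus = generate_baskets(
        taxonomy,
        goals,
        n_baskets=config.n_baskets,
        goals_per_basket=config.goals_per_basket,
        noise_rate=config.noise_rate,
        seed=base + 2,
    )
    store = build_store(
        corpus,
        taxonomy,
        embedding_dimension=min(config.embedding_dimension, config.catalog_size),
        seed=base + 3,
    )
    trips, true = generate_trips(store, config)
    return SimulationResult(
        taxonomy=taxonomy,
        goals=goals,
        corpus=corpus,
        store=store,
        trips=trips,
        true_betas=true,
        config=config,
    )
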
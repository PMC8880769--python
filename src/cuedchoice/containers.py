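"""Core data containers shared across the package.

The pipeline moves between four kinds of objects: a product taxonomy
(a five-level is-a hierarchy), an unordered basket corpus, a store of
product-by-product similarity matrices, and ordered per-shopper trip
logs. All of them are thin, validated wrappers over numpy arrays and
pandas frames so that analyses stay vectorised.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical representation names, in fixed order.
REPRESENTATIONS = ("episodic", "semantic", "hierarchy")

#: Navigation methods a choice can be made through.
NAV_METHODS = ("search", "category", "offers", "forgotten_rec")


class InvalidConfigError(ValueError):
    """A configuration value violates a precondition."""


@dataclass(frozen=True)
class Taxonomy:
    """A fixed-depth is-a hierarchy mapping every product to a leaf.

    Parameters
    ----------
    depth
        Number of levels ``D`` (5 for a standard retailer taxonomy).
    paths
        Mapping ``product_id -> tuple`` of node identifiers from the
        top level (coarsest) down to the leaf, length ``depth``.
        Node identifiers encode their ancestry, so equality of the
        ``l``-th entry means the two products share all levels ``1..l``.
    """

    depth: int
    paths: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise InvalidConfigError("taxonomy depth must be >= 1")
        for pid, path in self.paths.items():
            if len(path) != self.depth:
                raise InvalidConfigError(
                    f"product {pid!r} has path of length {len(path)}, expected {self.depth}"
                )

    @property
    def catalog(self) -> tuple[str, ...]:
        return tuple(sorted(self.paths))

    def path(self, product_id: str) -> tuple[str, ...]:
        return self.paths[product_id]

    def group(self, product_id: str, level: int) -> str:
        """Node identifier of ``product_id`` at 1-based ``level``."""
        if not 1 <= level <= self.depth:
            raise InvalidConfigError(f"level must be in 1..{self.depth}")
        return self.paths[product_id][level - 1]

    def shared_levels(self, a: str, b: str) -> int:
        """Number of levels shared top-down before the first divergence."""
        pa, pb = self.paths[a], self.paths[b]
        n = 0
        for x, y in zip(pa, pb):
            if x != y:
                break
            n += 1
        return n

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"product_id": pid, **{f"level{i + 1}": node for i, node in enumerate(path)}}
            for pid, path in sorted(self.paths.items())
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Taxonomy":
        level_cols = sorted(
            (c for c in frame.columns if c.startswith("level")),
            key=lambda c: int(c[5:]),
        )
        if "product_id" not in frame.columns or not level_cols:
            raise ValueError("taxonomy frame needs 'product_id' and 'level*' columns")
        paths = {
            str(r["product_id"]): tuple(str(r[c]) for c in level_cols)
            for _, r in frame.iterrows()
        }
        return cls(depth=len(level_cols), paths=paths)


@dataclass(frozen=True)
class BasketCorpus:
    """An unordered corpus of baskets (sets of product identifiers)."""

    baskets: tuple[frozenset[str], ...]
    catalog: tuple[str, ...]

    def __post_init__(self) -> None:
        known = set(self.catalog)
        for i, b in enumerate(self.baskets):
            if not b:
                raise InvalidConfigError(f"basket {i} is empty")
            unknown = b - known
            if unknown:
                raise InvalidConfigError(
                    f"basket {i} contains products outside the catalog: {sorted(unknown)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.baskets)

    @classmethod
    def from_iterable(
        cls, baskets: Iterable[Iterable[str]], catalog: Sequence[str] | None = None
    ) -> "BasketCorpus":
        frozen = tuple(frozenset(b) for b in baskets)
        if catalog is None:
            catalog = sorted(set().union(*frozen)) if frozen else []
        return cls(baskets=frozen, catalog=tuple(catalog))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"basket_id": i, "product_id": pid}
            for i, basket in enumerate(self.baskets)
            for pid in sorted(basket)
        ]
        return pd.DataFrame(rows, columns=["basket_id", "product_id"])

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, catalog: Sequence[str] | None = None
    ) -> "BasketCorpus":
        groups = frame.groupby("basket_id")["product_id"].apply(
            lambda s: frozenset(map(str, s))
        )
        return cls.from_iterable(groups.tolist(), catalog=catalog)


@dataclass
class SimilarityStore:
    """Per-representation symmetric product-by-product similarity matrices.

    Matrices are indexed by ``catalog`` order; entries lie in ``[0, 1]``.
    The diagonal is defined but never consulted by the choice rule,
    because trips sample without replacement.
    """

    catalog: tuple[str, ...]
    matrices: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.catalog = tuple(self.catalog)
        n = len(self.catalog)
        for name, m in self.matrices.items():
            m = np.asarray(m, dtype=float)
            if m.shape != (n, n):
                raise ValueError(f"matrix {name!r} has shape {m.shape}, expected {(n, n)}")
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"matrix {name!r} is not symmetric")
            if m.min() < -1e-12 or m.max() > 1 + 1e-12:
                raise ValueError(f"matrix {name!r} has entries outside [0, 1]")
            self.matrices[name] = np.clip(m, 0.0, 1.0)
        self._index = {pid: i for i, pid in enumerate(self.catalog)}

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.matrices)

    def index(self, product_id: str) -> int:
        return self._index[product_id]

    def indices(self, product_ids: Iterable[str]) -> np.ndarray:
        return np.fromiter((self._index[p] for p in product_ids), dtype=np.int64)

    def similarity(self, name: str, a: str, b: str) -> float:
        return float(self.matrices[name][self._index[a], self._index[b]])

    def log_matrices(
        self, names: Sequence[str], epsilon: float
    ) -> np.ndarray:
        """Stacked ``log(S_k + epsilon)``, shape ``(k, n, n)``."""
        if epsilon <= 0:
            raise InvalidConfigError("epsilon must be > 0")
        return np.stack([np.log(self.matrices[k] + epsilon) for k in names])


@dataclass
class TripLog:
    """Ordered per-shopper choice sequences with response times and labels.

    ``trips`` has one row per choice with columns ``shopper_id``,
    ``timestep`` (1-based, consecutive within shopper), ``product_id``,
    ``iri_seconds`` (inter-response interval; NaN for the first choice,
    which has no predecessor), and ``nav_method``.  ``shopper_errors``
    optionally carries per-shopper ``removed_count``/``forgotten_count``.
    """

    trips: pd.DataFrame
    shopper_errors: pd.DataFrame | None = None

    REQUIRED = ("shopper_id", "timestep", "product_id", "iri_seconds", "nav_method")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.trips.columns]
        if missing:
            raise ValueError(f"trip table missing required column(s): {missing}")
        self.trips = self.trips.sort_values(["shopper_id", "timestep"]).reset_index(
            drop=True
        )
        for sid, grp in self.trips.groupby("shopper_id", sort=False):
            ts = grp["timestep"].to_numpy()
            if ts[0] != 1 or not np.array_equal(ts, np.arange(1, len(ts) + 1)):
                raise ValueError(
                    f"shopper {sid!r}: timesteps must be consecutive 1-based integers"
                )
            if grp["product_id"].duplicated().any():
                dup = grp.loc[grp["product_id"].duplicated(), "product_id"].iloc[0]
                raise ValueError(
                    f"shopper {sid!r}: product {dup!r} repeated within a trip"
                )

    @property
    def shoppers(self) -> tuple:
        return tuple(self.trips["shopper_id"].unique())

    def __len__(self) -> int:
        return len(self.shoppers)

    def sequences(self) -> dict:
        """Choice sequence per shopper, in timestep order."""
        return {
            sid: grp["product_id"].tolist()
            for sid, grp in self.trips.groupby("shopper_id", sort=False)
        }

    def filter_nav(self, methods: Iterable[str]) -> "TripLog":
        """Restrict each trip to choices made via the given navigation methods.

        The surviving choices form a subsequence per shopper; timesteps are
        renumbered consecutively so downstream code runs unchanged.
        Shoppers left with fewer than one choice are dropped.
        """
        keep = set(methods)
        sub = self.trips[self.trips["nav_method"].isin(keep)].copy()
        sub["timestep"] = sub.groupby("shopper_id").cumcount() + 1
        errors = None
        if self.shopper_errors is not None:
            kept = sub["shopper_id"].unique()
            errors = self.shopper_errors[
                self.shopper_errors["shopper_id"].isin(kept)
            ].reset_index(drop=True)
        return TripLog(trips=sub.reset_index(drop=True), shopper_errors=errors)


@dataclass
class AttentionWeights:
    """Non-negative attention weights, one per knowledge representation."""

    beta: dict[str, float]

    def __post_init__(self) -> None:
        for name, b in self.beta.items():
            if b < 0:
                raise InvalidConfigError(f"beta[{name!r}] = {b} must be >= 0")

    def as_array(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.beta.get(n, 0.0) for n in names], dtype=float)


@dataclass
class FitResult:
    """Maximum-likelihood fit of the retrieval model for one shopper."""

    shopper_id: object
    model_spec: tuple[str, ...]
    beta_hat: AttentionWeights
    log_likelihood: float
    n_transitions: int
    bic: float
    bic_random: float
    delta_bic_pct: float
    converged: bool
    n_restarts_used: int

    def __post_init__(self) -> None:
        k = len(self.model_spec)
        expected = k * np.log(self.n_transitions) - 2.0 * self.log_likelihood
        if not np.isclose(self.bic, expected, rtol=1e-9, atol=1e-9):
            raise ValueError("BIC does not satisfy k*ln(n) - 2*logL")

    def to_dict(self) -> dict:
        d = {
            "shopper_id": self.shopper_id,
            "model_spec": "+".join(self.model_spec),
            "log_likelihood": self.log_likelihood,
            "n_transitions": self.n_transitions,
            "bic": self.bic,
            "bic_random": self.bic_random,
            "delta_bic_pct": self.delta_bic_pct,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
        }
        for name in REPRESENTATIONS:
            d[f"beta_{name}"] = self.beta_hat.beta.get(name, np.nan)
        return d


def fits_to_frame(fits: Iterable[FitResult]) -> pd.DataFrame:
    return pd.DataFrame([f.to_dict() for f in fits])
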
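"""Lift analysis and spectral clustering of between-group transitions.

Consecutive choices are mapped to their taxonomy groups at a chosen
level; the lift of a group-to-group transition is its observed joint
frequency relative to what marginal independence would predict,

    lift(a, b) = P(a, b) / (P_source(a) * P_dest(b)).

``lift - 1 > 0`` flags enriched transitions. Thresholding negative
excesses at zero and symmetrising yields an affinity over groups, which
normalised-Laplacian spectral embedding plus seeded k-means partitions
into higher-order blocks; the number of clusters is selected by maximum
silhouette on the embedding (mean-modularity on the affinity is
available as an alternative criterion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .containers import InvalidConfigError, SimilarityStore, Taxonomy, TripLog

__all__ = ["TransitionMatrix", "ClusterSolution", "transition_lift", "spectral_cluster"]


@dataclass
class TransitionMatrix:
    """Group-to-group transition counts and lift at one taxonomy level."""

    level: int
    groups: tuple[str, ...]
    counts: np.ndarray  # integer counts, source x destination
    lift: np.ndarray  # NaN where a marginal is zero

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())


def transition_lift(
    trips: TripLog, taxonomy: Taxonomy, level: int, nav_filter=None
) -> TransitionMatrix:
    """Observed-over-expected transition frequencies between taxonomy groups.

    Joint probabilities are transition counts over the total number of
    transitions; source and destination marginals are taken over the
    same total, so ``sum_ab P(a,b) = 1`` and lift is invariant to
    duplicating every trip. Groups with a zero source or destination
    marginal get NaN (undefined) lift entries.
    """
    if not 1 <= level <= taxonomy.depth:
        raise InvalidConfigError(f"level must be in 1..{taxonomy.depth}")
    if nav_filter is not None:
        if isinstance(nav_filter, str):
            nav_filter = [nav_filter]
        trips = trips.filter_nav(nav_filter)
    groups = sorted(
        {taxonomy.group(p, level) for p in taxonomy.catalog}
    )
    gidx = {g: i for i, g in enumerate(groups)}
    counts = np.zeros((len(groups), len(groups)), dtype=np.int64)
    for seq in trips.sequences().values():
        gs = [gidx[taxonomy.group(p, level)] for p in seq]
        for a, b in zip(gs[:-1], gs[1:]):
            counts[a, b] += 1
    total = counts.sum()
    if total == 0:
        raise InvalidConfigError("trip log contains no transitions")
    P = counts / total
    p_src = P.sum(axis=1)
    p_dst = P.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lift = P / np.outer(p_src, p_dst)
    lift[np.outer(p_src == 0, np.ones(len(groups), dtype=bool))] = np.nan
    lift[np.outer(np.ones(len(groups), dtype=bool), p_dst == 0)] = np.nan
    return TransitionMatrix(level=level, groups=tuple(groups), counts=counts, lift=lift)


@dataclass
class ClusterSolution:
    """Selected spectral partition of the transition groups."""

    k: int
    assignment: dict[str, int]
    quality: dict[int, float]  # selection score per candidate k
    affinity: np.ndarray


def _affinity(tm: TransitionMatrix) -> np.ndarray:
    excess = np.nan_to_num(tm.lift, nan=0.0) - 1.0
    np.maximum(excess, 0.0, out=excess)
    return (excess + excess.T) / 2.0


def _spectral_embedding(A: np.ndarray, dim: int) -> np.ndarray:
    d = A.sum(axis=1)
    inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.maximum(d, 1e-300)), 0.0)
    M = inv_sqrt[:, None] * A * inv_sqrt[None, :]
    # eigenvectors of the normalised affinity == smallest of the Laplacian
    vals, vecs = np.linalg.eigh((M + M.T) / 2.0)
    emb = vecs[:, ::-1][:, :dim]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    return emb / np.where(norms > 0, norms, 1.0)


def spectral_cluster(
    tm: TransitionMatrix, k_range=range(2, 11), seed: int = 0
) -> ClusterSolution:
    """Cluster transition groups on the thresholded-lift affinity.

    Embeds groups with the top eigenvectors of the normalised affinity
    (equivalently, the bottom of the normalised Laplacian), runs seeded
    k-means for each candidate ``k``, and keeps the ``k`` with the best
    silhouette on the embedding (ties to the smaller ``k``). A
    disconnected affinity triggers a warning; components then dominate
    the partition naturally through the embedding.
    """
    groups = tm.groups
    n = len(groups)
    if n < 2:
        raise InvalidConfigError("need at least 2 groups to cluster")
    k_range = [k for k in k_range if 2 <= k <= n]
    if not k_range:
        raise InvalidConfigError("k_range contains no feasible cluster counts")
    A = _affinity(tm)
    n_comp, _ = connected_components((A > 0).astype(int), directed=False)
    if n_comp > 1:
        warnings.warn(
            f"affinity graph has {n_comp} connected components; clusters will "
            "follow components"
        )
    quality: dict[int, float] = {}
    best: tuple[float, int, np.ndarray] | None = None
    for k in k_range:
        emb = _spectral_embedding(A, dim=k)
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(emb)
        if len(set(labels)) < 2 or k >= n:
            score = -1.0 if k < n else 1.0  # k == n: every group its own cluster
        else:
            score = float(silhouette_score(emb, labels))
        quality[k] = score
        if best is None or score > best[0] + 1e-12:
            best = (score, k, labels)
    _, k, labels = best
    return ClusterSolution(
        k=k,
        assignment={g: int(l) for g, l in zip(groups, labels)},
        quality=quality,
        affinity=A,
    )
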
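"""Episodic, semantic, and hierarchical similarity representations.

Three product-by-product similarity matrices feed the retrieval model:

* **episodic** — the probability that two products co-occur in the same
  unordered basket, ``S(i, j) = n_ij / N`` over ``N`` baskets.  A direct
  record of shared purchasing episodes.
* **semantic** — cosine similarity between distributed product embeddings
  trained on basket co-occurrence (PPMI + truncated SVD by default, or a
  skip-gram-with-negative-sampling trainer), negatives clamped to zero.
* **hierarchy** — fraction of shared levels on two products' root-to-leaf
  paths in the product taxonomy; 1 iff same leaf, 0 iff they diverge at
  the top level.

All matrices are symmetric with entries in ``[0, 1]`` so they can be
exponentiated by non-negative attention weights in the choice rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import BasketCorpus, InvalidConfigError, SimilarityStore, Taxonomy

__all__ = [
    "EmbeddingModel",
    "episodic_similarity",
    "train_embedding",
    "semantic_similarity",
    "hierarchical_similarity",
    "build_store",
]


def _incidence(corpus: BasketCorpus) -> np.ndarray:
    """Binary baskets-by-products incidence matrix in catalog order."""
    index = {pid: j for j, pid in enumerate(corpus.catalog)}
    B = np.zeros((len(corpus.baskets), len(corpus.catalog)), dtype=np.float64)
    for i, basket in enumerate(corpus.baskets):
        for pid in basket:
            B[i, index[pid]] = 1.0
    return B


def episodic_similarity(corpus: BasketCorpus, conditional: bool = False) -> np.ndarray:
    """Basket co-occurrence probability matrix.

    ``S(i, j) = n_ij / N`` where ``n_ij`` counts baskets containing both
    products and ``N`` is the corpus size.  With ``conditional=True`` the
    asymmetric variant ``n_ij / n_i`` is symmetrised by averaging; the
    joint form is the default because the choice rule expects a symmetric
    score.

    Products never observed in the corpus get an all-zero row (with a
    warning) rather than an error.
    """
    if len(corpus) == 0:
        raise InvalidConfigError("corpus is empty")
    B = _incidence(corpus)
    counts = B.T @ B  # n_ij, with n_ii on the diagonal
    marginals = np.diag(counts)
    absent = marginals == 0
    if absent.any():
        missing = [corpus.catalog[j] for j in np.flatnonzero(absent)[:5]]
        warnings.warn(
            f"{int(absent.sum())} catalog product(s) never appear in the corpus "
            f"(e.g. {missing}); their similarity rows are zero."
        )
    if conditional:
        with np.errstate(divide="ignore", invalid="ignore"):
            cond = counts / marginals[:, None]
        cond[~np.isfinite(cond)] = 0.0
        return (cond + cond.T) / 2.0
    return counts / len(corpus)


@dataclass
class EmbeddingModel:
    """Distributed product representation trained on basket co-occurrence."""

    dimension: int
    vectors: np.ndarray  # (n_products, dimension), catalog order
    catalog: tuple[str, ...]
    method: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding contains non-finite entries")
        if self.vectors.shape != (len(self.catalog), self.dimension):
            raise ValueError("embedding shape does not match catalog/dimension")


def _cooccurrence_counts(corpus: BasketCorpus) -> np.ndarray:
    B = _incidence(corpus)
    counts = B.T @ B
    np.fill_diagonal(counts, 0.0)
    return counts


def _ppmi(counts: np.ndarray) -> np.ndarray:
    total = counts.sum()
    row = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(counts * total) - np.log(np.outer(row, row))
    pmi[~np.isfinite(pmi)] = 0.0
    return np.maximum(pmi, 0.0)


def _train_sgns(
    corpus: BasketCorpus,
    dimension: int,
    seed: int,
    epochs: int = 5,
    negatives: int = 5,
    lr: float = 0.025,
) -> np.ndarray:
    """Skip-gram with negative sampling over unordered basket contexts.

    Every ordered pair within a basket is a positive example; negatives
    are drawn from the unigram distribution raised to the 3/4 power.
    """
    rng = np.random.default_rng(seed)
    n = len(corpus.catalog)
    index = {pid: j for j, pid in enumerate(corpus.catalog)}
    W = (rng.random((n, dimension)) - 0.5) / dimension
    C = np.zeros((n, dimension))
    freq = np.zeros(n)
    pairs = []
    for basket in corpus.baskets:
        idx = [index[p] for p in basket]
        for a in idx:
            freq[a] += 1
            for b in idx:
                if a != b:
                    pairs.append((a, b))
    if not pairs:
        return W
    noise = np.maximum(freq, 1e-12) ** 0.75
    noise /= noise.sum()
    pairs_arr = np.array(pairs, dtype=np.int64)
    for _ in range(epochs):
        order = rng.permutation(len(pairs_arr))
        negs = rng.choice(n, size=(len(pairs_arr), negatives), p=noise)
        for row, (a, b) in enumerate(pairs_arr[order]):
            targets = np.concatenate(([b], negs[row]))
            labels = np.zeros(len(targets))
            labels[0] = 1.0
            scores = C[targets] @ W[a]
            g = (labels - 1.0 / (1.0 + np.exp(-scores))) * lr
            wa = W[a].copy()
            W[a] += g @ C[targets]
            C[targets] += np.outer(g, wa)
    return W


def train_embedding(
    corpus: BasketCorpus,
    method: str = "ppmi_svd",
    dimension: int = 50,
    seed: int = 0,
    center: bool = True,
    **hyperparameters,
) -> EmbeddingModel:
    """Train product embeddings from within-basket co-occurrence.

    ``ppmi_svd`` (default) builds a positive pointwise-mutual-information
    matrix and keeps the top singular directions — fully deterministic.
    ``sgns`` runs a seeded skip-gram-negative-sampling pass treating each
    basket as an unordered context window.

    With ``center=True`` (default) the mean embedding vector is
    subtracted before use — the standard common-component removal step.
    PPMI factorisations give every product a large shared positive
    component that inflates all cosines and mirrors raw co-occurrence
    frequency; removing it leaves the directions that actually
    discriminate between product meanings.
    """
    if len(corpus) == 0:
        raise InvalidConfigError("corpus is empty")
    if dimension < 2:
        raise InvalidConfigError("embedding dimension must be >= 2")
    if dimension > len(corpus.catalog):
        raise InvalidConfigError(
            f"dimension {dimension} exceeds catalog size {len(corpus.catalog)}"
        )
    if method == "ppmi_svd":
        ppmi = _ppmi(_cooccurrence_counts(corpus))
        U, s, _ = np.linalg.svd(ppmi, hermitian=True)
        vectors = U[:, :dimension] * np.sqrt(s[:dimension])
        # fix the sign of each singular vector so output is reproducible
        signs = np.sign(U[np.abs(U[:, :dimension]).argmax(axis=0), np.arange(dimension)])
        signs[signs == 0] = 1.0
        vectors = vectors * signs
    elif method == "sgns":
        vectors = _train_sgns(corpus, dimension, seed, **hyperparameters)
    else:
        raise InvalidConfigError(f"unknown embedding method {method!r}")
    vectors = np.asarray(vectors, dtype=float)
    if center:
        vectors = vectors - vectors.mean(axis=0)
    return EmbeddingModel(
        dimension=dimension,
        vectors=vectors,
        catalog=corpus.catalog,
        method=method,
        hyperparameters={"seed": seed, "center": center, **hyperparameters},
    )


def semantic_similarity(model: EmbeddingModel) -> np.ndarray:
    """Cosine similarity of embeddings, negatives clamped to zero.

    Clamping keeps entries in ``[0, 1]`` as required by the retrieval
    rule, which exponentiates similarities. Zero vectors (products with
    no co-occurrence signal) yield similarity 0 with everything.
    """
    norms = np.linalg.norm(model.vectors, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} product(s) have zero embedding vectors; "
            "their semantic similarities are 0."
        )
    safe = np.where(zero, 1.0, norms)
    unit = model.vectors / safe[:, None]
    cos = unit @ unit.T
    cos[zero, :] = 0.0
    cos[:, zero] = 0.0
    np.clip(cos, 0.0, 1.0, out=cos)
    return (cos + cos.T) / 2.0


def hierarchical_similarity(
    taxonomy: Taxonomy, catalog: tuple[str, ...] | None = None
) -> np.ndarray:
    """Shared-path-prefix similarity from the product taxonomy.

    ``S(i, j)`` is the number of levels shared from the top down to the
    first divergence, divided by the depth ``D``; it takes at most
    ``D + 1`` distinct values ``{0, 1/D, ..., 1}`` and equals 1 iff the
    two products share a leaf.
    """
    cat = taxonomy.catalog if catalog is None else tuple(catalog)
    unmapped = [p for p in cat if p not in taxonomy.paths]
    if unmapped:
        raise InvalidConfigError(f"products not mapped to taxonomy leaves: {unmapped[:5]}")
    D = taxonomy.depth
    # integer-code each full prefix path[:l+1] so that code equality at
    # level l implies agreement at every coarser level too; the count of
    # agreeing levels is then exactly the shared prefix length
    codes = np.empty((len(cat), D), dtype=np.int64)
    for lvl in range(D):
        seen: dict[tuple[str, ...], int] = {}
        for i, pid in enumerate(cat):
            prefix = taxonomy.paths[pid][: lvl + 1]
            codes[i, lvl] = seen.setdefault(prefix, len(seen))
    S = np.zeros((len(cat), len(cat)))
    for lvl in range(D):
        S += (codes[:, lvl][:, None] == codes[:, lvl][None, :]).astype(float)
    return S / D


def build_store(
    corpus: BasketCorpus,
    taxonomy: Taxonomy,
    embedding_method: str = "ppmi_svd",
    embedding_dimension: int = 50,
    seed: int = 0,
    conditional_episodic: bool = False,
) -> SimilarityStore:
    """Build the three-representation similarity store from raw data."""
    model = train_embedding(
        corpus, method=embedding_method, dimension=embedding_dimension, seed=seed
    )
    matrices = {
        "episodic": episodic_similarity(corpus, conditional=conditional_episodic),
        "semantic": semantic_similarity(model),
        "hierarchy": hierarchical_similarity(taxonomy, catalog=corpus.catalog),
    }
    return SimilarityStore(
        catalog=corpus.catalog,
        matrices=matrices,
        provenance={
            "embedding_method": embedding_method,
            "embedding_dimension": embedding_dimension,
            "seed": seed,
            "n_baskets": len(corpus),
            "conditional_episodic": conditional_episodic,
        },
    )
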
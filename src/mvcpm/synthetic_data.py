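"""Stochastic-block-model network generator and Gaussian feature simulator.

The simulation study draws, for each view, an unweighted undirected graph
from a stochastic block model (SBM): nodes are partitioned into K clusters
and an edge between nodes in clusters l and s appears independently with
probability ``prob_matrix[l, s]``.  Diagonal entries of the probability
matrix give within-cluster densities, off-diagonal entries between-cluster
densities.  The four canonical probability matrices P1..P4 (scaled by 1/n)
share the diagonal (16, 18, 17) and differ only in how much between-cluster
noise they add.

Cluster memberships may differ across views, which is exactly the
consistent-vs-differential pattern the clustering method targets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SBMConfig",
    "FeatureSimConfig",
    "MultiViewGraphSet",
    "connection_probability_matrix",
    "generate_sbm_view",
    "generate_multiview_sbm",
    "generate_feature_views",
    "write_adjacency_tsv",
    "write_labels_tsv",
]

# Numerators of the four canonical K=3 connection-probability matrices;
# actual probabilities are these divided by the node count n of the view.
_P_NUMERATORS: dict[str, np.ndarray] = {
    "P1": np.array(
        [[16.0, 0.0, 0.0], [0.0, 18.0, 0.0], [0.0, 0.0, 17.0]]
    ),
    "P2": np.array(
        [[16.0, 0.4, 0.6], [0.4, 18.0, 0.55], [0.6, 0.55, 17.0]]
    ),
    "P3": np.array(
        [[16.0, 0.8, 1.2], [0.8, 18.0, 1.1], [1.2, 1.1, 17.0]]
    ),
    "P4": np.array(
        [[16.0, 1.2, 1.8], [1.2, 18.0, 1.65], [1.8, 1.65, 17.0]]
    ),
}


def connection_probability_matrix(name: str, n: int) -> np.ndarray:
    """Return one of the canonical probability matrices P1..P4 scaled by 1/n.

    The divisor ``n`` is the total node count of the view (150 or 600 in the
    two standard regimes), which keeps the expected within-cluster degree at
    roughly 5 at both scales.
    """
    try:
        base = _P_NUMERATORS[name]
    except KeyError:
        raise ValueError(
            f"unknown probability matrix {name!r}; choose from {sorted(_P_NUMERATORS)}"
        ) from None
    if n <= 0:
        raise ValueError("divisor n must be positive")
    return base / float(n)


@dataclass(frozen=True)
class SBMConfig:
    """Configuration of a multiview stochastic block model.

    Parameters
    ----------
    n_views
        Number of views M.
    cluster_sizes_per_view
        M integer vectors, each summing to the common node count N.  All
        vectors must have the same length K.
    prob_matrix
        K x K symmetric matrix of connection probabilities (already divided
        by ``prob_scale_n``).
    prob_scale_n
        The divisor n that was applied to the probability numerators;
        recorded for provenance.
    seed
        Master seed; each view draws from an independent child stream so
        adding a view does not perturb earlier views.
    """

    n_views: int
    cluster_sizes_per_view: tuple[tuple[int, ...], ...]
    prob_matrix: np.ndarray
    prob_scale_n: int
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(tuple(int(s) for s in v) for v in self.cluster_sizes_per_view)
        object.__setattr__(self, "cluster_sizes_per_view", sizes)
        P = np.asarray(self.prob_matrix, dtype=float)
        object.__setattr__(self, "prob_matrix", P)
        if self.n_views != len(sizes):
            raise ValueError("n_views must equal len(cluster_sizes_per_view)")
        if self.n_views < 1:
            raise ValueError("need at least one view")
        totals = {sum(v) for v in sizes}
        if len(totals) != 1:
            raise ValueError(f"cluster sizes must sum to the same N in every view, got {totals}")
        ks = {len(v) for v in sizes}
        if len(ks) != 1 or P.shape != (ks.pop(), len(sizes[0])):
            raise ValueError("prob_matrix must be K x K with K = len(every size vector)")
        _validate_prob_matrix(P)

    @property
    def n_nodes(self) -> int:
        return sum(self.cluster_sizes_per_view[0])

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes_per_view[0])


@dataclass(frozen=True)
class FeatureSimConfig:
    """Gaussian mixture feature matrices for exercising the real-data path.

    Each view is a features-by-samples matrix; samples in cluster k share a
    mean vector (a random unit direction scaled by ``separation``) plus
    isotropic Gaussian noise of standard deviation ``noise_sd``.
    """

    n_views: int
    n_samples: int
    n_features: tuple[int, ...]
    cluster_sizes: tuple[int, ...]
    separation: float = 5.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_features", tuple(int(f) for f in self.n_features))
        object.__setattr__(self, "cluster_sizes", tuple(int(s) for s in self.cluster_sizes))
        if self.n_views < 1 or self.n_samples < 1 or any(f < 1 for f in self.n_features):
            raise ValueError("all counts must be positive")
        if len(self.n_features) != self.n_views:
            raise ValueError("need one feature count per view")
        if sum(self.cluster_sizes) != self.n_samples:
            raise ValueError("cluster sizes must sum to n_samples")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.separation < 0:
            raise ValueError("separation must be nonnegative")


@dataclass
class MultiViewGraphSet:
    """M symmetric weighted adjacency matrices over the same N nodes."""

    adjacencies: list
    labels: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        ns = {a.shape[0] for a in self.adjacencies}
        if len(ns) != 1:
            raise ValueError("all views must share the same node count")
        if self.labels is not None and len(self.labels) != len(self.adjacencies):
            raise ValueError("need one label vector per view")

    @property
    def n_views(self) -> int:
        return len(self.adjacencies)

    @property
    def n_nodes(self) -> int:
        return self.adjacencies[0].shape[0]


def _validate_prob_matrix(P: np.ndarray) -> None:
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("prob_matrix must be square")
    if not np.allclose(P, P.T):
        raise ValueError("prob_matrix must be symmetric")
    if np.any(P < 0) or np.any(P > 1):
        raise ValueError("connection probabilities must lie in [0, 1]")


def generate_sbm_view(
    sizes,
    prob_matrix: np.ndarray,
    seed,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one SBM graph.

    Parameters
    ----------
    sizes
        Cluster sizes; their sum is the node count N.  Nodes are labelled in
        blocks: the first ``sizes[0]`` nodes form cluster 0, and so on.
    prob_matrix
        K x K symmetric matrix of edge probabilities.
    seed
        Integer seed or ``numpy.random.Generator``.

    Returns
    -------
    adjacency : (N, N) float array
        Symmetric 0/1 adjacency with zero diagonal.
    labels : (N,) int array
        True cluster index (0-based) of each node.
    """
    sizes = np.asarray(sizes, dtype=int)
    if np.any(sizes <= 0):
        raise ValueError("cluster sizes must be positive")
    P = np.asarray(prob_matrix, dtype=float)
    _validate_prob_matrix(P)
    if len(sizes) != P.shape[0]:
        raise ValueError("len(sizes) must match prob_matrix dimension")

    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    n = labels.size
    # Edge probability for every unordered pair, drawn on the upper triangle.
    pair_prob = P[labels[:, None], labels[None, :]]
    upper = np.triu(rng.random((n, n)) < pair_prob, k=1)
    adjacency = (upper | upper.T).astype(float)
    return adjacency, labels


def generate_multiview_sbm(config: SBMConfig) -> MultiViewGraphSet:
    """Draw M independent SBM views from one master seed.

    Each view uses its own child stream of the master ``SeedSequence``, so
    the first views are reproduced bit-for-bit when ``n_views`` grows.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_views)
    adjacencies, labels = [], []
    for sizes, child in zip(config.cluster_sizes_per_view, children):
        a, lab = generate_sbm_view(sizes, config.prob_matrix, np.random.default_rng(child))
        adjacencies.append(a)
        labels.append(lab)
    return MultiViewGraphSet(adjacencies=adjacencies, labels=labels)


def generate_feature_views(
    config: FeatureSimConfig,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Simulate per-view feature-by-sample matrices with a shared partition.

    Returns the list of (n_features[m], n_samples) matrices and the common
    ground-truth labels.  Cluster means are random unit directions scaled by
    ``config.separation``; with separation well above ``noise_sd`` the
    clusters are linearly separable and the full pipeline should recover the
    partition exactly.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_views)
    labels = np.repeat(np.arange(len(config.cluster_sizes)), config.cluster_sizes)
    views = []
    for g, child in zip(config.n_features, children):
        rng = np.random.default_rng(child)
        means = rng.normal(size=(len(config.cluster_sizes), g))
        norms = np.linalg.norm(means, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        means = config.separation * means / norms
        x = means[labels].T + rng.normal(scale=config.noise_sd, size=(g, config.n_samples))
        views.append(x)
    return views, labels


def write_adjacency_tsv(path, adjacency: np.ndarray, dense: bool = True) -> None:
    """Write adjacency either as a dense matrix TSV or a 3-column edge list."""
    path = Path(path)
    if dense:
        np.savetxt(path, adjacency, delimiter="\t", fmt="%.10g")
        return
    i, j = np.nonzero(np.triu(adjacency, k=1))
    with path.open("w") as fh:
        for a, b in zip(i, j):
            fh.write(f"{a}\t{b}\t{adjacency[a, b]:.10g}\n")


def write_labels_tsv(path, labels: np.ndarray) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("node_id\tcluster\n")
        for i, lab in enumerate(labels):
            fh.write(f"{i}\t{int(lab)}\n")


def sbm_config_from_yaml(path) -> SBMConfig:
    """Load an :class:`SBMConfig` from a YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "prob_matrix_name" in raw:
        n = int(raw.get("prob_scale_n", sum(raw["cluster_sizes_per_view"][0])))
        P = connection_probability_matrix(raw.pop("prob_matrix_name"), n)
        raw["prob_matrix"] = P
        raw["prob_scale_n"] = n
    raw["cluster_sizes_per_view"] = tuple(tuple(v) for v in raw["cluster_sizes_per_view"])
    field_names = {f.name for f in dataclasses.fields(SBMConfig)}
    return SBMConfig(**{k: v for k, v in raw.items() if k in field_names})
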
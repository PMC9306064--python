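"""From the solver embedding to per-view and integrative cluster labels.

The stacked embedding treats every (view, sample) pair as one point in R^K,
so a single k-means fit labels all views with one shared centroid set —
labels are automatically comparable across views, with no permutation
matching step.  Samples whose label differs between views are then
reconciled into one integrative label by majority vote, with k-NN ties
broken in the view-averaged embedding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .multiview_model import EmbeddingBlocks

__all__ = ["ClusterResult", "kmeans_stacked", "integrative_assign", "write_labels_tsv"]

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    """Cluster labels produced by the pipeline (labels are 1-based, 1..K)."""

    per_view_labels: list[np.ndarray]
    integrative_labels: np.ndarray | None = None
    centroids: np.ndarray | None = None
    consensus_fraction: np.ndarray | None = None

    @property
    def n_views(self) -> int:
        return len(self.per_view_labels)

    @property
    def n_samples(self) -> int:
        return self.per_view_labels[0].size


def kmeans_stacked(
    x: EmbeddingBlocks,
    k: int,
    seed: int = 0,
    restarts: int = 20,
    max_retries: int = 3,
) -> ClusterResult:
    """Jointly k-means-cluster all N*M stacked embedding rows into K groups.

    Row (m-1)*N + i carries the label of sample i in view m.  Uses
    squared-Euclidean k-means with greedy (k-means++) seeding and
    ``restarts`` independent initialisations, keeping the best inertia.
    An empty cluster in the best solution triggers a reseeded retry and an
    error after ``max_retries`` failures.
    """
    if k < 2:
        raise ValueError("need at least two clusters")
    n, _ = x.shape
    stacked = x.stacked
    for attempt in range(max_retries):
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed + attempt)
        flat = km.fit_predict(stacked)
        if np.unique(flat).size == k:
            break
        logger.warning("k-means returned an empty cluster; retrying with a new seed")
    else:
        raise RuntimeError(f"k-means produced an empty cluster in {max_retries} attempts")
    labels = flat.reshape(x.n_views, n) + 1  # 1-based labels
    return ClusterResult(
        per_view_labels=[labels[m].copy() for m in range(x.n_views)],
        centroids=km.cluster_centers_.copy(),
    )


def integrative_assign(
    result: ClusterResult,
    x: EmbeddingBlocks,
    k_nn: int = 5,
    seed: int = 0,
) -> ClusterResult:
    """Reconcile per-view labels into one integrative label per sample.

    Samples labelled identically in every view keep that label.  Discordant
    samples take the majority label across views; when the vote ties, the
    label is decided by the majority among the ``k_nn`` nearest concordant
    samples in the view-averaged embedding (mean of the X_m rows).  If no
    sample is concordant at all, the integrative labels fall back to a fresh
    k-means on the view-averaged embedding (logged).
    """
    labels = np.vstack(result.per_view_labels)  # (M, N)
    m, n = labels.shape
    k = int(labels.max())
    mean_embed = np.mean(x.blocks, axis=0)  # (N, K)

    concordant = np.all(labels == labels[0], axis=0)
    integrative = np.zeros(n, dtype=int)
    integrative[concordant] = labels[0, concordant]

    if not concordant.any():
        logger.warning(
            "no sample is labelled consistently across views; "
            "falling back to k-means on the view-averaged embedding"
        )
        km = KMeans(n_clusters=k, n_init=20, random_state=seed)
        integrative = km.fit_predict(mean_embed) + 1
    else:
        conc_idx = np.nonzero(concordant)[0]
        for i in np.nonzero(~concordant)[0]:
            votes = np.bincount(labels[:, i], minlength=k + 1)
            top = votes.max()
            winners = np.nonzero(votes == top)[0]
            if winners.size == 1:
                integrative[i] = winners[0]
                continue
            # Tie: vote among the k_nn nearest concordant neighbours.
            dist = np.linalg.norm(mean_embed[conc_idx] - mean_embed[i], axis=1)
            order = np.lexsort((conc_idx, dist))
            neigh = conc_idx[order[:k_nn]]
            nv = np.bincount(integrative[neigh], minlength=k + 1)
            # Restrict to the tied labels; remaining ties go to the lowest label.
            nv_masked = np.full_like(nv, -1)
            nv_masked[winners] = nv[winners]
            integrative[i] = int(np.argmax(nv_masked))

    consensus = np.mean(labels == integrative[None, :], axis=0)
    return ClusterResult(
        per_view_labels=result.per_view_labels,
        integrative_labels=integrative,
        centroids=result.centroids,
        consensus_fraction=consensus,
    )


def write_labels_tsv(path, result: ClusterResult, sample_ids=None) -> None:
    """Write labels as TSV: sample_id, view_1..view_M, integrative."""
    n = result.n_samples
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(n)]
    with open(path, "w") as fh:
        cols = [f"view_{m + 1}" for m in range(result.n_views)]
        if result.integrative_labels is not None:
            cols.append("integrative")
        fh.write("sample_id\t" + "\t".join(cols) + "\n")
        for i in range(n):
            row = [str(ids[i])] + [str(int(v[i])) for v in result.per_view_labels]
            if result.integrative_labels is not None:
                row.append(str(int(result.integrative_labels[i])))
            fh.write("\t".join(row) + "\n")
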
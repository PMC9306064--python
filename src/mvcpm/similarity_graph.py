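"""Feature matrices to patient-patient k-NN similarity networks.

The real-data front end of the pipeline: standardise every feature, measure
pairwise sample similarity with a Gaussian (RBF) kernel whose bandwidth is
the standard deviation of the pairwise Euclidean distances, and sparsify the
dense similarity matrix into a symmetric k-nearest-neighbour graph.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "normalize_features",
    "gaussian_similarity",
    "knn_graph",
    "read_feature_matrix",
    "write_matrix_tsv",
]

logger = logging.getLogger(__name__)


def read_feature_matrix(path, sep: str | None = None) -> pd.DataFrame:
    """Read a features-by-samples matrix from TSV/CSV.

    Expects a header row of sample IDs and a first column of feature IDs.
    Raises on non-numeric cells, naming the offending coordinates.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    bad = df.map(lambda v: not isinstance(v, (int, float, np.number)) or pd.isna(v))
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        coords = [(df.index[r], df.columns[c]) for r, c in zip(rows[:5], cols[:5])]
        raise ValueError(f"non-numeric or missing cells at (feature, sample): {coords}")
    return df.astype(float)


def write_matrix_tsv(path, matrix: np.ndarray) -> None:
    np.savetxt(path, np.asarray(matrix), delimiter="\t", fmt="%.10g")


def normalize_features(features: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Standardise every feature (row) to mean 0 and variance 1.

    Uses the population variance, so a two-sample feature (0, 2) maps to
    (-1, 1).  Zero-variance features carry no information about sample
    structure and are dropped with a logged warning.
    """
    values = np.asarray(features, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D features-by-samples matrix")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population SD (ddof=0)
    keep = sd[:, 0] > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d zero-variance feature(s)", n_dropped)
    out = (values[keep] - mean[keep]) / sd[keep]
    if isinstance(features, pd.DataFrame):
        return pd.DataFrame(out, index=features.index[keep], columns=features.columns)
    return out


def gaussian_similarity(
    features: pd.DataFrame | np.ndarray,
) -> tuple[np.ndarray, float]:
    """Gaussian similarity S(i, j) = exp(-d(i, j)^2 / (2 alpha^2)).

    ``d`` is the Euclidean distance between sample columns; the bandwidth
    ``alpha`` is the standard deviation of the multiset of all N(N-1)/2
    pairwise distances, so the kernel adapts to the scale of the view.

    Returns the N x N similarity matrix (symmetric, unit diagonal) and alpha.
    """
    values = np.asarray(features, dtype=float)
    n = values.shape[1]
    if n < 2:
        raise ValueError("need at least two samples")
    d = pdist(values.T)  # condensed pairwise distances between sample columns
    alpha = float(np.std(d))
    if alpha == 0.0:
        raise ValueError(
            "all pairwise sample distances are equal (degenerate geometry); "
            "Gaussian bandwidth alpha would be zero"
        )
    s = np.exp(-squareform(d) ** 2 / (2.0 * alpha**2))
    np.fill_diagonal(s, 1.0)
    return s, alpha


def knn_graph(similarity: np.ndarray, k: int) -> np.ndarray:
    """Sparsify a similarity matrix into a symmetric k-NN adjacency.

    An edge (i, j) with weight S(i, j) is kept when j is among the k most
    similar neighbours of i *or* i among the k most similar of j (union
    symmetrisation, which preserves the declared symmetry of the adjacency).
    Ties in similarity are broken by the lower node index.  Diagonal is zero.
    """
    s = np.asarray(similarity, dtype=float)
    n = s.shape[0]
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity must be square")
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")

    # Per-row neighbour ranking: highest similarity first, ties to the lower
    # index; the node itself is excluded.
    mask = np.zeros((n, n), dtype=bool)
    idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((idx, -s[i]))
        order = order[order != i]
        mask[i, order[:k]] = True
    union = mask | mask.T
    adjacency = np.where(union, s, 0.0)
    np.fill_diagonal(adjacency, 0.0)
    return adjacency
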
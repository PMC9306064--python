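"""Coupled block-Laplacian model: operator, objective, gradient, multiplier.

The integrative model couples the per-view graph Laplacians L_m = D_m - A_m
through a block matrix

    L = blockdiag(L_1, ..., L_M) - beta * (off-diagonal identity blocks),

so that for an embedding X stacked from per-view blocks X_m (each N x K)

    (L X)_m = L_m X_m - beta * sum_{h != m} X_h.

Minimising Tr(X^T L X) under the per-view constraints X_m^T X_m = I_K
simultaneously finds the spectral embedding of every view (first term) and
aligns the embeddings across views (coupling term).  The block structure is
exploited throughout; the (N*M) x (N*M) matrix is never materialised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "BlockOperator",
    "EmbeddingBlocks",
    "laplacian",
    "apply_block_operator",
    "objective",
    "gradient",
    "multiplier",
    "merit",
]


def _is_sparse(a) -> bool:
    return sp.issparse(a)


def laplacian(adjacency) -> tuple:
    """Combinatorial graph Laplacian L = D - A and the degree matrix D.

    Accepts dense arrays or scipy sparse matrices (returned in kind).
    The input must be square, symmetric and nonnegative; row sums of L
    are exactly zero.
    """
    if _is_sparse(adjacency):
        a = adjacency.tocsr()
        if a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if (abs(a - a.T) > 1e-12 * max(1.0, abs(a).max())).nnz > 0:
            raise ValueError("adjacency must be symmetric")
        if a.nnz and a.data.min() < 0:
            raise ValueError("adjacency must be nonnegative")
        deg = np.asarray(a.sum(axis=1)).ravel()
        d = sp.diags(deg, format="csr")
        return (d - a).tocsr(), d
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12 * max(1.0, np.abs(a).max())):
        raise ValueError("adjacency must be symmetric")
    if np.any(a < 0):
        raise ValueError("adjacency must be nonnegative")
    deg = a.sum(axis=1)
    d = np.diag(deg)
    return d - a, d


@dataclass
class BlockOperator:
    """The block matrix L acting on per-view embedding blocks.

    Attributes
    ----------
    laplacians
        M symmetric N x N Laplacians (dense or sparse).
    degrees
        The matching degree matrices.
    beta_couple
        Nonnegative coupling strength between views (default 1).
    """

    laplacians: list
    degrees: list = field(default_factory=list)
    beta_couple: float = 1.0

    def __post_init__(self) -> None:
        if self.beta_couple < 0:
            raise ValueError("beta_couple must be nonnegative")
        ns = {l.shape[0] for l in self.laplacians}
        if len(ns) != 1:
            raise ValueError("all Laplacians must share the node count")

    @classmethod
    def from_adjacencies(cls, adjacencies, beta_couple: float = 1.0) -> "BlockOperator":
        laps, degs = [], []
        for a in adjacencies:
            l, d = laplacian(a)
            laps.append(l)
            degs.append(d)
        return cls(laplacians=laps, degrees=degs, beta_couple=beta_couple)

    @property
    def n_views(self) -> int:
        return len(self.laplacians)

    @property
    def n_nodes(self) -> int:
        return self.laplacians[0].shape[0]

    def dense(self) -> np.ndarray:
        """Assemble the full (N*M) x (N*M) coupled matrix (testing/debug only)."""
        n, m = self.n_nodes, self.n_views
        full = np.zeros((n * m, n * m))
        eye = np.eye(n)
        for i in range(m):
            li = self.laplacians[i]
            full[i * n : (i + 1) * n, i * n : (i + 1) * n] = (
                li.toarray() if _is_sparse(li) else np.asarray(li)
            )
            for j in range(m):
                if i != j:
                    full[i * n : (i + 1) * n, j * n : (j + 1) * n] = -self.beta_couple * eye
        return full


@dataclass
class EmbeddingBlocks:
    """Per-view embedding blocks X_m (each N x K) with a stacked view."""

    blocks: list[np.ndarray]

    def __post_init__(self) -> None:
        shapes = {b.shape for b in self.blocks}
        if len(shapes) != 1:
            raise ValueError("all blocks must share shape (N, K)")

    @property
    def n_views(self) -> int:
        return len(self.blocks)

    @property
    def shape(self) -> tuple[int, int]:
        return self.blocks[0].shape

    @property
    def stacked(self) -> np.ndarray:
        """The (N*M) x K stacked matrix X = (X_1; ...; X_M)."""
        return np.vstack(self.blocks)

    def copy(self) -> "EmbeddingBlocks":
        return EmbeddingBlocks([b.copy() for b in self.blocks])

    def norm(self) -> float:
        return float(np.sqrt(sum(np.sum(b * b) for b in self.blocks)))

    def __sub__(self, other: "EmbeddingBlocks") -> "EmbeddingBlocks":
        return EmbeddingBlocks([a - b for a, b in zip(self.blocks, other.blocks)])


def apply_block_operator(op: BlockOperator, x: EmbeddingBlocks) -> EmbeddingBlocks:
    """Compute L @ X blockwise: (LX)_m = L_m X_m - beta * sum_{h != m} X_h."""
    if x.n_views != op.n_views or x.shape[0] != op.n_nodes:
        raise ValueError(
            f"dimension mismatch: operator is {op.n_views} views of {op.n_nodes} nodes, "
            f"embedding is {x.n_views} views of {x.shape[0]} nodes"
        )
    total = np.sum(x.blocks, axis=0)
    out = [
        lm @ xm - op.beta_couple * (total - xm)
        for lm, xm in zip(op.laplacians, x.blocks)
    ]
    return EmbeddingBlocks(out)


def objective(op: BlockOperator, x: EmbeddingBlocks) -> float:
    """The trace objective f(X) = Tr(X^T L X)."""
    lx = apply_block_operator(op, x)
    return float(sum(np.sum(a * b) for a, b in zip(x.blocks, lx.blocks)))


def gradient(op: BlockOperator, x: EmbeddingBlocks) -> EmbeddingBlocks:
    """G = L X, the gradient convention used by the solver.

    The Euclidean gradient of Tr(X^T L X) for symmetric L is 2 L X; the
    constant factor is dropped here and absorbed by the scale-adaptive
    Barzilai-Borwein stepsizes downstream.
    """
    return apply_block_operator(op, x)


def multiplier(g_block: np.ndarray, x_block: np.ndarray) -> np.ndarray:
    """Closed-form Lagrangian multiplier delta = psi(G^T X) = (G^T X + X^T G) / 2.

    Symmetric by construction; at a feasible stationary point it equals the
    classical multiplier of the orthogonality constraint.
    """
    gtx = g_block.T @ x_block
    return 0.5 * (gtx + gtx.T)


def merit(op: BlockOperator, x: EmbeddingBlocks, beta_pen: float) -> float:
    """Penalty-model merit function h(X), used for monitoring descent.

    h = f(X) - 1/2 sum_m <psi(G_m^T X_m), X_m^T X_m - I>
             + beta_pen/4 sum_m ||X_m^T X_m - I||_F^2

    For feasible X every correction term vanishes and h = f.
    """
    lx = apply_block_operator(op, x)
    h = float(sum(np.sum(a * b) for a, b in zip(x.blocks, lx.blocks)))
    k = x.shape[1]
    eye = np.eye(k)
    for gm, xm in zip(lx.blocks, x.blocks):
        infeas = xm.T @ xm - eye
        h -= 0.5 * float(np.sum(multiplier(gm, xm) * infeas))
        h += 0.25 * beta_pen * float(np.sum(infeas * infeas))
    return h
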
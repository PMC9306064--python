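"""Scoring and the simulation experiment driver.

Simulation accuracy is the Rand index R = (TP + TN) / (TP + TN + FP + FN)
over all unordered sample pairs, computed per view against that view's
ground truth and averaged across views.  Real-data clusterings are scored
with silhouette coefficients and, when survival metadata are available, the
K-group log-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb
from sklearn.metrics import silhouette_score

from .cluster_assign import kmeans_stacked
from .multiview_model import BlockOperator, EmbeddingBlocks
from .penalty_solver import SolverConfig, solve
from .synthetic_data import SBMConfig, generate_multiview_sbm

__all__ = [
    "EvalReport",
    "ExperimentSpec",
    "rand_index",
    "run_sbm_experiment",
    "run_pipeline",
    "silhouette_scores",
    "logrank_test",
]

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """Container for the scores of one clustering run."""

    rand_per_view: list[float] | None = None
    rand_mean: float | None = None
    confusion: tuple[int, int, int, int] | None = None  # TP, TN, FP, FN
    silhouette_common: float | None = None
    silhouette_avg: float | None = None
    silhouette_int: float | None = None
    logrank_p: float | None = None


@dataclass
class ExperimentSpec:
    """Grid of SBM settings for the simulation study.

    ``settings`` maps a setting name (e.g. "P1") to an :class:`SBMConfig`;
    every setting is replicated ``replicates`` times with independent seeds
    spawned from ``seed``.
    """

    settings: dict[str, SBMConfig]
    replicates: int = 50
    n_clusters: int = 3
    beta_couple: float = 1.0
    solver: SolverConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def rand_index(labels_a, labels_b) -> tuple[float, int, int, int, int]:
    """Rand index and the pair-level confusion counts (R, TP, TN, FP, FN).

    TP counts pairs co-clustered in both labelings, TN pairs separated in
    both; R = (TP + TN) / C(N, 2).  Invariant to relabelling either side.
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.size != b.size:
        raise ValueError(f"label vectors differ in length: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need at least two samples")
    # Contingency table of the two partitions.
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    n = a.size
    total = int(comb(n, 2, exact=True))
    same_both = int(sum(comb(int(x), 2, exact=True) for x in table.ravel()))
    same_a = int(sum(comb(int(x), 2, exact=True) for x in table.sum(axis=1)))
    same_b = int(sum(comb(int(x), 2, exact=True) for x in table.sum(axis=0)))
    tp = same_both
    fn = same_a - same_both  # co-clustered in a, separated in b
    fp = same_b - same_both
    tn = total - tp - fn - fp
    return (tp + tn) / total, tp, tn, fp, fn


def run_pipeline(
    graphs,
    n_clusters: int,
    beta_couple: float = 1.0,
    solver: SolverConfig | None = None,
    kmeans_seed: int = 0,
):
    """Full clustering pipeline on a set of adjacency matrices.

    Builds the coupled block operator, runs the penalty solver, and k-means
    clusters the stacked embedding.  Returns (result, embedding, state).
    """
    op = BlockOperator.from_adjacencies(graphs, beta_couple=beta_couple)
    x, state = solve(op, n_clusters, solver)
    result = kmeans_stacked(x, n_clusters, seed=kmeans_seed)
    return result, x, state


def run_sbm_experiment(spec: ExperimentSpec) -> pd.DataFrame:
    """Replicate the SBM study: mean and SD of the view-averaged Rand index.

    Per replicate: draw a fresh multiview SBM, run the full pipeline, and
    compute the Rand index of each view's labels against that view's ground
    truth, averaged over views.  Returns one row per setting with columns
    (setting, mean_rand, sd_rand, replicates, n_converged).
    """
    master = np.random.SeedSequence(spec.seed)
    rows = []
    for name, config in spec.settings.items():
        children = master.spawn(spec.replicates)
        rands, n_converged = [], 0
        for child in children:
            sub = child.generate_state(3) % (2**31)
            graphs = generate_multiview_sbm(
                SBMConfig(
                    n_views=config.n_views,
                    cluster_sizes_per_view=config.cluster_sizes_per_view,
                    prob_matrix=config.prob_matrix,
                    prob_scale_n=config.prob_scale_n,
                    seed=int(sub[0]),
                )
            )
            solver = spec.solver or SolverConfig()
            solver = SolverConfig(**{**solver.__dict__, "seed": int(sub[1])})
            try:
                result, _, state = run_pipeline(
                    [np_to_sparse(a) for a in graphs.adjacencies],
                    spec.n_clusters,
                    beta_couple=spec.beta_couple,
                    solver=solver,
                    kmeans_seed=int(sub[2]),
                )
            except Exception as exc:  # non-convergence is recorded, not fatal
                logger.warning("replicate failed for setting %s: %s", name, exc)
                continue
            n_converged += state.converged
            per_view = [
                rand_index(result.per_view_labels[m], graphs.labels[m])[0]
                for m in range(graphs.n_views)
            ]
            rands.append(float(np.mean(per_view)))
        rows.append(
            {
                "setting": name,
                "mean_rand": float(np.mean(rands)),
                "sd_rand": float(np.std(rands, ddof=1)) if len(rands) > 1 else 0.0,
                "replicates": len(rands),
                "n_converged": int(n_converged),
            }
        )
    return pd.DataFrame(rows)


def np_to_sparse(a: np.ndarray):
    """CSR view of a dense adjacency (the solver only needs matvecs)."""
    import scipy.sparse as sp

    return sp.csr_matrix(a)


def silhouette_scores(
    x: EmbeddingBlocks,
    result,
) -> tuple[float, float, float]:
    """The (common, average, integrative) silhouette triple.

    * common — integrative labels scored on the view-averaged embedding;
    * average — mean over views of each view's labels scored on its X_m;
    * integrative — integrative labels scored on the stacked rows.

    Euclidean distances throughout.  Requires at least two distinct labels.
    """
    if result.integrative_labels is None:
        raise ValueError("integrative labels missing; run integrative_assign first")
    integ = result.integrative_labels
    if np.unique(integ).size < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    mean_embed = np.mean(x.blocks, axis=0)
    common = float(silhouette_score(mean_embed, integ))
    per_view = []
    for m in range(x.n_views):
        lab = result.per_view_labels[m]
        if np.unique(lab).size < 2:
            logger.warning("view %d collapsed to one cluster; silhouette skipped", m)
            continue
        per_view.append(float(silhouette_score(x.blocks[m], lab)))
    average = float(np.mean(per_view)) if per_view else float("nan")
    stacked_labels = np.tile(integ, x.n_views)
    integrative = float(silhouette_score(x.stacked, stacked_labels))
    return common, average, integrative


def logrank_test(labels, survival: pd.DataFrame) -> float:
    """K-group log-rank p-value for survival differences between clusters.

    ``survival`` must carry columns ``time`` (positive) and ``event``
    (0 = censored, 1 = observed), aligned with ``labels``.
    """
    from lifelines.statistics import multivariate_logrank_test

    labels = np.asarray(labels).ravel()
    if np.unique(labels).size < 2:
        raise ValueError("log-rank test needs at least two groups")
    time = np.asarray(survival["time"], dtype=float)
    event = np.asarray(survival["event"], dtype=int)
    if time.size != labels.size:
        raise ValueError("survival table and labels differ in length")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if not set(np.unique(event)) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    res = multivariate_logrank_test(time, labels, event)
    return float(res.p_value)
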
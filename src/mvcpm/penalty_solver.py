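"""First-order penalty solver for the orthogonality-constrained trace model.

Instead of retracting every iterate back onto the Stiefel manifold, the
solver minimises an exact-penalty merit function over a Frobenius ball of
radius r slightly larger than sqrt(K): each iteration takes a plain gradient
step of the augmented Lagrangian (with the closed-form symmetric multiplier)
and, only when the step leaves the ball, rescales the block back onto its
boundary.  Stepsizes follow the alternating Barzilai-Borwein (ABB) rule.
Because the penalty model returns only approximately feasible points, the
final blocks are polished to exact orthonormality by a polar decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .multiview_model import (
    BlockOperator,
    EmbeddingBlocks,
    gradient,
    merit,
    multiplier,
    objective,
)

__all__ = [
    "SolverConfig",
    "SolverState",
    "SolverDivergence",
    "aug_lagrangian_gradient",
    "step_and_safeguard",
    "bb_stepsize",
    "solve",
]

logger = logging.getLogger(__name__)


class SolverDivergence(RuntimeError):
    """Raised when an iterate develops non-finite entries."""


@dataclass
class SolverConfig:
    """Tuning knobs of the penalty solver.

    Attributes
    ----------
    beta_pen
        Quadratic-penalty weight, or ``"auto"`` for 0.01 * |f(X0)| — small
        penalties converge fastest while the multiplier term keeps the
        stationary points of the merit function feasible.
    radius_factor
        The safeguard ball has radius r = radius_factor * sqrt(K); any value
        >= 1 keeps the Stiefel manifold strictly inside the ball.
    stepsize_rule
        "ABB" (alternate BB1/BB2 by iteration parity), "BB1", "BB2" or
        "fixed" (always ``mu_init``).
    mu_init, mu_bounds
        First-iteration stepsize and the clamp interval for BB values.
    tol
        Relative gradient-norm stopping tolerance
        max_m ||D_m||_F / max(1, ||X||_F) <= tol.
    max_iter
        Iteration cap; hitting it sets ``converged=False`` (no exception).
    seed
        Seeds the random orthonormal initialisation.
    init
        "random_orthonormal" (QR of a Gaussian block per view) or
        "spectral" (bottom-K eigenvectors of each L_m).
    feas_restore_tol
        Feasibility safeguard: when max_m ||X_m^T X_m - I||_F exceeds this
        threshold the iterate is projected back onto the Stiefel manifold
        (polar decomposition) and the BB history is reset.  The penalty
        model keeps stationary points feasible only for beta_pen above a
        problem-dependent bound; for smaller penalties the iterate can
        drift towards rank-deficient merit minimisers, and the restoration
        clips that drift.  Set to ``inf`` to disable.
    printed_multiplier_sign
        Audit switch: use the printed "+X_m delta" multiplier sign instead of
        the descent-correct "-X_m delta" (see ``aug_lagrangian_gradient``).
    """

    beta_pen: float | str = "auto"
    radius_factor: float = 1.04
    stepsize_rule: str = "ABB"
    mu_init: float = 1e-3
    mu_bounds: tuple[float, float] = (1e-10, 1e2)
    tol: float = 1e-6
    max_iter: int = 1000
    seed: int = 0
    init: str = "random_orthonormal"
    feas_restore_tol: float = 1e-2
    printed_multiplier_sign: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.mu_bounds
        if not (0 < lo < hi):
            raise ValueError("mu_bounds must satisfy 0 < mu_min < mu_max")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.radius_factor < 1:
            raise ValueError("radius_factor must be >= 1")
        if self.stepsize_rule not in {"ABB", "BB1", "BB2", "fixed"}:
            raise ValueError(f"unknown stepsize rule {self.stepsize_rule!r}")
        if self.init not in {"random_orthonormal", "spectral"}:
            raise ValueError(f"unknown init {self.init!r}")
        if not (self.beta_pen == "auto" or float(self.beta_pen) > 0):
            raise ValueError("beta_pen must be positive or 'auto'")


@dataclass
class SolverState:
    """Iteration state and histories of one solver run."""

    x: EmbeddingBlocks
    grad_blocks: EmbeddingBlocks | None = None
    n_iter: int = 0
    mu: float = 0.0
    beta_pen: float = 0.0
    radius: float = 0.0
    converged: bool = False
    n_restorations: int = 0
    pre_polar_feasibility: float = float("nan")
    objective_history: list[float] = field(default_factory=list)
    merit_history: list[float] = field(default_factory=list)
    feasibility_history: list[float] = field(default_factory=list)
    mu_history: list[float] = field(default_factory=list)

    def feasibility(self) -> float:
        """max_m ||X_m^T X_m - I||_F of the current blocks."""
        return _feasibility_of(self.x)


def _feasibility_of(x: EmbeddingBlocks) -> float:
    k = x.shape[1]
    eye = np.eye(k)
    return max(float(np.linalg.norm(b.T @ b - eye)) for b in x.blocks)


def aug_lagrangian_gradient(
    op: BlockOperator,
    x: EmbeddingBlocks,
    beta_pen: float,
    printed_multiplier_sign: bool = False,
) -> EmbeddingBlocks:
    """Blockwise gradient of the augmented Lagrangian.

    D_m = G_m - X_m delta(X_m) + beta_pen X_m (X_m^T X_m - I_K)

    with G = L X and delta(X_m) = psi(G_m^T X_m).  The multiplier term is
    *subtracted*: subtracting the projection of the gradient onto the span of
    X_m yields the Riemannian-gradient form that vanishes at feasible
    stationary points.  ``printed_multiplier_sign=True`` flips that sign (for audit
    only; the resulting direction is not a descent direction).
    """
    g = gradient(op, x)
    k = x.shape[1]
    eye = np.eye(k)
    sign = 1.0 if printed_multiplier_sign else -1.0
    out = []
    for gm, xm in zip(g.blocks, x.blocks):
        delta = multiplier(gm, xm)
        out.append(gm + sign * (xm @ delta) + beta_pen * (xm @ (xm.T @ xm - eye)))
    return EmbeddingBlocks(out)


def step_and_safeguard(
    x: EmbeddingBlocks,
    d: EmbeddingBlocks,
    mu: float,
    r: float,
) -> EmbeddingBlocks:
    """Gradient step X - mu*D with per-block projection onto the ball ||.||_F <= r."""
    if mu < 0 or r <= 0:
        raise ValueError("need mu >= 0 and r > 0")
    out = []
    for xm, dm in zip(x.blocks, d.blocks):
        xt = xm - mu * dm
        if not np.all(np.isfinite(xt)):
            raise SolverDivergence("non-finite iterate after gradient step")
        nrm = float(np.linalg.norm(xt))
        if nrm > r:
            xt = (r / nrm) * xt
        out.append(xt)
    return EmbeddingBlocks(out)


def bb_stepsize(
    s_prev: EmbeddingBlocks | None,
    y_prev: EmbeddingBlocks | None,
    n_iter: int,
    rule: str,
    mu_init: float = 1e-3,
    mu_bounds: tuple[float, float] = (1e-10, 1e2),
) -> float:
    """Barzilai-Borwein stepsize from consecutive iterate/gradient differences.

    With S = X_k - X_{k-1} and Y = D_k - D_{k-1} (vectorised across all
    blocks), BB1 = <S,S>/<S,Y> and BB2 = <S,Y>/<Y,Y>; ABB uses BB1 on odd
    iterations and BB2 on even ones.  The merit function is nonconvex, so
    <S, Y> can be negative; the raw ratio is taken in absolute value (the
    usual BB safeguard for nonconvex objectives) and clamped to
    ``mu_bounds``.  A zero denominator or non-finite value falls back to
    ``mu_init``.  With no history (first iteration) the rule returns
    ``mu_init``.
    """
    if rule == "fixed" or s_prev is None or y_prev is None:
        return mu_init
    ss = float(sum(np.sum(a * a) for a in s_prev.blocks))
    sy = float(sum(np.sum(a * b) for a, b in zip(s_prev.blocks, y_prev.blocks)))
    yy = float(sum(np.sum(b * b) for b in y_prev.blocks))
    if rule == "ABB":
        rule = "BB1" if n_iter % 2 == 1 else "BB2"
    if rule == "BB1":
        raw = ss / sy if sy != 0 else float("nan")
    elif rule == "BB2":
        raw = sy / yy if yy != 0 else float("nan")
    else:  # pragma: no cover - guarded by SolverConfig
        raise ValueError(f"unknown stepsize rule {rule!r}")
    lo, hi = mu_bounds
    if not np.isfinite(raw) or raw == 0:
        return mu_init
    return float(min(max(abs(raw), lo), hi))


def _initial_blocks(op: BlockOperator, k: int, config: SolverConfig) -> EmbeddingBlocks:
    n = op.n_nodes
    if config.init == "spectral":
        import scipy.sparse as sp

        blocks = []
        for lm in op.laplacians:
            if sp.issparse(lm):
                # Dense fallback is fine at the problem sizes used here.
                lm = lm.toarray()
            w, v = np.linalg.eigh(np.asarray(lm))
            blocks.append(v[:, :k].copy())
        return EmbeddingBlocks(blocks)
    rng = np.random.default_rng(config.seed)
    blocks = []
    for _ in range(op.n_views):
        q, _ = np.linalg.qr(rng.standard_normal((n, k)))
        blocks.append(q)
    return EmbeddingBlocks(blocks)


def _polar_orthonormalize(x: EmbeddingBlocks) -> EmbeddingBlocks:
    """Project every block onto the Stiefel manifold via its polar factor."""
    out = []
    for b in x.blocks:
        u, _, vt = np.linalg.svd(b, full_matrices=False)
        out.append(u @ vt)
    return EmbeddingBlocks(out)


def solve(
    op: BlockOperator,
    k: int,
    config: SolverConfig | None = None,
) -> tuple[EmbeddingBlocks, SolverState]:
    """Run the penalty iteration until the gradient tolerance or ``max_iter``.

    Parameters
    ----------
    op
        The coupled block operator.
    k
        Embedding dimension K (number of clusters).
    config
        Solver configuration; defaults are the recommended settings
        (beta_pen = 0.01|f(X0)|, r = 1.04 sqrt(K), ABB steps).

    Returns
    -------
    x : EmbeddingBlocks
        The final blocks, polished to exact per-view orthonormality by a
        polar decomposition.
    state : SolverState
        Histories, convergence flag, and the pre-polish feasibility residual.
    """
    config = config or SolverConfig()
    x = _initial_blocks(op, k, config)
    f0 = objective(op, x)
    if config.beta_pen == "auto":
        beta_pen = 0.01 * abs(f0) if f0 != 0 else 0.01
    else:
        beta_pen = float(config.beta_pen)
    r = config.radius_factor * np.sqrt(k)

    state = SolverState(x=x, beta_pen=beta_pen, radius=r)
    d = aug_lagrangian_gradient(op, x, beta_pen, config.printed_multiplier_sign)
    x_prev: EmbeddingBlocks | None = None
    d_prev: EmbeddingBlocks | None = None

    for it in range(1, config.max_iter + 1):
        state.x = x
        gnorm = d.norm()
        state.objective_history.append(objective(op, x))
        state.merit_history.append(merit(op, x, beta_pen))
        state.feasibility_history.append(state.feasibility())
        if gnorm / max(1.0, x.norm()) <= config.tol:
            state.converged = True
            break
        s_prev = x - x_prev if x_prev is not None else None
        y_prev = d - d_prev if d_prev is not None else None
        mu = bb_stepsize(
            s_prev, y_prev, it, config.stepsize_rule, config.mu_init, config.mu_bounds
        )
        state.mu_history.append(mu)
        try:
            x_new = step_and_safeguard(x, d, mu, r)
        except SolverDivergence as exc:
            raise SolverDivergence(f"{exc} at iteration {it}") from None
        x_prev, d_prev = x, d
        x = x_new
        if _feasibility_of(x) > config.feas_restore_tol:
            # Drift safeguard: snap back to the manifold, forget BB history.
            x = _polar_orthonormalize(x)
            x_prev = d_prev = None
            state.n_restorations += 1
        d = aug_lagrangian_gradient(op, x, beta_pen, config.printed_multiplier_sign)
        state.x = x
        state.n_iter = it
        state.mu = mu

    state.x = x
    state.grad_blocks = d
    state.pre_polar_feasibility = state.feasibility()
    x_final = _polar_orthonormalize(x)
    state.x = x_final
    if not state.converged:
        logger.warning(
            "penalty solver stopped at max_iter=%d with relative gradient norm %.3e",
            config.max_iter,
            d.norm() / max(1.0, x.norm()),
        )
    return x_final, state


def write_trace_tsv(path, state: SolverState) -> None:
    """Dump the per-iteration trace (f, h, feasibility, mu) as TSV."""
    import itertools

    with open(path, "w") as fh:
        fh.write("iteration\tobjective\tmerit\tfeasibility\tmu\n")
        rows = itertools.zip_longest(
            state.objective_history,
            state.merit_history,
            state.feasibility_history,
            state.mu_history,
            fillvalue=float("nan"),
        )
        for i, (f, h, feas, mu) in enumerate(rows):
            fh.write(f"{i}\t{f:.10g}\t{h:.10g}\t{feas:.10g}\t{mu:.10g}\n")
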
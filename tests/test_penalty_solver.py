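"""Penalty solver: gradient formula, safeguard, BB stepsizes, convergence."""

import numpy as np
import pytest

from mvcpm import (
    BlockOperator,
    EmbeddingBlocks,
    SolverConfig,
    aug_lagrangian_gradient,
    bb_stepsize,
    objective,
    solve,
    step_and_safeguard,
)
from mvcpm.penalty_solver import SolverDivergence


def single_view_op(adjacency):
    return BlockOperator.from_adjacencies([adjacency], beta_couple=0.0)


class TestAugLagrangianGradient:
    def test_vanishes_on_invariant_subspace(self, random_weighted_graph):
        op = single_view_op(random_weighted_graph)
        w, v = np.linalg.eigh(np.asarray(op.laplacians[0]))
        x = EmbeddingBlocks([v[:, :3]])
        d = aug_lagrangian_gradient(op, x, beta_pen=2.0)
        # feasible invariant subspace: Riemannian gradient and penalty are 0
        assert d.norm() < 1e-10

    def test_literal_printed_form_is_not_stationary(self, random_weighted_graph):
        # audit switch: with the printed "+X delta" sign, D = 2G != 0 even at
        # a feasible stationary point
        op = single_view_op(random_weighted_graph)
        w, v = np.linalg.eigh(np.asarray(op.laplacians[0]))
        x = EmbeddingBlocks([v[:, :3]])
        d = aug_lagrangian_gradient(op, x, beta_pen=2.0, printed_multiplier_sign=True)
        assert d.norm() > 1.0

    def test_zero_input(self, random_weighted_graph):
        op = single_view_op(random_weighted_graph)
        x = EmbeddingBlocks([np.zeros((30, 2))])
        d = aug_lagrangian_gradient(op, x, beta_pen=1.0)
        assert d.norm() == 0.0

    def test_matches_term_by_term_formula(self, rng, random_weighted_graph):
        op = BlockOperator.from_adjacencies([random_weighted_graph] * 2, beta_couple=0.6)
        x = EmbeddingBlocks([rng.normal(size=(30, 3)) for _ in range(2)])
        beta_pen = 0.8
        d = aug_lagrangian_gradient(op, x, beta_pen)
        from mvcpm import apply_block_operator, multiplier

        g = apply_block_operator(op, x)
        for dm, gm, xm in zip(d.blocks, g.blocks, x.blocks):
            ref = (
                gm
                - xm @ multiplier(gm, xm)
                + beta_pen * xm @ (xm.T @ xm - np.eye(3))
            )
            assert np.allclose(dm, ref)


class TestStepAndSafeguard:
    def test_interior_point_unchanged(self, rng):
        x = EmbeddingBlocks([rng.normal(size=(5, 2)) * 0.1])
        d = EmbeddingBlocks([rng.normal(size=(5, 2))])
        out = step_and_safeguard(x, d, mu=0.01, r=10.0)
        assert np.allclose(out.blocks[0], x.blocks[0] - 0.01 * d.blocks[0])

    def test_exterior_point_projected_to_sphere(self, rng):
        x = EmbeddingBlocks([rng.normal(size=(5, 2)) * 100])
        d = EmbeddingBlocks([np.zeros((5, 2))])
        r = 1.5
        out = step_and_safeguard(x, d, mu=1.0, r=r)
        assert np.linalg.norm(out.blocks[0]) == pytest.approx(r)

    def test_zero_step_is_identity(self, rng):
        x = EmbeddingBlocks([rng.normal(size=(5, 2))])
        d = EmbeddingBlocks([rng.normal(size=(5, 2))])
        out = step_and_safeguard(x, d, mu=0.0, r=100.0)
        assert np.array_equal(out.blocks[0], x.blocks[0])

    def test_non_finite_raises_divergence(self):
        x = EmbeddingBlocks([np.array([[np.inf]])])
        d = EmbeddingBlocks([np.array([[0.0]])])
        with pytest.raises(SolverDivergence):
            step_and_safeguard(x, d, mu=1.0, r=1.0)


class TestBBStepsize:
    def _blocks(self, *vals):
        return EmbeddingBlocks([np.array([list(vals)], dtype=float)])

    def test_equal_differences_give_unit_step(self):
        s = self._blocks(1.0, 2.0)
        assert bb_stepsize(s, s, 3, "BB1") == pytest.approx(1.0)
        assert bb_stepsize(s, s, 3, "BB2") == pytest.approx(1.0)

    def test_scalar_example(self):
        s = self._blocks(1.0, 0.0)
        y = self._blocks(2.0, 0.0)
        assert bb_stepsize(s, y, 1, "BB1") == pytest.approx(0.5)
        assert bb_stepsize(s, y, 2, "BB2") == pytest.approx(0.5)

    def test_abb_alternates_by_parity(self, rng):
        s = EmbeddingBlocks([rng.normal(size=(4, 2))])
        y = EmbeddingBlocks([rng.normal(size=(4, 2)) + 2.0])
        ss = sum(np.sum(a * a) for a in s.blocks)
        sy = sum(np.sum(a * b) for a, b in zip(s.blocks, y.blocks))
        yy = sum(np.sum(b * b) for b in y.blocks)
        odd = bb_stepsize(s, y, 3, "ABB")
        even = bb_stepsize(s, y, 4, "ABB")
        assert odd == pytest.approx(abs(ss / sy))
        assert even == pytest.approx(abs(sy / yy))

    def test_no_history_returns_mu_init(self):
        assert bb_stepsize(None, None, 1, "ABB", mu_init=0.123) == 0.123


class TestSolve:
    def test_single_view_reaches_bottom_eigenvalue_sum(self, random_weighted_graph):
        op = single_view_op(random_weighted_graph)
        x, state = solve(op, 3, SolverConfig(seed=0))
        w = np.linalg.eigvalsh(np.asarray(op.laplacians[0]))
        assert state.converged
        assert objective(op, x) == pytest.approx(w[:3].sum(), rel=1e-6)

    def test_final_blocks_exactly_orthonormal(self, small_sbm):
        op = BlockOperator.from_adjacencies(small_sbm.adjacencies, beta_couple=1.0)
        x, state = solve(op, 3, SolverConfig(seed=0))
        for b in x.blocks:
            assert np.linalg.norm(b.T @ b - np.eye(3)) < 1e-12
        assert state.pre_polar_feasibility < 1e-3

    def test_deterministic_histories(self, small_sbm):
        op = BlockOperator.from_adjacencies(small_sbm.adjacencies, beta_couple=1.0)
        _, s1 = solve(op, 3, SolverConfig(seed=42))
        _, s2 = solve(op, 3, SolverConfig(seed=42))
        assert s1.objective_history == s2.objective_history
        assert s1.mu_history == s2.mu_history

    def test_fixed_small_step_merit_nonincreasing(self, random_weighted_graph):
        op = single_view_op(random_weighted_graph)
        cfg = SolverConfig(seed=3, stepsize_rule="fixed", mu_init=1e-3, max_iter=50)
        _, state = solve(op, 3, cfg)
        h = state.merit_history
        diffs = np.diff(h)
        assert np.all(diffs <= 1e-10)

    def test_single_view_subspace_matches_eigenvectors(self, random_weighted_graph):
        op = single_view_op(random_weighted_graph)
        x, _ = solve(op, 3, SolverConfig(seed=5))
        w, v = np.linalg.eigh(np.asarray(op.laplacians[0]))
        # principal angles between converged span and bottom-eigenvector span
        sv = np.linalg.svd(x.blocks[0].T @ v[:, :3], compute_uv=False)
        angles = np.arccos(np.clip(sv, -1, 1))
        assert np.max(angles) < 1e-3

    def test_max_iter_sets_flag_without_raising(self, random_weighted_graph):
        op = single_view_op(random_weighted_graph)
        _, state = solve(op, 3, SolverConfig(seed=0, max_iter=3))
        assert not state.converged
        assert state.n_iter == 3

    def test_spectral_init_converges_immediately(self, random_weighted_graph):
        op = single_view_op(random_weighted_graph)
        x, state = solve(op, 2, SolverConfig(seed=0, init="spectral"))
        w = np.linalg.eigvalsh(np.asarray(op.laplacians[0]))
        assert objective(op, x) == pytest.approx(w[:2].sum(), rel=1e-8)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SolverConfig(mu_bounds=(1.0, 0.5))
        with pytest.raises(ValueError):
            SolverConfig(radius_factor=0.5)
        with pytest.raises(ValueError):
            SolverConfig(stepsize_rule="newton")
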
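"""Steady-state solvers against closed forms and each other."""

import numpy as np
import pytest
from scipy.stats import binom

import gjgate as gj
from gjgate import tensor_core as tc
from gjgate.models import BlockGenerator, birth_death_generator, enumerate_states
from gjgate.solvers import (
    InvalidBandError,
    ReducibleChainError,
    SolverOptions,
    UnsupportedStructureError,
    convergence_check,
    group_inverse,
    solve_banded,
    solve_block_gauss_seidel,
    solve_block_recursive,
    solve_dense,
    solve_steady_state,
)

from conftest import random_generator_matrix


def _toy_block_generator(q, block_sizes):
    space = enumerate_states("two12")  # placeholder metadata for toys
    return BlockGenerator(
        Q=q,
        partition=tuple(block_sizes),
        bandwidth=tc.bandwidth(q),
        state_space=space,
        voltage_splits=[],
    )


class TestDense:
    def test_two_state_balance(self):
        a, b = 0.3, 0.9
        res = solve_dense(np.array([[-a, a], [b, -b]]))
        np.testing.assert_allclose(
            res.pi, [b / (a + b), a / (a + b)], atol=1e-14
        )
        assert res.residual <= 1e-10
        assert res.outer_iterations == 0

    def test_product_form_of_independent_gates(self):
        a, b = 0.004, 0.009
        q1 = np.array([[-a, a], [b, -b]])
        res = solve_dense(tc.kron_sum(q1, q1))
        local = np.array([b, a]) / (a + b)
        np.testing.assert_allclose(res.pi, np.kron(local, local), atol=1e-12)

    def test_symmetric_birth_death_is_binomial(self):
        """Equal per-subgate rates: closed count is Binomial(6, 1/2) by
        detailed balance."""
        res = solve_dense(birth_death_generator(0.005, 0.005))
        np.testing.assert_allclose(
            res.pi, binom.pmf(np.arange(7), 6, 0.5), atol=1e-12
        )

    def test_reducible_chain_rejected(self):
        q = np.zeros((4, 4))
        q[0, 1], q[1, 0] = 0.1, 0.2
        q[2, 3], q[3, 2] = 0.3, 0.4
        np.fill_diagonal(q, -q.sum(axis=1))
        with pytest.raises(ReducibleChainError):
            solve_dense(q)


class TestBanded:
    def test_matches_dense_on_two12(self, two12_gen, two12_dense_pi):
        res = solve_banded(two12_gen.Q, 7, 7)
        np.testing.assert_allclose(res.pi, two12_dense_pi, atol=1e-10)

    def test_tridiagonal_two_state_chain(self):
        a, b = 0.2, 0.5
        res = solve_banded(np.array([[-a, a], [b, -b]]), 1, 1)
        np.testing.assert_allclose(
            res.pi, [b / (a + b), a / (a + b)], atol=1e-14
        )

    def test_matches_dense_on_three6(self, three6_gen):
        k1, k2, _ = three6_gen.bandwidth
        res = solve_banded(three6_gen.Q, k1, k2)
        np.testing.assert_allclose(
            res.pi, solve_dense(three6_gen.Q).pi, atol=1e-10
        )

    def test_too_narrow_band_rejected(self, two12_gen):
        with pytest.raises(InvalidBandError):
            solve_banded(two12_gen.Q, 3, 3)


class TestBlockRecursive:
    def test_agrees_with_dense_to_1e12(self, two12_gen, two12_dense_pi):
        """The direct recursion reproduces the stable dense solution to
        ~1e-12 on the 49-state model (small generator entries keep the
        elimination well conditioned)."""
        res = solve_block_recursive(two12_gen)
        assert np.max(np.abs(res.pi - two12_dense_pi)) < 1e-12

    def test_constant_rate_product_of_binomials(self):
        p = gj.GatingParams(A=0.0, P=1, K=0.01, V0=0.0)
        gen = gj.build_generator("two12", p, p, 40.0)
        res = solve_block_recursive(gen)
        marginal = binom.pmf(np.arange(7), 6, 0.5)
        np.testing.assert_allclose(
            res.pi, np.kron(marginal, marginal), atol=1e-12
        )

    def test_two_block_toy_with_diagonal_off_blocks(self):
        rng = np.random.default_rng(5)
        n = 3
        up = np.diag(rng.uniform(0.1, 1.0, n))
        lo = np.diag(rng.uniform(0.1, 1.0, n))
        d1 = random_generator_matrix(rng, n)
        d2 = random_generator_matrix(rng, n)
        q = np.block([[d1, up], [lo, d2]])
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        gen = _toy_block_generator(q, (n, n))
        res = solve_block_recursive(gen)
        np.testing.assert_allclose(res.pi, solve_dense(q).pi, atol=1e-12)

    def test_varying_block_sizes_rejected(self, three6_gen):
        with pytest.raises(UnsupportedStructureError):
            solve_block_recursive(three6_gen)

    def test_non_block_tridiagonal_rejected(self):
        rng = np.random.default_rng(9)
        q = random_generator_matrix(rng, 6)  # dense coupling
        with pytest.raises(UnsupportedStructureError):
            solve_block_recursive(_toy_block_generator(q, (2, 2, 2)))


class TestBlockGaussSeidel:
    def test_fixed_point_converges_in_one_sweep(self, two12_gen, two12_dense_pi):
        opts = SolverOptions(
            method="block_gauss_seidel",
            epsilon=1e-6,
            initial_vector=two12_dense_pi,
        )
        res = solve_block_gauss_seidel(two12_gen, opts)
        assert res.converged
        assert res.outer_iterations == 1

    def test_agreement_scales_with_epsilon(self, two12_gen, two12_dense_pi):
        """Stopping on consecutive-iterate differences leaves an error of
        order epsilon; tightening epsilon tightens the agreement with the
        dense oracle accordingly."""
        res6 = solve_block_gauss_seidel(
            two12_gen, SolverOptions(method="block_gauss_seidel", epsilon=1e-6)
        )
        assert res6.converged
        assert np.max(np.abs(res6.pi - two12_dense_pi)) <= 1e-5

        res12 = solve_block_gauss_seidel(
            two12_gen, SolverOptions(method="block_gauss_seidel", epsilon=1e-12)
        )
        assert np.max(np.abs(res12.pi - two12_dense_pi)) <= 1e-9

    def test_iterations_nondecreasing_as_epsilon_tightens(self, two12_gen):
        counts = []
        for exp in range(4, 13):
            res = solve_block_gauss_seidel(
                two12_gen,
                SolverOptions(method="block_gauss_seidel", epsilon=10.0**-exp),
            )
            assert res.converged
            counts.append(res.outer_iterations)
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_residual_decreases_after_first_sweep(
        self, two12_gen, three6_gen, three12_gen
    ):
        """max|pi Q| decreases non-strictly over outer sweeps once the
        transient of the uniform start has passed (the very first sweep
        of the 784-state model can raise it)."""
        for gen in (two12_gen, three6_gen, three12_gen):
            res = solve_block_gauss_seidel(
                gen, SolverOptions(method="block_gauss_seidel", epsilon=1e-10)
            )
            h = res.residual_history[1:]
            assert all(
                later <= earlier * (1 + 1e-12)
                for earlier, later in zip(h, h[1:])
            )

    def test_nonconvergence_reported(self, two12_gen):
        res = solve_block_gauss_seidel(
            two12_gen,
            SolverOptions(
                method="block_gauss_seidel", epsilon=1e-12,
                max_outer_iterations=3,
            ),
        )
        assert not res.converged
        assert res.outer_iterations == 3


class TestConvergenceCheck:
    def test_identical_vectors(self):
        assert convergence_check([0.5, 0.5], [0.5, 0.5], 1e-12)

    def test_threshold_is_strict(self):
        assert not convergence_check([0.0, 2e-6], [0.0, 0.0], 1e-6)
        assert convergence_check([9e-7, -9e-7], [0.0, 0.0], 1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            convergence_check([0.1], [0.1, 0.2], 1e-6)


class TestEquivalences:
    def test_dtmc_and_ctmc_steady_states_agree(self, two12_gen, two12_dense_pi):
        """For P = I + tau*Q (tau small enough that P is stochastic) the
        fixed point of pi P = pi equals the null vector of Q."""
        q = two12_gen.Q
        tau = 0.5 / np.abs(np.diag(q)).max()
        p = np.eye(q.shape[0]) + tau * q
        assert np.all(p >= 0)
        a = p.T - np.eye(q.shape[0])
        a[-1, :] = 1.0
        rhs = np.zeros(q.shape[0])
        rhs[-1] = 1.0
        pi_dtmc = np.linalg.solve(a, rhs)
        pi_dtmc /= pi_dtmc.sum()
        np.testing.assert_allclose(pi_dtmc, two12_dense_pi, atol=1e-10)

    def test_invariance_under_global_rescaling(self, two12_gen, two12_dense_pi):
        for c in (0.1, 7.0):
            res = solve_dense(c * two12_gen.Q)
            np.testing.assert_allclose(res.pi, two12_dense_pi, atol=1e-12)

    def test_dispatch_covers_all_methods(self, two12_gen, two12_dense_pi):
        for method in ("dense_ge", "banded_ge", "block_recursive",
                       "block_gauss_seidel"):
            res = solve_steady_state(
                two12_gen, SolverOptions(method=method, epsilon=1e-10)
            )
            assert np.max(np.abs(res.pi - two12_dense_pi)) <= 1e-7
            assert res.method == method


class TestGroupInverse:
    def test_defining_identities_on_two_state_chain(self):
        q = np.array([[-0.3, 0.3], [0.8, -0.8]])
        qh = group_inverse(q)
        np.testing.assert_allclose(q @ qh @ q, q, atol=1e-12)
        np.testing.assert_allclose(qh @ q @ qh, qh, atol=1e-12)
        np.testing.assert_allclose(q @ qh, qh @ q, atol=1e-12)

    def test_matches_fundamental_matrix_construction(self):
        """Independent route: uniformize to a DTMC P = I + t*Q, build the
        fundamental matrix Z = (I - P + W)^-1; the DTMC group inverse is
        Z - W, and since Q = -(I - P)/t, scaling by -t recovers Q#."""
        rng = np.random.default_rng(21)
        q = random_generator_matrix(rng, 5)
        qh = group_inverse(q)
        t = 0.4 / np.abs(np.diag(q)).max()
        p = np.eye(5) + t * q
        pi = solve_dense(q).pi
        w = np.outer(np.ones(5), pi)
        z = np.linalg.inv(np.eye(5) - p + w)
        np.testing.assert_allclose(qh, -t * (z - w), atol=1e-10)

    def test_perturbation_bound(self, two12_gen, two12_dense_pi):
        """||dpi||_1 / ||pi||_1 <= ||Q#||_inf * ||dQ||_inf for structured
        small perturbations of the generator (re-solve oracle)."""
        q = two12_gen.Q
        pi = two12_dense_pi
        qh_norm = np.abs(group_inverse(q)).sum(axis=1).max()
        rng = np.random.default_rng(17)
        for _ in range(10):
            off = q - np.diag(np.diag(q))
            pert = off * (1 + 1e-3 * rng.standard_normal(off.shape))
            pert = np.clip(pert, 0.0, None)
            qp = pert.copy()
            np.fill_diagonal(qp, 0.0)
            np.fill_diagonal(qp, -qp.sum(axis=1))
            pi_p = solve_dense(qp).pi
            lhs = np.abs(pi_p - pi).sum() / np.abs(pi).sum()
            rhs = qh_norm * np.abs(qp - q).sum(axis=1).max()
            assert lhs <= rhs

    def test_reducible_chain_rejected(self):
        q = np.zeros((2, 2))
        with pytest.raises(ReducibleChainError):
            group_inverse(q)
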
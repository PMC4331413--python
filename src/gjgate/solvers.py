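"""Steady-state solvers for ``pi Q = 0`` with ``sum(pi) = 1``.

Four interchangeable methods, matched to the block structure of the GJ
generators:

``dense_ge``
    Baseline Gaussian elimination on the transposed system with one
    equation replaced by the normalization constraint.
``banded_ge``
    Banded factorization exploiting the generator's bandwidth: one
    probability is pinned, the remaining banded subsystem is solved by
    LAPACK's banded driver, and the vector is renormalized.
``block_recursive``
    A block Thomas-style forward elimination / back substitution over an
    equal-size block-tridiagonal partition (the 49-state model).  Direct
    and, thanks to the small generator entries, accurate to ~1e-12
    against dense elimination despite its known sensitivity to rounding.
``block_gauss_seidel``
    Iterative block sweeps in index order; each inner system solves
    against the banded (tridiagonal for the 49- and 28-state models)
    diagonal block.  The iterate is renormalized after every outer
    sweep and iteration stops when consecutive iterates differ by less
    than ``epsilon`` in every entry.

A group inverse and the associated steady-state perturbation bound are
also provided for sensitivity analysis over voltage sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from . import tensor_core
from .models import BlockGenerator

__all__ = [
    "SolverOptions",
    "SolverResult",
    "ReducibleChainError",
    "InvalidBandError",
    "UnsupportedStructureError",
    "solve_dense",
    "solve_banded",
    "solve_block_recursive",
    "solve_block_gauss_seidel",
    "solve_steady_state",
    "convergence_check",
    "group_inverse",
    "METHODS",
]

METHODS = ("dense_ge", "banded_ge", "block_recursive", "block_gauss_seidel")


class ReducibleChainError(ValueError):
    """The generator does not describe an irreducible chain."""


class InvalidBandError(ValueError):
    """Nonzero entries fall outside the supplied band."""


class UnsupportedStructureError(ValueError):
    """The generator lacks the block structure the method requires."""


@dataclass(frozen=True)
class SolverOptions:
    """Options shared by the steady-state solvers.

    ``epsilon`` is the outer-iteration stopping tolerance (max absolute
    entrywise difference of consecutive iterates); ``initial_vector``
    overrides the default uniform ``1/n`` start, e.g. for warm starts.
    """

    method: str = "dense_ge"
    epsilon: float = 1e-6
    max_outer_iterations: int = 10_000
    initial_vector: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; use {METHODS}")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if self.initial_vector is not None:
            v = np.asarray(self.initial_vector, dtype=float)
            if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(
                    "initial_vector must be nonnegative and sum to 1"
                )


@dataclass
class SolverResult:
    """Steady-state probability vector with solver diagnostics.

    ``outer_iterations`` is 0 for direct methods; ``residual`` is the
    max-norm of ``pi Q``.  ``residual_history`` (iterative methods)
    records the residual after each outer sweep.
    """

    pi: np.ndarray
    outer_iterations: int
    residual: float
    converged: bool
    method: str = ""
    residual_history: list[float] = field(default_factory=list)


def _as_matrix(q) -> np.ndarray:
    if isinstance(q, BlockGenerator):
        return q.Q
    return np.asarray(q, dtype=float)


def _residual(pi: np.ndarray, q: np.ndarray) -> float:
    return float(np.max(np.abs(pi @ q)))


def _finalize(pi: np.ndarray, q: np.ndarray, method: str) -> SolverResult:
    total = pi.sum()
    if not np.isfinite(total) or total <= 0:
        raise ReducibleChainError(
            "steady-state solve produced a non-normalizable vector; "
            "the chain is likely reducible"
        )
    pi = pi / total
    res = _residual(pi, q)
    if not np.isfinite(res) or res > 1e-6 * max(1.0, np.abs(q).max()):
        raise ReducibleChainError(
            f"steady-state residual {res:.3e} too large; the generator is "
            "singular beyond rank one (reducible chain)"
        )
    return SolverResult(pi=pi, outer_iterations=0, residual=res,
                        converged=True, method=method)


def solve_dense(q) -> SolverResult:
    """Direct dense solve of the constrained transposed system.

    The singular system ``pi Q = 0`` is closed by replacing the last
    column of ``Q`` (one redundant balance equation) with ones, encoding
    ``sum(pi) = 1``.
    """
    q = _as_matrix(q)
    n = q.shape[0]
    a = q.copy()
    a[:, -1] = 1.0
    rhs = np.zeros(n)
    rhs[-1] = 1.0
    try:
        pi = np.linalg.solve(a.T, rhs)
    except np.linalg.LinAlgError as exc:
        raise ReducibleChainError(f"constrained system singular: {exc}") from exc
    return _finalize(pi, q, "dense_ge")


def _banded_pinned_solve(q: np.ndarray, k1: int, k2: int, pin: int) -> np.ndarray:
    """Fix ``pi[pin] = 1`` and solve the remaining banded balance
    equations (transposed, row/column ``pin`` deleted) for the rest."""
    n = q.shape[0]
    keep = np.arange(n) != pin
    at = q[np.ix_(keep, keep)].T  # deleting a row/column never widens the band
    m = n - 1
    lo, up = min(k2, m - 1), min(k1, m - 1)
    ab = np.zeros((lo + up + 1, m))
    for i in range(m):
        for j in range(max(0, i - lo), min(m, i + up + 1)):
            ab[up + i - j, j] = at[i, j]
    rhs = -q[pin, keep]
    try:
        y = sla.solve_banded((lo, up), ab, rhs)
    except (ValueError, np.linalg.LinAlgError) as exc:
        raise ReducibleChainError(f"banded solve failed: {exc}") from exc
    pi = np.empty(n)
    pi[keep] = y
    pi[pin] = 1.0
    return pi


def solve_banded(q, k1: int, k2: int) -> SolverResult:
    """Banded Gaussian elimination within the band ``(k1, k2)``.

    One probability is pinned to close the singular system; the
    remaining banded subsystem of the transposed balance equations is
    solved with LAPACK's banded driver and the vector renormalized.
    Pinning a state of near-zero probability is numerically hostile
    when the steady state spans many orders of magnitude, so the pin is
    chosen adaptively: start at the last state and re-pin at the
    largest-magnitude entry of the previous attempt until the solution
    is clean.  Raises :class:`InvalidBandError` if any nonzero lies
    outside the supplied band.
    """
    q = _as_matrix(q)
    n = q.shape[0]
    mk1, mk2, _ = tensor_core.bandwidth(q)
    if mk1 > k1 or mk2 > k2:
        raise InvalidBandError(
            f"band ({k1}, {k2}) too narrow: nonzeros need ({mk1}, {mk2})"
        )
    if n == 1:
        return _finalize(np.ones(1), q, "banded_ge")

    scale = np.abs(q).max()
    pin = n - 1
    tried: set[int] = set()
    best: np.ndarray | None = None
    best_res = np.inf
    for _ in range(4):
        tried.add(pin)
        pi = _banded_pinned_solve(q, k1, k2, pin)
        total = pi.sum()
        if np.isfinite(total) and total > 0:
            cand = pi / total
            res = _residual(cand, q)
            clean = cand.min() >= -1e-12 and res <= 1e-10 * max(1.0, scale)
            if res < best_res:
                best, best_res = pi, res
            if clean:
                return _finalize(pi, q, "banded_ge")
        nxt = int(np.argmax(np.abs(pi)))
        if nxt in tried:
            nxt = next((j for j in (0, n // 2) if j not in tried), None)
            if nxt is None:
                break
        pin = nxt
    if best is None:
        raise ReducibleChainError("banded solve failed at every pivot state")
    return _finalize(best, q, "banded_ge")


def _check_block_tridiagonal(q: np.ndarray, slices) -> None:
    nb = len(slices)
    for bi in range(nb):
        for bj in range(nb):
            if abs(bi - bj) <= 1:
                continue
            if np.any(q[slices[bi], slices[bj]] != 0.0):
                raise UnsupportedStructureError(
                    f"nonzero entries in block ({bi}, {bj}); the generator "
                    "is not block tridiagonal under its partition"
                )


def solve_block_recursive(gen: BlockGenerator) -> SolverResult:
    """Direct block-recursive (Thomas-style) solve over equal-size blocks.

    Forward elimination expresses each block segment of ``pi`` through
    the next one (``pi_i = pi_{i+1} S_i``); the final block solves a
    small singular system and back substitution recovers the rest.  The
    sub/super-diagonal blocks of the 49-state model are diagonal
    matrices, which keeps the recursion cheap and stable.

    Only defined for an equal-block block-tridiagonal partition; the
    varying-block 28-state model raises
    :class:`UnsupportedStructureError`.
    """
    if not isinstance(gen, BlockGenerator):
        raise TypeError("solve_block_recursive needs a BlockGenerator")
    sizes = set(gen.partition)
    if len(sizes) != 1:
        raise UnsupportedStructureError(
            "block recursion requires equal block sizes; got partition "
            f"{gen.partition} (varying blocks: use banded or block "
            "Gauss-Seidel instead)"
        )
    q = gen.Q
    slices = gen.block_slices()
    _check_block_tridiagonal(q, slices)
    nb = len(slices)
    if nb < 2:
        return solve_dense(q)

    diag = [q[slices[i], slices[i]] for i in range(nb)]
    upper = [q[slices[i], slices[i + 1]] for i in range(nb - 1)]
    lower = [q[slices[i + 1], slices[i]] for i in range(nb - 1)]

    # pi_i = pi_{i+1} S_i with S_1 = -L_1 D_1^{-1} and
    # S_i = -L_i (D_i + S_{i-1} U_{i-1})^{-1}.
    s_mats: list[np.ndarray] = []
    carry = diag[0]
    for i in range(nb - 1):
        s_i = -lower[i] @ np.linalg.inv(carry)
        s_mats.append(s_i)
        if i < nb - 2:
            carry = diag[i + 1] + s_i @ upper[i]
    # last block: pi_last (D_last + S_{nb-1} U_{nb-1}) = 0
    m_last = diag[-1] + s_mats[-1] @ upper[-1]
    a = m_last.copy()
    a[:, -1] = 1.0
    rhs = np.zeros(a.shape[0])
    rhs[-1] = 1.0
    try:
        pi_last = np.linalg.solve(a.T, rhs)
    except np.linalg.LinAlgError as exc:
        raise ReducibleChainError(f"terminal block singular: {exc}") from exc

    segments = [pi_last]
    for s_i in reversed(s_mats):
        segments.append(segments[-1] @ s_i)
    pi = np.concatenate(list(reversed(segments)))
    return _finalize(pi, q, "block_recursive")


def _block_band_storage(block: np.ndarray) -> tuple[tuple[int, int], np.ndarray]:
    """Banded storage of ``block.T`` for the inner solves (Thomas algorithm
    when the block is tridiagonal)."""
    k1, k2, _ = tensor_core.bandwidth(block)
    at = block.T
    m = at.shape[0]
    lo, up = min(k2, m - 1), min(k1, m - 1)
    ab = np.zeros((lo + up + 1, m))
    for i in range(m):
        for j in range(max(0, i - lo), min(m, i + up + 1)):
            ab[up + i - j, j] = at[i, j]
    return (lo, up), ab


def solve_block_gauss_seidel(
    gen: BlockGenerator, opts: SolverOptions | None = None
) -> SolverResult:
    """Block Gauss-Seidel sweeps over the generator's block partition.

    One outer iteration sweeps the blocks in index order, solving
    ``pi_i Q_ii = -sum_{j != i} pi_j Q_ji`` against the banded diagonal
    block with already-updated segments for ``j < i``.  The iterate is
    renormalized to sum 1 after each sweep; iteration stops when all
    entries of consecutive iterates differ by less than ``epsilon``.
    """
    if not isinstance(gen, BlockGenerator):
        raise TypeError("solve_block_gauss_seidel needs a BlockGenerator")
    opts = opts or SolverOptions(method="block_gauss_seidel")
    q = gen.Q
    n = q.shape[0]
    slices = gen.block_slices()
    nb = len(slices)

    inner = [_block_band_storage(q[s, s]) for s in slices]
    # nonzero off-diagonal block columns feeding each block's inner system
    feeders: list[list[int]] = []
    for i in range(nb):
        feeders.append(
            [
                j
                for j in range(nb)
                if j != i and np.any(q[slices[j], slices[i]] != 0.0)
            ]
        )

    pi = (
        np.asarray(opts.initial_vector, dtype=float).copy()
        if opts.initial_vector is not None
        else np.full(n, 1.0 / n)
    )
    converged = False
    history: list[float] = []
    outer = 0
    for outer in range(1, opts.max_outer_iterations + 1):
        pi_old = pi.copy()
        for i in range(nb):
            rhs = np.zeros(slices[i].stop - slices[i].start)
            for j in feeders[i]:
                rhs -= pi[slices[j]] @ q[slices[j], slices[i]]
            (lo, up), ab = inner[i]
            pi[slices[i]] = sla.solve_banded((lo, up), ab, rhs)
        total = pi.sum()
        if not np.isfinite(total) or total == 0.0:
            raise ReducibleChainError("Gauss-Seidel iterate degenerated")
        pi /= total
        history.append(_residual(pi, q))
        if convergence_check(pi, pi_old, opts.epsilon):
            converged = True
            break
    pi = pi / pi.sum()
    return SolverResult(
        pi=pi,
        outer_iterations=outer,
        residual=_residual(pi, q),
        converged=converged,
        method="block_gauss_seidel",
        residual_history=history,
    )


def convergence_check(pi_new, pi_old, epsilon: float) -> bool:
    """True iff consecutive iterates differ by less than ``epsilon`` in
    every entry (max absolute entrywise difference)."""
    pi_new = np.asarray(pi_new, dtype=float)
    pi_old = np.asarray(pi_old, dtype=float)
    if pi_new.shape != pi_old.shape:
        raise ValueError(
            f"iterate length mismatch: {pi_new.shape} vs {pi_old.shape}"
        )
    return bool(np.max(np.abs(pi_new - pi_old)) < epsilon)


def solve_steady_state(gen, opts: SolverOptions | None = None) -> SolverResult:
    """Dispatch to the solver named in ``opts.method``."""
    opts = opts or SolverOptions()
    if opts.method == "dense_ge":
        return solve_dense(gen)
    if opts.method == "banded_ge":
        if isinstance(gen, BlockGenerator):
            k1, k2, _ = gen.bandwidth
        else:
            k1, k2, _ = tensor_core.bandwidth(_as_matrix(gen))
        return solve_banded(gen, k1, k2)
    if opts.method == "block_recursive":
        return solve_block_recursive(gen)
    return solve_block_gauss_seidel(gen, opts)


def group_inverse(q) -> np.ndarray:
    """Group inverse ``Q#`` of an irreducible generator.

    With ``W = 1 pi`` (the rank-one projector onto the stationary
    direction), ``Q# = (Q + W)^{-1} - W``; it satisfies the defining
    identities ``Q Q# Q = Q``, ``Q# Q Q# = Q#`` and ``Q Q# = Q# Q =
    I - W``, and enters the steady-state perturbation bound
    ``||dpi|| / ||pi|| <= ||Q#|| * ||dQ||``.
    """
    q = _as_matrix(q)
    pi = solve_dense(q).pi  # raises ReducibleChainError when reducible
    w = np.outer(np.ones(q.shape[0]), pi)
    return np.linalg.inv(q + w) - w
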
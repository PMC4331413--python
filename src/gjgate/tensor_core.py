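"""Kronecker-algebra primitives for stochastic automata networks (SANs).

A SAN describes a large continuous-time Markov chain compositionally: the
system is split into small interacting automata, and the global
infinitesimal generator is a Kronecker-algebra expression over the local
generators.  For fully independent automata the global generator is the
plain Kronecker sum; when transition rates depend on the global state
("functional" rates) the composition generalizes — each transition still
moves exactly one automaton, but its rate is evaluated at the current
global state.

This module is deliberately free of biophysics.  Local automata carry
opaque string rate labels, and a caller-supplied :data:`RateFunction`
resolves a ``(label, global_state)`` pair to a nonnegative rate, including
any state-dependent multiplicity.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "LocalAutomaton",
    "RateFunction",
    "ModelEvaluationError",
    "kron_product",
    "kron_sum",
    "product_state_space",
    "assemble_functional_generator",
    "bandwidth",
]

#: Resolves (rate_label, global_state_tuple) -> nonnegative rate (1/time).
RateFunction = Callable[[str, tuple[int, ...]], float]


class ModelEvaluationError(ValueError):
    """A rate function returned a negative or non-finite value."""


@dataclass(frozen=True)
class LocalAutomaton:
    """One component Markov automaton of a SAN.

    Parameters
    ----------
    n_states
        Number of local states, indexed ``0 .. n_states-1``.
    transitions
        ``(from_index, to_index, rate_label)`` triples.  Self-transitions
        are not listed; the diagonal of any generator built from the
        automaton is derived as the negated off-diagonal row sum.
    """

    n_states: int
    transitions: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        if self.n_states <= 0:
            raise ValueError("automaton needs at least one state")
        for frm, to, label in self.transitions:
            if not (0 <= frm < self.n_states and 0 <= to < self.n_states):
                raise ValueError(
                    f"transition ({frm}, {to}, {label!r}) outside state range "
                    f"[0, {self.n_states})"
                )
            if frm == to:
                raise ValueError(f"self-transition listed at state {frm}")

    def outgoing(self) -> dict[int, list[tuple[int, str]]]:
        """Adjacency view: local state -> list of (target, label)."""
        adj: dict[int, list[tuple[int, str]]] = defaultdict(list)
        for frm, to, label in self.transitions:
            adj[frm].append((to, label))
        return dict(adj)


def kron_product(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Kronecker product ``A (x) B``: block (i, j) equals ``a_ij * B``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("Kronecker product of an empty matrix is undefined")
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("operands must be 2-D matrices")
    return np.kron(a, b)


def kron_sum(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Kronecker sum ``A (+) B = A (x) I_n + I_m (x) B`` of square matrices.

    For infinitesimal generators of independent automata this is exactly
    the generator of the joint chain; zero row sums are preserved.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for name, m in (("A", a), ("B", b)):
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.size == 0:
            raise ValueError(f"operand {name} must be square and nonempty")
    return np.kron(a, np.eye(b.shape[0])) + np.kron(np.eye(a.shape[0]), b)


def product_state_space(
    automata: Sequence[LocalAutomaton],
) -> list[tuple[int, ...]]:
    """Lexicographic product state space; the first automaton is the slow
    index, so its blocks appear contiguously in the global ordering."""
    return list(itertools.product(*(range(a.n_states) for a in automata)))


def assemble_functional_generator(
    automata: Sequence[LocalAutomaton],
    rates: RateFunction,
    ordering: Iterable[tuple[int, ...]] | None = None,
) -> np.ndarray:
    """Materialize the global generator of a SAN with functional rates.

    Every listed local transition contributes the entry
    ``Q[s, s'] += rates(label, s)`` where ``s'`` differs from the global
    state ``s`` only in the moving automaton's component.  Diagonal
    entries are the negated off-diagonal row sums, so every row sums to
    zero by construction.  With a rate function that ignores the global
    state the result coincides with the Kronecker sum of the local
    generators.

    Parameters
    ----------
    automata
        The component automata, slowest index first.
    rates
        Resolves ``(label, global_state)`` to a nonnegative rate.
    ordering
        Optional enumeration of the full product state space (tuples of
        local indices).  Defaults to lexicographic order with the first
        automaton slow.
    """
    automata = list(automata)
    if not automata:
        raise ValueError("need at least one automaton")
    full = product_state_space(automata)
    if ordering is None:
        states = full
    else:
        states = [tuple(s) for s in ordering]
        if len(states) != len(full) or set(states) != set(full):
            raise ValueError(
                "ordering must enumerate the full product state space "
                f"({len(full)} states) exactly once"
            )
    index = {s: i for i, s in enumerate(states)}
    adjacency = [a.outgoing() for a in automata]

    n = len(states)
    q = np.zeros((n, n))
    for s in states:
        i = index[s]
        for k, adj in enumerate(adjacency):
            for to, label in adj.get(s[k], ()):
                rate = float(rates(label, s))
                if not np.isfinite(rate) or rate < 0.0:
                    raise ModelEvaluationError(
                        f"rate function returned {rate!r} for label "
                        f"{label!r} at global state {s}"
                    )
                target = list(s)
                target[k] = to
                q[i, index[tuple(target)]] += rate
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def bandwidth(q: np.ndarray) -> tuple[int, int, int]:
    """Smallest half-bandwidths ``(k1, k2)`` and bandwidth ``m = k1+k2+1``.

    ``k1`` (``k2``) is the largest sub- (super-) diagonal offset holding a
    nonzero entry; a diagonal matrix measures ``(0, 0, 1)`` and a
    tridiagonal one ``(1, 1, 3)``.
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1]:
        raise ValueError("bandwidth is defined for square matrices")
    rows, cols = np.nonzero(q)
    if rows.size == 0:
        return 0, 0, 1
    offsets = cols - rows
    k1 = int(max(0, -offsets.min()))
    k2 = int(max(0, offsets.max()))
    return k1, k2, k1 + k2 + 1
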
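"""State-space enumeration and generator assembly for the GJ model variants.

Three channel models are supported, named by subgate count and subgate
state count:

``two_state_12``
    Both hemichannels gate; each of the 12 subgates is two-state (o/c).
    Lumping identical subgates by closed count gives two 7-state
    automata and a 49-state chain, partitioned into 7 blocks of 7 by the
    left closed count.  Off-diagonal blocks are diagonal matrices, so
    the generator is block tridiagonal with bandwidth 15.
``three_state_6``
    Only the left hemichannel gates (the right stays fully open); each
    of its 6 subgates is three-state (o/c/d).  States are (n_o, n_c)
    pairs with n_o + n_c <= 6 — 28 states in blocks of sizes 7..1 by
    ascending open count.
``three_state_12``
    Both hemichannels gate with three-state subgates: 28^2 = 784 states
    in 28 blocks of 28, a five-layer block structure.

All transition rates are *functional*: each global state determines a
voltage division across the two series hemichannels, and the Boltzmann
rates of a hemichannel are evaluated at its own voltage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from . import tensor_core
from .gating import (
    GatingParams,
    VoltageSplit,
    _right_voltage,
    solve_voltage_division,
    subgate_rates,
)

__all__ = [
    "TWO_STATE_12",
    "THREE_STATE_6",
    "THREE_STATE_12",
    "MODEL_KINDS",
    "StateSpace",
    "BlockGenerator",
    "UnsupportedRegimeError",
    "enumerate_states",
    "hemichannel_transitions",
    "build_generator",
    "lump_full_subgate_model",
    "LumpingComparison",
    "birth_death_generator",
    "is_irreducible",
    "export_triplets",
]

TWO_STATE_12 = "two_state_12"
THREE_STATE_6 = "three_state_6"
THREE_STATE_12 = "three_state_12"
MODEL_KINDS = (TWO_STATE_12, THREE_STATE_6, THREE_STATE_12)

#: CLI-friendly aliases.
KIND_ALIASES = {
    "two12": TWO_STATE_12,
    "three6": THREE_STATE_6,
    "three12": THREE_STATE_12,
}


class UnsupportedRegimeError(ValueError):
    """Operation requested outside the regime where it is exact."""


def _three_state_local_states() -> list[tuple[int, int]]:
    # Blocks by ascending open count; closed count ascending within block.
    return [(n_o, n_c) for n_o in range(7) for n_c in range(7 - n_o)]


@dataclass(frozen=True)
class StateSpace:
    """Ordered global state enumeration with its block partition.

    ``states`` holds semantic states: ``(n_l, n_r)`` closed-count pairs
    for ``two_state_12``, ``(n_o, n_c)`` tuples for ``three_state_6``
    and pairs of such tuples for ``three_state_12``.  ``block_sizes``
    partitions the ordering into the diagonal blocks used by the block
    solvers.
    """

    kind: str
    states: tuple
    block_sizes: tuple[int, ...]
    index_of: dict = field(repr=False, hash=False, compare=False)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def hemichannel_pairs(self) -> list[tuple]:
        """Per-state (left_state, right_state) pairs for conductance
        evaluation; the non-gating right hemichannel of ``three_state_6``
        is the fully open (6, 0) state."""
        if self.kind == TWO_STATE_12:
            return [(n_l, n_r) for n_l, n_r in self.states]
        if self.kind == THREE_STATE_6:
            return [(s, (6, 0)) for s in self.states]
        return [(left, right) for left, right in self.states]


def enumerate_states(kind: str) -> StateSpace:
    """Enumerate the global states of a model variant in block order."""
    kind = KIND_ALIASES.get(kind, kind)
    if kind == TWO_STATE_12:
        states = [(n_l, n_r) for n_l in range(7) for n_r in range(7)]
        block_sizes = (7,) * 7
    elif kind == THREE_STATE_6:
        states = _three_state_local_states()
        block_sizes = (7, 6, 5, 4, 3, 2, 1)
    elif kind == THREE_STATE_12:
        local = _three_state_local_states()
        states = [(left, right) for left in local for right in local]
        block_sizes = (28,) * 28
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return StateSpace(
        kind=kind,
        states=tuple(states),
        block_sizes=block_sizes,
        index_of={s: i for i, s in enumerate(states)},
    )


def hemichannel_transitions(state, kind: str) -> list[tuple]:
    """Moves of one hemichannel automaton: (target, rate_label, multiplicity).

    Two-state subgates (``state`` = closed count ``n``): ``n -> n-1``
    at ``n * lambda_co`` and ``n -> n+1`` at ``(6-n) * lambda_oc``.
    Three-state subgates (``state`` = ``(n_o, n_c)``): a closed subgate
    reopens (co) or sinks deeper (cd), an open one closes (oc), a deep
    one resurfaces (dc); multiplicities are the respective subgate
    counts.  Moves with zero multiplicity are omitted.
    """
    kind = KIND_ALIASES.get(kind, kind)
    if kind == TWO_STATE_12:
        n = int(state)
        if not 0 <= n <= 6:
            raise ValueError(f"closed count out of range: {state}")
        moves = []
        if n >= 1:
            moves.append((n - 1, "co", n))
        if n <= 5:
            moves.append((n + 1, "oc", 6 - n))
        return moves
    if kind in (THREE_STATE_6, THREE_STATE_12):
        n_o, n_c = state
        n_d = 6 - n_o - n_c
        if n_o < 0 or n_c < 0 or n_d < 0:
            raise ValueError(f"invalid three-state hemichannel state {state}")
        moves = []
        if n_c >= 1:
            moves.append(((n_o + 1, n_c - 1), "co", n_c))
        if n_o >= 1:
            moves.append(((n_o - 1, n_c + 1), "oc", n_o))
        if n_d >= 1:
            moves.append(((n_o, n_c + 1), "dc", n_d))
        if n_c >= 1:
            moves.append(((n_o, n_c - 1), "cd", n_c))
        return moves
    raise ValueError(f"unknown model kind {kind!r}")


@dataclass
class BlockGenerator:
    """Materialized global generator with its block partition metadata."""

    Q: np.ndarray
    partition: tuple[int, ...]
    bandwidth: tuple[int, int, int]
    state_space: StateSpace
    voltage_splits: list[VoltageSplit]
    params_left: GatingParams | None = None
    params_right: GatingParams | None = None
    vj: float = 0.0
    antiparallel: bool = True

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    def block_slices(self) -> list[slice]:
        bounds = np.concatenate(([0], np.cumsum(self.partition)))
        return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


class _FunctionalRates:
    """Resolves (label, global index tuple) -> rate, caching voltage splits.

    Labels are ``"l.oc"``-style: hemichannel side dot transition kind.
    The rate is the per-subgate Boltzmann rate at that hemichannel's
    voltage times the multiplicity of subgates able to make the move.
    """

    def __init__(self, kind, params_left, params_right, vj, antiparallel):
        self.kind = kind
        self.params_left = params_left
        self.params_right = params_right
        self.vj = vj
        self.antiparallel = antiparallel
        self.local_states = (
            list(range(7)) if kind == TWO_STATE_12
            else _three_state_local_states()
        )
        self._splits: dict[tuple[int, ...], VoltageSplit] = {}
        self._rates_cache: dict[tuple[str, float], object] = {}

    def hemichannel_states(self, gtuple: tuple[int, ...]):
        left = self.local_states[gtuple[0]]
        if self.kind == THREE_STATE_6:
            right = (6, 0)
        else:
            right = self.local_states[gtuple[1]]
        return left, right

    def split(self, gtuple: tuple[int, ...]) -> VoltageSplit:
        cached = self._splits.get(gtuple)
        if cached is None:
            left, right = self.hemichannel_states(gtuple)
            cached = solve_voltage_division(
                self.vj, left, right, self.params_left, self.params_right,
                antiparallel=self.antiparallel,
            )
            self._splits[gtuple] = cached
        return cached

    def __call__(self, label: str, gtuple: tuple[int, ...]) -> float:
        side, move = label.split(".", 1)
        split = self.split(gtuple)
        left, right = self.hemichannel_states(gtuple)
        if side == "l":
            params, v, state = self.params_left, split.v_left, left
        else:
            params = self.params_right
            v = _right_voltage(split.v_right, self.antiparallel)
            state = right
        key = (side, round(v, 12))
        rates = self._rates_cache.get(key)
        if rates is None:
            rates = subgate_rates(params, v)
            self._rates_cache[key] = rates
        if isinstance(state, tuple):
            n_o, n_c = state
            mult = {"co": n_c, "oc": n_o, "dc": 6 - n_o - n_c, "cd": n_c}[move]
        else:
            mult = {"co": state, "oc": 6 - state}[move]
        lam = getattr(rates, f"lambda_{move}")
        return mult * lam


def _local_automaton(side: str, kind: str) -> tensor_core.LocalAutomaton:
    if kind == TWO_STATE_12:
        local = list(range(7))
    else:
        local = _three_state_local_states()
    index = {s: i for i, s in enumerate(local)}
    sub_kind = TWO_STATE_12 if kind == TWO_STATE_12 else THREE_STATE_6
    transitions = []
    for s in local:
        for target, label, _mult in hemichannel_transitions(s, sub_kind):
            transitions.append((index[s], index[target], f"{side}.{label}"))
    return tensor_core.LocalAutomaton(len(local), tuple(transitions))


def build_generator(
    kind: str,
    params_left: GatingParams,
    params_right: GatingParams,
    vj: float,
    *,
    antiparallel: bool = True,
) -> BlockGenerator:
    """Assemble the global infinitesimal generator of a model variant.

    For every global state the transjunctional voltage is divided across
    the two hemichannels (cached per state), and each hemichannel's
    transition rates are evaluated at its own voltage.  The result is
    materialized as a dense matrix with block-partition and bandwidth
    metadata attached.
    """
    kind = KIND_ALIASES.get(kind, kind)
    space = enumerate_states(kind)
    if kind in (THREE_STATE_6, THREE_STATE_12):
        for name, p in (("left", params_left), ("right", params_right)):
            if p.deep is None and not (kind == THREE_STATE_6 and name == "right"):
                raise ValueError(
                    f"three-state models need deep-state parameters on the "
                    f"{name} hemichannel"
                )
    if kind == THREE_STATE_6:
        automata = [_local_automaton("l", kind)]
    else:
        automata = [_local_automaton("l", kind), _local_automaton("r", kind)]
    rates = _FunctionalRates(kind, params_left, params_right, vj, antiparallel)
    q = tensor_core.assemble_functional_generator(automata, rates)
    # Global tuples in assembly order == enumeration order of the space.
    if kind == THREE_STATE_6:
        gtuples = [(i,) for i in range(space.n_states)]
    elif kind == TWO_STATE_12:
        gtuples = [(l, r) for l in range(7) for r in range(7)]
    else:
        gtuples = [(l, r) for l in range(28) for r in range(28)]
    splits = [rates.split(g) for g in gtuples]
    return BlockGenerator(
        Q=q,
        partition=space.block_sizes,
        bandwidth=tensor_core.bandwidth(q),
        state_space=space,
        voltage_splits=splits,
        params_left=params_left,
        params_right=params_right,
        vj=vj,
        antiparallel=antiparallel,
    )


def birth_death_generator(lambda_oc: float, lambda_co: float) -> np.ndarray:
    """7-state closed-count birth-death generator of one hemichannel with
    constant per-subgate rates: ``n -> n+1`` at ``(6-n)*lambda_oc`` and
    ``n -> n-1`` at ``n*lambda_co``."""
    q = np.zeros((7, 7))
    for n in range(7):
        if n <= 5:
            q[n, n + 1] = (6 - n) * lambda_oc
        if n >= 1:
            q[n, n - 1] = n * lambda_co
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


@dataclass(frozen=True)
class LumpingComparison:
    """Steady states of the unlumped 4096-state subgate chain aggregated by
    closed counts, next to the lumped 49-state model's steady state."""

    n_unlumped: int
    aggregated: np.ndarray
    lumped: np.ndarray

    @property
    def max_abs_diff(self) -> float:
        return float(np.max(np.abs(self.aggregated - self.lumped)))


def _sparse_steady_state(q: sp.spmatrix) -> np.ndarray:
    n = q.shape[0]
    a = sp.lil_matrix(q.T)
    a[-1, :] = 1.0
    rhs = np.zeros(n)
    rhs[-1] = 1.0
    pi = splu(sp.csc_matrix(a)).solve(rhs)
    return pi / pi.sum()


def lump_full_subgate_model(
    params_left: GatingParams,
    vj: float = 0.0,
    params_right: GatingParams | None = None,
    *,
    antiparallel: bool = True,
    rates: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> LumpingComparison:
    """Check exact lumpability of the 12-automaton subgate chain.

    Builds the full 2^12 = 4096-state generator of 12 independent
    two-state subgates, solves its steady state, aggregates by
    (closed-count left, closed-count right), and compares with the
    lumped 49-state model solved directly.

    Exact lumpability needs state-independent rates.  With voltage
    division that holds only in the degenerate ``A = 0`` regime (rates
    then ``K/(2*tau)`` on each side); pass explicit constant per-subgate
    ``rates = ((oc_l, co_l), (oc_r, co_r))`` to exercise asymmetric
    rates.  Anything else raises :class:`UnsupportedRegimeError`.
    """
    params_right = params_right if params_right is not None else params_left
    if rates is None:
        if params_left.A != 0 or params_right.A != 0:
            raise UnsupportedRegimeError(
                "lumpability check needs state-independent rates: voltage "
                "division makes Boltzmann rates functional unless A = 0 "
                "(or pass explicit constant rates)"
            )
        rates = tuple(
            (p.K / 2.0 / p.tau, p.K / 2.0 / p.tau)
            for p in (params_left, params_right)
        )
    (oc_l, co_l), (oc_r, co_r) = rates

    def subgate_q(oc: float, co: float) -> sp.csr_matrix:
        # local state 0 = open, 1 = closed
        return sp.csr_matrix(np.array([[-oc, oc], [co, -co]]))

    def ksum(a: sp.spmatrix, b: sp.spmatrix) -> sp.csr_matrix:
        return (
            sp.kron(a, sp.identity(b.shape[0]), format="csr")
            + sp.kron(sp.identity(a.shape[0]), b, format="csr")
        )

    q_big: sp.spmatrix = subgate_q(oc_l, co_l)
    for i in range(1, 12):
        oc, co = (oc_l, co_l) if i < 6 else (oc_r, co_r)
        q_big = ksum(q_big, subgate_q(oc, co))
    pi_big = _sparse_steady_state(q_big)

    aggregated = np.zeros(49)
    for s in range(4096):
        n_l = bin((s >> 6) & 0x3F).count("1")
        n_r = bin(s & 0x3F).count("1")
        aggregated[n_l * 7 + n_r] += pi_big[s]

    q_lumped = tensor_core.kron_sum(
        birth_death_generator(oc_l, co_l), birth_death_generator(oc_r, co_r)
    )
    from .solvers import solve_dense  # local import avoids a cycle

    lumped = solve_dense(q_lumped).pi
    return LumpingComparison(4096, aggregated, lumped)


def is_irreducible(q: np.ndarray) -> bool:
    """True iff the chain with generator ``q`` is irreducible (the graph of
    positive off-diagonal entries is strongly connected)."""
    q = np.asarray(q, dtype=float)
    off = q.copy()
    np.fill_diagonal(off, 0.0)
    n_comp, _ = connected_components(
        sp.csr_matrix(off > 0), directed=True, connection="strong"
    )
    return n_comp == 1


def export_triplets(gen: BlockGenerator | np.ndarray, path: str | Path) -> None:
    """Write the nonzero generator entries as plain-text (row, col, value)."""
    q = gen.Q if isinstance(gen, BlockGenerator) else np.asarray(gen)
    rows, cols = np.nonzero(q)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("row\tcol\tvalue\n")
        for i, j in zip(rows, cols):
            fh.write(f"{i}\t{j}\t{float(q[i, j])!r}\n")
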
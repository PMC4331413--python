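"""Voltage-dependent gating biophysics of gap-junction hemichannels.

A gap-junction (GJ) channel is two hemichannels in series, each a hexamer
of connexins.  Every connexin contributes a *subgate* that switches
between an open (o) and a closed (c) state — optionally also a
deep-closed (d) state — under the voltage its hemichannel experiences.

The pieces implemented here:

* Boltzmann open<->closed transition probabilities and their conversion
  to continuous-time rates via a short time step ``tau``;
* rectified (exponentially voltage-dependent) open/closed subgate
  conductances;
* hemichannel conductance as a parallel sum of subgate conductances;
* the series voltage division across the two hemichannels, found by a
  fixed-point iteration because the circuit is nonlinear;
* the steady-state junctional conductance, a probability-weighted series
  combination over all gating states.

All voltages are in mV; rates are in 1/time with the time unit set by
``tau``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "DeepGatingParams",
    "GatingParams",
    "VoltageSplit",
    "SubgateRates",
    "transition_probabilities",
    "rates_from_probabilities",
    "subgate_conductances",
    "hemichannel_conductance",
    "solve_voltage_division",
    "junction_conductance",
    "load_params",
    "params_from_dict",
]

# exp() overflows near 710; saturate symmetrically well inside that.
_EXP_MAX = 700.0

#: Open-state conductance prefactor at zero voltage (arbitrary units).
G_OPEN_0 = 2.0
#: Closed-state (residual) conductance prefactor at zero voltage.
G_CLOSED_0 = 0.25


@dataclass(frozen=True)
class DeepGatingParams:
    """Boltzmann parameters of the closed <-> deep-closed subgate step.

    The printed model defines only the o<->c law; the c<->d step reuses
    the same functional form with its own independent parameter set.
    """

    A: float
    P: int
    K: float
    V0: float

    def __post_init__(self) -> None:
        _validate_boltzmann(self.A, self.P, self.K, "deep")


@dataclass(frozen=True)
class GatingParams:
    """Per-subgate biophysical constants of one hemichannel.

    Parameters
    ----------
    A
        Gating sensitivity to voltage (1/mV), >= 0.  ``A = 0`` is the
        degenerate voltage-insensitive regime with constant rates.
    P
        Gating polarity, +1 or -1.
    K
        Kinetic constant (dimensionless).  Scales both o->c and c->o
        probabilities equally, so it changes kinetics but cancels in the
        equilibrium ratio and leaves the steady state unchanged.
    V0
        Half-activation voltage (mV): at ``V = V0`` the o->c and c->o
        probabilities are equal (both ``K/2``).
    Ro, Rc
        Rectification constants (mV) of the open and closed subgate
        conductances; ``inf`` means no rectification.
    tau
        Time step converting transition probabilities to rates
        (``lambda = p / tau``).
    deep
        Optional parameters of the c<->d step (three-state models only).
    g_deep_policy
        Deep-state conductance rule: ``"closed"`` (conducts like the
        closed state, the default) or ``"constant"`` (fixed residual
        value ``g_deep_value``).
    """

    A: float
    P: int
    K: float
    V0: float
    Ro: float = math.inf
    Rc: float = math.inf
    tau: float = 1.0
    deep: DeepGatingParams | None = None
    g_deep_policy: str = "closed"
    g_deep_value: float = 0.0

    def __post_init__(self) -> None:
        _validate_boltzmann(self.A, self.P, self.K, "gating")
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        for name, r in (("Ro", self.Ro), ("Rc", self.Rc)):
            if r == 0 or math.isnan(r):
                raise ValueError(f"{name} must be nonzero (inf = none)")
        if self.g_deep_policy not in ("closed", "constant"):
            raise ValueError(f"unknown g_deep_policy {self.g_deep_policy!r}")

    def with_deep(self, deep: DeepGatingParams) -> "GatingParams":
        return replace(self, deep=deep)


def _validate_boltzmann(a: float, p: int, k: float, what: str) -> None:
    if a < 0 or not math.isfinite(a):
        raise ValueError(f"{what} sensitivity A must be >= 0, got {a}")
    if p not in (-1, 1):
        raise ValueError(f"{what} polarity P must be +1 or -1, got {p}")
    if not (k > 0 and math.isfinite(k)):
        raise ValueError(f"{what} kinetic constant K must be > 0, got {k}")


@dataclass(frozen=True)
class VoltageSplit:
    """Series voltage division across the two hemichannels.

    ``v_left + v_right`` equals the transjunctional voltage by
    construction.  ``iterations`` counts fixed-point steps (>= 1);
    ``converged`` reports whether the 0.1 % relative tolerance was met
    before the iteration cap.
    """

    v_left: float
    v_right: float
    iterations: int
    converged: bool


@dataclass(frozen=True)
class SubgateRates:
    """Per-subgate transition rates (1/time) at a given voltage."""

    lambda_oc: float
    lambda_co: float
    lambda_cd: float = 0.0
    lambda_dc: float = 0.0


def transition_probabilities(params, v: float) -> tuple[float, float]:
    """Boltzmann o->c and c->o transition probabilities at voltage ``v``.

    With ``k = exp(A*P*(v - V0))`` the probabilities are
    ``p_oc = K*k/(1+k)`` and ``p_co = K/(1+k)``; both lie in ``(0, K)``
    and their ratio is exactly ``k`` (``K`` cancels at equilibrium).
    Overflow of the exponential saturates to the limits ``(K, 0)`` /
    ``(0, K)``.

    ``params`` may be a :class:`GatingParams` or a
    :class:`DeepGatingParams` (any object with ``A, P, K, V0``).
    """
    x = params.A * params.P * (v - params.V0)
    if x > _EXP_MAX:
        return params.K, 0.0
    if x < -_EXP_MAX:
        return 0.0, params.K
    k = math.exp(x)
    return params.K * k / (1.0 + k), params.K / (1.0 + k)


def rates_from_probabilities(p: float, tau: float) -> float:
    """Convert a short-step transition probability to a CTMC rate ``p/tau``."""
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if p < 0:
        raise ValueError(f"probability must be nonnegative, got {p}")
    return p / tau


def subgate_conductances(params: GatingParams, v: float) -> tuple[float, float]:
    """Rectified open and closed subgate conductances at voltage ``v``.

    ``g_o = 2*exp(P*v/Ro)`` and ``g_c = 0.25*exp(P*v/Rc)``; an infinite
    rectification constant yields the flat prefactor at every voltage.
    """
    return (
        G_OPEN_0 * _rectify(params.P * v, params.Ro),
        G_CLOSED_0 * _rectify(params.P * v, params.Rc),
    )


def _rectify(pv: float, r: float) -> float:
    if math.isinf(r):
        return 1.0
    x = pv / r
    if x > _EXP_MAX:
        x = _EXP_MAX
    elif x < -_EXP_MAX:
        x = -_EXP_MAX
    return math.exp(x)


def subgate_rates(params: GatingParams, v: float) -> SubgateRates:
    """All per-subgate rates at voltage ``v`` (c<->d only if ``deep`` set)."""
    p_oc, p_co = transition_probabilities(params, v)
    lam_oc = rates_from_probabilities(p_oc, params.tau)
    lam_co = rates_from_probabilities(p_co, params.tau)
    lam_cd = lam_dc = 0.0
    if params.deep is not None:
        p_cd, p_dc = transition_probabilities(params.deep, v)
        lam_cd = rates_from_probabilities(p_cd, params.tau)
        lam_dc = rates_from_probabilities(p_dc, params.tau)
    return SubgateRates(lam_oc, lam_co, lam_cd, lam_dc)


def hemichannel_conductance(state, params: GatingParams, v: float) -> float:
    """Parallel conductance of the six subgates of one hemichannel.

    ``state`` is either the closed-subgate count ``n`` in ``0..6``
    (two-state subgates: ``n*g_c + (6-n)*g_o``) or an ``(n_o, n_c)``
    tuple with ``n_o + n_c <= 6`` (three-state subgates, the remaining
    ``6 - n_o - n_c`` subgates deep-closed with conductance set by
    ``g_deep_policy``).
    """
    g_o, g_c = subgate_conductances(params, v)
    if isinstance(state, tuple):
        n_o, n_c = state
        n_d = 6 - n_o - n_c
        if n_o < 0 or n_c < 0 or n_d < 0:
            raise ValueError(f"invalid three-state hemichannel state {state}")
        g_d = g_c if params.g_deep_policy == "closed" else params.g_deep_value
        return n_o * g_o + n_c * g_c + n_d * g_d
    n = int(state)
    if not 0 <= n <= 6:
        raise ValueError(f"closed-subgate count must be in 0..6, got {state}")
    return n * g_c + (6 - n) * g_o


def _right_voltage(v_right: float, antiparallel: bool) -> float:
    # Docked hemichannels face each other, so by default the right one
    # senses the voltage across it with opposite sign.
    return -v_right if antiparallel else v_right


def solve_voltage_division(
    vj: float,
    left_state,
    right_state,
    params_left: GatingParams,
    params_right: GatingParams,
    *,
    antiparallel: bool = True,
    rtol: float = 1e-3,
    max_iter: int = 100,
    damping: float = 0.5,
) -> VoltageSplit:
    """Divide ``vj`` across the two series hemichannels at a gating state.

    Solves the fixed point ``v_left = vj * g_right / (g_left + g_right)``
    with both conductances evaluated at the voltages being solved for
    (damped fixed-point iteration).  The iteration stops when the
    relative change of both voltages between consecutive iterations is
    below ``rtol`` (default 0.1 %), or at ``max_iter`` with
    ``converged=False`` and a warning.

    At the fixed point the series current balances:
    ``v_left * g_left == v_right * g_right``.
    """
    if not math.isfinite(vj):
        raise ValueError(f"transjunctional voltage must be finite, got {vj}")
    if vj == 0.0:
        return VoltageSplit(0.0, 0.0, 1, True)

    v_left = vj / 2.0
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        v_right = vj - v_left
        g_left = hemichannel_conductance(left_state, params_left, v_left)
        g_right = hemichannel_conductance(
            right_state, params_right, _right_voltage(v_right, antiparallel)
        )
        total = g_left + g_right
        if total <= 0.0:
            v_target = vj / 2.0  # both hemichannels blocked: degenerate split
        else:
            v_target = vj * g_right / total
        step = v_target - v_left
        v_new = v_left + damping * step
        # Undamped update measures the distance of the map, i.e. the
        # change a full fixed-point iteration would make.
        scale_l = max(abs(v_target), abs(v_new), 1e-300)
        scale_r = max(abs(vj - v_target), abs(vj - v_new), 1e-300)
        if abs(step) <= rtol * scale_l and abs(step) <= rtol * scale_r:
            v_left = v_target
            converged = True
            break
        v_left = v_new
    if not converged:
        import warnings

        warnings.warn(
            f"voltage division did not converge in {max_iter} iterations "
            f"(vj={vj}, states={left_state}/{right_state})",
            RuntimeWarning,
            stacklevel=2,
        )
    return VoltageSplit(v_left, vj - v_left, iterations, converged)


def junction_conductance(
    pi: Sequence[float],
    state_pairs: Iterable[tuple],
    params_left: GatingParams,
    params_right: GatingParams,
    vj: float,
    *,
    antiparallel: bool = True,
    splits: Sequence[VoltageSplit] | None = None,
) -> float:
    """Steady-state junctional conductance ``g_j``.

    ``g_j = sum_i pi_i * g_left,i * g_right,i / (g_left,i + g_right,i)``
    with each term evaluated at that state's own voltage split.  Pass
    ``splits`` (aligned with ``pi``) to reuse cached voltage divisions;
    otherwise they are recomputed.  States where both hemichannels have
    ~zero conductance contribute nothing.
    """
    pairs = list(state_pairs)
    if len(pairs) != len(pi):
        raise ValueError("pi and state_pairs must have equal length")
    total_p = float(sum(pi))
    if abs(total_p - 1.0) > 1e-9:
        raise ValueError(f"pi must sum to 1 (got {total_p!r})")
    g_total = 0.0
    for i, (p, (left_state, right_state)) in enumerate(zip(pi, pairs)):
        split = (
            splits[i]
            if splits is not None
            else solve_voltage_division(
                vj, left_state, right_state, params_left, params_right,
                antiparallel=antiparallel,
            )
        )
        g_left = hemichannel_conductance(left_state, params_left, split.v_left)
        g_right = hemichannel_conductance(
            right_state, params_right,
            _right_voltage(split.v_right, antiparallel),
        )
        denom = g_left + g_right
        if denom > 1e-300:
            g_total += p * g_left * g_right / denom
    return g_total


# ---------------------------------------------------------------------------
# Parameter I/O: flat key-value config (YAML), dotted or nested deep keys.

_DEEP_KEYS = {"A", "P", "K", "V0"}


def params_from_dict(data: dict) -> GatingParams:
    """Build :class:`GatingParams` from a flat mapping.

    Accepts top-level keys ``A, P, K, V0, Ro, Rc, tau, g_deep_policy,
    g_deep_value`` and deep-state parameters either as dotted keys
    (``deep.A`` ...) or a nested ``deep:`` mapping.
    """
    data = dict(data)
    deep_data: dict[str, float] = {}
    nested = data.pop("deep", None)
    if isinstance(nested, dict):
        deep_data.update(nested)
    for key in list(data):
        if key.startswith("deep."):
            deep_data[key.split(".", 1)[1]] = data.pop(key)
    kwargs = {}
    for key in ("A", "K", "V0", "Ro", "Rc", "tau", "g_deep_value"):
        if key in data:
            kwargs[key] = float(data.pop(key))
    if "P" in data:
        kwargs["P"] = int(data.pop("P"))
    if "g_deep_policy" in data:
        kwargs["g_deep_policy"] = str(data.pop("g_deep_policy"))
    if data:
        raise ValueError(f"unknown gating parameter keys: {sorted(data)}")
    if deep_data:
        extra = set(deep_data) - _DEEP_KEYS
        if extra:
            raise ValueError(f"unknown deep parameter keys: {sorted(extra)}")
        kwargs["deep"] = DeepGatingParams(
            A=float(deep_data["A"]),
            P=int(deep_data.get("P", 1)),
            K=float(deep_data["K"]),
            V0=float(deep_data["V0"]),
        )
    return GatingParams(**kwargs)


def load_params(path: str | Path) -> GatingParams:
    """Read gating parameters from a flat key-value YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of parameter keys")
    return params_from_dict(data)
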
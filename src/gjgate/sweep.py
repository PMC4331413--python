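"""Voltage-sweep driver: steady-state g_j-V_j curves and warm starts.

Computes the junctional conductance of a GJ model over a grid of
transjunctional voltages.  With an iterative solver, each grid point can
either restart from the uniform vector (cold start, "Method I") or reuse
the previous grid point's solution as the initial iterate (warm start,
"Method II") — steady states at nearby voltages are close because the
generator perturbation is small, so warm starts cut outer iterations
without changing the solution.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gating import DeepGatingParams, GatingParams, junction_conductance
from .models import KIND_ALIASES, build_generator
from .solvers import SolverOptions, solve_steady_state

__all__ = [
    "SweepConfig",
    "SweepRecord",
    "SweepResult",
    "run_sweep",
    "generate_fixture_params",
    "default_params",
    "write_results",
    "read_results",
]

#: Reuse the previous solution only across small voltage increments.
WARM_START_MAX_STEP_MV = 1.0


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of one voltage sweep.

    The grid runs from ``v_start`` to ``v_end`` in steps of ``v_step``
    (the step must tile the interval exactly).  ``warm_start`` selects
    Method II for iterative solvers; direct solvers ignore it.
    """

    model_kind: str
    params_left: GatingParams
    params_right: GatingParams
    v_start: float = 0.0
    v_end: float = 100.0
    v_step: float = 0.1
    method: str = "block_gauss_seidel"
    epsilon: float = 1e-6
    warm_start: bool = True
    antiparallel: bool = True
    seed: int = 0

    def grid(self) -> np.ndarray:
        if self.v_step <= 0:
            raise ValueError("v_step must be positive")
        span = self.v_end - self.v_start
        count = span / self.v_step
        if abs(count - round(count)) > 1e-9:
            raise ValueError(
                f"v_step {self.v_step} does not tile [{self.v_start}, "
                f"{self.v_end}] exactly"
            )
        k = int(round(count))
        return np.round(self.v_start + self.v_step * np.arange(k + 1), 9)


@dataclass(frozen=True)
class SweepRecord:
    vj_mv: float
    gj: float
    gj_normalized: float
    outer_iterations: int
    residual: float
    converged: bool


@dataclass
class SweepResult:
    """Per-voltage conductance records plus summed solver effort."""

    records: list[SweepRecord]
    totals: dict[str, float] = field(default_factory=dict)
    all_converged: bool = True

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])


def run_sweep(config: SweepConfig) -> SweepResult:
    """Sweep the voltage grid, solving the steady state at every point.

    Returns per-voltage junctional conductance (raw and normalized to
    the grid point nearest 0 mV), solver iteration counts and residuals.
    Non-converged solves are recorded and the sweep continues.
    """
    kind = KIND_ALIASES.get(config.model_kind, config.model_kind)
    grid = config.grid()
    iterative = config.method == "block_gauss_seidel"

    raw: list[tuple[float, float, int, float, bool]] = []
    prev_pi = None
    prev_v = None
    for vj in grid:
        gen = build_generator(
            kind, config.params_left, config.params_right, float(vj),
            antiparallel=config.antiparallel,
        )
        initial = None
        if (
            iterative
            and config.warm_start
            and prev_pi is not None
            and abs(vj - prev_v) <= WARM_START_MAX_STEP_MV
        ):
            initial = prev_pi
        opts = SolverOptions(
            method=config.method,
            epsilon=config.epsilon,
            initial_vector=initial,
        )
        res = solve_steady_state(gen, opts)
        gj = junction_conductance(
            res.pi,
            gen.state_space.hemichannel_pairs(),
            config.params_left,
            config.params_right,
            float(vj),
            antiparallel=config.antiparallel,
            splits=gen.voltage_splits,
        )
        raw.append((float(vj), gj, res.outer_iterations, res.residual,
                    res.converged))
        prev_pi, prev_v = res.pi, vj

    norm_idx = int(np.argmin(np.abs(grid)))
    g_ref = raw[norm_idx][1]
    records = [
        SweepRecord(
            vj_mv=v,
            gj=g,
            gj_normalized=g / g_ref if g_ref != 0 else np.nan,
            outer_iterations=it,
            residual=r,
            converged=c,
        )
        for v, g, it, r, c in raw
    ]
    totals = {
        "outer_iterations": int(sum(r.outer_iterations for r in records)),
        "points": len(records),
    }
    return SweepResult(
        records=records,
        totals=totals,
        all_converged=all(r.converged for r in records),
    )


def default_params(three_state: bool = False) -> GatingParams:
    """Shipped synthetic homotypic parameter set (not fitted to any
    recording).  Rates land in the 1e-3..1e-2 magnitude band typical of
    these models; mild rectification; half-activation at 30 mV."""
    deep = (
        DeepGatingParams(A=0.04, P=1, K=0.004, V0=50.0)
        if three_state
        else None
    )
    return GatingParams(
        A=0.04, P=1, K=0.008, V0=30.0, Ro=200.0, Rc=100.0, tau=1.0, deep=deep
    )


def generate_fixture_params(
    seed: int, three_state: bool = False
) -> tuple[GatingParams, GatingParams]:
    """Reproducible random homotypic parameter set for a given seed.

    Draws sensitivity A in [0.01, 0.1] /mV, half-activation V0 in
    [10, 60] mV, kinetic constant K in [0.005, 0.02] (so generator
    entries average in the 1e-4..1e-1 band at |Vj| <= 100 mV) and mild
    rectification constants.  The same set is returned for both
    hemichannels.
    """
    rng = np.random.default_rng(seed)
    deep = (
        DeepGatingParams(
            A=float(rng.uniform(0.01, 0.1)),
            P=1,
            K=float(rng.uniform(0.002, 0.01)),
            V0=float(rng.uniform(30.0, 70.0)),
        )
        if three_state
        else None
    )
    params = GatingParams(
        A=float(rng.uniform(0.01, 0.1)),
        P=1,
        K=float(rng.uniform(0.005, 0.02)),
        V0=float(rng.uniform(10.0, 60.0)),
        Ro=float(rng.uniform(100.0, 500.0)),
        Rc=float(rng.uniform(50.0, 300.0)),
        tau=1.0,
        deep=deep,
    )
    return params, params


_CSV_COLUMNS = [
    "vj_mv", "gj", "gj_normalized", "outer_iterations", "residual", "converged"
]


def write_results(
    result: SweepResult, path: str | Path, format: str = "csv"
) -> None:
    """Export a sweep to CSV (fixed column order) or JSON (full record
    structure plus totals); values round-trip at full float precision."""
    path = Path(path)
    if format == "csv":
        frame = result.as_frame()
        if frame.empty:
            frame = pd.DataFrame(columns=_CSV_COLUMNS)
        frame[_CSV_COLUMNS].to_csv(path, index=False, float_format="%.17g")
    elif format == "json":
        payload = {
            "records": [asdict(r) for r in result.records],
            "totals": result.totals,
            "all_converged": result.all_converged,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"format must be 'csv' or 'json', got {format!r}")


def read_results(path: str | Path, format: str = "csv") -> SweepResult:
    """Load a sweep written by :func:`write_results`."""
    path = Path(path)
    if format == "csv":
        frame = pd.read_csv(path)
        records = [
            SweepRecord(
                vj_mv=float(r.vj_mv),
                gj=float(r.gj),
                gj_normalized=float(r.gj_normalized),
                outer_iterations=int(r.outer_iterations),
                residual=float(r.residual),
                converged=bool(r.converged),
            )
            for r in frame.itertuples()
        ]
        totals = {
            "outer_iterations": int(sum(r.outer_iterations for r in records)),
            "points": len(records),
        }
        return SweepResult(
            records=records,
            totals=totals,
            all_converged=all(r.converged for r in records),
        )
    if format == "json":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        records = [SweepRecord(**r) for r in payload["records"]]
        return SweepResult(
            records=records,
            totals=payload["totals"],
            all_converged=payload["all_converged"],
        )
    raise ValueError(f"format must be 'csv' or 'json', got {format!r}")
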
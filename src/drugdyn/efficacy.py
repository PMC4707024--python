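"""Intervention efficacy E(t) and strategy comparisons.

The efficacy of a control strategy is the proportional reduction in active
users relative to the starting level,

    E(t) = 1 - (I(t) + Ia(t)) / (I(0) + Ia(0)),

so E(0) = 0 and E(t) = 1 at elimination.  E is bounded above by 1 but NOT
below by 0: without effective control in a supercritical regime
(R_d > 1, small initial prevalence) active use grows and E goes negative.
Only the upper bound is asserted here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .control import (
    CostWeights,
    OCProblem,
    OCSolution,
    fbsm_solve,
    objective,
    simulate_controlled,
)
from .model import Parameters, StateVector, Trajectory

__all__ = [
    "EfficacyCurve",
    "Scenario",
    "StrategyComparison",
    "efficacy_curve",
    "compare_strategies",
]


@dataclass(frozen=True)
class EfficacyCurve:
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal shape")
        if abs(self.values[0]) > 1e-12:
            raise ValueError("E(0) must be 0")
        if np.any(self.values > 1.0 + 1e-12):
            raise ValueError("E(t) cannot exceed 1")

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"t": self.times, "E": self.values}).to_csv(
            path, index=False, float_format="%.17g"
        )


def _times_states(solution) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(solution, OCSolution):
        return solution.times, solution.states
    if isinstance(solution, Trajectory):
        return solution.times, solution.states
    raise TypeError(f"expected OCSolution or Trajectory, got {type(solution)!r}")


def efficacy_curve(
    solution,
    initial_I: float | None = None,
    initial_Ia: float | None = None,
) -> EfficacyCurve:
    """E(t) pointwise on the solution grid.

    The reference level defaults to the first node of the solution itself;
    it must be positive.
    """
    times, states = _times_states(solution)
    i0 = states[0, 1] if initial_I is None else float(initial_I)
    ia0 = states[0, 2] if initial_Ia is None else float(initial_Ia)
    base = i0 + ia0
    if base <= 0:
        raise ValueError("efficacy undefined: I(0) + Ia(0) must be positive")
    active = states[:, 1] + states[:, 2]
    return EfficacyCurve(times, 1.0 - active / base)


@dataclass(frozen=True)
class Scenario:
    """A named control policy: constant (u, v) or the FBSM optimum."""

    name: str
    kind: str             # "constant" | "optimal"
    u: float = 0.0
    v: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "optimal"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")


@dataclass(frozen=True)
class StrategyComparison:
    times: np.ndarray
    results: dict[str, dict]

    def summary(self) -> dict:
        return {
            name: {"J": r["J"], "final_active": r["final_active"]}
            for name, r in self.results.items()
        }


def compare_strategies(
    params: Parameters,
    initial: StateVector,
    T: float,
    scenarios: Sequence[Scenario],
    *,
    weights: CostWeights | None = None,
    u_max: float = 0.95,
    v_max: float = 0.95,
    n_nodes: int = 4001,
) -> StrategyComparison:
    """Per-scenario cost J, final active share and full efficacy curve."""
    if len(scenarios) < 2:
        raise ValueError("need at least two scenarios to compare")
    weights = weights or CostWeights()
    times = np.linspace(0.0, T, n_nodes)
    results: dict[str, dict] = {}
    for sc in scenarios:
        if sc.kind == "optimal":
            sol = fbsm_solve(
                OCProblem(
                    params=params,
                    initial=initial,
                    T=T,
                    weights=weights,
                    u_max=u_max,
                    v_max=v_max,
                    n_nodes=n_nodes,
                )
            )
            states, j_val = sol.states, sol.J
            u_arr, v_arr = sol.u, sol.v
        else:
            u_arr = np.full_like(times, sc.u)
            v_arr = np.full_like(times, sc.v)
            states = simulate_controlled(params, initial, times, u_arr, v_arr)
            j_val = objective(times, states, u_arr, v_arr, weights)
        curve = efficacy_curve_from_states(times, states)
        results[sc.name] = {
            "J": j_val,
            "final_active": float(states[-1, 1] + states[-1, 2]),
            "efficacy": curve,
            "u": u_arr,
            "v": v_arr,
        }
    return StrategyComparison(times, results)


def efficacy_curve_from_states(times: np.ndarray, states: np.ndarray) -> EfficacyCurve:
    base = states[0, 1] + states[0, 2]
    if base <= 0:
        raise ValueError("efficacy undefined: I(0) + Ia(0) must be positive")
    return EfficacyCurve(times, 1.0 - (states[:, 1] + states[:, 2]) / base)
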
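"""Compartmental dynamics of illicit drug use.

The population (normalized to proportions, ``N <= 1``) is split into
susceptibles ``S``, light/occasional users ``I``, heavy users ``Ia``,
drug-induced mentally ill ``M`` and detected users in rehabilitation ``R``.
Initiation is a social "contact" process with force of infection

    lambda = beta * (I + kappa * Ia),    kappa >= 1,

so heavy users exert ``kappa``-fold more influence than light users.  The
module provides the uncontrolled vector field, numerical integration, the
basic reproduction number ``R_d`` (closed form and next-generation-matrix
oracle), both equilibria, and a linear-stability check of the drug-free
state.  ``R_d`` acts as the usual invasion threshold: the drug-free
equilibrium (1,0,0,0,0) is stable iff ``R_d <= 1``, and a unique positive
(drug-persistence) equilibrium exists iff ``R_d > 1``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Parameters",
    "StateVector",
    "TimeGrid",
    "Trajectory",
    "EquilibriumReport",
    "PARAMETER_NAMES",
    "TABLE2_RANGES",
    "PRESETS",
    "get_preset",
    "sample_parameters",
    "load_parameters",
    "save_parameters",
    "force_of_infection",
    "ode_rhs",
    "simulate",
    "reproduction_number",
    "next_generation_rd",
    "drug_free_equilibrium",
    "endemic_equilibrium",
    "dfe_stability",
    "jacobian",
    "SimulationError",
]

PARAMETER_NAMES = (
    "beta", "kappa", "mu", "alpha", "gamma", "rho", "epsilon",
    "sigma", "phi", "psi", "d", "delta", "omega",
)

#: Admissible ranges for every rate/factor (per year except kappa).
TABLE2_RANGES: dict[str, tuple[float, float]] = {
    "omega": (0.1, 0.9),
    "mu": (0.02, 0.03),
    "kappa": (1.0, 1.85),
    "beta": (0.31, 0.36),
    "gamma": (0.01, 0.14),
    "rho": (0.13, 0.78),
    "epsilon": (0.54, 0.85),
    "alpha": (0.01, 0.75),
    "psi": (0.01, 0.05),
    "delta": (0.1, 0.18),
    "d": (0.077, 0.23),
    "sigma": (0.10, 0.33),
    "phi": (0.08, 0.09),
}


class SimulationError(RuntimeError):
    """Integration failed; ``last_time`` holds the last valid time reached."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


@dataclass(frozen=True)
class Parameters:
    """The thirteen model rates/factors.

    All rates are per year; ``kappa`` is a dimensionless modification factor
    (heavy users recruit ``kappa``-fold more effectively, so ``kappa >= 1``).
    ``sigma <= phi`` (light users escalate to mental illness no faster than
    heavy users) is expected but only warned about, since the shipped
    baseline preset has ``sigma`` below its own admissible range.
    """

    beta: float    # transmission ("social influence") strength
    kappa: float   # heavy-user influence modification factor, >= 1
    mu: float      # recruitment = background exit rate
    alpha: float   # light -> heavy escalation
    gamma: float   # detection of light users
    rho: float     # detection of heavy users
    epsilon: float  # detection of mentally ill
    sigma: float   # light -> mental illness
    phi: float     # heavy -> mental illness
    psi: float     # permanent exit of light users
    d: float       # permanent exit of heavy users
    delta: float   # permanent exit of mentally ill
    omega: float   # recovery (permanent exit) from rehabilitation

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name}={v!r} must be finite and >= 0")
        if self.kappa < 1.0:
            raise ValueError(f"kappa={self.kappa} must be >= 1")
        if self.sigma > self.phi:
            warnings.warn(
                f"sigma={self.sigma} > phi={self.phi}: light users escalate to "
                "mental illness faster than heavy users",
                UserWarning,
                stacklevel=2,
            )

    # Aggregate outflow rates reused throughout: E for the light-user class,
    # C for the heavy-user class.
    @property
    def light_outflow(self) -> float:
        return self.alpha + self.gamma + self.mu + self.sigma + self.psi

    @property
    def heavy_outflow(self) -> float:
        return self.rho + self.phi + self.mu + self.d

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def replace(self, **updates: float) -> "Parameters":
        return replace(self, **updates)


def _build_presets() -> dict[str, Parameters]:
    # the lower-bound preset has sigma > phi by construction; the advisory
    # warning is for user-supplied sets, not the shipped tables
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return {
            # Baseline column of the published parameter table (symbols
            # trusted over the table's verbal labels for d/delta, which are
            # swapped there).
            "table2_baseline": Parameters(
                beta=0.35, kappa=1.25, mu=0.02, alpha=0.01, gamma=0.1,
                rho=0.35, epsilon=0.6, sigma=0.05, phi=0.09, psi=0.035,
                d=0.2, delta=0.14, omega=0.3,
            ),
            # Lower bounds of the same table; the evaluation point of the
            # published sensitivity analysis.
            "table2_lower": Parameters(
                beta=0.31, kappa=1.0, mu=0.02, alpha=0.01, gamma=0.01,
                rho=0.13, epsilon=0.54, sigma=0.10, phi=0.08, psi=0.01,
                d=0.077, delta=0.1, omega=0.1,
            ),
        }


PRESETS: dict[str, Parameters] = _build_presets()


def get_preset(name: str) -> Parameters:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def sample_parameters(rng: np.random.Generator) -> Parameters:
    """Draw one admissible parameter set uniformly within the table ranges."""
    draw = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in TABLE2_RANGES.items()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return Parameters(**draw)


def sample_regime_parameters(
    rng: np.random.Generator,
    regime: str,
    *,
    rd_margin: float = 0.1,
    rate_floor: float = 0.008,
) -> Parameters:
    """Draw an admissible set conditioned on the threshold regime.

    ``regime`` is "subcritical" (R_d <= 1 - rd_margin) or "supercritical"
    (R_d >= 1 + rd_margin).  Draws are additionally required to have the
    relevant equilibrium's leading Jacobian eigenvalue at or below
    ``-rate_floor``: near the threshold the approach to the attractor slows
    as ~1/|eigenvalue|, so a floor on the decay rate keeps long-horizon
    convergence checks meaningful on a finite horizon.
    """
    if regime not in ("subcritical", "supercritical"):
        raise ValueError(f"unknown regime {regime!r}")
    while True:
        params = sample_parameters(rng)
        rd = reproduction_number(params)
        if regime == "subcritical":
            if rd <= 1.0 - rd_margin and dfe_stability(params)[1] <= -rate_floor:
                return params
        else:
            if rd >= 1.0 + rd_margin:
                report = endemic_equilibrium(params)
                if report.leading_eigenvalue <= -rate_floor:
                    return params


def load_parameters(path: str | Path) -> Parameters:
    """Read a flat ``key: value`` config (YAML or JSON) into Parameters."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        import yaml

        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: expected a flat mapping of parameter values")
    extra = set(data) - set(PARAMETER_NAMES)
    if extra:
        raise ValueError(f"{path}: unknown parameter keys {sorted(extra)}")
    missing = set(PARAMETER_NAMES) - set(data)
    if missing:
        raise ValueError(f"{path}: missing parameter keys {sorted(missing)}")
    return Parameters(**{k: float(data[k]) for k in PARAMETER_NAMES})


def save_parameters(params: Parameters, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(params.as_dict(), indent=2) + "\n")
    else:
        import yaml

        path.write_text(yaml.safe_dump(params.as_dict(), sort_keys=False))


@dataclass(frozen=True)
class StateVector:
    """Population proportions (S, I, Ia, M, R), each in [0, 1], N <= 1."""

    S: float
    I: float
    Ia: float
    M: float
    R: float

    _TOL = 1e-8

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < -self._TOL):
            raise ValueError(f"state components must be >= 0, got {arr}")
        n = float(arr.sum())
        if n > 1.0 + self._TOL:
            raise ValueError(f"total proportion N={n} exceeds 1")

    @property
    def N(self) -> float:
        return self.S + self.I + self.Ia + self.M + self.R

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.I, self.Ia, self.M, self.R], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "StateVector":
        s, i, ia, m, r = (float(x) for x in np.asarray(arr, dtype=float))
        return cls(s, i, ia, m, r)


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid in years, ``n_nodes >= 2``."""

    start: float
    end: float
    n_nodes: int

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("TimeGrid needs at least 2 nodes")
        if not self.end > self.start:
            raise ValueError("TimeGrid end must exceed start")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(self.start, self.end, self.n_nodes)


@dataclass(frozen=True)
class Trajectory:
    """States on a time grid; ``states`` has shape (n_nodes, 5)."""

    grid: TimeGrid
    states: np.ndarray

    def __post_init__(self) -> None:
        if self.states.shape != (self.grid.n_nodes, 5):
            raise ValueError(
                f"states shape {self.states.shape} does not match grid "
                f"({self.grid.n_nodes} nodes)"
            )

    @property
    def times(self) -> np.ndarray:
        return self.grid.times

    def __iter__(self) -> Iterator[StateVector]:
        for row in self.states:
            yield StateVector.from_array(row)

    @property
    def final(self) -> StateVector:
        return StateVector.from_array(self.states[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.states, columns=["S", "I", "Ia", "M", "R"]
        ).assign(t=self.times)[["t", "S", "I", "Ia", "M", "R"]]

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class EquilibriumReport:
    state: StateVector
    classification: str              # "drug-free" | "endemic"
    rd: float
    leading_eigenvalue: float        # max real part of the Jacobian spectrum

    def __post_init__(self) -> None:
        if self.classification == "endemic" and not self.rd > 1.0:
            raise ValueError("endemic classification requires R_d > 1")


# ----------------------------------------------------------------------------
# Vector field


def force_of_infection(params: Parameters, state: StateVector) -> float:
    """Per-susceptible initiation rate lambda = beta * (I + kappa * Ia)."""
    return params.beta * (state.I + params.kappa * state.Ia)


def _rhs(t: float, y: np.ndarray, p: Parameters) -> np.ndarray:
    s, i, ia, m, r = y
    lam = p.beta * (i + p.kappa * ia)
    return np.array([
        p.mu - lam * s - p.mu * s,
        lam * s - p.light_outflow * i,
        p.alpha * i - p.heavy_outflow * ia,
        p.sigma * i + p.phi * ia - (p.epsilon + p.mu + p.delta) * m,
        p.gamma * i + p.rho * ia + p.epsilon * m - (p.mu + p.omega) * r,
    ])


def ode_rhs(t: float, state: StateVector, params: Parameters) -> np.ndarray:
    """Time derivative of (S, I, Ia, M, R); the system is autonomous."""
    return _rhs(t, state.as_array(), params)


def jacobian(params: Parameters, state: StateVector) -> np.ndarray:
    """Analytic Jacobian of the vector field at ``state``."""
    p, s = params, state
    lam = force_of_infection(p, s)
    b, bk = p.beta, p.beta * p.kappa
    return np.array([
        [-lam - p.mu, -b * s.S, -bk * s.S, 0.0, 0.0],
        [lam, b * s.S - p.light_outflow, bk * s.S, 0.0, 0.0],
        [0.0, p.alpha, -p.heavy_outflow, 0.0, 0.0],
        [0.0, p.sigma, p.phi, -(p.epsilon + p.mu + p.delta), 0.0],
        [0.0, p.gamma, p.rho, p.epsilon, -(p.mu + p.omega)],
    ])


# ----------------------------------------------------------------------------
# Numerical integration

_RTOL = 1e-8
_ATOL = 1e-10
_NEG_TOL = 1e-8


def simulate(
    params: Parameters,
    initial: StateVector,
    grid: TimeGrid,
    *,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model over ``grid`` with an adaptive solver.

    Positivity is enforced a posteriori: undershoots below ``-1e-8`` raise,
    smaller ones are clipped to zero on output.
    """
    sol = solve_ivp(
        _rhs,
        (grid.start, grid.end),
        initial.as_array(),
        args=(params,),
        method=method,
        rtol=_RTOL,
        atol=_ATOL,
        t_eval=grid.times,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else grid.start
        raise SimulationError(f"integration failed: {sol.message}", last_time=last)
    states = sol.y.T.copy()
    if states.min() < -_NEG_TOL:
        t_bad = grid.times[np.argmin(states.min(axis=1))]
        raise SimulationError(
            f"negative state component {states.min():.3e} at t={t_bad:.3f}",
            last_time=float(t_bad),
        )
    np.clip(states, 0.0, None, out=states)
    return Trajectory(grid, states)


# ----------------------------------------------------------------------------
# Reproduction number and equilibria


def reproduction_number(params: Parameters) -> float:
    """Closed-form basic reproduction number.

    With E = alpha+gamma+mu+sigma+psi (light-user outflow) and
    C = rho+phi+mu+d (heavy-user outflow):

        R_d = beta * (alpha*kappa + C) / (E * C)
    """
    e, c = params.light_outflow, params.heavy_outflow
    if e <= 0 or c <= 0:
        raise ZeroDivisionError(
            f"outflow rates must be positive (E={e}, C={c})"
        )
    return params.beta * (params.alpha * params.kappa + c) / (e * c)


def next_generation_rd(params: Parameters) -> float:
    """R_d as the spectral radius of the next-generation matrix F V^-1.

    Independent numerical route: F holds new-initiation terms linearized at
    the drug-free equilibrium, V the transition/exit terms of (I, Ia).
    """
    e, c = params.light_outflow, params.heavy_outflow
    f_mat = np.array([[params.beta, params.beta * params.kappa], [0.0, 0.0]])
    v_mat = np.array([[e, 0.0], [-params.alpha, c]])
    ngm = f_mat @ np.linalg.inv(v_mat)
    return float(np.max(np.abs(np.linalg.eigvals(ngm))))


def drug_free_equilibrium() -> StateVector:
    return StateVector(1.0, 0.0, 0.0, 0.0, 0.0)


def endemic_equilibrium(params: Parameters) -> EquilibriumReport | None:
    """Closed-form drug-persistence equilibrium, or None when R_d <= 1.

    The equilibrium force of infection is lambda* = mu*(R_d - 1), giving
    S* = 1/R_d and the remaining components by balance of in/outflows.
    """
    rd = reproduction_number(params)
    if rd <= 1.0:
        return None
    p = params
    lam = p.mu * (rd - 1.0)
    s = 1.0 / rd
    i = lam * s / p.light_outflow
    ia = p.alpha * i / p.heavy_outflow
    m = (p.sigma * i + p.phi * ia) / (p.epsilon + p.mu + p.delta)
    r = (p.gamma * i + p.rho * ia + p.epsilon * m) / (p.mu + p.omega)
    state = StateVector(s, i, ia, m, r)
    lead = float(np.max(np.linalg.eigvals(jacobian(params, state)).real))
    return EquilibriumReport(state, "endemic", rd, lead)


_THRESHOLD_TOL = 1e-9


def dfe_stability(params: Parameters) -> tuple[str, float]:
    """Linear stability of the drug-free state.

    Returns ``(classification, leading_eigenvalue)`` with classification in
    {"stable", "unstable", "threshold"}; the threshold tag is reported when
    R_d is within 1e-9 of one.
    """
    rd = reproduction_number(params)
    lead = float(
        np.max(np.linalg.eigvals(jacobian(params, drug_free_equilibrium())).real)
    )
    if abs(rd - 1.0) < _THRESHOLD_TOL:
        return "threshold", lead
    return ("unstable" if lead > 0 else "stable"), lead
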
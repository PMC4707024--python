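"""Calibration of the model to biannual prevalence series.

Observed series are treatment-demand prevalence percentages reported twice a
year ("97a"/"97b" = first/second half of 1997, 0.5-year spacing).  The model
clock starts at the first non-missing observation.  Calibration is bounded
nonlinear least squares on a chosen model observable (by default the active
user share ``100*(I+Ia)/N``), with multistart over Latin-hypercube draws
inside the parameter box to guard against local minima.

Which state combination the treatment-demand data actually measures is not
knowable from the data source, so three observables are selectable:
``active`` (light + heavy users), ``with_mental`` (plus the mentally ill)
and ``detected_share`` (the rehabilitation class).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model import (
    PARAMETER_NAMES,
    TABLE2_RANGES,
    Parameters,
    SimulationError,
    StateVector,
    TimeGrid,
    Trajectory,
    get_preset,
    reproduction_number,
    simulate,
)

__all__ = [
    "PrevalenceSeries",
    "FitConfig",
    "FitResult",
    "OBSERVABLES",
    "load_prevalence_series",
    "observable",
    "residuals",
    "fit",
    "fixture_path",
]

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "-", "—", "–", "na", "nan", "NA", "NaN"}

#: Shipped verbatim series (regional biannual treatment-demand percentages).
FIXTURES = ("cape_town", "durban", "gauteng", "mpumalanga")


def fixture_path(name: str) -> Path:
    """Path to one of the packaged regional prevalence CSVs."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    return Path(__file__).parent / "data" / f"{name}.csv"


@dataclass(frozen=True)
class PrevalenceSeries:
    """Biannual percentage observations with a missing-value mask.

    ``times`` are years from the first non-missing observation (0.5 apart);
    leading missing rows carry negative times and contribute nothing to any
    residual.  ``values`` holds NaN where missing.
    """

    labels: tuple[str, ...]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.labels) != self.times.size or self.times.size != self.values.size:
            raise ValueError("labels, times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        obs = self.values[self.mask]
        if obs.size == 0:
            raise ValueError("series contains no non-missing observations")
        if np.any((obs < 0) | (obs > 100)):
            raise ValueError("observed percentages must lie in [0, 100]")

    @property
    def mask(self) -> np.ndarray:
        """True where an observation is present."""
        return ~np.isnan(self.values)

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())

    @property
    def observed_times(self) -> np.ndarray:
        return self.times[self.mask]

    @property
    def observed_values(self) -> np.ndarray:
        return self.values[self.mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels, "percent": self.values})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def _series_from_values(labels, values) -> PrevalenceSeries:
    values = np.asarray(values, dtype=float)
    present = ~np.isnan(values)
    if not present.any():
        raise ValueError("series is entirely missing")
    first = int(np.argmax(present))
    times = 0.5 * (np.arange(values.size) - first)
    return PrevalenceSeries(tuple(str(l) for l in labels), times, values)


def load_prevalence_series(source: str | Path) -> PrevalenceSeries:
    """Read a prevalence CSV (long ``label,percent`` or wide as-printed).

    Missing cells may be empty or an em/en dash.  Any other non-numeric cell
    raises with the offending row label.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] == ["label", "percent"] and df.shape[1] == 2:
        labels = df.iloc[:, 0].str.strip().tolist()
        raw = df.iloc[:, 1].str.strip().tolist()
    else:
        # wide format: header row = labels, single data row = values
        if len(df) != 1:
            raise ValueError(
                f"{source}: wide-format input must have exactly one data row"
            )
        labels = [c.strip() for c in df.columns]
        raw = [str(v).strip() for v in df.iloc[0]]
    values = []
    for label, cell in zip(labels, raw):
        if cell in _MISSING_TOKENS:
            values.append(np.nan)
            continue
        try:
            values.append(float(cell))
        except ValueError:
            raise ValueError(
                f"{source}: non-numeric value {cell!r} at label {label!r}"
            ) from None
    return _series_from_values(labels, values)


# ----------------------------------------------------------------------------
# Observables

OBSERVABLES = ("active", "with_mental", "detected_share")


def observable(trajectory: Trajectory, which: str = "active") -> np.ndarray:
    """Model prevalence (percent) on the trajectory grid.

    ``active``: 100*(I+Ia)/N; ``with_mental``: 100*(I+Ia+M)/N;
    ``detected_share``: 100*R/N.
    """
    if which not in OBSERVABLES:
        raise ValueError(f"unknown observable {which!r}; choose from {OBSERVABLES}")
    s = trajectory.states
    n = s.sum(axis=1)
    if np.any(n <= 0):
        raise ValueError("total population N is zero at some node")
    if which == "active":
        num = s[:, 1] + s[:, 2]
    elif which == "with_mental":
        num = s[:, 1] + s[:, 2] + s[:, 3]
    else:
        num = s[:, 4]
    return 100.0 * num / n


# ----------------------------------------------------------------------------
# Fit configuration and residuals


@dataclass(frozen=True)
class FitConfig:
    """What is free, within which box, and how the optimizer is started."""

    free: tuple[str, ...]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    estimate_initial: bool = True
    ic_bounds: tuple[float, float] = (0.0, 0.99)
    initial: StateVector = StateVector(0.97, 0.02, 0.01, 0.0, 0.0)
    base: Parameters = None  # type: ignore[assignment]
    observable: str = "active"
    multistart: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.free:
            raise ValueError("free parameter set must be non-empty")
        unknown = set(self.free) - set(PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"unknown free parameters {sorted(unknown)}")
        if self.base is None:
            object.__setattr__(self, "base", get_preset("table2_baseline"))
        for name in self.free:
            lo, hi = self.resolved_bounds(name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
        if self.observable not in OBSERVABLES:
            raise ValueError(f"unknown observable {self.observable!r}")

    def resolved_bounds(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, TABLE2_RANGES[name])

    @property
    def theta_names(self) -> tuple[str, ...]:
        extra = ("I0", "Ia0") if self.estimate_initial else ()
        return self.free + extra

    def theta_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for name in self.free:
            b = self.resolved_bounds(name)
            lo.append(b[0])
            hi.append(b[1])
        if self.estimate_initial:
            lo += [self.ic_bounds[0]] * 2
            hi += [self.ic_bounds[1]] * 2
        return np.asarray(lo), np.asarray(hi)

    def unpack(self, theta: np.ndarray) -> tuple[Parameters, StateVector]:
        updates = dict(zip(self.free, (float(x) for x in theta[: len(self.free)])))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            params = self.base.replace(**updates)
        if self.estimate_initial:
            i0, ia0 = float(theta[-2]), float(theta[-1])
            if i0 + ia0 > 0.999:
                raise ValueError("I(0)+Ia(0) exceeds the population")
            init = StateVector(1.0 - i0 - ia0, i0, ia0, 0.0, 0.0)
        else:
            init = self.initial
        return params, init


@dataclass(frozen=True)
class FitResult:
    estimates: dict[str, float]
    initial: StateVector
    sse: float
    rd: float
    converged: bool
    starts: tuple[dict, ...]
    config: FitConfig

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("SSE must be non-negative")

    def summary(self) -> dict:
        return {
            "estimates": self.estimates,
            "initial_state": list(self.initial.as_array()),
            "sse": self.sse,
            "rd": self.rd,
            "converged": self.converged,
            "n_starts": len(self.starts),
        }


_PENALTY = 1e6


def _grid_for(series: PrevalenceSeries) -> TimeGrid:
    t_max = float(series.observed_times.max())
    n = int(round(t_max / 0.5)) + 1
    return TimeGrid(0.0, t_max, max(n, 2))


def residuals(
    theta: np.ndarray, series: PrevalenceSeries, config: FitConfig
) -> np.ndarray:
    """Model-minus-data percent residuals at the non-missing observations.

    Integrator failures (or inadmissible initial states) yield a constant
    large-penalty vector so the optimizer can retreat.
    """
    times = series.observed_times
    keep = times >= 0  # leading missing rows sit before the model clock
    try:
        params, init = config.unpack(np.asarray(theta, dtype=float))
        traj = simulate(params, init, _grid_for(series))
    except (SimulationError, ValueError) as exc:
        logger.warning("residual evaluation failed (%s); returning penalty", exc)
        return np.full(int(keep.sum()), _PENALTY)
    model_vals = observable(traj, config.observable)
    model_at_obs = np.interp(times[keep], traj.times, model_vals)
    return model_at_obs - series.observed_values[keep]


def fit(series: PrevalenceSeries, config: FitConfig) -> FitResult:
    """Bounded multistart least squares; deterministic given ``config.seed``."""
    n_theta = len(config.theta_names)
    required = max(4, len(config.free) + 2)
    if series.n_observed < required:
        raise ValueError(
            f"need at least {required} non-missing observations, "
            f"got {series.n_observed}"
        )
    lo, hi = config.theta_bounds()
    starts = [0.5 * (lo + hi)]
    if config.multistart > 1:
        sampler = qmc.LatinHypercube(d=n_theta, seed=config.seed)
        draws = qmc.scale(sampler.random(config.multistart - 1), lo, hi)
        starts.extend(list(draws))

    records: list[dict] = []
    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                residuals, x0, bounds=(lo, hi), args=(series, config), method="trf"
            )
            rec = {
                "x0": [float(v) for v in x0],
                "sse": float(sol.cost * 2.0),
                "success": bool(sol.success),
                "x": [float(v) for v in sol.x],
            }
            if sol.success and (best is None or rec["sse"] < best[0]):
                best = (rec["sse"], sol.x)
        except Exception as exc:  # pragma: no cover - defensive
            rec = {"x0": [float(v) for v in x0], "error": str(exc), "success": False}
        records.append(rec)

    if best is None:
        raise RuntimeError(
            f"all {len(starts)} starts failed to converge; records: {records}"
        )
    sse, x = best
    params, init = config.unpack(x)
    estimates = dict(zip(config.theta_names, (float(v) for v in x)))
    return FitResult(
        estimates=estimates,
        initial=init,
        sse=float(sse),
        rd=reproduction_number(params),
        converged=True,
        starts=tuple(records),
        config=config,
    )
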
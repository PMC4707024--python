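"""Normalized forward sensitivity (elasticity) indices of R_d.

The index of R_d with respect to a parameter p is

    Gamma_p = (dR_d/dp) * (p / R_d),

the relative change in R_d per relative change in p.  Since R_d is linear in
beta, Gamma_beta = +1 always: a 10% increase in the social-influence strength
raises R_d by exactly 10%.  Closed forms are provided for the ten parameters
entering R_d, alongside a central-difference numerical route used as an
independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import Parameters, reproduction_number

__all__ = [
    "SENSITIVE_PARAMETERS",
    "SensitivityReport",
    "sensitivity_index",
    "sensitivity_index_numeric",
    "sensitivity_table",
]

#: Parameters that enter R_d; epsilon, delta and omega do not.
SENSITIVE_PARAMETERS = (
    "beta", "kappa", "alpha", "mu", "gamma", "sigma", "psi", "rho", "phi", "d",
)


@dataclass(frozen=True)
class SensitivityReport:
    """Indices sorted by decreasing |Gamma|, plus the evaluation point."""

    indices: dict[str, float]
    params: Parameters
    method: str  # "closed_form" | "numeric"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"parameter": list(self.indices), "index": list(self.indices.values())}
        )

    def formatted(self, sig_figs: int = 2) -> dict[str, float]:
        """Indices rounded to ``sig_figs`` significant figures."""
        return {k: round_sig(v, sig_figs) for k, v in self.indices.items()}


def round_sig(x: float, sig_figs: int = 2) -> float:
    """Round to significant figures (0 maps to 0)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig_figs - 1))


def sensitivity_index(params: Parameters, name: str) -> float:
    """Closed-form Gamma for one parameter of R_d.

    With E = alpha+gamma+mu+sigma+psi, C = rho+phi+mu+d and
    K = alpha*kappa + C (the numerator bracket of R_d):

        Gamma_beta  = 1
        Gamma_kappa = alpha*kappa / K
        Gamma_x     = -x*alpha*kappa / (C*K)   for x in {rho, phi, d}
        Gamma_x     = -x / E                   for x in {gamma, sigma, psi}
        Gamma_alpha = alpha * (kappa/K - 1/E)
        Gamma_mu    = mu * (1/K - 1/E - 1/C)
    """
    if name not in SENSITIVE_PARAMETERS:
        raise ValueError(
            f"R_d does not depend on {name!r}; sensitivity is not applicable"
        )
    p = params
    e, c = p.light_outflow, p.heavy_outflow
    k = p.alpha * p.kappa + c
    if name == "beta":
        return 1.0
    if name == "kappa":
        return p.alpha * p.kappa / k
    if name in ("rho", "phi", "d"):
        x = getattr(p, name)
        return -x * p.alpha * p.kappa / (c * k)
    if name in ("gamma", "sigma", "psi"):
        return -getattr(p, name) / e
    if name == "alpha":
        return p.alpha * (p.kappa / k - 1.0 / e)
    # mu enters the numerator bracket and both outflow denominators
    return p.mu * (1.0 / k - 1.0 / e - 1.0 / c)


def _rd_raw(values: dict) -> float:
    """R_d straight from raw values (no validation; used for differencing)."""
    e = values["alpha"] + values["gamma"] + values["mu"] + values["sigma"] + values["psi"]
    c = values["rho"] + values["phi"] + values["mu"] + values["d"]
    return values["beta"] * (values["alpha"] * values["kappa"] + c) / (e * c)


def sensitivity_index_numeric(
    params: Parameters, name: str, rel_step: float = 1e-6
) -> float:
    """Central-difference elasticity d(log R_d)/d(log p); cross-check route.

    Works on raw values so boundary points (e.g. kappa = 1) can be probed
    on both sides.
    """
    if name not in SENSITIVE_PARAMETERS:
        raise ValueError(
            f"R_d does not depend on {name!r}; sensitivity is not applicable"
        )
    value = getattr(params, name)
    if value == 0:
        return 0.0
    h = value * rel_step
    raw = params.as_dict()
    hi = _rd_raw({**raw, name: value + h})
    lo = _rd_raw({**raw, name: value - h})
    return (hi - lo) / (2.0 * h) * (value / _rd_raw(raw))


def sensitivity_table(
    params: Parameters, method: str = "closed_form"
) -> SensitivityReport:
    """All ten applicable indices, sorted by |Gamma| descending."""
    fn = sensitivity_index if method == "closed_form" else sensitivity_index_numeric
    raw = {name: fn(params, name) for name in SENSITIVE_PARAMETERS}
    ordered = dict(sorted(raw.items(), key=lambda kv: -abs(kv[1])))
    return SensitivityReport(ordered, params, method)
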
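# drugdyn

Compartmental dynamics, calibration and optimal control of illicit drug
use in a community.

Illicit drug use spreads through social contact: susceptible people start
using under the influence of current users, escalate from occasional to
heavy use, may develop drug-induced mental illness, and can be detected
and moved into rehabilitation. `drugdyn` implements this as a
five-compartment model — susceptibles `S`, light users `I`, heavy users
`Ia`, mentally ill `M`, detected/rehabilitating `R` (proportions,
`N ≤ 1`) — with force of initiation

```
λ = β (I + κ Ia),    κ ≥ 1,
```

and per-year rates for escalation (α), detection (γ, ρ, ε),
mental-illness progression (σ, φ), permanent exit (ψ, d, δ), recovery (ω)
and demography (μ). The basic reproduction number

```
R_d = β (ακ + C) / (E C),   E = α+γ+μ+σ+ψ,   C = ρ+φ+μ+d,
```

is the invasion threshold: drug use dies out when `R_d ≤ 1` and persists
at a unique endemic level when `R_d > 1`.

The package is aimed at epidemiological modellers who want a tested
reference implementation of this model family: simulation and equilibrium
analysis, elasticities of `R_d`, least-squares calibration to biannual
prevalence series (four South African regional series are packaged), a
seeded synthetic-data generator for parameter-recovery studies, and a
two-control optimal-intervention solver (forward-backward sweep on the
Pontryagin conditions) minimizing

```
J[u, v] = ∫₀ᵀ [ I + Ia + A u² + (B/2) v² ] dt ,
```

where `u(t)` weakens social influence and `v(t)` scales detection effort.

## Worked example

```python
import numpy as np
from drugdyn import (
    get_preset, reproduction_number, endemic_equilibrium,
    sensitivity_table, fbsm_solve, efficacy_curve,
)
from drugdyn.control import reference_problem

params = get_preset("table2_baseline")
print(f"R_d at baseline: {reproduction_number(params):.4f}")

eq = endemic_equilibrium(params)
print(f"endemic state: S*={eq.state.S:.4f}, I*={eq.state.I:.5f}, Ia*={eq.state.Ia:.6f}")

top = list(sensitivity_table(get_preset("table2_lower")).indices.items())[:3]
print("most influential parameters:", [(n, round(v, 4)) for n, v in top])

solution = fbsm_solve(reference_problem(params))
print(f"optimal-control run: J={solution.J:.6f}, "
      f"iterations={solution.iterations}, converged={solution.converged}")
efficacy = efficacy_curve(solution)
print(f"efficacy after 4 years: {efficacy.values[np.searchsorted(solution.times, 4.0)]:.3f}")
```

prints

```
R_d at baseline: 1.6587
endemic state: S*=0.6029, I*=0.03694, Ia*=0.000560
most influential parameters: [('beta', 1.0), ('sigma', -0.6667), ('mu', -0.1354)]
optimal-control run: J=0.120428, iterations=20, converged=True
efficacy after 4 years: 0.654
```

Reading the output: at the baseline parameters each drug user recruits
about 1.66 new users over their using career, so use persists — at a
modest endemic level (about 3.7% light and 0.06% heavy users). `R_d`
responds one-for-one to the social-influence strength β (elasticity +1),
which is why the first control targets it. Under the 20-year optimal
intervention (weights A = 5e−7, B = 3e−7, controls capped at 0.95), both
controls saturate for nearly the whole horizon and active drug use falls
65% within four years and ~98.5% by year 20, at objective value
J ≈ 0.1204 — marginally below both the no-control and the
constant-at-cap policies.

The same pipeline is available from the shell:

```sh
drugdyn rd --preset table2_baseline
drugdyn sensitivity --preset table2_lower --out sens.csv
drugdyn fit --input src/drugdyn/data/cape_town.csv --free beta,kappa \
            --seed 7 --out fit.json
drugdyn control --t-horizon 20 --out solution.csv
drugdyn synth --noise-sd 2 --seed 3 --out synthetic_series.csv
```

## Data

`src/drugdyn/data/` contains the biannual treatment-demand prevalence
series for Cape Town, Durban, Gauteng and Mpumalanga (1996b–2008a,
percent; leading blanks are missing values), as published by the South
African Community Epidemiology Network on Drug Use (SACENDU) reporting
system. Loaders, the synthetic generator and the fitting layer all share
the same `label,percent` CSV dialect.

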
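# Methods

## Model

The population is normalized to proportions and partitioned into
susceptibles `S`, light (occasional) drug users `I`, heavy users `Ia`,
people with drug-induced mental illness `M`, and detected users in
rehabilitation `R`, with `N = S + I + Ia + M + R ≤ 1`. Initiation is a
social contact process with force of infection

```
λ = β (I + κ Ia),    κ ≥ 1,
```

so heavy users recruit κ-fold more effectively than light users. The
uncontrolled dynamics are

```
dS/dt  = μ − λS − μS
dI/dt  = λS − (α + γ + σ + μ + ψ) I
dIa/dt = αI − (ρ + φ + μ + d) Ia
dM/dt  = σI + φIa − (ε + μ + δ) M
dR/dt  = γI + ρIa + εM − (μ + ω) R
```

with recruitment/background-exit rate μ; escalation α; detection rates γ
(light), ρ (heavy), ε (mentally ill); mental-illness progression σ (light)
and φ (heavy); permanent exits ψ, d, δ; and recovery ω. All rates are per
year. A point worth flagging: the force of infection is β·(I + κIa), the
only grouping for which the closed-form reproduction number below agrees
with the next-generation-matrix construction.

Writing `E = α + γ + μ + σ + ψ` (total light-user outflow) and
`C = ρ + φ + μ + d` (heavy-user outflow), the basic reproduction number is

```
R_d = β (ακ + C) / (E C).
```

The drug-free equilibrium (1, 0, 0, 0, 0) is stable iff `R_d ≤ 1`; for
`R_d > 1` a unique positive equilibrium exists with equilibrium force of
infection `λ* = μ(R_d − 1)`, `S* = 1/R_d`, `I* = λ*S*/E`, `Ia* = αI*/C`,
and `M*`, `R*` by balance. At the shipped baseline preset
`R_d ≈ 1.6587` and `(S*, I*, Ia*) ≈ (0.6029, 0.03694, 0.00056)`.
Analytic global-stability proofs are out of scope here; the package checks
the threshold behaviour numerically (see below).

## Parameter presets and their quirks

Two presets ship: `table2_baseline` and `table2_lower` (the lower bounds
of the admissible ranges). Two documented quirks of the published
parameter table are handled deliberately:

- the verbal labels of `d` and `δ` are swapped relative to the equations;
  the symbols are trusted (`d ∈ [0.077, 0.23]`, baseline 0.2, heavy-user
  exit; `δ ∈ [0.1, 0.18]`, baseline 0.14, mentally-ill exit);
- the baseline `σ = 0.05` lies outside its own admissible range
  [0.10, 0.33] and violates the modelling assumption `σ ≤ φ`. Both values
  are honored (the range bounds calibration boxes; the baseline drives
  scenario runs), and `σ > φ` produces a validation warning rather than an
  error.

## Sensitivity analysis

Elasticities (normalized forward sensitivity indices)
`Γ_p = (∂R_d/∂p)(p/R_d)` have closed forms; `Γ_β = 1` identically since
`R_d` is linear in β. The closed forms are cross-checked against a
central-difference oracle on the log scale (relative step 1e−6, agreement
to 1e−6 over random admissible draws). The default evaluation point is
the lower-bound preset, where the four reproducible published entries are
recovered at their printed precision: κ → 0.032, ρ → −0.013, d → −0.008,
φ → −0.0082. Five further published entries (α, μ, γ, ψ, σ) and a row
labelled with a symbol absent from the model do not follow from the index
definition at either printed parameter set; they are computed but not
asserted against. Likewise the published claim that the lower-bound
parameters give `R_d = 6.22` is inconsistent with the closed form (which
gives 2.1340 there); the package documents the discrepancy by computing
the value rather than reproducing the printed one.

## Numerical integration and threshold checks

The uncontrolled system is integrated with `scipy.integrate.solve_ivp`
(LSODA, rtol 1e−8, atol 1e−10). Undershoots below −1e−8 raise; smaller
negative roundoff is clipped to zero on output. Threshold dynamics are
verified by long-horizon integration (T = 2000 years, matching the
slowest relevant rate μ ≈ 0.02/yr): 20 subcritical draws must land within
1e−6 (sup norm) of the drug-free state and 20 supercritical draws within
1e−6 of the closed-form endemic state.

Random draws for these checks are conditioned on the regime
(`sample_regime_parameters`): `R_d ≤ 0.9` or `R_d ≥ 1.1`, plus the
requirement that the relevant equilibrium's leading Jacobian eigenvalue
be at most −0.008/yr. The eigenvalue floor is the direct convergence-rate
criterion: the approach to the attractor decays like `exp(λ_lead t)`, so
`exp(−0.008·2000) ≈ 1e−7` clears the 1e−6 tolerance, while draws arbitrarily
close to `R_d = 1` approach their attractor arbitrarily slowly and no
finite horizon could certify the limit for them.

## Calibration

Observed series are biannual treatment-demand percentages ("97a"/"97b"
half-year labels, 0.5-year spacing); four regional series (Cape Town,
Durban, Gauteng, Mpumalanga) ship as packaged CSVs exactly as published.
The model clock starts at each series' first non-missing observation;
leading missing values (late reporting onset) are excluded from the
residual vector, never imputed.

Which state combination treatment-demand data measure is not identifiable
from the source, so the observable is configurable: `active`
100(I+Ia)/N (default), `with_mental` 100(I+Ia+M)/N, or `detected_share`
100R/N. Calibration is bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) with the
admissible ranges as default box bounds, multistart from seeded
Latin-hypercube draws (default 20 starts plus the box midpoint), and, by
default, free initial conditions I(0), Ia(0) with
S(0) = 1 − I(0) − Ia(0), M(0) = R(0) = 0. Integrator failures inside a
residual evaluation return a constant 1e6 penalty vector so the optimizer
retreats. Fits are bit-reproducible given the seed.

The published fit reports no estimated parameter values or SSEs, so
calibration quality is validated by parameter recovery on synthetic data
instead: noise-free series must return the generating β and κ to within
1% relative error, and with 2-percentage-point Gaussian noise the median
relative error on β over 10 seeded replicates must stay below 10%.
Recovery experiments default to 5 multistarts — ample for 2–3 smooth free
parameters — keeping a 10-replicate study under a few seconds.

## Synthetic data

The generator samples a model observable on the biannual grid and adds
i.i.d. Gaussian noise on the percent scale, truncated to [0, 100]
(additive-on-percent mirrors the data's scale; the source states no noise
model). Missingness is generated only as a leading run, the pattern seen
in the regional tables. The generator emulates the *statistical shape* of
treatment-demand data, not its sampling mechanics: reporting-coverage
drift, centre-level clustering and demand-vs-prevalence bias are absent,
so recovery results certify the estimator, not the epidemiology of any
real region. A parameter whose replicate estimates spread over more than
half their admissible range is flagged weakly identified (ε is the
canonical example: it barely moves the active-user share).

## Optimal control

Two controls act on the dynamics: `u(t)` scales initiation down by
`(1 − u)`, and `v(t)` multiplies all three detection rates (γ, ρ, ε). Note
the consequence of the published controlled system's form: `v = 1`
reproduces baseline detection and `v = 0` removes detection entirely, so
the controlled field reduces to the uncontrolled one at `(u, v) = (0, 1)`,
not at `(0, 0)`. The objective is

```
J[u, v] = ∫₀ᵀ [ I + Ia + A u² + (B/2) v² ] dt
```

(this literal asymmetric quadratic form is the default; a symmetric
`(A/2)u²` variant is a flag, with the u-characterization denominator
switching 2A ↔ A). A and B are balancing coefficients in arbitrary
monetary units; no discounting. The reference scenario uses T = 20 years,
A = 5e−7, B = 3e−7, both controls bounded by 0.95, initial state
(0.97, 0.02, 0.01, 0, 0).

First-order conditions (Pontryagin minimum principle): the adjoint system
is `dp/dt = −∂H/∂x` with `p(T) = 0`, and since H is strictly convex and
separable in (u, v) the pointwise minimizers are the clipped stationary
points

```
u* = clip[ (p_I − p_S) λS / (2A), 0, u_max ]
v* = clip[ (p_I γI + p_Ia ρIa + p_M εM − p_R(γI + ρIa + εM)) / B, 0, v_max ]
```

The adjoint rows are cross-checked in the tests against finite differences
of −∂H/∂x.

The forward-backward sweep method (FBSM) iterates: classical RK4 forward
for the state, RK4 backward for the adjoint (state and controls linearly
interpolated at half-steps), control update by relaxation
`u ← ½(u_old + u*)`, stopping when the max node-wise change of both
controls falls below 1e−4 (max 500 iterations; the reference scenario
converges in ~20). A final pass projects the converged iterate exactly,
re-integrates state and adjoint under the projected controls, and projects
once more, so the returned controls are *exactly* the Hamiltonian
minimizers for the returned state/adjoint pair and the reported J is
consistent with the returned controls.

Grid resolution is a genuine numerical constraint here: with A, B at the
1e−7 scale, control is essentially free, the optimal controls saturate at
their bound over almost the whole horizon, and the switch-off boundary
layer before T is only ~0.007 years wide (where the adjoint-weighted
benefit falls below the marginal quadratic cost). The default grid is
4001 nodes (h = 0.005 at T = 20) and the reference scenario uses 8001;
at h = 0.01 the layer is unresolved and the discretized J of the optimal
policy can exceed that of the constant-at-bound policy by ~2e−9, inverting
an ordering whose true continuous-time magnitude is only ~4e−9 (the
control-cost saving over the layer).

## Efficacy

`E(t) = 1 − (I(t)+Ia(t))/(I(0)+Ia(0))` measures proportional reduction in
active users; `E(0) = 0` and `E = 1` at elimination. E is bounded above
by 1 but not below by 0: with no control in a supercritical regime and
small initial prevalence, active use grows and E goes negative. The
package asserts only `E ≤ 1` and reports E on the solver grid without
smoothing. Strategy comparisons report per-scenario J, final active share
and the full E(t) curve; under the reference scenario the optimal policy
dominates no-control pointwise in E and is (marginally) cheaper than the
constant-at-bound policy. Time is in years throughout, consistent with
the per-year rate units.

## Problem sizes used by the shipped checks

Threshold dynamics: 20 + 20 conditioned draws, T = 2000. NGM cross-check:
1,000 draws. Sensitivity oracle: 100–500 random draws. Recovery: 24-point
series, 10 noisy replicates. FBSM reference: 8001 nodes, T = 20.
The full test suite runs in well under a minute on one core except for
the FBSM-dependent tests (~20 s).

## Known limitations

- The calibration observable is a modelling choice; nothing in the data
  pins it down, and fitted parameters shift accordingly.
- Identifiability from a single 24-point series is weak for most of the
  13 parameters; only low-dimensional free sets (2–3 parameters) are
  meaningfully constrained.
- The FBSM is a fixed-point iteration on necessary conditions; it does
  not certify global optimality (no bang-bang/singular-arc analysis).
- No uncertainty quantification (CIs, bootstrap) is provided for fits.
- Demographic stochasticity and age/gender structure are out of scope.
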
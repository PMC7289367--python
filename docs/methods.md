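# Methods

## Model and assumptions

The package simulates a single VWF multimer grafted at a point on a platelet
surface, reduced to one conformational coordinate. The dimensionless
equation of motion

    q'' = −τ̃ q^(3/7) + q^(1/7) − 1

treats the molecule as a unit mass in the potential
`Ũ_τ̃(q) = (7/10) τ̃ q^(10/7) − (7/8) q^(8/7) + q`, with the shear term
`−τ̃ q^(3/7)` driving unfolding and `q^(1/7) − 1` the restoring force of the
effective surface tension that re-globularizes the chain. Assumptions
inherited from this reduction:

* **Conservative dynamics.** No viscous damping or thermal noise acts on
  `q`; energy changes only through the time dependence of `τ̃`. This is what
  makes the separatrix criterion exact and the amplitude asymptote `τ̃_#`
  sharp. Relaxation *toward* equilibria after a subcritical burst is
  therefore not modelled (a damped molecule would settle into a minimum
  instead of oscillating); activation verdicts are unaffected because they
  are decided at separatrix crossing or first origin contact.
* **Laminar, spatially uniform shear** along the platelet trajectory:
  `τ̃(t̃)` is a prescribed scalar history. Turbulent or stochastic forcing
  is out of scope.
* **Quasi-2D geometry**: one molecule, one coordinate; no interaction
  between neighbouring multimers and no receptor biology downstream of
  unfolding.

State relations: folded state `q_m = (3N/2)^(7/3)`, degree of unfolding
`u = 1 − (q/q_m)^(3/7)`. Multimer sizes `N < 3` are rejected: for them the
fold point `q = (3/2)^7` can leave the physical interval and the
three-regime landscape degenerates.

## Bifurcation analysis

Stationary points of `Ũ_τ̃` solve `τ̃ s³ − s + 1 = 0` in `s = q^(1/7)`.
Working in `s` turns a fractional-power root search into a cubic with a
closed-form discriminant, so no bracketing is needed near the fold. The
smaller positive root is the barrier (`q_barrier`, equal to the saddle
`q = 1` at zero shear, where the cubic degenerates and the value is set
exactly rather than solved); the larger is the interior minimum, reported
only when it lies strictly inside `(0, q_m)`. The partial-unfolding onset
`τ̃_* = ((3N/2)^(1/3) − 1)/(3N/2)` follows from stationarity at `q_m`; the
fold catastrophe `τ̃_c = 4/27` from the double-root condition (at
`s = 3/2`, independent of `N`). At `τ̃ = τ̃_c` exactly the degenerate
stationary point is classified as monostable (no barrier reported).

## Integration and boundaries

`simulate` uses adaptive DOP853 with `rtol = atol = 1e-9` by default —
momenta reach O(10²–10³) and energies O(10⁴), so tight relative control is
needed for the energy tests; measured drift at constant shear is below
1e-10 relative over spans of 10. Integration is split at the shear
profile's breakpoints so discontinuous waveforms never straddle a step.
Three events are located: origin contact (`q = 0`), folded-wall contact
(`q = q_m`), and separatrix crossing (zero-shear energy rising through the
saddle energy `1/8` while `q̇ < 0`).

Boundary handling:

* **Origin**, restitution `e ∈ [0, 1]`: `e = 0` (default) is irreversible
  adhesion — the trajectory terminates in the unfolded absorbing state,
  matching the view that a fully unfolded multimer stays unfolded; `e > 0`
  reflects with `q̇ → −e q̇`. The activation verdict is independent of `e`
  since it is fixed at first origin contact.
* **Folded wall**, STICKY (default) or REFLECT: STICKY zeroes outward
  momentum; while the net force presses into the wall (`τ̃ ≤ τ̃_*`) the
  molecule is held there, and it is released when the shear first exceeds
  `τ̃_* + 1e-7`. The small slack makes the pull-off force decisively
  negative so the freed coordinate leaves the wall monotonically instead of
  dithering in roundoff; the shear impulse ignored while waiting is orders
  of magnitude below the integration tolerance.

A fixed-step velocity-Verlet mode (`simulate_verlet`) exists solely to
audit energy drift of the adaptive integrator; it has no boundary or event
handling.

The separatrix test itself is the energy inequality (`q̇ < 0` and either
`q < 1` or `q̇²/2 + Ũ₀(q) > 1/8`), not an integration to `q = 0`; the two
are equivalent for conservative motion and the inequality is exact. A state
exactly at rest is classified as not crossing, consistent with the strict
inequality in the momentum criterion.

## Activation criteria

`classify` simulates from the folded rest state `(q_m, 0)` over the
profile's support. If the origin is not reached while shear acts, the
conservative separatrix test at the final state decides the post-history
fate exactly — no open-ended integration horizon is needed — and the
residual momentum at eventual origin contact follows from energy
conservation (`|q̇_B| = sqrt(2 E₀)`). The momentum sufficient condition is
evaluated at the trajectory's last state (the end of the shear burst, or
the origin-contact state if absorption happened earlier).

`critical_duration(τ̃_m)` brackets and bisects the rectangular-impulse
duration with the simulator as oracle (relative tolerance 1e-6, iteration
cap 200, initial bracket `[0, 10·CSS₀/τ̃_m]` doubled as needed). The
amplitude asymptote `τ̃_#` is the root of
`Ũ_τ̃(q_m) = Ũ_τ̃(q_barrier(τ̃))` in `(τ̃_*, τ̃_c)`, found by Brent's
method on that residual; amplitudes at or below it return an infinite
duration (reported as `never`). Critical-duration values are raw
dimensionless times; any normalization to a characteristic unfolding time
is left to the user as an external constant.

## Units

All core computation is dimensionless. The physical bridge
(`stress_scale = 4σ/(kd)`, `time_scale = sqrt(4m₀/(15σπ))`) carries no
default constants — the model fixes none of `k, d, σ, m₀`, and inventing
values would lend results false precision. `calibrate_stress_scale` instead
pins the fold catastrophe `τ̃_c = 4/27` to a user-supplied physical
activation stress (e.g. the commonly cited 80 dyn/cm² for sustained shear,
giving a stress scale of 540 dyn/cm²); this is a convenience heuristic,
clearly separated from model predictions.

## Randomized checks and problem sizes

The implication-chain test draws 200 shear histories (fixed seed) mixing
rectangular, trapezoid, truncated-Gaussian and half-sine waveforms with
log-uniform amplitudes in [0.02, 30] — spanning sub-`τ̃_*` to deep
impulsive — and log-uniform durations in [0.05, 50]. This yields roughly a
quarter activating and three quarters not, so both implications are
exercised non-vacuously. The critical-duration curve is tabulated on a
12-point geometric grid from just above `τ̃_#` to `50 τ̃_c`. These sizes
keep the full suite under ten seconds on one CPU while covering every
regime; they are desk-scale by construction, since the model itself is a
single ODE.

What the synthetic waveforms do *not* emulate: measured CFD shear histories
are noisy, non-smooth and multi-peaked. The CSV ingestion path
(piecewise-linear interpolation, exact piecewise integrals) handles such
data, but the package's tests establish correctness of the mechanics, not
fidelity of any particular CFD pipeline.

## Known limitations

* No damping or thermal fluctuations: near-threshold verdicts are sharp in
  the model but would be smeared in reality.
* The partially elastic origin (`0 < e < 1`) is supported but no empirical
  restitution value is known; defaults favour the absorbing limit.
* Validity in turbulent flow is untested and outside the model's
  assumptions.
* The dimensional prefactors entering the time scale matter only when
  converting to physical seconds; users supplying their own constants
  should check the resulting scales against measured unfolding times.
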
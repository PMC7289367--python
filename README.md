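# sipact — shear-induced platelet activation via VWF unfolding

Platelets passing through high-shear regions of the circulation — stenosed
arteries, mechanical heart valves, ventricular assist devices — can be
activated without any agonist, through the mechanics of von Willebrand
factor (VWF). A VWF multimer grafted on the platelet surface is a collapsed
globule at rest; strong shear stress unfolds it into an extended chain whose
A1 domains engage platelet GPIb receptors. `sipact` implements a
coarse-grained dynamical model of that unfolding and the activation criteria
it implies, for people studying flow-induced thrombosis or post-processing
per-platelet shear histories from CFD.

## The model

The conformation of an `N`-subunit multimer is tracked by one dimensionless
coordinate `q = (2r/d)^7` (with `r` the globule radius and `d` the subunit
size), running from the folded state `q_m = (3N/2)^(7/3)` down to `0`
(fully unfolded). Under dimensionless shear `τ̃(t̃)` it moves like a unit
mass in a potential:

    q'' = −τ̃ q^(3/7) + q^(1/7) − 1,
    Ũ_τ̃(q) = (7/10) τ̃ q^(10/7) − (7/8) q^(8/7) + q.

The landscape has three regimes: below `τ̃_* = ((3N/2)^(1/3)−1)/(3N/2)` the
molecule is bistable between folded and unfolded; between `τ̃_*` and the
fold catastrophe `τ̃_c = 4/27` a partially unfolded minimum replaces the
folded one; above `τ̃_c` only the unfolded state survives. The degree of
unfolding is `u = 1 − (q/q_m)^(3/7)`.

For unsteady shear the decisive object is the zero-shear separatrix through
the saddle at `q = 1`: once a trajectory crosses it moving toward `q = 0`,
free motion completes the unfolding. This yields

* a **sufficient** condition — end-of-burst momentum `|q̇_out|` exceeding
  the separatrix momentum `|q̇_A| = sqrt(2(Ũ₀(1) − Ũ₀(q_m)))`;
* a **necessary** condition on the cumulative shear stress
  `CSS = ∫ τ̃ dt̃ > CSS₀(N)` with the closed form

      CSS₀ = (3N/2)^(1/3) · sqrt(7/4 + (1/4)(3N/2)^(−8/3) − 2(3N/2)^(−1/3)),

  an increasing function of multimer size — larger multimers need more
  cumulative shear, and conversely are the first to activate platelets;
* the exact verdict by direct integration of the equation of motion, with
  physical boundary handling at `q = 0` (restitution `e ∈ [0,1]`) and at
  the folded wall `q_m`.

For rectangular impulses of amplitude `τ̃_m` the package also computes the
critical duration `t̃_F(τ̃_m)`, which diverges at an amplitude asymptote
`τ̃_#` (below it no finite impulse unfolds a resting molecule) and
approaches the hyperbola `τ̃_m · t̃_F = CSS₀` for strong impulses.

## Worked example

Thresholds for the reference multimer size `N = 36`:

```
$ sipact css0 --N 36
N = 36
q_m = 11021.8
css0 = 4.17638
saddle_momentum = 225.524
```

`q_m` is the folded-state coordinate, `css0` the critical cumulative shear
stress (dimensionless), and `saddle_momentum` the separatrix momentum
`|q̇_A|`. Critical impulse durations across amplitudes:

```
$ sipact critical --N 36 --tau 0.05 --tau 0.3 --tau 1 --tau 10
# N = 36  tau_hash = 0.0610399  css0 = 4.17638
tau_m   t_F
0.05    never
0.3     15.6439
1       4.31523
10      0.418973
```

The 0.05 amplitude sits below the asymptote `τ̃_# ≈ 0.061`: no duration
unfolds the molecule. At `τ̃_m = 10` the product `10 × 0.419 = 4.19` is
already within 1% of `CSS₀ = 4.176` — the impulsive (hyperbola) regime.
Classifying a smooth shear burst:

```
$ sipact classify --N 36 --waveform half-sine --tau-m 3 --duration 2
verdict = not-activated
css = 3.81972
css0 = 4.17638
necessary_met = False
momentum_sufficient_met = False
```

The burst's cumulative shear (3.82) falls short of `CSS₀` (4.18), so the
necessary condition already rules activation out, and the simulation
agrees. CSV shear histories (`time,shear_stress` columns, e.g. exported
along a CFD platelet trajectory) are classified the same way via
`--csv path.csv`; the same functionality is available from Python through
`sipact.classify`, `sipact.critical_curve`, `sipact.simulate` and friends.

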
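# digrow

**Differential-growth lattice model of pigment-cell patterning** — a kinetic
Monte Carlo simulator plus mean-field Turing analysis for the two-species
(xanthophore/melanophore) model of zebrafish skin pattern formation *without
any cell movement*.

## The scientific problem

Zebrafish skin motifs look and behave like reaction–diffusion Turing
patterns, yet they are built from a discrete mosaic of essentially immobile
pigment cells, not from diffusing morphogens.  This package implements a
minimal stochastic model showing that Turing patterns can nonetheless arise
through *differential growth*: birth and death rates of immobile cells that
depend nonlocally on their neighbors.

The skin is a square lattice whose nodes hold a xanthophore (X, yellow), a
melanophore (M, black) or neither (S), with seven elementary stochastic
processes:

| process | rate | effect |
|---|---|---|
| X birth | `b_X` | S → X |
| M birth | `b_M` | S → M |
| X natural death | `d_X` | X → S |
| M natural death | `d_M` | M → S |
| short-range inhibition of X | `s_M` | X → S if a first neighbor is M |
| short-range inhibition of M | `s_X` | M → S if a first neighbor is X |
| long-range activation of M | `l_X` | S → M if a site at distance `h` is X |

The mutual short-range inhibition provides effective short-range activation
(each species clears room for itself locally), while the long-range
`l_X`-activation of melanophores by distant xanthophores provides the
long-range inhibition of X — the classic Turing ingredients, with no
transport at all.

Averaging the master equation with the mean-field closure
⟨A_i B_j⟩ ≈ ⟨A_i⟩⟨B_j⟩ gives, for average occupations *x*, *m* and
σ = 1 − x − m,

```
dx/dt = b_X σ − d_X x − s_M x ⟨m⟩_nn
dm/dt = b_M σ − d_M m − s_X m ⟨x⟩_nn + l_X σ ⟨x⟩_h
```

where ⟨·⟩_nn and ⟨·⟩_h are first-neighbor and distance-`h` neighborhood
averages.  Linearising about the mixed steady state
(x\* = b_X/l_X, m\* = (l_X − b_X)/(s + l_X), admissible iff l_X ≥ b_X)
gives a dispersion relation ω(k) with nonlocal factors cos(ka) and cos(kha)
(`lattice` mode) or their O(a²) truncations — cross-diffusion-like terms
(`continuum` mode).  The package computes ω(k) in both modes, locates the
Turing bifurcation h_T and the critical wavelength λ_T = 2π/k_T, both by
bisection and by an independent closed form (double root of the determinant
quadratic in k²), and verifies the model's signature law λ ≈ 2h against
stochastic simulations.

## Worked example

```python
from digrow import (ModelParams, SimConfig, run, structure_factor, critical_h,
                    homogeneous_steady_states, classify_morphology)

params = ModelParams(b_X=1.0, s_X=1.0, s_M=1.0, l_X=2.5, h=8)

for s in homogeneous_steady_states(params):
    print(f"{s.label:6s} x={s.x:.4f} m={s.m:.4f} admissible={s.admissible}")

crit = critical_h(params)
print(f"h_T = {crit.h_T:.3f}  lambda_T = {crit.lambda_T:.3f}  "
      f"lambda_T/h_T = {crit.lambda_T/crit.h_T:.2f}")

traj = run(params, SimConfig(n_attempts=50_000_000, seed=2, shape=(64, 64)))
spec = structure_factor(traj.final)
morph = classify_morphology(traj.final)
print(f"pattern: {morph.label}  wavelength = {spec.peak_wavelength:.1f} cells "
      f"(2h = {2*params.h})  peak significance = {spec.peak_significance:.0f}")
```

prints

```
ALL_X  x=1.0000 m=0.0000 admissible=True
MIXED  x=0.4000 m=0.4286 admissible=True
ALL_M  x=0.0000 m=1.0000 admissible=True
h_T = 1.811  lambda_T = 3.992  lambda_T/h_T = 2.20
pattern: STRIPES  wavelength = 13.3 cells (2h = 16)  peak significance = 83
```

Three homogeneous steady states exist (saturated yellow, saturated black,
and the mixed state); the mixed state undergoes a Turing bifurcation already
at h_T ≈ 1.8 for this activation strength, with critical wavelength about
twice the interaction distance.  A 64×64 stochastic run at h = 8 settles
into a striped X/M mixture whose dominant spectral wavelength (13–16 cells)
is again ≈ 2h, and far above the noise floor (peak significance ≫ 5).

## Command line

`digrow simulate | analyze | dispersion | bifurcation | oracle |
reproduce-figure | make-fixture` — run `digrow COMMAND --help`.  Grids are
written as plain CSV (0/1/2 = S/X/M) plus PNG renderings (X yellow, M black,
S white, iridophore mask shaded); every simulation writes a JSON manifest
with parameters, seed and file checksums.  `reproduce-figure fig1|fig2|fig3`
regenerates the reference pattern panels, the bifurcation diagram with KMC
morphology labels, and the dispersion curves around h_T (desk-scale by
default, `--full` for the full-size runs).

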
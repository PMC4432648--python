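# Methods

## Model

Nodes of a periodic square lattice (spacing `a`, one node per cell diameter)
hold exactly one of {S, X, M}: empty, xanthophore, melanophore.  Cells never
move; the only dynamics are the seven elementary processes listed in the
README, each with a time-independent rate constant.  Two neighborhoods
matter: the 4 von Neumann first neighbors (2 on a ring) carry the mutual
short-range inhibition, and the long-range activation of melanophore birth
acts at distance `h`.  In 1-D the long-range neighborhood is exactly
{i − h, i + h}; in 2-D we generalise it isotropically to the one-cell-wide
Euclidean ring |d − h| < 0.5 under the periodic metric (the 4 axis-aligned
sites at distance h are available as an alternative via
`neighborhood=axes` for sensitivity checks — they anisotropically bias
stripe orientation, the ring does not).

**Rate convention.**  Neighbor-mediated processes act through the *average*
occupancy of the relevant neighborhood: the simulator picks one uniformly
random neighbor and accepts the event only if that neighbor has the required
type, so the effective rate is `c_k ×` (eligible-neighbor fraction).  This
convention makes the mixed steady state and its admissibility condition
(l_X ≥ b_X) come out in the simple closed form used throughout; a
sum-over-pairs convention would rescale `s` and `l_X` by the neighborhood
size and shift the admissibility threshold to l_X ≥ b_X / 2.

**Simplified regime.**  All reference computations use
d_X = d_M = b_M = 0 and s_X = s_M = s: deaths and spontaneous melanophore
births are slow compared to the interaction-driven processes on the
timescale of pattern establishment.  The saturated states (all-X, all-M) are
then absorbing in the strict mathematical sense, but pattern selection is
decided long before absorption matters on any simulated timescale.

## Kinetic Monte Carlo algorithm

Rejection sampling: per attempt, draw a uniform site, a process k with
probability P_k = c_k / Σ c_j, and (when needed) a uniform neighbor; apply
the event iff the local configuration permits it; advance the clock by
1/N₀ regardless of acceptance.  One "Monte Carlo step" is one attempt, so
one time unit is one sweep.  The algorithm's clock measures time in units of
Σ c_k; stationary quantities are invariant under this rescaling, which is
why the simulator can be compared directly with the exact CTMC oracle.

Three uniform variates are consumed per attempt in fixed order (site,
process, neighbor — the last drawn even when unused), from a single
generator seeded once per run: identical seeds give bit-identical
trajectories.  The inner loop is JIT-compiled (numba) and sustains roughly
10⁷ attempts/s on one core.  Per-site occupancy time-averages are
accumulated event-driven (O(1) per attempt) over a post-burn-in window, and
global coverages are also averaged over 20 equal batches so Monte Carlo
standard errors can be estimated by batch means.

The iridophore pre-pattern is a static mask on a contiguous band of rows on
which both melanophore birth processes are rejected for the whole run.

## Mean-field reduction and linear stability

Averaging the master equation and factorising pair probabilities gives the
site-wise kinetics quoted in the README.  For plane-wave perturbations about
a homogeneous steady state on a 1-D lattice, every short-range-mediated
coupling of the *neighbor* variable picks up cos(ka) and the long-range one
cos(kha); entries where the perturbed variable is local carry no factor:

```
J(k) = [ -b_X - d_X - s_M m*,            -b_X - s_M x* c1          ]
       [ -b_M - s_X m* c1 + l_X(σ* ch - x*),  -b_M - d_M - (s_X + l_X) x* ]
```

with c1 = cos(ka), ch = cos(kha) (`lattice` mode), or their second-order
truncations 1 − (ka)²/2, 1 − (kha)²/2 (`continuum` mode, the PDE limit in
which the nonlocal interactions appear as cross-diffusion-like terms).  The
growth rate ω(k) is the leading eigenvalue of J(k).

**Turing point.**  In the simplified regime the trace of J(k) is
k-independent and negative, so instability is governed by the determinant,
which in continuum mode is a quadratic in u = k²:
det(u) = α − βu − γu², with β and γ linear in w = h² − 1 (because
l_X σ* = s m* at the mixed state).  The bifurcation is the double-root
condition β² + 4αγ = 0 — a quadratic in w solved in closed form
(`critical_h_closed_form`), with k_T² = β / (2|γ|).  Of its two roots, only
the one with β > 0 places the determinant minimum at positive k²; it is
always the larger root, and yields the smallest valid h_T.  The independent
check is `critical_h`: bisection on continuous h against the sign of
max_k ω(k) (relative tolerance 10⁻⁶), with ω maximised by a 10⁴-point grid
scan over (0, π/a] plus bounded local refinement to 10⁻⁸.  Both routes agree
to better than 10⁻⁴ relative over a 20-point (l_X, s) grid (tested).

Degenerate multiple maxima of ω(k) (possible in lattice mode through
cos(kha) harmonics) are resolved by returning the smallest maximising k and
flagging the result.  The analysis is strictly 1-D; 2-D simulations are
compared against the 1-D k_T under the isotropy of the ring neighborhood.

**Reference values** (b_X = s = 1, a = 1, computed by the package):
at l_X = 1.0193, h_T = 7.999 (rounds to 8) with max ω < −10⁻³ at h = 7 and
> +10⁻³ at h = 9; at l_X = 2.5, the lattice-mode fastest-growing wavelength
at h = 16 is 2.02 h, and the continuum critical point has
λ_T / h_T = 2.204.  Near the admissibility threshold the continuum ratio
drops (≈ 1.31 at l_X = 1.0193); the λ ≈ 2h law is a lattice-mode and
simulation statement there.

**Deterministic lattice ODEs.**  `integrate_lattice_meanfield` integrates
the site-wise mean-field ODEs on a ring (LSODA, rtol 10⁻⁸ / atol 10⁻¹⁰).
The vector field leaves the simplex {x, m ≥ 0, x + m ≤ 1} invariant, so no
clipping is applied; the result is validated against a 10⁻⁶ bound tolerance
and the integration fails loudly rather than silently projecting.

## Exact oracle

For rings of N ≤ 7 sites the full master equation over 3^N configurations is
built explicitly with the same rate convention (neighbor fractions over the
two-offset multiset {i − h, i + h} mod N, which may collide on tiny rings —
the simulator uses the identical convention, so the two agree exactly).
Stationarity is solved by dense linear algebra with a residual bound of
10⁻¹²; irreducibility (all seven rates > 0) is verified by strong
connectivity, and reducible chains (e.g. the simplified regime, whose
saturated states are absorbing) are rejected by name.  The oracle also
reports exact pair correlations and the worst-case mean-field factorisation
error, which decays to zero as the interaction rates are scaled away.

## Pattern quantification

*Structure factor*: FFT of the mean-subtracted M-indicator field, power
normalised so the total equals the field variance (Parseval, tested at
10⁻⁶), radially binned with width 2π/max(W, H), peak taken over bins
excluding k = 0 with quadratic interpolation; peak significance = peak power
over median bin power, with > 5 treated as a real intrinsic wavelength.
The M field is used because melanophore domains are what experiments track;
near-binary patterns give the same peak on the X field by complementarity.

*Morphology*: coverages below 2% give the homogeneous labels; otherwise the
minority phase's 4-connected components on the torus decide — components are
unwrapped through the periodic boundary, their second-moment ellipse (with a
1/12-pixel variance floor) gives an elongation, and a size-weighted mean
elongation ≥ 2 or a component spanning a full period (percolation) gives
STRIPES, else spots of the minority phase.  Components below 4 pixels are
counted but excluded from elongation statistics (they are demographic noise,
single newborn or dying cells).  All thresholds (2%, elongation 2, 4-pixel
floor, ±15° orientation sectors) are package choices exposed as arguments;
the underlying categories are qualitative.

*Orientation anisotropy*: spectral power within ±15° of the vertical k-axis
over that within ±15° of the horizontal k-axis; > 1 means horizontal
stripes.

## Synthetic fixtures and what tests show

`make_stripes` / `make_spots` / `make_noise` plant clean periodic stripes,
disk lattices and i.i.d. fields to calibrate the estimators.  They emulate
the *geometry* of simulated patterns, not their statistics: real KMC
snapshots carry demographic noise (isolated cells, ragged interfaces,
defects) that the fixtures lack, so fixture tests validate the estimators'
correctness while only the KMC-based tests validate their robustness.  None
of the synthetic data emulates real fish skin: passing tests demonstrate
internal consistency of model, theory and simulation, not biological fit.

## Problem sizes

Stochastic checks run at reduced scale as a package choice: 64×64 lattices
with h = 8 and 3–5 × 10⁷ attempts for wavelength and orientation statistics,
96×96 with h = 15 and 10⁸ attempts for the morphology sequence, against the
full-scale reference of 100×100 with h = 16 and 10⁹ attempts (reachable via
`digrow reproduce-figure --full`).  At 64×64 a wavelength of 2h = 16 cells
leaves four periods per axis, enough for a clean spectral peak; at 96×96 the
h = 15 morphologies hold ~3 periods.  Smaller lattices bias the spectral
peak towards the few available discrete modes, which is the dominant
contribution to the ±25% scatter of the simulated wavelength ratio.

## Known limitations

- The mean-field closure ignores pair correlations; the oracle shows
  factorisation errors of a few 10⁻² at reference interaction strengths, so
  mean-field steady states are approximations to the true lattice averages.
- Morphology labels are threshold-based and can flip on borderline
  labyrinths (elongation near 2); sequence tests therefore use majority
  votes over seeds.
- No cell motility, no third species beyond the static iridophore mask, no
  hexagonal or off-lattice geometry, and no weakly nonlinear (amplitude
  equation) analysis: stripe-vs-spot selection in 2-D is assessed
  empirically.
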
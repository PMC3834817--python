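# Methods

`visemech` models a DNA "molecular vise": a hairpin whose all-A-T stem
applies a near-constant compressive force, through two single-stranded
tethers, to a short duplex "target strand" hybridized across the loop apex.
FRET between a dye pair at the stem–loop junction reports how far the stem
has unzipped, and therefore how the target responds to compression: a
short, stiff target stays straight and unzips the stem (low FRET); past
the Euler threshold it buckles and the stem re-zips (FRET recovers); at
high ionic strength a locally melted kink replaces smooth buckling.  This
note records the model, its parameters, the numerical choices, and what
the shipped calibrations do and do not establish.

## Continuum mechanics

The duplex is a worm-like chain with bending modulus `κ = l_p·k_B·T`
(`l_p = 46.5` nm by default, the consensus value from cyclization and
stretching experiments; `k_B = 0.0138065` pN·nm/K, `T = 298` K).  The
classical results used throughout:

* Euler buckling force of a rod of length `h`: `F_c = π²κ/h²`; the
  buckling length at constant force `F`: `h_b = π·√(κ/F)`.  At 9 pN,
  `h_b = 14.48 nm = 42.6 bp` at a 0.34 nm/bp rise.
* Planar pinned–pinned elastica at fixed end-to-end distance `x`: with
  `k = sin(α/2)` the modulus of the pendulum solution,
  `x/h = 2E(k)/K(k) − 1`, `F = κ(2K(k)/h)²`, and the bending energy has
  the closed form `U = F·(x − h(1 − 2k²))`.  These relations are
  tabulated once on a 4001-point grid of `x/h` and interpolated.
* Constant-curvature arc: `U = κL/(2R²)`; a 64-bp minicircle stores
  `2π²κ/L ≈ 42.2 k_BT`.
* One-hinge closed elastica ("teardrop"): within the closed one-hinge
  pendulum family the closure condition `2E(k) = K(k)` fixes the shape
  uniquely (`k ≈ 0.9089`); its energy is 71.2% of the circle's, i.e. a
  single fully flexible kink releases 28.8% of a minicircle's bending
  energy and a second, diametric kink releases the rest.  The test suite
  checks both the elastica and the teardrop against brute-force
  discretized-chain minimizations (SLSQP over segment tangent angles).

Single-stranded DNA is an extensible freely jointed chain: fractional
extension `x/L = [coth(Fb/k_BT) − k_BT/(Fb)]·(1 + F/S)` with contour
0.59 nm/nt, Kuhn length `b = 1.5` nm and stretch modulus `S = 800` pN.
Stretching free energies are work integrals of the inverted
force–extension law, tabulated per nucleotide (extensivity) on a dense
force grid up to 300 pN; spans beyond the reachable contour carry an
infinite-energy sentinel.

The stem's A-T base-pairing energy defaults to `dg_bp_stem = 1.3` k_BT/bp.
With the ssDNA model above this places the equilibrium unzipping plateau
(`dg = 2·g_nt(F)`, where `g_nt` is the free energy released per
transferred nucleotide) at 10.0 pN, consistent with the ~9 pN A-T
unzipping force given the uncertainty of the ssDNA parameterization;
`mechanics.calibrate_stem_energy()` pins the plateau to an exact force if
desired.  The buckling minimum of the predicted FRET curves tracks this
plateau force, so the pair (ssDNA model, `dg_bp_stem`) should be treated
as one calibration unit.

## The ensemble model

States are enumerated on a grid (one-dimensional collinear closure):
stem unzipping `m = 0..39` (exhaustive), target end-to-end `x` and dye
separation `r ≤ x` on 0.1-nm grids.  The 2m unzipped stem nucleotides
span `r` through the open fork; the two tethers (the unhybridized halves
of the loop) together span `x − r`.  Because the fork position
equilibrates, the tether pair is treated as one combined chain of
`t1 + t2` nucleotides — exact for even splits by FJC extensivity, and the
correct off-centre optimum for odd splits (forcing equal per-tether spans
would make 1-nt tethers unreachable and produce an odd/even artifact in
the curves).

The statistical weight of a state is `exp(−E)` with

```
E = m·dg_bp_stem + U_ss(2m nt; r) + (3/2)·ln(2m)
  + U_ss(t1+t2 nt; x−r) + G_bend(x)
```

Two measure terms dress the bare energies, making the sum a faithful
finite-temperature ensemble rather than a zero-temperature energy
landscape:

* `G_bend(x) = U_elastica(x) − k_BT·ln B(δ) + 2·k_BT·ln max(x/h, 0.4)`.
  `B(δ) = Σ_l (−1)^{l+1} l² e^{−(l²−1)δ}` with `δ = π²(1 − x/h)·l_p/h`
  is the stiff-chain (Wilhelm–Frey) fluctuation measure: it tends to 1
  away from full extension and vanishes with an essential singularity at
  `x = h` — a thermalized chain is never exactly straight.  It is
  evaluated by the direct series for `δ ≥ 0.15` and by its
  Poisson-resummed (Jacobi-theta) form below that, where the alternating
  series cancels catastrophically in floating point.  The `2·ln(x/h)`
  term converts the radial end-to-end density to the directional one
  appropriate for the collinear closure (the `4πx²` shell factor divided
  out), capped at `x/h = 0.4` where the shell picture ends.
* `(3/2)·ln(2m)` is the saddle-point prefactor of the fork chain's
  end-to-end density (`Q_n ∝ n^{−3/2} e^{−n·i(ξ)}`): unzipping carries a
  translational-entropy cost beyond base pairing and stretching.

`scripts/validate_thermal_measure.py` checks this composite weight
against umbrella-sampled Metropolis Monte Carlo of a discrete worm-like
chain (free ends, pivot moves, WHAM stitching): the model's
`−ln P_vec(x)` tracks the sampled free energy to within a few tenths of
k_BT over `x/h ∈ (0.45, 1)` for contour-to-persistence ratios spanning
the vise's target strands.  These measure terms are what produce the
small thermal shortening of the predicted buckling transition (a
~40-bp minimum against the 42.6-bp constant-force estimate) and they
remove the odd/even tether artifact; without them the transition sits at
the zero-temperature threshold.

FRET is the Förster point-dipole form `E = 1/(1 + ((r + r_off)/R_0)^6)`
with `R_0 = 6.2` nm (a plausible value for a Cy3B/AF647-class pair) and
`r_off = 0`; the predicted curve is the Boltzmann average of `E` over the
grid.  Prediction involves no random numbers and is memoized per
(parameters, design, grid).

Model-to-data fitting follows the two-stage scheme the readout demands: a
single multiplicative scale factor per loop (closed form
`a = Σmd/Σm²`), then an optional scan of `l_p` minimizing the pooled
residual.  `lp_for_minimum_at` reports the onset boundary — scanning
`l_p` downward, the largest value at which a loop's predicted minimum
sits at the requested target length, interpolated half a grid step —
because "the minimum shifts to 30 bp" is a statement about where that
shift first happens.

## Meltable worm-like chain (kinking)

Kinked states add an apex-centred melt bubble of `n = 1..6` bp and a
hinge opening angle `φ` on a 5° grid.  The duplex arms are straight rigid
rods (`x = (h−n)·rise·sin(φ/2)`); the melted region absorbs the full
turning angle `π − φ` as a constant-curvature segment of persistence
length `lp_melt = 1` nm.  The kink free energy decomposes as

```
ΔG_kink = [n·dg_melt + σ_coop + U_bend(melt)]  +  [ΔG_relax ≤ 0]
```

with `ΔG_kink` computed exactly as the difference of constrained
partition functions (kinked-with-bubble-n vs duplex-only).  The three
relaxation channels (duplex bending, ssDNA stretching, stem re-zipping)
are reported as the differences of the channel's ensemble means, rescaled
proportionally so the six terms sum exactly to `ΔG_kink`; the small
residual so absorbed is the entropy difference between the two state
sets.  A mismatch contributes its destabilization `ΔΔG` as a credit to
the bubble's base-pairing term whenever the bubble covers its position
(`n ≥ 2·|offset|`).

The two-parabola energy-landscape picture is available analytically:
`effective_bending_energy` returns the lower convex envelope of the
intact (`κc²/2`) and melted (`ε + κ_m c²/2`) energy densities with the
common-tangent points `c_A = √(a₂ε/(a₁(a₁−a₂)))`, `c_B = a₁c_A/a₂`
(`a_i = l_p/2` per unit length in k_BT), labelling the coexistence window
"kinked".

## Salt calibration

Ionic conditions map to parameters through simple laws with configurable
coefficients (`saltmodel.SaltCoefficients`): effective monovalent ionic
strength `I = 30 mM (tris/borate background) + [Na⁺] + 60·[Mg²⁺]`;
base-pairing energies grow as `+0.30·ln(I/I_ref)` k_BT/bp; the bubble
penalty falls as `−3.3·ln(I/I_ref)` k_BT (counterion condensation
preferentially stabilizes the condensed, sharply bent kink); the ssDNA
Kuhn length shrinks as `(I_ref/I)^{0.1}`; and `l_p` carries a small
Odijk–Skolnick–Fishman component (32.4 nm·mM).

Two coefficients are true calibration artifacts and are documented as
such: the reference bubble penalty `σ_coop = 26 k_BT` and the
`3.3 k_BT`/e-fold kink stabilization.  They were set, once, so that the
model reproduces the qualitative phenomenology: no kinking anywhere at
the reference condition, a sodium transition midpoint between the 50 and
100 mM scan points, and a 30-bp kinking transition at 250 mM Na⁺.
`σ_coop` is larger than bare two-state melting cooperativity estimates
(~10 k_BT) because the collinear closure overestimates the strain free
energy that the kink relaxes; the surplus is absorbed into `σ_coop`
rather than into the geometry.  Passing the calibration-level tests
therefore shows internal consistency of the shipped parameter set, not an
independent measurement of bubble thermodynamics.  The single-axis
"equivalent monovalent" treatment of Mg²⁺ is crude by construction: one
multiplier cannot simultaneously place the Mg midpoint at exactly 0.5 mM
and make 1 mM Mg²⁺ as strongly kink-stabilizing as 250 mM Na⁺; the
default (×60) favors the midpoint and is checked only qualitatively.

With the shipped high-salt calibration the kinking minima of the 36- and
40-nt loops sit at 29 and 31 bp: the collinear closure separates the two
loops' transitions by ~2 bp (their tether slack differs), so the
transition length is reported as the mean of the two loops.

## Synthetic data

Generators are pure functions of (spec, seed) using numpy's PCG64
(`default_rng`); outputs are bit-reproducible.  FRET curves emulate
gel-derived replicate averages: truncated-Gaussian noise (sd 0.02) on the
model curve, four replicates, SEM = sd/√n.  Channel tables emulate
three-cube gel scans: `A_GG = B(1−E)`, `A_RR = BE`,
`A_GR = γBE + αA_GG + δA_RR` with a log-uniform per-band brightness `B`
and log-normal channel noise (CV 0.05); the construction is the exact
inverse of the crosstalk correction, so extraction is exact at zero
noise.  The mismatch panel drives the MWLC model with a synthetic
destabilization table (ordered like the nearest-neighbour stability
ranking of the eight single mismatches; illustrative values, not
literature constants) at a 50 mM Na⁺ assay condition, where the intact
target still bends as a WLC but destabilized targets kink.

What the generators do **not** emulate — and hence what passing recovery
tests cannot establish about real gels: band detection and integration,
electrophoretic mobility, steric clash between target and tethers at
short target lengths, dye linker dynamics and orientation factors, and
spatial noise correlations within a gel.

## Numerical choices

* Grids: `dx = dr = 0.1` nm, hinge 5°, `n_melt ≤ 6`.  Doubling the
  resolution changes predicted FRET by < 0.005 (tested).
* Elastica inversion `x/h → k` by `brentq` at `xtol = 1e−14` on a cached
  4001-point table; ssDNA tables use 5700 force points to 300 pN.
* The curve minimum is the deepest strictly interior local minimum; a
  `min_depth` filter (0.01–0.1 depending on context, i.e. at or above
  the measurement noise scale) ignores dips smaller than the data could
  resolve.
* Partition sums use raw `exp(−E)` in float64 (state energies are
  O(10¹) k_BT, far from underflow); infeasible states are `inf`, never
  silently dropped.
* Exact Spearman p-values enumerate all `n!` permutations for tie-free
  `n ≤ 9` (vectorized, ~40 ms at n = 8); ties or larger n fall back to
  the large-sample approximation with a warning.  The p-value is
  two-sided by definition; note that for `n = 8, Σd² = 8`
  (ρ = 0.905) the one-sided count is half, ≈ 2.3×10⁻³.

## Known limitations

* The collinear closure is the main geometric idealization: it
  overestimates tether strain (absorbed by `σ_coop`), separates the
  36/40-nt loops' kink transitions by ~2 bp, and leaves the predicted
  low-salt curves without the short-target steric-clash plateau seen in
  measured data (deliberately not modelled).
* Torsion is ignored throughout (the vise applies pure bending), so
  minicircle energetics here are bending-only.
* The melted region is a single effective chain with one persistence
  length; sequence-resolved nearest-neighbour melting inside the bubble
  is out of scope (mismatches enter only through a position-gated ΔΔG).
* The salt laws are empirical one-axis corrections, not electrostatics;
  coefficients outside the calibrated 0–250 mM Na⁺ / 0–1 mM Mg²⁺ window
  are extrapolations.
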
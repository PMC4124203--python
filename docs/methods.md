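# Methods

## Model and assumptions

The simulator implements sequential quenching (SQ): irreversible adsorption
in which each arriving particle diffuses on the surface among its already
quenched predecessors and is then fixed permanently.  The model is athermal
with respect to desorption (no particle ever leaves or moves again after
quenching) and strictly two-dimensional: transport from solution to the
surface is not resolved, an arriving particle simply appears at a uniformly
random position.  Only the newest particle is mobile, so there is no
collective relaxation; the final structure is history-dependent and in
general not an equilibrium configuration.

Surface chemistry enters solely through the pair potential.  The
triangular well

u(r) = ∞ for r < d; −(ε/U)(λd − r)/(λd − d) for d ≤ r ≤ λd; 0 beyond λd

bundles particle–particle and particle–surface energetics into a single
region-dependent depth ε/U: on a favorable region (small U, e.g. a
laser-ablated stripe) particles bind each other strongly; on a passivated
region (large U, e.g. a PEO-coated stripe) the same pair is weakly bound.
The depth factor is taken from the stripe occupied by the **moving**
particle, evaluated at its current (or proposed) position.  This is the
convention that creates a thermodynamic drive toward favorable stripes: the
same pair geometry is deeper in energy when the mobile particle stands on a
small-U stripe, so Metropolis sampling pulls it across the boundary.  A
symmetric (pair-midpoint) assignment would weaken but not qualitatively
change this drive; the moving-particle convention is the simplest one
consistent with "energy of the particle where it moves".

## Parameters

| parameter | meaning | default | notes |
| --- | --- | --- | --- |
| L | box side, units of d | 20 | periodic in both axes; 1000 d² box for the finite-size check |
| ρ\* | target reduced density ρd² | 0.3 | N = round(ρ\*L²/d²): 120 and 300 particles on the two boxes |
| T\* | kT/ε | 1.0 | the Boltzmann exponent is E/(T\*ε) |
| λ | well-range multiplier | 1.5 | well width (λ−1)d = 0.5 d |
| U1, U2 | stripe energy factors | 1, 1 | depth ε/U; pattern R1\|R2\|R3 = U1, U2, U1 |
| moves | attempted Metropolis moves per particle | 3000 | fixed budget, no convergence test |
| max displacement | per-axis proposal cap | 0.5 d | independent uniform offsets per axis |
| realizations | ensemble size | 100 | independent streams per realization |
| Δr | RDF bin width | 0.05 d | resolves the 0.5 d well with 10 bins |
| r_max | RDF range | L/2 | minimum-image validity limit |

Stripe widths default to equal thirds along x (the pattern is uniform in
y); widths are configurable as (label, width-fraction, factor) triples.
With both axes periodic, R1 and R3 are adjacent across the x-boundary;
both carry U1, so the energy landscape stays consistent.

## Protocol details and numerical choices

* **Move counting.**  "Moves" are attempted moves, rejections included —
  the standard Metropolis convention, and the only one with bounded cost
  when wells are orders of magnitude deeper than kT (acceptance rates then
  approach zero for bound particles).
* **Proposal.**  Independent per-axis uniform offsets in [−0.5d, +0.5d]
  (square proposal), symmetric, so plain Metropolis acceptance is valid.
  Proposals are wrapped into [0, L) before region lookup and energy
  evaluation; because the cap never exceeds L/2, a single conditional fold
  suffices.
* **Hard core.**  A proposal overlapping any quenched particle has
  E = +∞ and is rejected outright; insertion draws are repeated until the
  candidate clears the hard core, with a retry cap (10⁶) that converts a
  jammed, infeasible density into a diagnosable error rather than a
  livelock.  Every emitted configuration satisfies the pairwise minimum-
  image distance ≥ d invariant exactly.
* **Energy bookkeeping.**  The mobile particle's energy is evaluated
  against all quenched particles by direct summation (N ≤ a few hundred at
  the densities of interest, so no cell list is needed); the compiled
  kernel accumulates terms in insertion order with the same arithmetic as
  the pure-Python reference, and a brute-force oracle checks exact
  agreement.  Energies are reported in units of ε.
* **Randomness.**  One master seed; realization k of an ensemble (and
  condition i of a sweep) runs on an entropy path (seed, [i,] k) fed
  through `numpy.random.SeedSequence`, giving independent, order-invariant,
  bit-reproducible streams.  Identical inputs and seed reproduce
  configurations exactly.
* **RDF normalization.**  N_i counts unordered pairs; the literal
  linear-shell formula g = N_i/(π r_i Δr ρ N n) with r_i the lower bin edge
  is the default (for the r_i = 0 bin, where it degenerates, the exact
  annulus area is substituted).  An exact-annulus mode
  (`mode="shell"`) is available; for uniformly random input both calibrate
  to g = 1 within sampling error.  ρ is the global density N/L² even on
  patterned surfaces, so stripe clustering appears as g > 1 structure.
  Ensemble averages pool counts over configurations (identical to averaging
  per-realization g at equal N); the quoted uncertainty is the standard
  error of single-realization g values.
* **Ensemble errors.**  Occupancy fractions are computed per realization
  (summing to 1 each) and aggregated to mean ± standard error.

## What the synthetic generators emulate

The ideal-gas generator produces uniformly random points with no hard core:
it is the definitional g = 1 reference of the RDF normalization and mimics
nothing else about adsorption.  The lattice generator pins RDF peak
positions analytically.  Passing tests against these references validates
the estimator and the sampling kernel, not the realism of the physical
model: real protein adsorption involves solution-phase transport,
orientation and conformation changes, and soft (electrostatic, depletion)
interactions that the hard-disk + triangular-well model deliberately omits.

## Observed behavior and known limitations

* **Finite-size independence.**  Because the interaction range is 1.5 d,
  first-peak heights on 400 d² and 1000 d² boxes agree to within ensemble
  error (about a percent at a few hundred realizations); the acceptance
  script reports the measured relative difference, which at these ensemble
  sizes is dominated by Monte Carlo noise rather than any systematic box
  effect.
* **Selectivity crossover.**  With U2 = 1 and kT = ε, lowering U1 deepens
  the outer-stripe wells as ε/U1.  The center-stripe occupancy falls below
  half its area share already at U2/U1 = 5 (wells of 5 ε capture and hold
  diffusing particles within the 3000-move budget); at U2/U1 = 2 occupancy
  is only mildly depressed (≈ 0.24 vs 1/3).  The crossover to selective
  adsorption in this implementation therefore lies between ratios 2 and 5.
* **Saturation and annealing at extreme depths.**  Once ε/U ≫ kT, capture
  is total and the first-peak height saturates; the residual trend is set
  by annealing, not binding: at depth ~10³ ε a bound particle can still
  accept micro-rearrangements (uphill steps of order kT correspond to
  displacements ~kT·(λ−1)d/depth), while at depth ~10⁴ ε it cannot, so
  slightly *shallower* deep wells pack contacts marginally better.  In
  consequence the peak height is not strictly monotone in U1 across the
  saturated regime, and fixed-ratio series (same U1/U2, different absolute
  scale) agree only to a few percent rather than exactly.  Both effects are
  systematic but small (1–5 % of the peak height) and invisible at
  figure-level comparison of g(r) curves.
* **Fixed move budget.**  3000 attempted moves is a protocol parameter,
  not a convergence guarantee; structures are quenched out of equilibrium
  by design, and a handful of particles remain on unfavorable stripes even
  at extreme energy ratios.

## Problem sizes used in the shipped checks

The test suite runs scaled-down ensembles (10–40 realizations; trajectories
of 2 × 10⁶ steps for the stationarity check, thinned to every 500th step to
decorrelate samples before a χ² comparison against a midpoint-quadrature
Boltzmann reference on a 5 × 5 cell grid).  The acceptance script uses 300
realizations per box for the finite-size comparison — above the
100-realization floor, to sharpen the statistical part of the difference —
and 20 realizations per condition for the selectivity scan.
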
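# Methods

## The model

Chromatin is coarse-grained at 100 kbp per bead (σ0 = 150 nm, the gyration
diameter of a 500-nucleosome segment).  Each bead carries a sequence class —
forest (F, CGI-rich, compartment-A-like) or prairie (P, CGI-poor,
compartment-B-like) — a lamina-association flag (LAD) and a TAD-boundary
flag.  Energies are in ε0 = k_B·T0 with T0 = 308 K (≈ 2.6 kJ/mol), time in
τ0 = σ0√(m/ε0), bead mass m = 1.

The potential has four terms:

1. **FENE backbone** between consecutive beads of a chain,
   U(r) = −½·K·R0²·ln(1 − (r/R0)²), K = 30 ε0/σ0², R0 = 1.5 σ0, divergent
   at R0.
2. **Truncated-and-shifted Lennard-Jones** between every bead pair (bonded
   pairs included), cutoff rc = 1.3 σ0, so attraction exists only between
   beads effectively in contact:
   U(r) = 4ε[(σ0/r)¹² − (σ0/r)⁶ − (σ0/rc)¹² + (σ0/rc)⁶] for r < rc, else 0.
   The well depth U(rc) − U(2^{1/6}σ0) = 0.3430·ε, i.e. 1.0–1.7 ε0 for the
   allowed ε ∈ [3, 5] ε0 — a van-der-Waals-scale contact energy.  The class
   pair strengths default to ε_PP = 4.6, ε_FF = 4.3, ε_PF = 3.0 ε0
   (heterochromatin-like P–P contacts strongest, F–P weakest, driving
   microphase separation of the block copolymer).  Note that the energy is
   continuous at rc but the force is not; this truncation is the model's
   definition (it matches LAMMPS `pair_style lj/cut` with
   `pair_modify shift yes`) and its consequences for energy conservation
   are discussed below.
3. **Harmonic TAD-boundary bonds** U = ε_b·r² (zero rest length, no ½
   factor, exactly as defined) between consecutive TAD-boundary beads of a
   chain; ε_FB = 0.4, ε_PB = 0.2 ε0/σ0² — F-TADs are smaller and more
   tightly looped than P-TADs.  A bond is classed F-TAD when strictly more
   than half of the spanned beads (endpoints included) are F, else P-TAD
   (ties break to P).
4. **Spherical wall** of radius R.  LAD beads feel an attractive LJ toward
   the nearest wall point (ε_LC = 6.7 ε0, cutoff 1.3 σ0, mimicking lamina
   tethering); all other beads a purely repulsive WCA wall (cutoff
   2^{1/6} σ0; its prefactor, 1.0 ε0, is irrelevant to the physics because
   the term is purely repulsive).  Wall distance is measured radially from
   the bead center to the sphere surface.

The container radius follows from the chromatin volume fraction φ = 5%
with the bead volume taken as a sphere of diameter σ0:
R = (n·(σ0/2)³/φ)^{1/3} (13.6 σ0 for 1000 beads).  Published radii for
specific chromosomes (e.g. 16.7 σ0) assume a different bead-volume
convention that is not derivable from φ alone, so `container_radius`
accepts an explicit override.

## Synthetic annotations

The generator builds chains of alternating F/P blocks in which every block
is a whole number of TADs: the number of TADs per block is shifted-geometric
(minimum 1) with mean = block mean / TAD mean, and each TAD length is
shifted-geometric with the class mean (F 4.4 beads, P 6.6 beads — the means
measured on human chr10).  This composition realizes the requested mean TAD
sizes exactly in expectation, with no truncation bias at block edges.  When
a class's block mean is below its TAD mean the block is one TAD of the
block's mean length.  Default composition is f_fraction = 0.5 with a
20-bead F+P period; LADs are whole P domains selected largest-first
("concentrated") or smallest-first ("dispersed") until the requested
fraction of P beads is covered (within one domain).  Geometric lengths make
single-chain composition estimates noisy — a 2000-bead P-rich chain holds
only ~100 blocks — which is why statistical tests pool several chains.

What the generator does **not** emulate: real chromosomes have long-range
correlated domain structure, centromere-proximal repeat deserts, and
TAD-size distributions with heavier tails than geometric; passing tests on
synthetic chains therefore validate the pipeline mechanics and the model's
qualitative physics, not chromosome-specific numbers.

## Dynamics

The integrator is a BAOAB splitting of underdamped Langevin dynamics with
dt = 0.01 τ0.  Two desk-scale efficiency choices, both documented here
because they alter no equilibrium average:

* **Friction γ = 0.25 τ0⁻¹.**  Langevin friction in a reduced-unit model is
  a sampling-rate knob, not a physical observable; the slow collective
  modes (center-of-mass diffusion toward the wall, globule reorganization)
  relax ∝ 1/γ, so a small γ buys equilibration at fixed step count.
* **Thermostat (OU) substep every 4 steps**, with the exact
  exp(−γ·4dt) decay.  At γ = 0.25 the velocity relaxation time is 4 τ0 =
  400 steps, so the Ornstein–Uhlenbeck process is still resolved ~100×
  per relaxation time.

Kinetic temperature is measured from half-step (midpoint) velocities;
full-step velocities in velocity-Verlet-type schemes are biased low by
O((ω·dt)²) for stiff modes.  With these settings the measured kinetic
temperature is within 1% of the target on dense test systems.

**Initialization and annealing.**  Each replica starts from a random
self-avoiding walk (step 1 σ0, minimum pair separation 0.8 σ0, placed
inside the sphere) with Maxwell–Boltzmann velocities at 5 T0, then anneals
the thermostat linearly from 5 T0 to 1 T0.  Two stability measures apply
during annealing only: a displacement cap (0.05 σ0/step) for the first 10⁴
steps resolves the steep overlaps of the fresh walk, and bead speeds are
clipped at 2× the instantaneous thermal speed for the rest of the anneal —
at T ≈ 5 the bare dt = 0.01 τ0 step is unstable against rare collision
spikes that can overstretch a K = 30 FENE bond.  The clip affects ~0.7% of
thermal draws and only during equilibration; production dynamics are
unmodified.

**Energy conservation.**  With the thermostat off the integrator conserves
energy to the usual velocity-Verlet shadow-energy accuracy *between* cutoff
crossings; each crossing of the rc = 1.3 σ0 cutoff injects an O(F(rc)·dt)
error because the model's truncated-shifted force is discontinuous there
(F(rc) ≈ 10 ε0/σ0 at ε = 4.6).  The NVE check therefore uses a cold
compact chain in which no pair crosses the cutoff.

**Neighbor search** uses counting-sort cell lists at the cutoff scale with
a Verlet skin (default 0.45 σ0), rebuilt when the two most-displaced beads
could jointly have closed the skin gap.  Forces, integration and contact
counting are JIT-compiled (numba).

## Observables

Two beads are in contact when their center-to-center distance is strictly
below 2.5 σ0.  The contact map pools all frames of all replicas with equal
weight; its diagonal is defined as 1 and excluded from P(N).  P(N) averages
the map over all same-chain pairs at each separation (FF/PP restrictions
keep pairs whose two beads are both F/P).  Power-law exponents are −slope
of an ordinary least-squares line on (log₁₀N, log₁₀P); the three regime
windows are 300–700 kbps (TAD scale), 700 kbps–7 Mbps, and 7–20 Mbps.
Radial profiles count F and P beads in 200 equal-thickness shells, divide
by shell volume, and average over frames; the abscissa is r/R.  The
windowed Fourier analysis takes the 5th contact-map diagonal, cuts it into
non-overlapping 20-bead (2 Mbps) windows, subtracts each window's mean, and
averages amplitude spectra over F-majority and P-majority windows
separately.  Inter-chain statistics compare same-chain contact means at
separations > 5 Mbps with the mean over all cross-chain bead pairs.
External P(N) tables are aligned by matching P at N = 300 kbps (nearest
grid point) to the simulated value.

## Desk-scale protocol and what it reproduces

The published protocol (2×10⁸ steps per replica) is exported to LAMMPS
rather than run natively.  The package's desk-scale protocol — used by the
test suite and by `scripts/acceptance.py` — is: 1000-bead synthetic chain,
reference parameters, 4 replicas, 10⁵ annealing + 10⁶ production steps per
replica, snapshots every 10⁴ steps (≈ 8–10 CPU-minutes total).  Directional
comparisons (parameter sweeps, two-chain systems, LAD-pattern contrasts)
use 300–500-bead chains and 6–8×10⁵ steps.

At this scale the ensemble reproduces: the three-regime shape of P(N) with
a clearly steeper intermediate regime (α ≈ 1.2 vs ≈ 1.3 published) and a
long-range flattening (α < 1); the direction of the ε_PB effect (TAD-scale
α decreases, intermediate α increases with stronger boundary bonds); LAD
ordering toward the wall and its strengthening with ε_LC; chain-territory
contrasts.  It does **not** reach the fully wall-adsorbed equilibrium: at
10⁶ steps only a minority of LAD beads (∼5–8%) are adsorbed, because the
collapsed globule's center-of-mass must diffuse to the wall and the
adsorbed layer then spreads slowly.  Two published numbers are known to
sit beyond desk scale as a consequence: the sharp peripheral P-density
peak, and the TAD-regime exponent α ≈ 0.8, which we measure at ≈ 1.0 —
the central-globule state packs short-range contacts more steeply than the
spread, wall-wetted conformation.  Both converge only on production-length
runs (the LAMMPS export path).

## Numerical choices and edge cases

* Ties in the F/P majority vote (and uncovered bins) resolve to P, the
  background class; a trailing partial bin is kept if ≥ 50 kbp.
* A bead "has" lamina signal when signal intervals overlap > 50% of its
  bin; a domain becomes a LAD when strictly more than half its beads have
  signal.
* Centromere beads are removed by the bin-midpoint rule and the chain is
  re-bonded across the gap.
* P(N) fits drop non-positive points and require ≥ 3 points per window.
* Replicas derive independent seeds from the master seed
  (`SeedSequence`), so results are independent of execution order; every
  stage is deterministic given its seed.
* The LAMMPS export writes the FENE bond with its internal WCA term zeroed
  and `special_bonds lj 1 1 1`, because the class-dependent pair potential
  already acts on bonded neighbors (the native engine does the same).

## Known limitations

* Single-precision contact kinetics of real chromosomes (loop extrusion,
  cell-type-specific epigenetics) are outside the model by construction.
* The wall-adsorption equilibrium is out of desk-scale reach (above); any
  quantitative statement about peripheral LAD density requires the
  production-scale protocol.
* The harmonic boundary-bond form ε_b·r² with zero rest length is taken
  exactly as defined; with a nonzero rest length TAD loops would be looser
  and the short-range P(N) regime shallower.
* No hydrodynamics, no topological (strand-passage) constraints, single
  nucleus-free-volume convention.
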
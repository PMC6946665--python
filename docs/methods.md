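# Methods

## The model

`ringmelt` simulates dense melts of `M` unknotted, mutually nonconcatenated
ring polymers of `N` monomers each, in reduced Lennard-Jones units
(`epsilon = sigma = m = k_B = 1`, `tau = sigma sqrt(m/epsilon)`), at fixed
volume `V = M N / rho` with periodic boundaries.  Interactions are the
classic bead-spring melt force field:

* **Excluded volume** between all monomer pairs: the purely repulsive,
  cut-shifted Lennard-Jones (WCA) potential
  `U(r) = 4[(1/r)^12 - (1/r)^6] + 1` for `r < 2^(1/6)`, zero beyond.
* **Connectivity**: FENE bonds
  `U(r) = -(1/2) K r_max^2 log[1 - (r/r_max)^2]` with `K = 30`,
  `r_max = 1.5`.  The combination of the stiff FENE spring and the WCA core
  makes bond lengths fluctuate near 0.97 and keeps chains effectively
  uncrossable, which is what conserves the melt's topological state.
* **Bending**: `U(theta) = k_theta (1 - cos(theta - pi))`, `k_theta = 1.5`,
  applied to all consecutive triplets (cyclically on rings; interior
  triplets only after cutting).

Activity is heterogeneous in temperature, not in force: one consecutive arc
of `N_h` monomers per active ring (default `N/8`) couples to a Langevin
thermostat at `T_h = 3` while everything else couples to a second
thermostat at `T_c = 1`; both use friction `gamma = 2/3` per `tau`.  `M_a
<= M` rings are active.  The equations of motion are integrated by velocity
Verlet at `dt = 0.005 tau` with friction and Gaussian noise entering the
force once per step (the convention of common MD engines); each monomer's
noise variance `2 m gamma k_B T_i / dt` comes from its own label.

### What the two thermostats do and do not control

Per-channel fluctuation–dissipation is exact for non-interacting monomers:
the engine reproduces Maxwell–Boltzmann statistics at each channel's
temperature to a fraction of a percent (see `tests/test_engine.py`).  In a
*dense* melt, however, the measured kinetic temperatures `m<v^2>/3` of the
two channels do **not** equal the thermostat set points.  Interactions
conduct heat: for two particles coupled by a spring of stiffness `k` with
separate baths, the exact stationary solution of the linear
Ornstein–Uhlenbeck system shows both kinetic temperatures collapsing to the
bath average once `k >> m gamma^2` — and the effective stiffnesses here
(FENE ~500, WCA curvature ~456 at contact) are far beyond `gamma = 2/3`.
At `rho = 0.85` a desk melt with a 12.5% hot fraction measures hot ~1.7 and
cold ~1.2 instead of 3 and 1 (cross-checked against an independent BAOAB
integrator and the exact two-bead solution).  The thermostat temperatures
are therefore control parameters — the sources of stronger and weaker
isotropic white noise — while the measured kinetic temperatures are
emergent and geometry-dependent (they move toward the set points as hot
segments segregate).  All temperature-related outputs of this package
report the measured quantity.

## Melt construction

The builder guarantees the topological invariants by construction and
verifies them exactly afterwards:

1. Each ring is created as a compact **double-folded loop**: a random-walk
   spine (step 0.965) confined to a ball whose radius scales as
   `(3N/4 pi rho)^(1/3)`, traversed out and back with the return strand
   displaced by 0.6 sigma perpendicular to both turn steps.  The loop is
   the boundary of a thin ribbon along the spine, hence unknotted, and its
   spatial size is set by the confinement ball — close to the equilibrium
   melt size — rather than by the contour length.  Starting near the right
   size matters: initial conformations far from equilibrium (e.g. flat
   circles) relax only on the ring diffusion time and leave segment
   statistics drifting for the whole desk-scale run.
2. Rings are placed in disjoint lattice cells of an inflated box (disjoint
   convex regions cannot be linked), then the box is compressed affinely in
   geometric stages (factor 0.92) to the target volume.  During push-off
   the WCA pair force magnitude is capped (ramped 10 -> 30 -> 80 at fixed
   box to separate the ribbon strands, 200 during compression) and each
   ring is held inside its cell by a flat-bottom spherical tether
   (k = 5), which prevents the chains from ballooning into the transient
   free volume.  The cap and tethers exist only in the builder; production
   runs always use the full potential.
3. After a short full-potential pre-equilibration, all `C(M,2)` pairwise
   Gauss linking numbers are computed **exactly** (solid-angle formula for
   polygonal curves, no quadrature error) and must vanish; bond lengths
   must be below `r_max`.  A gate failure triggers up to two deterministic
   rebuilds with derived seeds before raising.  An advisory
   Koniaris–Muthukumar–Taylor reduction screens each ring for knots
   ("unknot-consistent"/"suspect"); it is a heuristic that can fail to
   reduce a dense unknot, so it never gates.

Hot-arc placement is uniform per active ring (the model is invariant under
contour rotation).  The cut experiment removes, on every ring, the single
cold–cold bond antipodal (along the contour) to the hot arc's midpoint,
producing linear cold–hot–cold triblocks; internally the contour is
relabelled so the cut sits at the ring's storage boundary.

## Threading analysis

A disc-topology triangulated surface is spanned on each ring contour (fan
from the centroid) and evolved by steepest descent on total area with
backtracking line search, interleaved with mesh maintenance:
area-decreasing edge flips, splitting of interior edges longer than 1.4
sigma (so no bond can skip a triangle), and collapse of interior edges
shorter than 0.2 sigma, all preserving the Euler characteristic
`V - E + F = 1`.  The boundary never moves.  Default convergence: relative
area decrease below 1e-4 per sweep.  The surface approximates the minimum;
no global optimality is claimed, and self-intersection of the evolving
surface is not prevented — the piercing analysis is based on signed
crossings and tolerates it.

Piercings of ring `i` through the surface of ring `j` are found by
vectorized segment–triangle (Möller–Trumbore) intersection with bounding-box
pruning; grazing configurations trigger a deterministic 1e-7-sigma
perturbation retry.  The analysis runs in the minimum-image frame of the
surface ring and refuses rings wider than half the box (the desk-scale
fixtures are sized so a fully stretched ring stays below L/2).  The signed
crossing sum of a closed contour through the surface equals the pairwise
linking number — the test suite verifies this against the exact Gauss
number on generic loop sets — so nonconcatenated pairs always show an even
piercing count with signed sum zero, and violations raise a
concatenation-anomaly error.

Threading depth: piercing bond indices sorted along the threading ring's
contour split it into arcs; the two alternating-parity arc sums total `N`
and the smaller is `L_sep` (exact for two piercings), with
`Q = L_sep/(N - L_sep)`.  Clusters join rings when either direction threads
with `L_sep > L_cutoff` (union over the undirected graph); for mixtures the
biggest cluster overall and the biggest among passive-only clusters are
reported.  Kinetics work on directed pair sets per frame: gain/loss set
differences, the presence correlation `Phi(t, t0)` (re-formed threadings
count), and the first-unthreading survival distribution `pi(t, t0)` whose
final bin accumulates pairs threaded through the end of the window.
Surfaces are recomputed independently per frame for reproducibility.

## Observables

All displacement observables subtract the instantaneous system center of
mass (Langevin dynamics does not conserve momentum) and average over chains
only, with an explicit measurement origin `t0` (0 = activity onset) —
aging systems are not stationary, so no multi-origin averaging.

* `g3(t, t0)`: ring-COM mean squared displacement.
* `F_s(q, t, t0)`: self-ISF of ring COMs, averaged over all
  lattice-compatible wavevectors within a 2% shell of the requested
  magnitude (configurable); requests more than 5% from any available
  magnitude raise with the nearest alternatives listed.  The production
  wavevector `q* = 0.35/sigma` (the structure-factor maximum) needs a box
  of at least `2 pi / 0.35 = 18 sigma`; desk boxes report their own `q*`.
* Non-ergodicity parameter `f(q, t0)`: `F_s` at the last available lag.
* `EB(t)`: relative variance across rings of the per-ring time-averaged
  squared displacement at lag `Delta` (trapezoidal rule at the frame
  spacing).  For independent 3-D Brownian chains `EB -> (4/9) Delta/t`
  (the familiar `4/3` coefficient is the one-dimensional case); the test
  suite checks the 3-D law.
* Cold–hot vector `ch = COM(hot) - COM(cold)` per active ring; the
  directionality correlation `<e_d(t+Delta) . e_ch(t)>` quantifies motion
  toward the hot head.
* Internal distances `<R^2(s)>` within the hot or cold block, averaged over
  segment positions inside the block, rings and frames; power-law exponents
  (e.g. the trail exponent) are fitted by least squares on log–log axes
  over a caller-stated window (`fit_power_law`, which also serves the g3
  exponent analyses), reported with standard errors.
* 1-D COM displacement distributions with excess kurtosis
  `kappa = m4/m2^2 - 3`.
* Hot-segment neighbor count within a cutoff (3.25 sigma at production
  scale, the segment radius of gyration), with the uniform-distribution
  closed form `(4/3) pi c^3 (M-1)/V` as reference.
* Static structure factor of ring COMs on shell-averaged lattice
  wavevectors, reporting the peak position `q*`.

## Problem sizes and determinism

Desk-scale defaults used by the tests and the acceptance script: the
two-thermostat measurement uses 10 rings of 80 with 10-monomer hot arcs
(5e5 steps); segment statistics use 16 rings of 200 (2.25e5 steps, the
50-monomer internal segment then being N/4); threading fixtures use 48
rings of 12, whose fully-stretched span (3.7 sigma) provably stays below
half the box.  These sizes were chosen so every stage, builder included,
runs on a single CPU in minutes while keeping each observable's geometric
prerequisites valid.  Production-scale quantities that require thousands of
rings over multi-million-tau trajectories (the trail exponent 0.57, the
superdiffusive exponent 1.13, the glassy g3 plateaus and the aging ISF) are
exposed through the same pipeline and fit machinery but are not reproduced
at desk scale.

Every stochastic stage takes an explicit seed and is bitwise reproducible
given it: the builder (including its retry chain), the engine (single
seeded stream per integration chunk, derived via `SeedSequence`), activity
assignment and the perturbation retries of the piercing detector.  The CLI
embeds a hash of the full configuration in every output file and refuses to
combine files with mismatching hashes.

## Known limitations

* Desk melts are far from the glassy regime; passing tests validate the
  machinery and its analytic limits, not the production-scale phenomena.
* Desk-scale conformational statistics carry a finite-size bias: when the
  box edge is comparable to the ring extent (unavoidable for N = 200 rings
  in minute-scale runs), rings interact with their own periodic images and
  slowly swell beyond true melt statistics — internal 50-monomer segments
  equilibrate several percent above the production-scale reference.
  Avoiding this artifact is exactly why production studies use thousands
  of rings.
* The kinetic temperature of a labelled channel in a dense melt sits
  between the two set points (see above); reported channel temperatures
  are measurements, not set points.
* The KMT knot screen is advisory and may report "suspect" for dense
  unknots it cannot reduce.
* Minimal surfaces are local minima; `L_sep` inherits the usual convention
  of counting arc lengths in whole monomers.
* For boxes smaller than three WCA cutoffs per side the engine falls back
  to an O(n^2) pair sum; correctness is unchanged.
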
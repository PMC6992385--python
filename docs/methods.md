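# Methods

## Model

`polcpm` implements an extended cellular Potts model (CPM) of crawling
cells on a two-dimensional substrate. The substrate is tessellated into a
honeycomb lattice (unit center spacing); each hexagon is one discrete
cell–substrate adhesion patch, and each cell is a contiguous set of
occupied hexagons. Configurations evolve by elementary protrusion and
retraction events — one site conquering a lattice neighbor — accepted by a
Monte Carlo rule that gradually minimizes an effective energy while an
internal polarization field keeps the system out of equilibrium.

### Energies

For a cell with substrate contact area `A` (site count) and boundary
contour length `P`,

    H_cont = kappa_A A^2 + kappa_P P^2
    H_cyto = - sum_x eps(x)        (over the cell's sites)

`eps(x, t)` is the per-site polarization field, subsuming the local mass
of force-generating cytoskeleton and the local cell–substrate adhesion
strength; it is bounded to `[eps0 - delta_eps/2, eps0 + delta_eps/2]` and
vanishes on unoccupied sites. Cell–cell contacts contribute an adhesion
benefit `-B` per contact edge. Two dissipative (non-Hamiltonian) costs
enter elementary events: `delta_B` per cell–cell contact edge ruptured by
true separation (see below) and `D` per substrate bond lost when a cell
vacates a site. A substrate field `phi(x) <= 0` modulates the adhesion
energy of penalized sites (additively by default, multiplicatively as an
option); impenetrable micropattern walls are realized as hard-forbidden
sites, the `phi -> -inf` limit.

**Perimeter units.** The configuration caches store the perimeter as an
exact boundary-edge count (an integer, verified against a from-scratch
recount after arbitrary event sequences). The energy uses the physical
contour length, `P = edge_count / sqrt(3)`, since each boundary edge is
one hexagon side at unit lattice constant. This convention is load-
bearing: with raw edge counts in `kappa_P P^2`, every elementary move at
the reference parameters (`kappa_P ~ 0.06`, `kBT = 1`) costs 20–40 kBT and
the model freezes at all published polarizabilities, whereas with contour
lengths the single-cell migration onset emerges at specific polarizability
`delta_eps/kappa_P ~ 450–500`, where it is reported.

**Friction accounting.** The rupture surcharge `delta_B` is charged only
when a contact edge truly separates — the target site becoming empty in a
retraction — not when a junction migrates because one cell displaces the
other (the reversible `±B` bookkeeping still applies there). Charging it
per destroyed edge in *every* event (available as
`ModelParams.friction_mode = "per_edge"`) makes junction migration cost
12–24 kBT at the published cluster parameters (`B = 0, delta_B = 12`), and
because contact formation is then free while rupture is prohibitive, any
transient contact ratchets into a permanently locked aggregate: confined
clusters never rotate, contradicting the phenomenon the parameters are
printed for. Under the separation reading the cluster rotation onset and
phases come out as published.

### Kinetics

Events are drawn uniformly from the live set of *directed boundary pairs*
(neighboring sites with different owners, neither a wall, at least one a
cell), maintained incrementally. One Monte Carlo step (MCS) performs
`N_attempt` propose–evaluate–accept cycles with `N_attempt` frozen at the
MCS start equal to the current pair count; this boundary-local attempt
budget makes the MCS timescale insensitive to the empty-lattice size, and
it is the package's definition of the time unit. Moves that would
fragment a cell (checked by a cyclic-arc test with a flood-fill fallback)
or annihilate a cell's last site are rejected outright.

Acceptance is the canonical Metropolis rule `min(1, exp(-dH/kBT))` with
`kBT = 1`. Because the proposal set is state-dependent, plain Metropolis
is not exactly reversible; `balanced_proposals=True` adds the
Metropolis–Hastings factor (pair-count and proposal-channel-multiplicity
ratios) under which the feedback-free (`delta_eps = 0`) chain samples the
Boltzmann distribution exactly — verified against exhaustive enumeration
on a six-site lattice. The correction is an O(1/P) effect for
production-size cells but measurably lowers the motility onset, so the
canonical rule is the default.

### Polarity feedback

Each accepted event increments an integer regulatory accumulator `F` by
+1 on the gaining cell's sites and -1 on the losing cell's sites within
hex graph distance `R` of the event. Once per MCS every occupied site
relaxes with rate `mu` toward a target selected by the *sign* of `F`: the
upper bound for `F > 0`, the lower bound for `F < 0`, the rest value
`eps0` for `F = 0`; the accumulators are then reset. Newly conquered
sites inherit the conqueror's `eps` and `F = 0`. The bounds are the fixed
points of the update, so the field invariant holds by construction. With
`mu = 0.1` the intrinsic relaxation timescale is 10 MCS; velocities and
trajectory smoothing default to that window.

### Cell cycle

Cells are quiescent by default. Contact inhibition is a size threshold:
a quiescent cell whose area exceeds `A_T * A_ref` (with `A_ref` the
solitary-cell equilibrium area, measured by a short calibration run)
enters a deterministic growth state of duration `Tg`, during which
`kappa_A` ramps linearly to `kappa_A/2` (doubling the preferred area,
since `A* ~ eps0/kappa_A`) and `kappa_P` follows as
`kappa_P sqrt(kappa_A_eff/kappa_A)` so the perimeter energy per boundary
event stays size-invariant. A division state of duration `Td` follows
with the polarizability set to zero (mitotic rounding); at its end the
cell splits across the plane through its center of mass perpendicular to
the gyration-tensor major axis (stray fragments reassigned to the sister;
division deferred one MCS if no connected split exists). Daughters
restart quiescent and unpolarized with the mother's base parameters. An
optional stochastic quiescence-exit hazard (off by default)
desynchronizes the otherwise deterministic cycle.

## Observables

* **Trajectory statistics** — time-and-ensemble MSD; normalized heading
  autocorrelation `C(tau) = <u(t+tau) . u(t)>` from 10-MCS finite-
  difference velocities; least-squares fit of the 2-D Fürth form
  `MSD = 2 v^2 tau_p [tau - tau_p (1 - e^(-tau/tau_p))]` with relative
  weighting. The heading-correlation time is reported as the *integral*
  of `C` (equal to the time constant for an exponential); log-slope fits
  overweight the slow non-exponential tail produced by replicate
  heterogeneity and overestimate it roughly twofold.
* **Shape** — aspect ratio `l+/l-` from the square roots of the
  gyration-tensor eigenvalues; collinear cells report an infinite
  sentinel.
* **Curvature** — `<|d theta / d s|>` of the block-averaged (10 MCS) unit
  tangent; a dense circle of radius `rho` gives `1/rho` exactly.
* **Collective rotation** — signed cluster angular velocity
  `omega = e_z . <R_rel x v_rel / |R_rel|^2>` relative to the population
  means, counter-clockwise positive (a rigid CCW rotation at `omega0`
  reports `+omega0`); summary statistics `<|omega|>`, `sigma_omega`,
  `sigma_P`.
* **Tissue fields** — y-averaged kymographs of density (occupied-site
  fraction per x-bin), `sigma_xx`, and `v_x`. The per-cell stress is the
  virtual-uniform-dilation derivative of the cell energy per unit area,
  tension positive, with the polarization entering at its rest value:
  `Pi = 2 kappa_A_eff A + kappa_P_eff P^2/A - eps0`. It vanishes at the
  solitary equilibrium area and is negative for compressed cells. Using
  the cell's instantaneous mean polarization instead makes strongly
  polarized leading-edge cells look artificially slack and inverts the
  edge-first tension ordering of the expanding strip, so the rest-value
  form is used for kymographs. No force-level data exists in a CPM; this
  estimator is validated by its equilibrium-zero and compression-sign
  properties and by reproducing the X-shaped tension pattern
  qualitatively.
* **Fronts** — leading edge `h(y)` as the outermost occupied `x` per
  lattice row; roughness `w = std(h)` over tissue-bearing rows.
* **Growth bursts** — dominant period from the spacing of division-burst
  centroids in the cell-birth-rate series, with a periodogram fallback.

## Problem sizes and defaults

Because the attempt budget is boundary-local, single-cell and small-
cluster runs at the *published* parameters are cheap, and the package
uses them directly: `eps0 = 225`, `kappa_A = 0.18`, `R = 5`, `mu = 0.1`
for single cells (equilibrium area ~620 sites on a periodic lattice
sized ~6 cell diameters) and `r0 = 30.6`, `B = 0`, `delta_B = 12` for the
4-cell micropattern. Reducing `eps0` to shrink cells also shifts the
migration onset downward (the threshold tracks the cell contour length),
so it is not done for threshold measurements. Replicate counts (8–12 vs
the published 100) and durations (2.5–16 k MCS vs 10^4) are reduced.
Monolayer runs are genuinely scaled down: strips of ~130–360 cells
between walls at ±40 to ±175 (published: 2500–3300 cells at ±175), with
the sheet prepared directly as a slightly compressed confluent Voronoi
tiling plus a few hundred MCS of settling, instead of simulating growth
to confluence.

## What the reduced-scale experiments do and do not show

The harnesses reproduce, at reduced scale: the single-cell motility
onset near specific polarizability ~500 and the persistent-random-walk
statistics above it; the quiescent/rotating transition of confined
4-cell clusters near ~450 with bidirectional (R1-like) rotation at the
onset and unidirectional (R2-like) rotation above; growth bursts at the
cell-cycle period (200 MCS) in expanding proliferating sheets; the
edge-first, inward-propagating tension wave of migration-dominated
expansion; and rougher fronts under the fingering parameter set. In
narrow strips the contact-inhibition bursts synchronize the entire sheet
(full doublings) rather than propagating as partial bands, and fronts
meet across the periodic boundary once the lattice fills, so burst
observables are measured in the window before saturation.

One published result is *not* reproduced: the exact data collapse of the
persistence time onto a master curve of `delta_eps/kappa_P` under
`(delta_eps, kappa_P) -> (c delta_eps, c kappa_P)`. The speed collapses
cleanly, but the measured `tau_p` falls severalfold per doubling of
`kappa_P` at fixed ratio. Such a collapse is exact only when every event
margin is large compared to `kBT` (then only the scaling-invariant signs
of `dH` matter); under the contour-length energy convention that the
published onset values require, margins near onset are O(kBT) and the
thermal corrections break the scaling. The corresponding test asserts
the collapse as stated and fails, documenting the discrepancy.

## Numerical choices

* Odd-r offset coordinates (pointy-top hexagons), periodic cells
  rectangular with even row counts, so constant-x wall strips are
  continuous across the periodic-y seam.
* Unwrapped per-site Cartesian coordinates are assigned at conquest from
  the source site, making centers of mass (and hence MSDs) continuous
  across periodic images without winding counters.
* The steady-state oracle minimizes
  `kappa_A A^2 + kappa_P P_len(A)^2 - eps0 A` over near-minimal-perimeter
  clusters grown greedily (most-occupied-neighbor-first); Monte Carlo
  steady-state areas agree within ~10% (thermal fluctuation scale).
* Fürth fits use relative (sigma = MSD) weighting, positive-parameter
  bounds, and explicit convergence flags; non-convergence is never
  silent.
* Degenerate inputs: empty cells, all-zero velocity series, empty lag
  sets, and off-lattice sites raise; empty kymograph bins are NaN
  (missing), not zero; collinear cells report an infinite aspect ratio.
* All randomness flows from one integer seed through
  `numpy.random.SeedSequence` (replicate i gets child seed i); the numba
  kernel RNG is process-global and reseeded per simulation, so replicate
  runs are executed sequentially.

## Known limitations

* The proposal law and attempt normalization define the MCS unit; they
  rescale time relative to implementations that draw attempts per lattice
  site, so persistence times and speeds are comparable across this
  package's runs but not numerically portable to other CPM codes.
* Nematic stress fibers, reaction–diffusion polarity chemistry,
  apoptosis/extrusion, and cell-type-pair-specific adhesion are out of
  scope; a single cell type per run is assumed (per-cell effective
  parameters exist only for the cell cycle).
* The stress kymograph is an estimator over cell-level quantities, not a
  traction-force reconstruction.
* Full-scale tissue runs (thousands of cells for 10^4 MCS) are feasible
  but take tens of minutes; the bundled harnesses default to the reduced
  geometries above.
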
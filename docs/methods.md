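# Methods

## Model overview and assumptions

The simulator treats the marginal crypt epithelium (MCE) as a planar closed
chain of point cells connected by linear springs. The physical assumptions
are deliberately minimal:

- **Cells are points.** Following a Saint-Venant-style simplification,
  columnar cells are reduced to their centres; cell shape, contact and
  excluded-volume forces are not modelled. The only internal force is the
  junction spring (E-cadherin adhesion); the only external forces are the
  division pull at the focal rim cell and weak substrate anchors.
- **Quasi-static mechanics.** The system only visits equilibria: after each
  division the network is relaxed until every cell's net force is below
  tolerance. There is no inertia and no explicit time variable; "time" is
  the division count.
- **Planarity.** The opening contour and all force resolution live in the
  plane of the mucosal surface. Vertical (y-axis) components are carried in
  the resolved force state only as residual checks; symmetric out-of-plane
  components cancel and never drive displacement.
- **Substrate anchors.** Each rim cell is tied to its reference position by
  a weak spring (default stiffness 0.1, a tenth of the junction stiffness).
  This represents attachment to the basement membrane and is also what
  makes the mechanical problem well-posed: a net point force on an
  unanchored ring has no equilibrium. The anchor stiffness sets the
  compliance scale of the opening — softer anchors elongate faster — but
  does not change any of the qualitative conclusions.

All quantities are dimensionless: lengths in cell diameters, stiffnesses
scaled to the junction stiffness, forces in units of (junction stiffness ×
cell diameter). No physical parameter values are available for this system,
so only ratios are meaningful.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `ring_size` | 24 | rim cells in the MCE ring; a realistic crypt-opening circumference of a few tens of cells, large enough for smooth contours, small enough to relax quickly |
| `ring_radius` | 1.0 | sets the length unit |
| `junction_stiffness` | 1.0 | sets the force unit |
| `anchor_stiffness` | 0.1 | weak basement-membrane attachment (see above) |
| `E`, `I`, `Lc` | 1, 1/12, 2 | unit Young's modulus; `I` of a unit-square cell section about its centroid; buckled segment spanning two cell lengths, so `F_crit = π²/48 ≈ 0.2056` |
| `delta_F_per_division` | `0.05·F_crit` | per-division force increment; no increment law is available, so a constant 5% of the Euler load is used — 20 divisions to threshold |
| `K_spring` | 1.0 | Hooke constant of the rim cell's stretch/recovery cycle (distinct from the sine-mode amplitude, which shares the symbol K in classical notation) |
| `F_v` | 0.5 | constant viscous force per recovery; dissipates a meaningful fraction of each cycle without dominating it |
| `emt_tolerance_band` | 0.05 | fractional band above `F_crit` the elastic force may transiently occupy |
| `n_cross_sections` | 5 | depth sections of the pit |
| `attenuation_lambda` | 0.5 | exponential depth-decay rate of the accumulated displacement |
| `A_L_schedule` | empty | per-depth added-cell lengths from stress-induced differentiation of neighbouring stem-cell columns; validated not to break depth monotonicity |
| `n_divisions` | 200 | long enough for the full round → linear trajectory at the defaults |
| `relax_tol` | 1e-7 | force residual at which a configuration counts as equilibrated (the standalone `relax_ring` default is 1e-8) |

## Numerical choices

- **Relaxation** is damped fixed-point iteration on net nodal forces —
  overdamped gradient flow on the total energy. The step size starts at
  0.9 / (Gershgorin bound on per-node stiffness), grows 10% per accepted
  step, and backtracks by halving whenever a trial step raises the energy
  by more than 64 ulp of its magnitude. Near the minimum, energy
  differences fall below floating-point resolution; the scheme then takes
  the stability-bounded step on forces alone, which is what actually drives
  the residual to tolerances of 1e-8–1e-9. Iteration cap 10^5; exceeding it
  raises a convergence error carrying the final residual. Fixed points are
  verified in the test suite against an independent quasi-Newton
  minimization of the same energy (agreement better than 1e-6 in position
  on rings of up to 30 cells).
- **Shape drive.** The contour at each step is the ring equilibrium under a
  total pull `F_C−xz + K_spring·S_x` at the focal cell: the EMT-capped
  elastic force plus the accumulated creep expressed as an equivalent
  permanent force. This is the package's resolution of the apparent paradox
  that the pull both "grows without bound" and "stays at the Euler-force
  vicinity": the elastic part is regulated, the plastic part accumulates,
  and it is the plastic part that elongates the opening.
- **Moment of inertia** uses the midpoint rule with grid doubling and
  Richardson extrapolation until the relative change is below 1e-8.
- **Discrete buckling load** comes from the generalized symmetric
  eigenproblem `K_bend·v = F·K_geo·v` of an n-segment pinned chain
  (second-difference bending stiffness vs. first-difference geometric
  stiffness). The bending stiffness factor E·I is taken out of the solve so
  the result is exactly linear in it. The smallest eigenvalue converges to
  `π²EI/L_c²` from below with O(1/n²) error.
- **Amplitude independence** of the detected critical load is checked with
  the exact arc-length Rayleigh quotient (bending energy over
  end-shortening), which introduces an O((πK/L_c)²) amplitude dependence —
  about 0.05% across amplitudes of 1e-6–1e-2 of `L_c`, comfortably inside
  the small-bending regime. A warning fires when a profile's slope exceeds
  0.2, where equating curvature with the second derivative degrades.
- **Classifier thresholds** (round < 1.15 aspect; droplet ≥ 1.4 aspect with
  centroid asymmetry ≥ 0.02; linear ≥ 8) are conventions, exposed in
  `ClassifierThresholds`; the trajectory's monotone metrics, not the label
  boundaries, carry the scientific content.
- **Hysteresis ledger** arithmetic follows the magnitude convention: the
  minus signs of the restoring-force and energy-balance relations mark
  direction, not signed distances. The lossless branch (`F_v = 0`) returns
  the full stretch exactly so that lossless sequences accumulate exactly
  zero; rounding at very small `F_v` is clamped so recovery never exceeds
  stretch.
- **Serialization** uses 17 significant digits and round-trip float parsing,
  making re-runs of identical configurations byte-identical.

## What the fixture generator does and does not emulate

`make_fixture` produces regular rings and chains (optionally with seeded
radial jitter), teardrops and ellipses. These capture the geometry the
mechanics operates on — a closed rim of adhering cells — but not:
heterogeneous cell sizes or stiffnesses, cell division within the rim
itself, neighbouring crypts, or any three-dimensional tissue architecture.
Tests passing on these fixtures therefore validate the mechanics and its
invariants, not histological realism: real crypt rims are irregular, and
real lesions involve many interacting glands.

## Design choices where the design was open

- The per-division force increment, the exponential form of depth
  attenuation, and the EMT cap-to-threshold rule are all phenomenological
  choices where only qualitative behaviour (monotone growth, monotone
  decay, bounded force) is specified by the underlying model; each is a
  single exposed parameter or rule, chosen for being the simplest
  one-parameter law with the required monotonicity.
- The viscous term is a constant force per event rather than
  rate-dependent, because the model has no explicit time variable for a
  rate to refer to.
- The depth-ordered auxiliary length `D_L` has no operational definition in
  the underlying model; it is carried as an opaque strictly-increasing
  sequence (depth index plus cumulative added-cell length) and checked only
  for monotonicity.
- A single pit can at most reach the "linear" class; "groove" is assigned
  only when composing multiple adjacent pits whose openings are linear
  (a rendering convention reflecting how neighbouring columns' induced
  differentiation merges linear openings into a reticular pattern).
- The L-tube geometry is a centerline-plus-circular-sections model with a
  sharp right-angle elbow, not a watertight mesh; nothing downstream needs
  more.

## Problem sizes

The shipped configurations are desk-scale: rings of 12–30 cells, chains of
up to 128 segments, 200-division trajectories, 1,000-polygon isoperimetric
sweeps. The full test suite runs in well under a minute; the acceptance
script in a few seconds. Larger rings and longer runs scale linearly in
divisions and roughly linearly in ring size per relaxation.

## Known limitations

- No molecular mechanism: EMT is a force-capping event, not a cell-state
  model; microtubule/E-cadherin dynamics are outside scope.
- No gland fission, no multi-gland gastric units, no 3D packing.
- Cells never rearrange: the rim ring's topology is fixed, so T1-type
  neighbour exchanges and rim cell division are absent.
- The quantitative trajectory (how many divisions to reach "linear")
  depends on the phenomenological defaults above; only the ordering and
  monotonicity of the transition are robust model predictions.
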
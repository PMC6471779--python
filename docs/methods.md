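# Methods

`qsbiofilm` models AI-2 driven quorum sensing and biofilm formation in
*E. coli* as an extended hybrid Petri net, adds space by colouring the net
over a discrete grid, and validates the model with structural analysis,
four simulation regimes and a simulative PLTLc checker.  This note records
the modelling assumptions, the numerical choices, and what the synthetic
parameterisation can and cannot show.

## The net class

Places are discrete (non-negative integer tokens) or continuous
(non-negative reals); transitions are stochastic (exponential races) or
continuous (ODE fluxes).  Besides standard arcs there are *read* arcs
(enabled iff `m(p) >= w`, nothing consumed) and *inhibitor* arcs (enabled
iff `m(p) < w`).  All rates follow mass-action kinetics: the rate of a
transition with constant `k` is `k` times, over its standard and read
pre-arcs, the combinatorial factor `C(m, w)` for discrete places and `m^w`
for continuous ones.  Inhibitor arcs gate but never contribute a factor.
Constant places (genes, the QSeBC sensor) attach through read arcs only,
which gives them all-zero incidence rows and hence trivial one-place
P-invariants — this encoding is load-bearing for the structural results
and must not be replaced by self-loops.

## The model variants

**AI-2 production (exponential phase).**  21 places / 23 transitions:
the methionine cycle (Met → SAM → SAH → SRH → homocysteine → Met), the
DPD/AI-2 branch ending in the environment pool `AI2_Out`, the SAM
decarboxylation branch (Decarb_SAM, MTA, MTR, spermidine), and constitutive
LuxS/Pfs expression from two constant gene places.  `Nutrients` and
`Putrescine` are finite source pools.  Three wiring choices are not
determined by the qualitative pathway description and were fixed as
follows: methionine recovery consumes homocysteine *and* adenine (keeping
their totals balanced so both relax to the zero steady state); the Pfs
conversion of MTA produces into the spermidine (polyamine) pool; and
`Polyamin_util` drains putrescine.  These choices reproduce the published
structural fingerprint of the component exactly (two trivial 1-P-invariants
and minimal siphons, T-cover after bordering, STP, Extended Simple, hence
live).

**Biofilm formation (stationary phase).**  11 places / 15 transitions plus
the discrete threshold gate: `open` is enabled iff `m(AI2_Out) >= THR_open`
and `m(go) < 1`; `close` iff `m(AI2_Out) < THR_close`; the two conditions
exclude each other, so `go` carries at most one token and acts as a weight-1
side condition of `Transport_in`, whose rate is zero while the gate is
closed and otherwise depends only on `AI2_Out` and `LsrABCD`.  Rate
constants come in three levels with ratio 1 : 10 : 10^4 (low: basal
production and degradation; medium: everything else; high: open/close);
the stand-alone component uses 1 / 10 / 10^4 and the combined model
rescales to 1e-4 / 1e-3 / 1.  Initial marking: `QSeBC = 1` (constant),
`lsrGenes_LsrR = 1` (repressed state), the three Lsr proteins at 1,
everything else empty.

**Combined model.**  Union of the two components fused on the logical
place `AI2_Out` (each component's `AI2_In` renamed with a phase suffix),
plus a `Diffusion` sink whose rate constant is the diffusion parameter
`kd = 0.1` multiplied by the Moore neighbour count of the intended
dimensionality (2 / 8 / 26 in 1D / 2D / 3D).  Default thresholds
`THR_open = THR_close = 40` (the biological gate is symmetric).

**Spatial model.**  Every place is coloured with `Grid3D = {1..D1} x
{1..D2} x {1..D3}` (1-based, bounded, no wraparound).  All transitions
carry the colony `region` guard — occupancy at centre-relative offsets
divisible by the sparseness `S_i` within radius `R` — except `Diffusion`,
which becomes a two-way transport guarded by the 26-point Moore
neighbourhood, with its post arc carrying the `(a,b,c)` neighbour binding;
the non-spatial `inflow` source is dropped (external AI-2 arrives by
diffusion).  Unfolding instantiates region-guarded transitions once per
colony position and `Diffusion` once per ordered Moore-adjacent cell pair
(`8D^2 - 12D + 4` on a D x D 2D grid), prunes place instances no surviving
transition touches, and names instances `base__x_y_z` so traces aggregate
by position.  The resulting sizes obey `places = 31 N + D^2` and
`transitions = 39 N + 8D^2 - 12D + 4`; the corresponding published closed
form quotes 33 per-bacterium places (a two-place discrepancy in the
published per-bacterium place count that the reconstruction from the
component tables cannot close; the transition law matches exactly, e.g.
4255 transitions at D = 21, N = 25).

## Synthetic parameterisation

The original rate constants and initial concentrations of the production
component are experimentally derived and not printed in any source packaged
here, so `data/phase2_params_synthetic.yaml` is a synthetic stand-in.  It
was calibrated once, against two published qualitative targets, and then
frozen:

1. the RK4 trace over 10,000 time units must put all 21 species into the
   five published behaviour categories (see below), which pins the shape
   of every trajectory (initial falls, single peaks, plateaus, zero
   tails) and in particular requires peaks tall and narrow enough to beat
   the checker's 0.01 truncation quantum;
2. the spatial experiments must operate in the threshold-discriminating
   regime: the late-time AI-2 field spread uniformly over the 21 x 21 grid
   stays *below* `THR = 40` per cell (total AI-2 output is a few hundred
   tokens per bacterium), while a dense 5 x 5 colony exceeds the threshold
   locally during the production pulse.  Outside this regime the gate
   either never opens (no biofilm anywhere) or never closes (sparseness
   has no effect).

Consequences worth knowing: absolute token counts, totals, and time scales
are *not* comparable to the original study (whose totals are two to three
orders of magnitude larger); only orderings, category memberships,
structural results and closed-form sizes are.  Passing tests demonstrate
the mechanisms — threshold gating, repression/derepression, diffusion-
mediated colony communication — not quantitative agreement with wet-lab
kinetics.

## Simulation regimes

* **ODE (`simulate_ode`)** — classic fixed-step RK4 on `dm/dt = C v(m)`,
  recording at equidistant grid points; default step is a quarter of the
  recording interval (the packaged production model needs `h = 0.05..0.1`
  for its stiffest phase).  Negative excursions beyond tolerance raise.
* **Gillespie (`simulate_gillespie`)** — exact direct-method SSA over a
  flattened array encoding of the net, with dependency-graph propensity
  updates; records by previous-value hold.
* **Delta-leaping (`simulate_delta_leaping`)** — fixed maximum leap
  (default: the recording interval) shortened by a drift criterion
  (expected change of any population at most `eps` relative, never below a
  few tokens), midpoint-predicted Poisson firing counts, rejection with
  step halving on negative excursions, and an exact exponential race for
  *gated* transitions (inhibitor arcs or read arcs of weight > 1), so the
  go mechanism keeps single-token semantics.  When `tau * total propensity`
  is small the kernel takes exact SSA steps instead, which makes the tails
  of small systems unbiased.  Record points inside a leap get the linear
  interpolant of the leap's end states (conserves weighted token sums).
  The variance of individual trajectories is slightly inflated at large
  `eps`; ensemble means are unbiased to O(eps^2) by the midpoint predictor.
  The spatial experiments use `eps = 0.15..0.2`; the simulator
  cross-validation (below) checks this setting against the exact method.
* **Hybrid (`simulate_hybrid`)** — stochastic transitions (default: the
  ones marked stochastic by the builders, i.e. open/close) fire by
  integrated-hazard sampling over piecewise-constant propensities between
  RK4 substeps of the continuous subnet; the substep is capped by an
  explicit-stability bound (0.6 over the fastest per-place consumption
  coefficient), which handles the stiffness this model class is known for.
  Discrete places update instantaneously and are visible to continuous
  rates.  This is a deliberate simplification of full hybrid
  rejection-based simulation: exact for piecewise-smooth propensities up
  to the substep discretisation of the hazard.

All stochastic streams derive per-run seeds from `(seed, run)` via
`SeedSequence`, so every run is individually replayable and ensembles are
bit-reproducible.

## Structural analysis

Integer-exact throughout.  P/T-invariants come from Farkas elimination with
minimal-support pruning (read/inhibitor arcs excluded from the incidence
matrix); "covered with T-invariants" means every transition occurs in some
minimal invariant's support.  Siphons and traps treat read arcs as
self-loops and are enumerated by a branch-and-bound closure over feeding
transitions (guarded by a 40-place bound); traps are siphons of the
reversed net.  STP holds when every minimal siphon contains an initially
marked trap (checked via the maximal trap inside each siphon).  Extended
Simple is the asymmetric-choice condition on shared post-sets of places;
STP with ES yields time-independent liveness, STP alone freedom from dead
states.  Inhibitor arcs are outside this theory, so the go mechanism is
removed (`phase3_core`) before structural analysis, as in the original
study.

## The PLTLc checker

Finite-trace semantics over recorded traces; `G`/`F`/`U` with the
first-witness reading of `U` (provably equivalent to the any-witness
reading on finite traces).  Atoms compare arithmetic over `[X]`, `d[X]`,
`max[X]` and literals.  Values and maxima are truncated toward zero to two
decimals; derivatives are finite differences *of the truncated series* and
are not truncated again.  This makes `d[X] = 0` an exact steady-state
detector tolerant of sub-0.01 drift while slow relaxations still register
as sparse one-quantum steps — without this, the published "until steady
state zero" categories are unsatisfiable on smooth decays.  The behaviour
library orders six categories (always zero; constant positive; decreasing
to zero; increasing to steady state; single peak to zero; fall-rise-fall
to zero) and `classify` assigns the first match.

## Experiment configurations and problem sizes

* Behaviour classification: RK4, 10,000 time units, 10,000 recorded
  points, `h = 0.05`.
* Threshold scenarios: stand-alone biofilm component, horizons 100
  (unlimited supply) and 200 (limited, initial stock 100 tokens —
  the stock size is this package's choice), 10 runs.
* Colony sparseness: 21 x 21 grid, colonies R0/R2/R5/R7 with sparseness
  1/1/2/3 (25 bacteria except the single-bacterium row), delta-leaping,
  horizon 20,000 recorded at 1,000 points, 10 runs, `THR = 40`,
  `kd = 0.1`.  The companion 101 x 101 table is exposed through the same
  interface (`spatial_config_table(101)`) but is not part of the default
  test run; its per-run cost is roughly an order of magnitude higher.
* Simulator cross-validation: the 9 x 9 grid scenario (9 bacteria,
  radius 2, sparseness 2), both simulators at 5 runs over the first 1,500
  time units — the window in which production, import and diffusion are
  all active; beyond it the field is static and the comparison
  uninformative.  The AD map `|mean_1(t) - mean_2(t)|` is compared against
  the pooled standard error of the difference; entries beyond noise must
  remain a small unstructured minority.

## Known limitations

* The synthetic parameter file fixes scales the original study left
  unpublished; absolute totals (e.g. the dense-colony biofilm figure) are
  not reproducible, only their ordering across configurations.
* The delta-leaping variance bound is deliberately omitted (drift-only
  step control); per-run fluctuation statistics at large `eps` are
  slightly wide even though ensemble means validate against exact SSA.
* The hybrid engine is an explicit integrator with hazard sampling, not a
  rejection-based hybrid simulator; very stiff continuous subnets cost
  proportionally many substeps.
* Colour sets are grids only: no unions, nesting, torus boundaries or
  polar coordinates.
* The siphon enumeration is exponential in the worst case and refuses nets
  beyond 40 places; the study's nets are far below the bound.
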
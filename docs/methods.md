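# Methods

## Model

The simulator is a synchronous stochastic cellular automaton for the
seasonal dynamics of subterranean termite foraging territories.  Space is
an *L* × *L* square lattice of soil cells; time advances in discrete
steps.  Cell states are EMPTY, ACTIVE (a tunneling tip able to extend the
territory) and INACTIVE (occupied but no longer growing; empirically a
tunnel tip blocked by obstacles or water).  A territory is the set of
occupied cells sharing one founding label; territories are mutually
exclusive by construction.  The landscape is a static field of
tunneling-ease probabilities *P*<sub>trans</sub>, i.i.d. uniform on
[0, 1], representing spatial heterogeneity of soil penetrability.

**Summer growth (per synchronous step).**  Every active cell makes one
growth attempt: among its empty Moore neighbors a target is sampled with
probability proportional to *P*<sub>trans</sub>, and the attempt succeeds
with probability *P*<sub>trans</sub>(target) — favorable soil is both
preferred and easier to enter.  All attempts are evaluated
simultaneously; when several territories claim one cell, a single winner
is drawn uniformly — probability 0.5 for the pairwise case, extended
symmetrically to 1/*k* for *k* competitors.  A successful source stays active and its target becomes an
active cell of the same territory (growth is a multiplication of tips,
not a move).  A cell whose attempt fails — a failed draw, a lost contest,
or no empty neighbor at all — turns inactive, as does any active cell
enclosed by ≥ 7 inactive Moore neighbors.  Consequences: the total
occupied count is non-decreasing within a summer, and labels never
change once assigned.

An alternative reading of the growth rules, in which an active tip
persists through failed draws and is only inactivated by having no empty
neighbor (plus the 7-neighbor enclosure), was implemented and evaluated
during development; see *Limitations* for why the stricter
failure-inactivates reading was kept.

**Winter (one step).**  Independently per territory, cells are removed in
order of decreasing Euclidean distance from the founding seed until
`keep = max(1, round(σ/100 × size))` cells remain (half-up rounding;
distance ties broken uniformly at random).  The seed, at distance zero,
always survives.  All survivors are set inactive, and then
`min(n_react, size)` cells are reactivated, sampled without replacement
with weight equal to their distance from the seed (the seed's own weight
is zero unless it is the only cell; if the weight pool is exhausted the
draw falls back to uniform).  This encodes the field observation that
colonies contract toward the nest in winter and restart tunnel growth at
the periphery.

**Season cycling.**  One cycle is summer (*T* steps) → shrinkage →
reactivation.  The census (per-territory occupied-cell counts) is taken
at the end of each summer, and the run stops when the relative change in
the total count between consecutive censuses falls below `steady_tol`,
or after `n_cycles` cycles.  The grid returned is always the post-summer
grid, so analyses see territories at their seasonal maximum.

**Boundaries.**  The lattice is non-periodic.  Off-lattice sites never
receive growth and do not count toward the 7-inactive enclosure rule —
territories live in a finite arena.

## Parameters

| name | meaning | unit | default | rationale |
|---|---|---|---|---|
| `L` | lattice side | cells | 200 | arena used for the field-scale runs |
| `N` | founding pairs | count | 30 | lower end of the studied 30–90 range |
| `T_summer` | summer duration | steps | 36 | matches the New Orleans summer calibration |
| `sigma` | winter retention | % of cells | 20 | observed ~80% winter contraction of *C. formosanus* territories |
| `n_react` | reactivated tips per territory | count | 5 | "several" periphery restart points |
| `n_cycles` | cycle cap | cycles | 50 | ample for the census total to stabilize (typically 10–25) |
| `steady_tol` | steadiness threshold | relative change | 0.01 | 1% change in total count between censuses |

SOM defaults: 6 × 7 map, 10 000 presentations, learning rate decaying
linearly 0.5 → 0.01, Gaussian neighborhood with radius decaying linearly
from max(rows, cols)/2 to 1, inputs min-max scaled to [0, 1] (without
scaling, *T* and *σ* of order tens would swamp *m* of order 0.1 in the
Euclidean distance).  Ward clustering cuts the dendrogram at *k* = 8; no
automatic cut criterion is applied.  Sweep defaults: *T*, *σ* ∈
{10, 15, …, 50}, *N* ∈ {30, 50, 70, 90}, 50 replicates.  The `desk`
preset (L = 100, 20 replicates, σ in steps of 10) is the problem size
used by the test suite and the acceptance script.

## Randomness and reproducibility

Each replicate of a sweep runs on its own substream seed derived from
`SeedSequence([master, N, T, σ, replicate])`, so results are independent
of the order in which combinations execute, and every run is
bit-reproducible from its seed.  Within a run, a single generator drives
landscape creation, seeding, growth draws, conflict resolution, tie
breaking and reactivation in a fixed order.  Conflict winners are chosen
by randomly permuting the proposals and keeping the first proposal per
target, which is exactly uniform.

## Numerical choices

- Shrinkage keeps `max(1, floor(σ/100 × size + 0.5))` cells: half-up
  rounding, with a floor of one so a territory can never go extinct.
- The two-segment slope fit takes ln⟨*A*⟩ against linear rank, tries
  every breakpoint *b* ∈ {2, …, N−2} (front = ranks 1..*b*), fits
  ordinary least squares to both segments and keeps the breakpoint with
  minimal total SSE, preferring the smallest breakpoint on ties.  *m* is
  reported as an absolute value.  Zero-size entries (defensive; they
  cannot arise from the simulator) are dropped with a warning before the
  log transform.
- The slope can be fitted to the replicate-averaged distribution
  (default) or per replicate and averaged (`slope_mode="per_replicate"`);
  both are exposed because the averaging order is a genuine free choice.
- Best-matching SOM units resolve ties to the lowest node index;
  training with a zero learning rate is the identity, and a single
  repeated input pulls the winner onto it (both are tested).
- Convex hulls of territory members (visualization only; territory size
  is always the cell count) degrade gracefully: one cell gives a single
  vertex, collinear cells a segment.

## What the generator emulates — and what it does not

All inputs are synthetic: the uniform landscape stands in for spatial
soil heterogeneity, and seeding is uniform over the arena.  Real
landscapes are spatially autocorrelated, colony founding is not uniform
in space or time, seasonal transitions are gradual rather than a step
function, and territory contraction responds to temperature, rainfall
and resource depletion rather than a fixed retention percentage.
Passing tests therefore certify the internal consistency of the model
and its analysis chain — exact shrinkage accounting, fair conflict
resolution, correct slope estimation, reproducibility — not the fidelity
of any particular parameter set to field colonies.

## Limitations

- **The σ response.**  With the failure-inactivates growth rule, the
  front slope *m* at short summers (*T* = 10) decreases monotonically as
  winter retention σ rises from 10 to 50: small σ leaves tiny, highly
  unequal territories, and large σ evens the leaders out.  An interior
  optimum of *m* at σ ≈ 30–40 — the signature expected if moderate
  retention maximized competitive differentiation — does not emerge at
  these conditions, and the corresponding check in the acceptance suite
  documents this as a failing assertion rather than hiding it.  The
  persistent-tip rule variant, including versions whose winter
  reactivation scales with territory size, shifts the profile toward
  flat or increasing in σ but does not produce a robust interior
  optimum either; only knife-edge parameter combinations show one.  The
  longer-summer trend (*m* rising with *T*) is robust under every
  variant examined.
- Growth from a single founding cell can stall permanently under the
  failure-inactivates rule (the lone tip dies on its first failed draw
  in ~⅓ of attempts on uniform soil); multi-seed runs recover through
  winter reactivation, but single-territory experiments should use
  favorable soil or several cycles.
- At *T* = 10 the steady state occupies well under half the arena, so
  most territory pairs never interact; competition-driven effects are
  necessarily weak at short summers.
- Territory compactness (perimeter-based shape metrics) is out of scope;
  hulls are provided for rendering only.
- The SOM cluster geometry (which nodes form which cluster) is
  stochastic and implementation-sensitive; only its structural
  properties (contraction, monotone Ward merges, non-empty clusters,
  reproducibility from a seed) are guaranteed.
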
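# Methods

## Circuit model

A grid circuit lives on integer coordinates with rows `y` increasing
downward from 0 and columns `x` increasing rightward from 0; positions are
reported as `(row, column)` and only cells with `x <= y` are addressable
(the triangular region an agent entering at the origin can ever reach — one
row down per step, at most one column right). The compiler places split
junctions on every cell of the rows at cumulative element sums and treats
every other cell as a pass junction; the exit row sits at the total sum.
Tag indices number the split-row cells row-major from the top-left starting
at 0, *including* cells that are unreachable in a fault-free circuit —
indices identify designed junction positions, not reachable states.

For Exact Cover the elements are the subsets' binary encodings, with the
first universe element as the least-significant bit. This bit order is a
real choice: with it, degrading the force-down junctions of the
no-cover instance `{{1,2},{1,3},{1,3,4},{1,2,3}}` (encodings 3, 5, 13, 7)
produces the spurious cover 3 + 5 + 7 = 15, which is the behaviour the
degradation study expects; the opposite order does not. Force-down junctions
sit exactly where the cell's column shares a bit with the current subset's
encoding: a column value is the OR of previously included (disjoint)
encodings, so bit overlap is element overlap. Force-down cells keep their
tag index — they are designed split positions — which is what lets the
degraded (force-down→split) circuit equal the plain Subset Sum circuit over
the encoded elements, tags included, and lets its spurious witnesses decode.

## Transition semantics

The agent state is `(x, y, dir, flag)`, optionally with a tag set. Every
step increments `y`. At a split the two successors are `(x, dir'=0)` and
`(x+1, dir'=1)`, the diagonal one collecting the cell's tag; a pass
preserves `dir`; a force-down resets it to 0. `dir` is unconstrained in the
initial state (the entry cell is always a split, so this matters only under
exotic fault placements, where both directions are enumerated). The exit
flag holds exactly at `y = max`.

Exploration is a breadth-first closure of this successor relation, so every
state reachable under *any* resolution of the nondeterminism is present.
This discharges the model's strong-fairness (compassion) obligation — that
a split visited infinitely often takes both branches infinitely often —
without any fairness machinery: on a finite acyclic single traversal,
"eventually explores both branches" and "exhaustively explores" coincide.
A wrap mode (exit states looping to the origin) exists on the successor
relation and in the SMV export, where the published models use it; it is off
by default because it does not change reachability verdicts and keeps state
graphs acyclic. Whether tags should survive a wrap is left open by the
single-traversal default rather than guessed.

Fault semantics: `PASS_AS_SPLIT` behaves as a split but collects no tag
(it is not a designed split and has no index); `PASS_FORCED` and
`SPLIT_FORCED` yield the single forced successor, a forced diagonal at a
designed split still collecting its tag. Forcing a split only removes a
branch, so it can never enlarge the exit set; forcing a *pass* junction can
— agents arriving against the forced direction are deflected onto
undesigned trajectories (this is how a single pass-forced fault makes both
`csum` and `nsum` fail on `S = {2,3,5}`: sums 1 and 6 appear while 3
disappears).

Witness extraction is shortest-path BFS with deterministic tie-breaking
(successor generation order: down before diagonal, true before false), and
every witness is replayable through the successor relation; `path_tags`
validates each step as it decodes.

## Verification queries

All verdicts derive from one exhaustive reachability computation. The
linear-time ("never reaches k") and branching-time ("some path reaches k")
forms of the specific-output query are exact negations on the explored
graph, so both are reported from the same computation; the distinction
matters only for model-checker runtime studies, which are out of scope —
the SMV export preserves both spec forms for anyone running NuSMV. The
overall-output queries compare the exit-column set against the brute-force
subset sums directly; the exported SMV models instead use the frozen
selector variables `sum`/`xsum` over the valid/invalid sum sets, the
standard encoding of a quantified reachability query as a family of initial
states. Verdicts are rendered VALID/INVALID in the fault-study vocabulary.

SAT tag counters range over 0..3 and saturate: a 3-CNF clause contains
three literals, so no path can satisfy it more often. Satisfiability is
"some exit state has all counters positive"; the decoded assignment leaves
variables that occur in no clause at an arbitrary value (True).

## Stochastic semantics

A grid circuit maps to a CRN with one species per *reachable* cell — plain
`x{i}y{j}` at split junctions, direction-carrying `x{i}y{j}d{k}` at pass and
force-down junctions — and one unimolecular reaction per admissible move,
the product species dropping or adding the direction component according to
the target cell's kind. Exit-row species are plain and absorbing (no
outgoing reactions, no wrap): simulated populations accumulate at the exits,
which is the measurable quantity. Restricting species to reachable cells
keeps the reaction system linear in the number of distinct partial sums
rather than quadratic in the grid extent.

All reactions default to rate 1.0 (per unit time); rates are configurable
per junction kind, and an optional wrong-direction reaction at pass
junctions (`pass_error_rate`, default 0 — off) provides a hook for
quantifying imperfect pass junctions. Simulation is Gillespie's direct
method — propensity = rate × copy number, exponential waiting times — run to
absorption by default. Agents are independent (no interaction or exclusion
effects), so with equal rates each split resolves down/diagonal with
probability 1/2 and each of the `2^N` subsets is realised with probability
`2^-N`; the test suite checks the implied exit-bin multinomial at
significance 0.01 over 5 seeds (allowing one rejection, the expected false
positive behaviour of repeated testing). Because every reaction is 1→1, the
total copy number is conserved at every event, which the trajectory exposes
(and tests verify) via full count reconstruction rather than by assumption.

## Problem sizes and defaults

Oracles are exhaustive by design — subset enumeration, subcollection
enumeration, truth tables (refused above 24 variables) — because they are
the ground truth the circuits are judged against. Randomised
circuit-vs-oracle suites run 100 instances per family at desk scale: Subset
Sum with up to 8 elements of value ≤ 12, Exact Cover with universes up to 6
and up to 6 subsets, 3-CNF with up to 10 variables and ~30 clauses. The
Exact Cover generator draws each universe element into a subset with
probability 0.35 (redrawing empty subsets), giving the small, overlapping
subsets typical of hand-built instances and keeping binary-encoded grids
compact. The distribution check uses `S = {2,3,5}` with 10 000 agents. The
largest circuits exercised are the two 8-element Exact Cover instances
(grid extent ≈ 550), which explore in well under a second because reachable
columns are limited to partial sums.

## Known limitations

- Verification is explicit-state and exhaustive; it is meant for circuit
  design studies, not for competitive SAT/ExCov solving, and scales with
  the number of distinct partial sums × rows.
- The SMV export is one-way and untested against a live NuSMV binary here;
  its fidelity is guarded by determinism and structural tests (spec names,
  variable ranges, variant differences), not by model-checker runs.
- Compassion is emitted as paired justice constraints in SMV, an
  approximation that is adequate for the reachability/safety queries used
  but is not a general compassion encoding.
- The CRN view covers grid circuits only; SAT networks have no stochastic
  translation, and multi-agent interaction/congestion is deliberately not
  modelled.
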
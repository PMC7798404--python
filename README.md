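# nbckit

Design, formal verification and stochastic simulation of **network-based
biocomputation (NBC) circuits** — nanofabricated planar networks in which
motile biological agents (actin filaments or microtubules driven by molecular
motors) explore all paths in parallel to solve combinatorial problems.

`nbckit` is for people designing such circuits: it compiles problem instances
into junction networks, exhaustively checks a design's logical correctness
*before* fabrication (with witness paths and counterexamples), studies the
effect of manufacturing faults, and simulates agent populations as a chemical
reaction network.

## The model

A circuit for the **Subset Sum** problem over `S = {s_1, ..., s_N}` is a
triangular grid of junctions. An agent at `(x, y)` always moves one row down
(`y' = y + 1`) and either keeps its column (`dir = 0`, down) or shifts one
right (`dir = 1`, diagonal). Rows at the cumulative sums
`0, s_1, s_1 + s_2, ...` hold **split junctions**, where the direction is
chosen nondeterministically; all other rows hold **pass junctions**, which
preserve it. Crossing the split row of element `s_t` diagonally adds `s_t` to
the agent's column, so the exit column at row `max = Σ s_i` is a subset sum,
and a population of agents computes *all* subset sums in parallel. Tag indices
on split junctions let an exit agent's tag set reconstruct exactly which
elements were added.

**Exact Cover** reduces to Subset Sum by encoding each subset as the integer
whose bits mark its elements (first universe element = least-significant
bit); **force-down junctions** replace splits wherever the column's bits
overlap the current subset's encoding, blocking re-inclusion of an
already-covered element. An exact cover exists iff the output `2^n - 1` is
reachable. **3-SAT** uses a DAG of literal junctions whose true/false
branches run through the clause junctions they satisfy; a formula is
satisfiable iff some exit agent holds a positive tag counter for every
clause.

Correctness queries are answered by exhaustive exploration of this
transition system: `ctl_k` (output `k` reachable) / `ltl_k` (never
reachable), `csum` / `nsum` (all valid sums reachable / no invalid sum
reachable) and `ctl_sat` / `ltl_sat`, each with a replayable witness or
counterexample. Models can also be exported in SMV syntax for the
NuSMV/nuXmv model checkers, and grid circuits translate to a chemical
reaction network (species per location, unimolecular movement reactions)
simulated with Gillespie's algorithm.

## Worked example

```python
import nbckit as nk

net = nk.build_ssp_network(nk.SSPInstance([2, 5, 9]))
graph = nk.explore(net)
print(sorted(nk.exit_columns(graph)))

ltl, ctl = nk.check_output(net, 11)
tags = nk.path_tags(ctl.witness, net)
print(ctl.holds, nk.tags_to_elements(net, tags))
```

prints

```
[0, 2, 5, 7, 9, 11, 14, 16]
True [2, 9]
```

— the 8 subset sums of `{2, 5, 9}`, and a witness that output 11 is computed
by adding 2 and 9. The same from the command line:

```
$ nbc verify ssp --set 2,5,9 --k 11
set: [2, 5, 9]
k: 11
reachable: True
witness_elements: [2, 9]
```

Fault injection (`nbc inject --fault '3,1,PASS_FORCED,0'`) and overall-output
verification (`nbc verify ssp --set 2,3,5 --all`) reproduce how a single
faulty junction flips `csum`/`nsum` from VALID/VALID to INVALID/INVALID,
naming the lost and spurious sums.

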
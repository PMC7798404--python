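"""Discrete nondeterministic semantics of biocomputation circuits.

An agent's configuration is its grid position (x, y), its direction of
movement (0 = down, 1 = diagonal) and an exit flag; optionally it carries
tags recording the split junctions where it went diagonal.  Every step moves
the agent one row down; the column stays or increments according to the
junction kind and the agent's direction.  Split junctions choose the new
direction nondeterministically; pass junctions preserve it; force-down
junctions reset it to down.  Injected faults override the designed
behaviour at their cell.

``explore`` computes the breadth-first closure of the successor relation
from the initial state (the agent entering at the top-left corner, direction
unconstrained), yielding a finite acyclic state graph that contains every
state reachable under *any* resolution of the nondeterminism.  This is the
whole content of the model's strong-fairness (compassion) requirements —
that both branches of every split are eventually taken — so reachability
verdicts read off the graph coincide with temporal-logic model checking of
the corresponding safety/reachability queries.

Clause and matrix SAT networks get the analogous treatment with states
carrying per-clause tag counters (saturating at 3, the most times a 3-CNF
clause can be satisfied along one path) or tag sets.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, NamedTuple, Optional, Sequence, Union

import networkx as nx

from .network import (
    DIAGONAL,
    DOWN,
    ClauseNetwork,
    FaultType,
    GridNetwork,
    JunctionKind,
    MatrixSatNetwork,
)

__all__ = [
    "GridState",
    "ClauseState",
    "MatrixState",
    "StateGraph",
    "initial_state",
    "successors",
    "explore",
    "exit_columns",
    "exit_states",
    "witness_path",
    "follow",
    "path_tags",
    "tags_to_elements",
    "tags_to_labels",
    "decode_assignment",
]


class GridState(NamedTuple):
    """One agent configuration in a grid network.

    ``dir`` is None only in the initial state, where the direction is
    deliberately unconstrained; ``tags`` is None in untagged exploration.
    """

    x: int
    y: int
    dir: Optional[int]
    flag: bool
    tags: Optional[frozenset[int]] = None


class ClauseState(NamedTuple):
    """Agent configuration in a clause network: current node + clause counters."""

    node: tuple
    counters: tuple[int, ...]
    flag: bool


class MatrixState(NamedTuple):
    """Agent configuration in a matrix SAT network: next literal row,
    assignment prefix and collected clause tags."""

    row: int
    assignment: tuple[bool, ...]
    tags: frozenset[int]
    flag: bool


AnyNetwork = Union[GridNetwork, ClauseNetwork, MatrixSatNetwork]
AnyState = Union[GridState, ClauseState, MatrixState]

#: Tag counters saturate here: a 3-CNF clause holds at most 3 literals.
COUNTER_CAP = 3


def initial_state(net: AnyNetwork, tagged: bool = False) -> AnyState:
    if isinstance(net, GridNetwork):
        return GridState(0, 0, None, False, frozenset() if tagged else None)
    if isinstance(net, ClauseNetwork):
        return ClauseState(("lit", 1), (0,) * net.num_clauses, False)
    if isinstance(net, MatrixSatNetwork):
        return MatrixState(1, (), frozenset(), False)
    raise TypeError(f"unsupported network type {type(net).__name__}")


# ---------------------------------------------------------------------------
# Successor relations
# ---------------------------------------------------------------------------

def _grid_successors(s: GridState, net: GridNetwork, wrap: bool) -> tuple[GridState, ...]:
    if s.y == net.exit_row:
        return (initial_state(net, tagged=s.tags is not None),) if wrap else ()
    kind = net.kind_at(s.y, s.x)
    fault = net.faults.get((s.y, s.x))
    # moves: (new column, new direction, tag added on this step)
    if fault is not None and fault.fault_type is FaultType.PASS_AS_SPLIT:
        # behaves as a split but is not a designed one: no tag index to add
        moves = [(s.x, DOWN, False), (s.x + 1, DIAGONAL, False)]
    elif fault is not None:  # PASS_FORCED or SPLIT_FORCED
        d = fault.forced_dir
        tag = d == DIAGONAL and kind is JunctionKind.SPLIT
        moves = [(s.x + d, d, tag)]
    elif kind is JunctionKind.SPLIT:
        moves = [(s.x, DOWN, False), (s.x + 1, DIAGONAL, True)]
    elif kind is JunctionKind.FORCE_DOWN:
        moves = [(s.x, DOWN, False)]
    else:  # PASS
        dirs = (DOWN, DIAGONAL) if s.dir is None else (s.dir,)
        moves = [(s.x + d, d, False) for d in dirs]
    out = []
    for nx_, nd, add_tag in moves:
        tags = s.tags
        if tags is not None and add_tag:
            tags = tags | {net.tag_index[(s.y, s.x)]}
        out.append(GridState(nx_, s.y + 1, nd, s.y + 1 == net.exit_row, tags))
    return tuple(out)


def _clause_successors(s: ClauseState, net: ClauseNetwork) -> tuple[ClauseState, ...]:
    if s.flag:
        return ()

    def after_chain(j: int) -> tuple:
        return ("lit", j + 1) if j < net.num_vars else ("exit",)

    def bump(counters: tuple[int, ...], clause: int) -> tuple[int, ...]:
        c = list(counters)
        c[clause - 1] = min(c[clause - 1] + 1, COUNTER_CAP)
        return tuple(c)

    node = s.node
    out = []
    if node[0] == "lit":
        j = node[1]
        for pol in (True, False):
            chain = net.chain(j, pol)
            if chain:
                out.append(ClauseState(("clause", j, pol, 0), bump(s.counters, chain[0]), False))
            else:
                nxt = after_chain(j)
                out.append(ClauseState(nxt, s.counters, nxt == ("exit",)))
    elif node[0] == "clause":
        _, j, pol, i = node
        chain = net.chain(j, pol)
        if i + 1 < len(chain):
            out.append(ClauseState(("clause", j, pol, i + 1), bump(s.counters, chain[i + 1]), False))
        else:
            nxt = after_chain(j)
            out.append(ClauseState(nxt, s.counters, nxt == ("exit",)))
    # deduplicate (both polarities of a clause-free literal coincide)
    seen, uniq = set(), []
    for t in out:
        if t not in seen:
            seen.add(t)
            uniq.append(t)
    return tuple(uniq)


def _matrix_successors(s: MatrixState, net: MatrixSatNetwork) -> tuple[MatrixState, ...]:
    if s.flag:
        return ()
    j = s.row
    out = []
    for value in (False, True):
        out.append(
            MatrixState(
                j + 1,
                s.assignment + (value,),
                s.tags | net.satisfied_by(j, value),
                j + 1 > net.num_vars,
            )
        )
    return tuple(out)


def successors(s: AnyState, net: AnyNetwork, wrap: bool = False) -> tuple[AnyState, ...]:
    """All successor states of ``s`` in ``net`` under every nondeterministic choice.

    With ``wrap`` on, exit states loop back to the initial state (an agent
    re-entering at the top-left corner); by default exit states are absorbing
    so a single traversal stays acyclic.
    """
    if isinstance(net, GridNetwork):
        if not (0 <= s.x <= s.y <= net.max):
            raise ValueError(f"state ({s.y}, {s.x}) is not addressable in this network")
        return _grid_successors(s, net, wrap)
    if isinstance(net, ClauseNetwork):
        return _clause_successors(s, net)
    if isinstance(net, MatrixSatNetwork):
        return _matrix_successors(s, net)
    raise TypeError(f"unsupported network type {type(net).__name__}")


# ---------------------------------------------------------------------------
# Exhaustive exploration
# ---------------------------------------------------------------------------

@dataclass
class StateGraph:
    """The finite transition system explored from the initial state.

    ``edges`` maps each discovered state to its successor tuple, in
    deterministic breadth-first discovery order.
    """

    net: AnyNetwork
    initial: AnyState
    edges: dict[AnyState, tuple[AnyState, ...]]

    @property
    def states(self):
        return self.edges.keys()

    def __len__(self) -> int:
        return len(self.edges)

    def exit_states(self) -> list[AnyState]:
        return [s for s in self.edges if s.flag]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for s, succs in self.edges.items():
            g.add_node(str(s), flag=bool(s.flag))
            for t in succs:
                g.add_edge(str(s), str(t))
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_edgelist(self, path) -> None:
        with open(path, "w") as fh:
            for s, succs in self.edges.items():
                for t in succs:
                    fh.write(f"{s}\t{t}\n")


def explore(net: AnyNetwork, tagged: bool = False) -> StateGraph:
    """Breadth-first closure of the successor relation (single traversal).

    Every state reachable under any resolution of the split-junction
    nondeterminism is present — the finite-exploration counterpart of the
    compassion requirement that both branches of every split are eventually
    taken.
    """
    init = initial_state(net, tagged=tagged)
    edges: dict[AnyState, tuple[AnyState, ...]] = {}
    queue = deque([init])
    edges[init] = ()
    while queue:
        s = queue.popleft()
        succs = successors(s, net)
        edges[s] = succs
        for t in succs:
            if t not in edges:
                edges[t] = ()
                queue.append(t)
    return StateGraph(net=net, initial=init, edges=edges)


def exit_states(g: StateGraph) -> list[AnyState]:
    return g.exit_states()


def exit_columns(g: StateGraph) -> set[int]:
    """Distinct exit-row columns — the subset sums the circuit can compute."""
    if not isinstance(g.net, GridNetwork):
        raise TypeError("exit_columns is defined for grid-network state graphs")
    return {s.x for s in g.edges if s.flag}


def witness_path(
    g: StateGraph, predicate: Callable[[AnyState], bool]
) -> Optional[list[AnyState]]:
    """A shortest initial-to-satisfying-state path, or None if unreachable.

    Breadth-first with parent pointers in discovery order, so the returned
    path is deterministic for a fixed graph.
    """
    if predicate(g.initial):
        return [g.initial]
    parent: dict[AnyState, AnyState] = {g.initial: g.initial}
    queue = deque([g.initial])
    while queue:
        s = queue.popleft()
        for t in g.edges[s]:
            if t in parent:
                continue
            parent[t] = s
            if predicate(t):
                path = [t]
                while path[-1] != g.initial:
                    path.append(parent[path[-1]])
                return list(reversed(path))
            queue.append(t)
    return None


def follow(net: GridNetwork, decisions: Mapping[int, int], tagged: bool = True) -> list[GridState]:
    """Trace the single path that resolves each split row per ``decisions``.

    ``decisions`` maps a split row to 0 (down) or 1 (diagonal); rows where
    the circuit leaves no choice (pass, force-down, forced faults) ignore the
    mapping.  Raises if a needed decision is missing.
    """
    s = initial_state(net, tagged=tagged)
    path = [s]
    while not s.flag:
        succs = successors(s, net)
        if len(succs) == 1:
            s = succs[0]
        else:
            if s.y not in decisions:
                raise KeyError(f"no decision supplied for split row {s.y}")
            want = decisions[s.y]
            s = next(t for t in succs if t.x - path[-1].x == want)
        path.append(s)
    return path


# ---------------------------------------------------------------------------
# Path decoding
# ---------------------------------------------------------------------------

def path_tags(path: Sequence[GridState], net: GridNetwork) -> frozenset[int]:
    """Tag indices collected along ``path`` (validated against the semantics).

    A tag is collected at each designed split junction where the path steps
    diagonally.  The sum of the corresponding block elements equals the exit
    column — tags reconstruct the computation.
    """
    tags: set[int] = set()
    for s, t in zip(path, path[1:]):
        if t not in successors(s, net):
            raise ValueError(f"invalid step {s} -> {t}")
        cell = (s.y, s.x)
        if t.x == s.x + 1 and cell in net.tag_index and net.kind_at(s.y, s.x) is JunctionKind.SPLIT:
            tags.add(net.tag_index[cell])
    return frozenset(tags)


def tags_to_elements(net: GridNetwork, tags: Iterable[int]) -> list[int]:
    """The element values added by the tagged diagonal choices."""
    return sorted(net.element_of_tag(t) for t in tags)


def tags_to_labels(net: GridNetwork, tags: Iterable[int]) -> list[int]:
    """Block labels (ExCov: 1-based subset indices) of the tagged choices."""
    return sorted(net.label_of_tag(t) for t in tags)


def decode_assignment(path: Sequence[ClauseState], net: ClauseNetwork) -> dict[int, bool]:
    """Recover the variable assignment a clause-network path realizes.

    A literal whose branches are both clause-free leaves the choice invisible
    in the state sequence; such variables affect no clause and default to True.
    """
    assignment: dict[int, bool] = {}
    for s, t in zip(path, path[1:]):
        if s.node[0] != "lit":
            continue
        j = s.node[1]
        if t.node[0] == "clause":
            assignment[j] = t.node[2]
        else:
            true_empty = not net.chain(j, True)
            false_empty = not net.chain(j, False)
            if true_empty and false_empty:
                assignment[j] = True
            else:
                assignment[j] = true_empty
    return assignment
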
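"""Compilation of problem instances into biocomputation circuits.

A grid network (Subset Sum / Exact Cover) is a triangular arrangement of
junctions on integer coordinates: rows ``y`` grow downward from 0, columns
``x`` rightward from 0, and only cells with ``x <= y`` are addressable.
Agents enter at the top-left corner (0, 0) and drift down one row per step,
optionally moving one column right (a "diagonal" step).  Rows at the
cumulative sums of the encoded elements hold split junctions, where an agent
nondeterministically keeps or changes column; all other rows hold pass
junctions that preserve the agent's direction.  The exit row sits at the
total sum, so an agent's exit column is the sum of the elements whose split
rows it crossed diagonally.

Exact Cover reuses the same grid over binary-encoded subsets, with
force-down junctions replacing splits wherever taking the diagonal would
re-include an already-covered universe element.

3-SAT uses two dedicated shapes: a matrix network (one split row per
literal) and a clause network (a DAG of literal junctions whose true/false
branches run through the clause junctions they satisfy).

Fault injection models manufacturing errors: a pass junction behaving as a
split, a pass junction forcing one direction, or a split junction forcing
one direction.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

import networkx as nx

from .problems import CNFFormula, ExCovInstance, SSPInstance, subset_encoding

__all__ = [
    "JunctionKind",
    "FaultType",
    "FaultSpec",
    "GridNetwork",
    "ClauseNetwork",
    "MatrixSatNetwork",
    "build_ssp_network",
    "build_excov_network",
    "build_sat_clause_network",
    "build_sat_matrix_network",
    "apply_fault",
    "degrade_force_down",
]

DOWN = 0
DIAGONAL = 1


class JunctionKind(Enum):
    SPLIT = "SPLIT"
    PASS = "PASS"
    FORCE_DOWN = "FORCE_DOWN"
    LITERAL = "LITERAL"
    CLAUSE = "CLAUSE"


class FaultType(Enum):
    PASS_AS_SPLIT = "PASS_AS_SPLIT"
    PASS_FORCED = "PASS_FORCED"
    SPLIT_FORCED = "SPLIT_FORCED"


@dataclass(frozen=True)
class FaultSpec:
    """A deliberate junction error: position (row, column), type, forced direction.

    ``forced_dir`` (0 = down, 1 = diagonal) is required for the two forcing
    types and meaningless for PASS_AS_SPLIT.
    """

    position: tuple[int, int]
    fault_type: FaultType
    forced_dir: Optional[int] = None

    def __post_init__(self):
        if self.fault_type in (FaultType.PASS_FORCED, FaultType.SPLIT_FORCED):
            if self.forced_dir not in (DOWN, DIAGONAL):
                raise ValueError(f"{self.fault_type.value} requires forced_dir 0 or 1")


@dataclass(frozen=True)
class Block:
    """One element's band of rows: split row, row span = element value."""

    start_row: int
    element: int
    #: 1-based subset index for ExCov networks, element ordinal for SSP.
    label: int


@dataclass
class GridNetwork:
    """A compiled Subset Sum / Exact Cover circuit on a triangular grid."""

    kind: str  # "ssp" | "excov"
    elements: tuple[int, ...]
    max: int
    split_rows: tuple[int, ...]
    blocks: tuple[Block, ...]
    #: kinds of split-row cells only; every other addressable cell is PASS.
    split_row_kinds: dict[tuple[int, int], JunctionKind]
    #: tag index of every split-row cell, row-major from the top-left.
    tag_index: dict[tuple[int, int], int]
    faults: dict[tuple[int, int], FaultSpec] = field(default_factory=dict)

    # -- geometry ----------------------------------------------------------
    @property
    def exit_row(self) -> int:
        return self.max

    def addressable(self, y: int, x: int) -> bool:
        return 0 <= x <= y <= self.max

    def kind_at(self, y: int, x: int) -> JunctionKind:
        """Designed junction kind at (row, column); faults do not change it."""
        if not self.addressable(y, x) or y >= self.max:
            raise ValueError(f"({y}, {x}) is not an addressable junction cell")
        return self.split_row_kinds.get((y, x), JunctionKind.PASS)

    def block_of_row(self, y: int) -> Block:
        """The element block whose split row is ``y``."""
        for b in self.blocks:
            if b.start_row == y:
                return b
        raise KeyError(f"row {y} is not a split row")

    def element_of_block(self, split_row: int) -> int:
        return self.block_of_row(split_row).element

    def element_of_tag(self, tag: int) -> int:
        """The element value added when the split with index ``tag`` goes diagonal."""
        return self.block_of_row(self._tag_rows[tag]).element

    def label_of_tag(self, tag: int) -> int:
        return self.block_of_row(self._tag_rows[tag]).label

    @property
    def _tag_rows(self) -> dict[int, int]:
        return {t: yx[0] for yx, t in self.tag_index.items()}

    def n_split_cells(self) -> int:
        return sum(
            1 for k in self.split_row_kinds.values() if k is JunctionKind.SPLIT
        )


def _grid_from_elements(
    kind: str, elements: Iterable[int], force_down_mask=None
) -> GridNetwork:
    elements = tuple(int(e) for e in elements)
    if not elements:
        raise ValueError("a grid network needs at least one element")
    if any(e < 1 for e in elements):
        raise ValueError(f"grid elements must be positive, got {elements}")
    total = sum(elements)
    split_rows, acc = [], 0
    for e in elements[:-1]:
        split_rows.append(acc)
        acc += e
    split_rows.append(acc)  # last block's split row
    blocks = tuple(
        Block(start_row=r, element=e, label=i + 1)
        for i, (r, e) in enumerate(zip(split_rows, elements))
    )
    kinds: dict[tuple[int, int], JunctionKind] = {}
    tags: dict[tuple[int, int], int] = {}
    t = 0
    for b in blocks:
        for x in range(b.start_row + 1):
            cell = (b.start_row, x)
            if force_down_mask is not None and (x & force_down_mask[b.label - 1]):
                kinds[cell] = JunctionKind.FORCE_DOWN
            else:
                kinds[cell] = JunctionKind.SPLIT
            tags[cell] = t
            t += 1
    return GridNetwork(
        kind=kind,
        elements=elements,
        max=total,
        split_rows=tuple(split_rows),
        blocks=blocks,
        split_row_kinds=kinds,
        tag_index=tags,
    )


def build_ssp_network(inst: SSPInstance) -> GridNetwork:
    """Compile a Subset Sum instance into its triangular grid circuit.

    Split rows sit at the cumulative sums 0, s1, s1+s2, ...; the exit row at
    the total.  Every cell of a split row is a split junction, all other
    cells pass junctions.  Tag indices number split cells row-major from the
    top-left (index 0), including cells unreachable in a fault-free circuit.
    """
    if not inst.elements:
        raise ValueError("cannot build a network for an empty set")
    return _grid_from_elements("ssp", inst.elements)


def build_excov_network(inst: ExCovInstance) -> GridNetwork:
    """Compile an Exact Cover instance via the binary reduction to Subset Sum.

    Elements are the subsets' binary encodings.  In the split row for subset
    S_t, the cell at column c is a force-down junction iff c shares a bit
    with enc(S_t): the column value is the OR of the encodings already
    included on the path, so a shared bit means a shared universe element and
    the diagonal (include S_t) must be blocked.
    """
    if not inst.subsets:
        raise ValueError("cannot build a network for an empty subset collection")
    enc = subset_encoding(inst)
    return _grid_from_elements("excov", enc, force_down_mask=enc)


def degrade_force_down(net: GridNetwork) -> GridNetwork:
    """The faulty ExCov variant whose force-down junctions behave as splits.

    Replacing every FORCE_DOWN with SPLIT yields exactly the Subset Sum
    network over the encoded elements — the circuit one would get by
    forgetting the disjointness constraint of the reduction.
    """
    kinds = {
        cell: (JunctionKind.SPLIT if k is JunctionKind.FORCE_DOWN else k)
        for cell, k in net.split_row_kinds.items()
    }
    return replace(net, split_row_kinds=kinds, faults=dict(net.faults))


def apply_fault(net: GridNetwork, fault: FaultSpec) -> GridNetwork:
    """Return a copy of ``net`` with ``fault`` injected; the original is unchanged.

    The fault type must match the designed kind at its position:
    PASS_AS_SPLIT and PASS_FORCED target pass cells, SPLIT_FORCED split cells.
    """
    y, x = fault.position
    kind = net.kind_at(y, x)  # raises for unaddressable positions
    needs = {
        FaultType.PASS_AS_SPLIT: JunctionKind.PASS,
        FaultType.PASS_FORCED: JunctionKind.PASS,
        FaultType.SPLIT_FORCED: JunctionKind.SPLIT,
    }[fault.fault_type]
    if kind is not needs:
        raise ValueError(
            f"{fault.fault_type.value} requires a {needs.value} cell but "
            f"({y}, {x}) is {kind.value}"
        )
    faults = dict(net.faults)
    faults[fault.position] = fault
    return replace(net, faults=faults)


# ---------------------------------------------------------------------------
# SAT networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClauseNetwork:
    """The literal/clause DAG encoding of a CNF formula.

    Literal junctions 1..m are visited in order; each has a TRUE and a FALSE
    branch.  A branch is a chain of clause junctions — the clauses satisfied
    by that polarity of the literal, in ascending clause order — ending at
    the next literal junction (or the exit after literal m).  Agents are
    tagged at each clause junction they traverse; an exit agent whose tag
    counters are all positive witnesses a satisfying assignment.
    """

    num_vars: int
    num_clauses: int
    #: (literal j, polarity) -> ascending clause indices (1-based) on that branch.
    branch_chains: dict[tuple[int, bool], tuple[int, ...]]

    def chain(self, literal: int, polarity: bool) -> tuple[int, ...]:
        return self.branch_chains[(literal, polarity)]

    def to_networkx(self) -> nx.DiGraph:
        """The underlying rooted DAG, for inspection and structural checks."""
        g = nx.DiGraph()
        exit_node = "exit"
        g.add_node(exit_node, kind="exit")
        for j in range(1, self.num_vars + 1):
            g.add_node(("lit", j), kind="literal", literal=j)
        for j in range(1, self.num_vars + 1):
            nxt = ("lit", j + 1) if j < self.num_vars else exit_node
            for pol in (True, False):
                prev = ("lit", j)
                for i, c in enumerate(self.branch_chains[(j, pol)]):
                    node = ("clause", j, pol, i)
                    g.add_node(node, kind="clause", clause=c)
                    g.add_edge(prev, node, polarity=pol)
                    prev = node
                g.add_edge(prev, nxt, polarity=pol)
        return g


def build_sat_clause_network(f: CNFFormula) -> ClauseNetwork:
    """Compile a CNF formula into the literal/clause DAG."""
    chains: dict[tuple[int, bool], tuple[int, ...]] = {}
    for j in range(1, f.num_vars + 1):
        for pol in (True, False):
            lit = j if pol else -j
            chains[(j, pol)] = tuple(
                i + 1 for i, c in enumerate(f.clauses) if lit in c
            )
    return ClauseNetwork(
        num_vars=f.num_vars, num_clauses=f.num_clauses, branch_chains=chains
    )


@dataclass(frozen=True)
class MatrixSatNetwork:
    """The matrix-model SAT circuit: one split decision row per literal.

    At row j the agent chooses x_j's value (diagonal = true, down = false)
    and is tagged, immediately after the decision, with every clause that
    choice satisfies.  The formula is satisfiable iff some exit agent carries
    tags for all clauses.
    """

    formula: CNFFormula

    @property
    def num_vars(self) -> int:
        return self.formula.num_vars

    @property
    def num_clauses(self) -> int:
        return self.formula.num_clauses

    def satisfied_by(self, literal: int, value: bool) -> frozenset[int]:
        """1-based indices of clauses satisfied by assigning ``literal`` = value."""
        lit = literal if value else -literal
        return frozenset(
            i + 1 for i, c in enumerate(self.formula.clauses) if lit in c
        )


def build_sat_matrix_network(f: CNFFormula) -> MatrixSatNetwork:
    """Compile a CNF formula into the matrix-model circuit."""
    return MatrixSatNetwork(formula=f)
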
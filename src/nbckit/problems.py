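"""Problem instances, brute-force oracles and random generators.

Network-based biocomputation circuits encode instances of three NP-complete
problems: Subset Sum (SSP), Exact Cover (ExCov) and Boolean satisfiability in
3-CNF.  This module defines the instance types, exhaustive combinatorial
oracles that serve as ground truth for circuit verification, the binary
subset-to-integer encoding used by the ExCov-to-SSP reduction, and seeded
random instance generators for property testing.

The oracles are deliberately naive (full enumeration, no pruning): they are
the reference against which the circuit semantics is judged, so simplicity
and obvious correctness matter more than speed.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "SSPInstance",
    "ExCovInstance",
    "CNFFormula",
    "oracle_subset_sums",
    "oracle_exact_cover",
    "oracle_sat",
    "subset_encoding",
    "random_ssp",
    "random_excov",
    "random_cnf3",
    "generate_instance",
]

#: Largest variable count accepted by the truth-table SAT oracle.
SAT_ORACLE_MAX_VARS = 24


@dataclass(frozen=True)
class SSPInstance:
    """A Subset Sum instance: a multiset of positive integers, optional target.

    The decision problem asks whether some subset of ``elements`` sums to the
    target ``k``.  The circuit encoding does not need ``k`` up front — the
    network computes *all* subset sums in parallel — so the target is optional
    and only used by specific-output verification queries.
    """

    elements: tuple[int, ...]
    target: Optional[int] = None

    def __init__(self, elements: Iterable[int], target: Optional[int] = None):
        elements = tuple(int(e) for e in elements)
        if any(e < 1 for e in elements):
            raise ValueError(f"SSP elements must be positive integers, got {elements}")
        if target is not None and target < 0:
            raise ValueError("SSP target must be non-negative")
        object.__setattr__(self, "elements", elements)
        object.__setattr__(self, "target", target)

    @property
    def total(self) -> int:
        return sum(self.elements)


@dataclass(frozen=True)
class ExCovInstance:
    """An Exact Cover instance: a universe and a collection of subsets.

    ``universe`` is an ordered sequence of distinct labels; the position of a
    label (1-based) defines its bit index in the binary reduction to Subset
    Sum.  Subsets may share elements with one another but must each be a
    subset of the universe.
    """

    universe: tuple
    subsets: tuple[frozenset, ...]

    def __init__(self, universe: Iterable, subsets: Iterable[Iterable]):
        universe = tuple(universe)
        if len(set(universe)) != len(universe):
            raise ValueError("universe labels must be distinct")
        subsets = tuple(frozenset(s) for s in subsets)
        uset = set(universe)
        for i, s in enumerate(subsets, start=1):
            extra = s - uset
            if extra:
                raise ValueError(
                    f"subset {i} contains labels not in the universe: {sorted(extra)}"
                )
        object.__setattr__(self, "universe", universe)
        object.__setattr__(self, "subsets", subsets)

    @property
    def n(self) -> int:
        return len(self.universe)


@dataclass(frozen=True)
class CNFFormula:
    """A CNF formula over variables 1..num_vars.

    Clauses are sets of signed literals in DIMACS convention: literal ``+j``
    is variable ``x_j``, ``-j`` its negation.  Empty clauses are rejected —
    they have no circuit encoding (and make the formula trivially false).
    """

    num_vars: int
    clauses: tuple[frozenset[int], ...]

    def __init__(self, num_vars: int, clauses: Iterable[Iterable[int]]):
        num_vars = int(num_vars)
        if num_vars < 1:
            raise ValueError("num_vars must be positive")
        clauses = tuple(frozenset(int(l) for l in c) for c in clauses)
        for i, c in enumerate(clauses, start=1):
            if not c:
                raise ValueError(f"clause {i} is empty")
            for lit in c:
                if lit == 0 or abs(lit) > num_vars:
                    raise ValueError(f"clause {i}: literal {lit} out of range 1..{num_vars}")
        object.__setattr__(self, "num_vars", num_vars)
        object.__setattr__(self, "clauses", clauses)

    @property
    def num_clauses(self) -> int:
        return len(self.clauses)

    def evaluate(self, assignment: Mapping[int, bool]) -> bool:
        """True iff ``assignment`` (variable index -> bool) satisfies every clause."""
        return all(
            any((lit > 0) == assignment[abs(lit)] for lit in clause)
            for clause in self.clauses
        )


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def oracle_subset_sums(inst: SSPInstance) -> set[int]:
    """All achievable subset sums of ``inst.elements``, by full enumeration.

    Always contains 0 (the empty subset) and the total sum.
    """
    elements = inst.elements
    sums = set()
    for r in range(len(elements) + 1):
        for combo in itertools.combinations(range(len(elements)), r):
            sums.add(sum(elements[i] for i in combo))
    return sums


def oracle_exact_cover(inst: ExCovInstance) -> tuple[bool, Optional[list[int]]]:
    """Decide exact cover by enumerating all subcollections.

    Returns ``(True, witness)`` where ``witness`` lists 1-based indices of
    pairwise-disjoint subsets whose union is the universe, or ``(False, None)``.
    The lexicographically first witness (by index tuple) is returned.
    """
    universe = set(inst.universe)
    m = len(inst.subsets)
    for r in range(m + 1):
        for combo in itertools.combinations(range(m), r):
            chosen = [inst.subsets[i] for i in combo]
            if sum(len(s) for s in chosen) != len(universe):
                continue
            union = set().union(*chosen) if chosen else set()
            if union == universe:
                # equal cardinality + equal union => pairwise disjoint
                return True, [i + 1 for i in combo]
    return False, None


def oracle_sat(f: CNFFormula) -> tuple[bool, Optional[dict[int, bool]]]:
    """Decide satisfiability by exhaustive truth-table enumeration.

    Guarded at ``SAT_ORACLE_MAX_VARS`` variables: beyond that the 2^m table is
    not desk-scale and the call is refused rather than silently truncated.
    Returns ``(True, assignment)`` for the first satisfying assignment in
    lexicographic order (False before True), or ``(False, None)``.
    """
    if f.num_vars > SAT_ORACLE_MAX_VARS:
        raise ValueError(
            f"truth-table oracle refuses {f.num_vars} variables "
            f"(limit {SAT_ORACLE_MAX_VARS})"
        )
    for bits in itertools.product((False, True), repeat=f.num_vars):
        assignment = {j + 1: bits[j] for j in range(f.num_vars)}
        if f.evaluate(assignment):
            return True, assignment
    return False, None


# ---------------------------------------------------------------------------
# ExCov -> SSP binary encoding
# ---------------------------------------------------------------------------

def subset_encoding(inst: ExCovInstance) -> tuple[int, ...]:
    """Encode each subset as the integer whose bits mark its elements.

    The universe element at (1-based) position ``i`` contributes ``2**(i-1)``
    — the first universe element is the least-significant bit.  The full
    universe therefore encodes to ``2**n - 1``, the exit value that signals an
    exact cover in the reduced Subset Sum network.
    """
    index = {label: i for i, label in enumerate(inst.universe)}
    return tuple(sum(1 << index[e] for e in s) for s in inst.subsets)


def universe_encoding(inst: ExCovInstance) -> int:
    """The target value ``2**n - 1`` for an ExCov instance with |U| = n."""
    return (1 << inst.n) - 1


# ---------------------------------------------------------------------------
# Random instance generators (seeded, deterministic)
# ---------------------------------------------------------------------------

def random_ssp(n_elements: int, max_element: int, seed: int) -> SSPInstance:
    """A random SSP instance with ``n_elements`` values drawn from 1..max_element."""
    if n_elements < 1 or max_element < 1:
        raise ValueError("n_elements and max_element must be >= 1")
    rng = random.Random(seed)
    return SSPInstance([rng.randint(1, max_element) for _ in range(n_elements)])


def random_excov(
    n_universe: int, n_subsets: int, seed: int, p_member: float = 0.35
) -> ExCovInstance:
    """A random ExCov instance over universe {1..n_universe}.

    Each subset includes each universe element independently with probability
    ``p_member`` and is redrawn if empty, giving the small, overlapping
    subsets typical of hand-built exact-cover examples while keeping the
    binary-encoded grid compact.
    """
    if n_universe < 1 or n_subsets < 1:
        raise ValueError("n_universe and n_subsets must be >= 1")
    rng = random.Random(seed)
    universe = tuple(range(1, n_universe + 1))
    subsets = []
    for _ in range(n_subsets):
        s: frozenset = frozenset()
        while not s:
            s = frozenset(e for e in universe if rng.random() < p_member)
        subsets.append(s)
    return ExCovInstance(universe, subsets)


def random_cnf3(num_vars: int, num_clauses: int, seed: int) -> CNFFormula:
    """A random 3-CNF formula: each clause has 3 distinct variables, random signs."""
    if num_vars < 3:
        raise ValueError("3-CNF generation needs at least 3 variables")
    if num_clauses < 1:
        raise ValueError("num_clauses must be >= 1")
    rng = random.Random(seed)
    clauses = []
    for _ in range(num_clauses):
        vars3 = rng.sample(range(1, num_vars + 1), 3)
        clauses.append([v if rng.random() < 0.5 else -v for v in vars3])
    return CNFFormula(num_vars, clauses)


def generate_instance(kind: str, seed: int, **sizes):
    """Dispatch to the generator for ``kind`` in {'ssp', 'excov', 'cnf3'}.

    Size parameters: ssp(n_elements, max_element); excov(n_universe,
    n_subsets); cnf3(num_vars, num_clauses).
    """
    if kind == "ssp":
        return random_ssp(seed=seed, **sizes)
    if kind == "excov":
        return random_excov(seed=seed, **sizes)
    if kind == "cnf3":
        return random_cnf3(seed=seed, **sizes)
    raise ValueError(f"unknown instance kind {kind!r}")
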
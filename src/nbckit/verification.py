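"""Correctness queries over explored circuits.

Three query families, mirroring how the circuits are checked in practice:

* specific output — ``ltl_k`` (output k is never reachable, a safety
  property) and ``ctl_k`` (some path reaches output k, a reachability
  property).  The two are logical negations of each other on the finite
  state graph.
* overall output — ``csum`` (every valid subset sum is reachable) and
  ``nsum`` (no invalid sum is reachable), with the verdict vocabulary
  VALID/INVALID and offending sums as counterexample material.
* SAT all-tags — ``ltl_sat`` / ``ctl_sat``: does some exit agent carry a
  positive tag counter for every clause?

All verdicts come from one exhaustive reachability computation on the state
graph; existential verdicts carry a witness path and universal violations a
counterexample path, each re-checkable by replaying the successor relation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .network import (
    ClauseNetwork,
    GridNetwork,
    MatrixSatNetwork,
    build_excov_network,
    build_sat_clause_network,
    build_ssp_network,
)
from .problems import (
    CNFFormula,
    ExCovInstance,
    SSPInstance,
    oracle_exact_cover,
    oracle_sat,
    oracle_subset_sums,
    universe_encoding,
)
from . import semantics
from .semantics import StateGraph, explore, exit_columns, witness_path

__all__ = [
    "Verdict",
    "check_output",
    "check_all_outputs",
    "check_excov",
    "check_sat",
    "verify_against_oracle",
]


@dataclass
class Verdict:
    """Outcome of one query: holds/violated plus supporting evidence.

    ``witness`` backs a true existential verdict; ``counterexample`` backs a
    false universal one.  ``sums`` carries the offending sum values for the
    overall-output queries.
    """

    query: str
    holds: bool
    witness: Optional[list] = None
    counterexample: Optional[list] = None
    sums: Optional[set[int]] = None
    detail: str = ""

    @property
    def valid(self) -> str:
        """Table-style VALID/INVALID rendering of the verdict."""
        return "VALID" if self.holds else "INVALID"

    def to_dict(self) -> dict:
        def coords(path):
            return None if path is None else [tuple(s)[:4] for s in path]

        return {
            "query": self.query,
            "holds": self.holds,
            "witness": coords(self.witness),
            "counterexample": coords(self.counterexample),
            "sums": sorted(self.sums) if self.sums is not None else None,
            "detail": self.detail,
        }


def _graph(net, graph: Optional[StateGraph]) -> StateGraph:
    return graph if graph is not None else explore(net)


def check_output(
    net: GridNetwork, k: int, graph: Optional[StateGraph] = None
) -> tuple[Verdict, Verdict]:
    """The (ltl_k, ctl_k) pair for a specific output column ``k``.

    ctl_k holds iff some exit state has column k (witness: a shortest path);
    ltl_k states k is never reached and is always the exact negation.
    """
    if not 0 <= k <= net.max:
        raise ValueError(f"output {k} outside the network range 0..{net.max}")
    g = _graph(net, graph)
    path = witness_path(g, lambda s: s.flag and s.x == k)
    reachable = path is not None
    ctl = Verdict(query="ctl_k", holds=reachable, witness=path,
                  detail=f"EF(flag & x = {k})")
    ltl = Verdict(query="ltl_k", holds=not reachable, counterexample=path,
                  detail=f"G !(flag & x = {k})")
    return ltl, ctl


def check_all_outputs(
    net: GridNetwork,
    valid_sums: Optional[set[int]] = None,
    graph: Optional[StateGraph] = None,
) -> tuple[Verdict, Verdict]:
    """The (csum, nsum) pair: all valid sums reachable / no invalid sum reachable.

    ``valid_sums`` defaults to the brute-force subset sums of the network's
    elements — the designed behaviour a fault-free circuit must realise.
    """
    if valid_sums is None:
        valid_sums = oracle_subset_sums(SSPInstance(net.elements))
    g = _graph(net, graph)
    exits = exit_columns(g)
    missing = set(valid_sums) - exits
    extra = exits - set(valid_sums)
    csum = Verdict(
        query="csum",
        holds=not missing,
        sums=missing or None,
        detail="all valid sums reachable" if not missing
        else f"unreachable valid sums: {sorted(missing)}",
    )
    nsum = Verdict(
        query="nsum",
        holds=not extra,
        sums=extra or None,
        detail="no invalid sum reachable" if not extra
        else f"reachable invalid sums: {sorted(extra)}",
    )
    if extra:
        nsum.counterexample = witness_path(
            g, lambda s: s.flag and s.x == min(extra)
        )
    return csum, nsum


def check_excov(
    net: GridNetwork, inst: ExCovInstance, graph: Optional[StateGraph] = None
) -> Verdict:
    """Does the circuit reach the full-universe output ``2**n - 1``?

    On success the witness path's tags decode to the covering subsets
    (1-based indices into the instance's collection).
    """
    target = universe_encoding(inst)
    g = _graph(net, graph)
    path = witness_path(g, lambda s: s.flag and s.x == target)
    v = Verdict(
        query="excov",
        holds=path is not None,
        witness=path,
        detail=f"target output {target}",
    )
    if path is not None:
        tags = semantics.path_tags(path, net)
        v.detail += f"; cover subsets {semantics.tags_to_labels(net, tags)}"
    return v


def check_sat(
    net: Union[ClauseNetwork, MatrixSatNetwork], graph: Optional[StateGraph] = None
) -> tuple[Verdict, Verdict]:
    """The (ltl_sat, ctl_sat) pair for a SAT network.

    ctl_sat holds iff some exit state satisfies every clause (all tag
    counters positive for the clause model; all clause tags present for the
    matrix model); ltl_sat is the negation.
    """
    g = _graph(net, graph)
    if isinstance(net, ClauseNetwork):
        pred = lambda s: s.flag and all(c > 0 for c in s.counters)  # noqa: E731
    else:
        n = net.num_clauses
        pred = lambda s: s.flag and len(s.tags) == n  # noqa: E731
    path = witness_path(g, pred)
    sat = path is not None
    ctl = Verdict(query="ctl_sat", holds=sat, witness=path,
                  detail="EF(flag & all tags > 0)")
    ltl = Verdict(query="ltl_sat", holds=not sat, counterexample=path,
                  detail="G !(flag & all tags > 0)")
    if sat and isinstance(net, ClauseNetwork):
        assignment = semantics.decode_assignment(path, net)
        ctl.detail += f"; assignment {assignment}"
    return ltl, ctl


# ---------------------------------------------------------------------------
# Oracle cross-check harness
# ---------------------------------------------------------------------------

@dataclass
class OracleReport:
    """Agreement between circuit verdicts and the brute-force oracle."""

    kind: str
    agree: bool
    checks: list[tuple[str, bool]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "agree": self.agree,
                "checks": [{"query": q, "agree": a} for q, a in self.checks]}


def verify_against_oracle(
    inst: Union[SSPInstance, ExCovInstance, CNFFormula]
) -> OracleReport:
    """Build the circuit for ``inst``, verify it, and compare with the oracle.

    SSP: ctl_k for every k in 0..max against membership in the brute-force
    subset sums.  ExCov: the full-universe reachability verdict against the
    exact-cover oracle.  CNF: the clause-network verdict against the
    truth-table oracle.
    """
    checks: list[tuple[str, bool]] = []
    if isinstance(inst, SSPInstance):
        net = build_ssp_network(inst)
        g = explore(net)
        sums = oracle_subset_sums(inst)
        exits = exit_columns(g)
        for k in range(net.max + 1):
            _, ctl = check_output(net, k, graph=g)
            checks.append((f"ctl_k[{k}]", ctl.holds == (k in sums)))
        checks.append(("exit_support", exits == sums))
        return OracleReport("ssp", all(a for _, a in checks), checks)
    if isinstance(inst, ExCovInstance):
        net = build_excov_network(inst)
        verdict = check_excov(net, inst)
        expected, _ = oracle_exact_cover(inst)
        checks.append(("excov", verdict.holds == expected))
        return OracleReport("excov", all(a for _, a in checks), checks)
    if isinstance(inst, CNFFormula):
        net = build_sat_clause_network(inst)
        _, ctl = check_sat(net)
        expected, _ = oracle_sat(inst)
        checks.append(("ctl_sat", ctl.holds == expected))
        return OracleReport("cnf", all(a for _, a in checks), checks)
    raise TypeError(f"unsupported instance type {type(inst).__name__}")
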
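"""SMV model export for the NuSMV / nuXmv model checkers.

The exporter reproduces the relational form of the circuit semantics: the
row always increments (wrapping from the exit row back to the origin), the
column follows the current direction, and the direction variable is
re-chosen nondeterministically on arriving at a split junction, forced down
at a force-down junction, and preserved at a pass junction.  Strong
fairness (compassion) — every split visited infinitely often takes both
branches infinitely often — is approximated by paired justice constraints,
since plain NuSMV models lack a compassion declaration.

Specification names follow the query families: ``ltl_k`` / ``ctl_k`` for a
specific output, ``csum`` / ``nsum`` for overall-output correctness via the
frozen selector variables ``sum`` and ``xsum``, and ``ltl_sat`` /
``ctl_sat`` for the SAT all-tags check.

The export is one-way: models are written, never executed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .network import ClauseNetwork, FaultType, GridNetwork, JunctionKind
from .problems import SSPInstance, oracle_subset_sums

__all__ = ["SmvModel", "write_smv"]


@dataclass(frozen=True)
class SmvModel:
    """Generated SMV module text plus the options that produced it."""

    text: str
    kind: str
    options: tuple[tuple[str, object], ...]

    def __str__(self) -> str:
        return self.text

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.text)


def _disj(terms: list[str]) -> str:
    if not terms:
        return "FALSE"
    return " | ".join(terms)


def _conj(terms: list[str]) -> str:
    if not terms:
        return "TRUE"
    return " & ".join(terms)


# ---------------------------------------------------------------------------
# Grid networks
# ---------------------------------------------------------------------------

def _grid_membership(net: GridNetwork, xv: str, yv: str) -> tuple[str, str]:
    """(split, force-down) membership expressions over variable texts xv, yv."""
    split_terms: list[str] = []
    fd_rows: dict[int, list[int]] = {}
    for r in net.split_rows:
        fd_cols = [
            x for x in range(r + 1)
            if net.split_row_kinds[(r, x)] is JunctionKind.FORCE_DOWN
        ]
        if fd_cols:
            fd_rows[r] = fd_cols
            cols = _disj([f"{xv} = {c}" for c in fd_cols])
            split_terms.append(f"({yv} = {r} & !({cols}))")
        else:
            split_terms.append(f"({yv} = {r})")
    # faulted pass-as-split cells behave as (untagged) splits
    for (r, c), fault in sorted(net.faults.items()):
        if fault.fault_type is FaultType.PASS_AS_SPLIT:
            split_terms.append(f"({yv} = {r} & {xv} = {c})")
    fd_terms = [
        f"({yv} = {r} & ({_disj([f'{xv} = {c}' for c in cols])}))"
        for r, cols in sorted(fd_rows.items())
    ]
    return _disj(split_terms), _disj(fd_terms)


def _grid_smv(
    net: GridNetwork,
    k: Optional[int],
    overall: bool,
    tagged: bool,
    valid_sums: Optional[set[int]],
) -> SmvModel:
    mx = net.max
    lines: list[str] = []
    out = lines.append
    out("MODULE main")
    out(f"-- grid circuit ({net.kind}), elements {list(net.elements)}, exit row {mx}")
    out("VAR")
    out(f"  x : 0..{mx};")
    out(f"  y : 0..{mx};")
    out("  dir : boolean;")
    tag_cells = sorted(net.tag_index.items(), key=lambda it: it[1])
    if tagged:
        for (r, c), t in tag_cells:
            out(f"  tag{t} : boolean;  -- split at row {r}, column {c}")
    if overall:
        if valid_sums is None:
            valid_sums = oracle_subset_sums(SSPInstance(net.elements))
        invalid = sorted(set(range(mx + 1)) - set(valid_sums))
        out("FROZENVAR")
        out(f"  sum : {{{', '.join(map(str, sorted(valid_sums)))}}};")
        if invalid:
            out(f"  xsum : {{{', '.join(map(str, invalid))}}};")
    out("DEFINE")
    out(f"  flag := y = {mx};")
    split_cur, fd_cur = _grid_membership(net, "x", "y")
    out(f"  in_split := {split_cur};")
    out(f"  in_forcedown := {fd_cur};")
    out("INIT")
    out("  x = 0 & y = 0")
    # row: always down one, wrap from the exit row to the origin
    out("TRANS")
    out(f"  next(y) = (y = {mx} ? 0 : y + 1)")
    # column: follows the current direction; reset on wrap
    out("TRANS")
    out(f"  (y = {mx} -> next(x) = 0) &")
    out(f"  (y < {mx} & !dir -> next(x) = x) &")
    out(f"  (y < {mx} & dir -> next(x) = x + 1)")
    # direction: re-chosen at splits (unconstrained), forced at force-down,
    # preserved at pass junctions; unconstrained on wrap (the origin is a split)
    split_next, fd_next = _grid_membership(net, "next(x)", "next(y)")
    out("TRANS")
    out(f"  (({fd_next}) -> !next(dir)) &")
    out(f"  (y < {mx} & !(({split_next}) | ({fd_next}) | next(y) = {mx})"
        " -> next(dir) = dir)")
    for (r, c), fault in sorted(net.faults.items()):
        if fault.fault_type in (FaultType.PASS_FORCED, FaultType.SPLIT_FORCED):
            want = "next(dir)" if fault.forced_dir else "!next(dir)"
            out("TRANS")
            out(f"  -- injected fault {fault.fault_type.value} at ({r}, {c})")
            out(f"  (next(y) = {r} & next(x) = {c} -> {want})")
    if tagged:
        for (r, c), t in tag_cells:
            out("TRANS")
            out(f"  next(tag{t}) = (tag{t} | (x = {c} & y = {r} & dir))")
        out("INIT")
        out("  " + _conj([f"!tag{t}" for _, t in tag_cells]))
    # compassion approximated by paired justice constraints: a split visited
    # infinitely often chooses each direction infinitely often
    for r in net.split_rows:
        for c in range(r + 1):
            if net.split_row_kinds[(r, c)] is not JunctionKind.SPLIT:
                continue
            out(f"JUSTICE !(x = {c} & y = {r}) | !dir")
            out(f"JUSTICE !(x = {c} & y = {r}) | dir")
    if k is not None:
        out(f"LTLSPEC NAME ltl_k := G !(flag & x = {k})")
        out(f"CTLSPEC NAME ctl_k := EF (flag & x = {k})")
    if overall:
        out("CTLSPEC NAME csum := EF (flag & x = sum)")
        if invalid:
            out("CTLSPEC NAME nsum := !(EF (flag & x = xsum))")
        else:
            out("CTLSPEC NAME nsum := TRUE")
    options = (("k", k), ("overall", overall), ("tagged", tagged))
    return SmvModel(text="\n".join(lines) + "\n", kind="grid", options=options)


# ---------------------------------------------------------------------------
# SAT clause networks
# ---------------------------------------------------------------------------

def _tag_order(net: ClauseNetwork, variable_order: str) -> list[int]:
    if variable_order == "default":
        return list(range(1, net.num_clauses + 1))
    if variable_order == "reordered":
        # by first appearance of each clause scanning the literal branches
        order: list[int] = []
        for j in range(1, net.num_vars + 1):
            for pol in (True, False):
                for c in net.chain(j, pol):
                    if c not in order:
                        order.append(c)
        order.extend(c for c in range(1, net.num_clauses + 1) if c not in order)
        return order
    raise ValueError(f"unknown variable_order {variable_order!r}")


def _hit_expr(net: ClauseNetwork, clause: int) -> str:
    terms = []
    for j in range(1, net.num_vars + 1):
        if clause in net.chain(j, True):
            terms.append(f"(lit = {j} & val)")
        if clause in net.chain(j, False):
            terms.append(f"(lit = {j} & !val)")
    return _disj(terms)


def _clause_smv(net: ClauseNetwork, sat_variant: str, variable_order: str) -> SmvModel:
    m, n = net.num_vars, net.num_clauses
    order = _tag_order(net, variable_order)
    lines: list[str] = []
    out = lines.append
    out("MODULE main")
    out(f"-- SAT clause circuit ({sat_variant} variant), {m} literals, {n} clauses")
    out("VAR")
    out(f"  lit : 1..{m + 1};")
    out("  val : boolean;")
    if sat_variant == "clause":
        max_chain = max((len(ch) for ch in net.branch_chains.values()), default=0)
        out(f"  cl : 0..{max(max_chain, 1)};")
    for c in order:
        out(f"  tag{c} : 0..3;")
    out("DEFINE")
    out(f"  flag := lit = {m + 1};")
    if sat_variant == "clause":
        len_terms = []
        for j in range(1, m + 1):
            for pol in (True, False):
                v = "val" if pol else "!val"
                len_terms.append(f"    lit = {j} & {v} : {len(net.chain(j, pol))};")
        out("  chain_len := case")
        lines.extend(len_terms)
        out("    TRUE : 0;")
        out("  esac;")
    out("INIT")
    out("  lit = 1" + (" & cl = 0" if sat_variant == "clause" else ""))
    out("INIT")
    out("  " + _conj([f"tag{c} = 0" for c in order]))
    if sat_variant == "clause":
        out("TRANS")
        out("  case")
        out("    flag : next(lit) = lit & next(cl) = cl & next(val) = val;")
        out("    cl < chain_len : next(lit) = lit & next(val) = val & next(cl) = cl + 1;")
        out("    TRUE : next(lit) = lit + 1 & next(cl) = 0;")
        out("  esac")
        # tag of the clause junction entered on this step
        for c in order:
            conds = []
            for j in range(1, m + 1):
                for pol in (True, False):
                    chain = net.chain(j, pol)
                    for i, cc in enumerate(chain):
                        if cc == c:
                            v = "val" if pol else "!val"
                            conds.append(f"(lit = {j} & {v} & cl = {i})")
            cond = _disj(conds)
            out("TRANS")
            out(f"  next(tag{c}) = (!flag & cl < chain_len & ({cond}) & tag{c} < 3"
                f" ? tag{c} + 1 : tag{c})")
    else:  # no-clause: one step per literal, tags merged into the literal step
        out("TRANS")
        out("  (flag -> next(lit) = lit) & (!flag -> next(lit) = lit + 1)")
        for c in order:
            hit = _hit_expr(net, c)
            out("TRANS")
            out(f"  next(tag{c}) = (!flag & ({hit}) & tag{c} < 3 ? tag{c} + 1 : tag{c})")
    all_tags = _conj([f"tag{c} > 0" for c in range(1, n + 1)])
    out(f"LTLSPEC NAME ltl_sat := G !(flag & {all_tags})")
    out(f"CTLSPEC NAME ctl_sat := EF (flag & {all_tags})")
    options = (("sat_variant", sat_variant), ("variable_order", variable_order))
    return SmvModel(text="\n".join(lines) + "\n", kind="sat", options=options)


# ---------------------------------------------------------------------------
# Entry point
# ---------------------------------------------------------------------------

def write_smv(
    net: Union[GridNetwork, ClauseNetwork],
    k: Optional[int] = None,
    overall: bool = False,
    tagged: bool = False,
    sat_variant: Optional[str] = None,
    variable_order: str = "default",
    valid_sums: Optional[set[int]] = None,
) -> SmvModel:
    """Generate the SMV module for a circuit.

    Grid networks accept ``k`` (specific-output specs), ``overall``
    (csum/nsum via the sum/xsum frozen selectors) and ``tagged``; SAT clause
    networks accept ``sat_variant`` ("clause" or "no_clause") and
    ``variable_order`` ("default" or "reordered").  Output is byte-identical
    for identical inputs.
    """
    if isinstance(net, GridNetwork):
        if sat_variant is not None:
            raise ValueError("sat_variant applies only to SAT clause networks")
        if k is not None and not 0 <= k <= net.max:
            raise ValueError(f"k={k} outside 0..{net.max}")
        return _grid_smv(net, k, overall, tagged, valid_sums)
    if isinstance(net, ClauseNetwork):
        if k is not None or overall or tagged:
            raise ValueError("k/overall/tagged apply only to grid networks")
        variant = sat_variant or "clause"
        if variant not in ("clause", "no_clause"):
            raise ValueError(f"unknown sat_variant {variant!r}")
        return _clause_smv(net, variant, variable_order)
    raise TypeError(f"unsupported network type {type(net).__name__}")
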
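"""DIMACS CNF reading and writing.

The standard exchange format for SAT instances: a header ``p cnf <vars>
<clauses>`` followed by whitespace-separated signed literals, each clause
terminated by 0.  Clauses may span lines; comment lines start with ``c``.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .problems import CNFFormula

__all__ = ["read_dimacs", "write_dimacs", "DimacsError"]


class DimacsError(ValueError):
    """A DIMACS parse error, carrying the offending line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


def read_dimacs(text: str) -> CNFFormula:
    """Parse DIMACS CNF text into a formula.

    Raises :class:`DimacsError` with a line number for a malformed or
    missing header, out-of-range literals, an unterminated final clause, or
    a clause count that contradicts the header.
    """
    num_vars: Optional[int] = None
    declared_clauses: Optional[int] = None
    clauses: list[list[int]] = []
    current: list[int] = []
    header_line = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("c"):
            continue
        if line.startswith("p"):
            if num_vars is not None:
                raise DimacsError(lineno, "duplicate problem header")
            parts = line.split()
            if len(parts) != 4 or parts[1] != "cnf":
                raise DimacsError(lineno, f"malformed header {line!r}; expected 'p cnf <vars> <clauses>'")
            try:
                num_vars, declared_clauses = int(parts[2]), int(parts[3])
            except ValueError:
                raise DimacsError(lineno, f"non-integer counts in header {line!r}") from None
            header_line = lineno
            continue
        if num_vars is None:
            raise DimacsError(lineno, "clause data before 'p cnf' header")
        for tok in line.split():
            try:
                lit = int(tok)
            except ValueError:
                raise DimacsError(lineno, f"not a literal: {tok!r}") from None
            if lit == 0:
                if not current:
                    raise DimacsError(lineno, "empty clause")
                clauses.append(current)
                current = []
            else:
                if abs(lit) > num_vars:
                    raise DimacsError(lineno, f"literal {lit} exceeds declared variable count {num_vars}")
                current.append(lit)
        last_line = lineno
    if num_vars is None:
        raise DimacsError(1, "missing 'p cnf' header")
    if current:
        raise DimacsError(last_line, "final clause missing its 0 terminator")
    if declared_clauses is not None and declared_clauses != len(clauses):
        raise DimacsError(
            header_line,
            f"header declares {declared_clauses} clauses but {len(clauses)} were read",
        )
    return CNFFormula(num_vars, clauses)


def write_dimacs(f: CNFFormula, comments: Iterable[str] = ()) -> str:
    """Serialize a formula to DIMACS text, with optional comment lines."""
    lines = [f"c {c}" for c in comments]
    lines.append(f"p cnf {f.num_vars} {f.num_clauses}")
    for clause in f.clauses:
        lits = sorted(clause, key=lambda l: (abs(l), l < 0))
        lines.append(" ".join(str(l) for l in lits) + " 0")
    return "\n".join(lines) + "\n"
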
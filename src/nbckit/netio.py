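"""Line-oriented plain-text serialization of grid networks.

Format (one record per line, '#' comments ignored):

    nbc-grid v1
    kind ssp
    elements 2 5 9
    cell <row> <col> <KIND> <tag_index>
    fault <row> <col> <TYPE> [<forced_dir>]

Only split-row cells are listed — every other addressable cell is a pass
junction.  The format round-trips exactly: reading a written network yields
an equal :class:`~nbckit.network.GridNetwork`.
"""

from __future__ import annotations

import yaml

from .network import FaultSpec, FaultType, GridNetwork, JunctionKind, _grid_from_elements
from .problems import CNFFormula, ExCovInstance, SSPInstance

__all__ = ["write_network_text", "read_network_text", "instance_from_yaml"]

_MAGIC = "nbc-grid v1"


def write_network_text(net: GridNetwork) -> str:
    lines = [_MAGIC, f"kind {net.kind}", "elements " + " ".join(map(str, net.elements))]
    for (y, x), kind in sorted(net.split_row_kinds.items()):
        lines.append(f"cell {y} {x} {kind.value} {net.tag_index[(y, x)]}")
    for (y, x), fault in sorted(net.faults.items()):
        rec = f"fault {y} {x} {fault.fault_type.value}"
        if fault.forced_dir is not None:
            rec += f" {fault.forced_dir}"
        lines.append(rec)
    return "\n".join(lines) + "\n"


def read_network_text(text: str) -> GridNetwork:
    lines = [
        ln.strip() for ln in text.splitlines() if ln.strip() and not ln.strip().startswith("#")
    ]
    if not lines or lines[0] != _MAGIC:
        raise ValueError(f"not a {_MAGIC!r} file")
    kind = None
    elements: tuple[int, ...] | None = None
    cells: list[tuple[int, int, JunctionKind, int]] = []
    faults: list[FaultSpec] = []
    for ln in lines[1:]:
        parts = ln.split()
        if parts[0] == "kind":
            kind = parts[1]
        elif parts[0] == "elements":
            elements = tuple(int(p) for p in parts[1:])
        elif parts[0] == "cell":
            cells.append((int(parts[1]), int(parts[2]), JunctionKind(parts[3]), int(parts[4])))
        elif parts[0] == "fault":
            forced = int(parts[4]) if len(parts) > 4 else None
            faults.append(FaultSpec((int(parts[1]), int(parts[2])), FaultType(parts[3]), forced))
        else:
            raise ValueError(f"unknown record {parts[0]!r}")
    if kind is None or elements is None:
        raise ValueError("missing 'kind' or 'elements' record")
    net = _grid_from_elements(kind, elements)
    # overlay the serialized cell kinds (force-down placement) and tags
    kinds = dict(net.split_row_kinds)
    tags = dict(net.tag_index)
    for y, x, k, t in cells:
        if (y, x) not in kinds:
            raise ValueError(f"cell ({y}, {x}) is not on a split row of these elements")
        kinds[(y, x)] = k
        tags[(y, x)] = t
    net.split_row_kinds = kinds
    net.tag_index = tags
    net.faults = {f.position: f for f in faults}
    return net


def instance_from_yaml(text: str):
    """Build a problem instance from a small YAML/key:value description.

    Schemas::

        problem: ssp          problem: excov            problem: cnf
        elements: [2, 5, 9]   universe: [1, 2, 3, 4]    num_vars: 3
        target: 11  # opt.    subsets: [[2], [3]]       clauses: [[1, -2, 3]]
    """
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or "problem" not in data:
        raise ValueError("instance description needs a 'problem' key")
    kind = data["problem"]
    try:
        if kind == "ssp":
            return SSPInstance(data["elements"], data.get("target"))
        if kind == "excov":
            return ExCovInstance(data["universe"], data["subsets"])
        if kind == "cnf":
            return CNFFormula(data["num_vars"], data["clauses"])
    except KeyError as e:
        raise ValueError(f"missing field {e} for problem {kind!r}") from None
    raise ValueError(f"unknown problem kind {kind!r}")
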
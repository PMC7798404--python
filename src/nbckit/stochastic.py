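"""Chemical-reaction-network semantics and stochastic simulation.

A grid circuit maps to a CRN with one species per reachable cell: plain
species ``x{i}y{j}`` at split junctions (and at the absorbing exit row),
direction-carrying species ``x{i}y{j}d{k}`` at pass and force-down
junctions, where the direction component records how the agent is moving.
Each junction's admissible moves become unimolecular reactions to the
species one row down, dropping or adding the direction component according
to the target cell's kind.  Copy numbers count how many agents sit at each
location, so a population of non-interacting agents explores the network in
parallel; exit-row species are absorbing.

``simulate_ssa`` runs Gillespie's direct method: propensity = rate x copy
number, exponential waiting times, one reaction fired per event.  Because
every reaction is 1 -> 1, the total copy number is conserved along any
trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Optional, Union
from xml.etree import ElementTree as ET

import numpy as np

from .network import DIAGONAL, DOWN, FaultType, GridNetwork, JunctionKind

__all__ = [
    "Species",
    "Reaction",
    "CRN",
    "Trajectory",
    "network_to_crn",
    "simulate_ssa",
    "exit_counts",
]


class Species(NamedTuple):
    """A network location, with a direction component at pass/force-down cells."""

    x: int
    y: int
    dir: Optional[int] = None

    @property
    def name(self) -> str:
        base = f"x{self.x}y{self.y}"
        return base if self.dir is None else f"{base}d{self.dir}"

    @classmethod
    def from_name(cls, name: str) -> "Species":
        import re

        m = re.fullmatch(r"x(\d+)y(\d+)(?:d([01]))?", name)
        if m is None:
            raise ValueError(f"not a species name: {name!r}")
        d = m.group(3)
        return cls(int(m.group(1)), int(m.group(2)), None if d is None else int(d))


class Reaction(NamedTuple):
    reactant: Species
    product: Species
    rate: float


@dataclass(frozen=True)
class CRN:
    """Species and unimolecular reactions derived from a grid circuit."""

    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    exit_row: int

    @property
    def index(self) -> dict[Species, int]:
        return {s: i for i, s in enumerate(self.species)}

    def entry(self) -> Species:
        return Species(0, 0, None)

    def exit_species(self) -> list[Species]:
        return [s for s in self.species if s.y == self.exit_row]

    def to_text(self) -> str:
        lines = [f"{r.reactant.name} -> {r.product.name} @ {r.rate:g}" for r in self.reactions]
        return "\n".join(lines) + "\n"

    def to_sbml(self) -> str:
        """A minimal SBML Level 3 document (mass-action unimolecular reactions)."""
        ns = "http://www.sbml.org/sbml/level3/version2/core"
        ET.register_namespace("", ns)
        sbml = ET.Element(f"{{{ns}}}sbml", {"level": "3", "version": "2"})
        model = ET.SubElement(sbml, f"{{{ns}}}model", {"id": "nbc_crn"})
        comps = ET.SubElement(model, f"{{{ns}}}listOfCompartments")
        ET.SubElement(comps, f"{{{ns}}}compartment",
                      {"id": "device", "constant": "true", "size": "1"})
        sps = ET.SubElement(model, f"{{{ns}}}listOfSpecies")
        for s in self.species:
            ET.SubElement(sps, f"{{{ns}}}species", {
                "id": s.name, "compartment": "device",
                "hasOnlySubstanceUnits": "true",
                "boundaryCondition": "false", "constant": "false",
            })
        rxns = ET.SubElement(model, f"{{{ns}}}listOfReactions")
        for i, r in enumerate(self.reactions):
            rx = ET.SubElement(rxns, f"{{{ns}}}reaction",
                               {"id": f"r{i}", "reversible": "false"})
            re_ = ET.SubElement(rx, f"{{{ns}}}listOfReactants")
            ET.SubElement(re_, f"{{{ns}}}speciesReference",
                          {"species": r.reactant.name, "stoichiometry": "1",
                           "constant": "true"})
            pr = ET.SubElement(rx, f"{{{ns}}}listOfProducts")
            ET.SubElement(pr, f"{{{ns}}}speciesReference",
                          {"species": r.product.name, "stoichiometry": "1",
                           "constant": "true"})
        ET.indent(sbml)
        return ET.tostring(sbml, encoding="unicode", xml_declaration=True) + "\n"


def _target_species(net: GridNetwork, x: int, y: int, d: int) -> Species:
    """Species form of the cell one step reaches: plain at splits and at the
    exit row, direction-carrying at pass/force-down cells."""
    if y == net.exit_row:
        return Species(x, y, None)
    kind = net.kind_at(y, x)
    if kind is JunctionKind.SPLIT:
        return Species(x, y, None)
    return Species(x, y, d)


def _moves(net: GridNetwork, x: int, y: int, d: Optional[int]) -> list[int]:
    """Admissible movement directions out of cell (y, x) arrived with direction d."""
    fault = net.faults.get((y, x))
    if fault is not None:
        if fault.fault_type is FaultType.PASS_AS_SPLIT:
            return [DOWN, DIAGONAL]
        return [fault.forced_dir]
    kind = net.kind_at(y, x)
    if kind is JunctionKind.SPLIT:
        return [DOWN, DIAGONAL]
    if kind is JunctionKind.FORCE_DOWN:
        return [DOWN]
    return [DOWN, DIAGONAL] if d is None else [d]


def network_to_crn(
    net: GridNetwork,
    default_rate: float = 1.0,
    kind_rates: Optional[Mapping[JunctionKind, float]] = None,
    pass_error_rate: float = 0.0,
) -> CRN:
    """Translate a grid circuit into its CRN over reachable cells.

    ``kind_rates`` overrides the rate of reactions leaving a junction kind;
    ``pass_error_rate`` > 0 additionally emits, at every pass junction, the
    wrong-direction reaction at that small rate — a hook for quantifying
    pass-junction errors, off by default.
    """
    if default_rate <= 0:
        raise ValueError("default_rate must be positive")
    kind_rates = dict(kind_rates or {})

    def rate_for(kind: JunctionKind) -> float:
        return float(kind_rates.get(kind, default_rate))

    species: dict[Species, None] = {}
    reactions: list[Reaction] = []
    entry = Species(0, 0, None)
    stack = [entry]
    species[entry] = None
    while stack:
        s = stack.pop()
        if s.y == net.exit_row:
            continue
        kind = net.kind_at(s.y, s.x)
        moves = _moves(net, s.x, s.y, s.dir)
        rate = rate_for(kind)
        emitted: list[tuple[int, float]] = [(d, rate) for d in moves]
        if (
            pass_error_rate > 0
            and kind is JunctionKind.PASS
            and s.dir is not None
            and len(moves) == 1
        ):
            emitted.append((1 - moves[0], pass_error_rate))
        for d, r in emitted:
            target = _target_species(net, s.x + d, s.y + 1, d)
            reactions.append(Reaction(s, target, r))
            if target not in species:
                species[target] = None
                stack.append(target)
    ordered = tuple(sorted(species, key=lambda sp: (sp.y, sp.x, -1 if sp.dir is None else sp.dir)))
    reactions.sort(key=lambda r: (r.reactant.y, r.reactant.x,
                                  -1 if r.reactant.dir is None else r.reactant.dir,
                                  r.product.x))
    return CRN(species=ordered, reactions=tuple(reactions), exit_row=net.exit_row)


# ---------------------------------------------------------------------------
# Gillespie direct method
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """An SSA trajectory: initial counts plus the fired-reaction event log."""

    crn: CRN
    seed: int
    initial_counts: np.ndarray  # per-species, aligned with crn.species
    times: np.ndarray  # event times, strictly increasing
    events: np.ndarray  # fired reaction index per event

    @property
    def n_events(self) -> int:
        return len(self.times)

    def final_counts(self) -> np.ndarray:
        counts = self.initial_counts.copy()
        idx = self.crn.index
        react = np.array([idx[r.reactant] for r in self.crn.reactions], dtype=np.intp)
        prod = np.array([idx[r.product] for r in self.crn.reactions], dtype=np.intp)
        np.subtract.at(counts, react[self.events], 1)
        np.add.at(counts, prod[self.events], 1)
        return counts

    def counts_matrix(self) -> np.ndarray:
        """Per-species copy numbers after each event, shape (n_events+1, n_species)."""
        idx = self.crn.index
        react = [idx[r.reactant] for r in self.crn.reactions]
        prod = [idx[r.product] for r in self.crn.reactions]
        out = np.empty((self.n_events + 1, len(self.crn.species)), dtype=np.int64)
        out[0] = self.initial_counts
        row = self.initial_counts.copy()
        for i, e in enumerate(self.events):
            row[react[e]] -= 1
            row[prod[e]] += 1
            out[i + 1] = row
        return out

    def totals_over_time(self) -> np.ndarray:
        """Total copy number after each event (length n_events + 1)."""
        return self.counts_matrix().sum(axis=1)

    def is_absorbed(self) -> bool:
        counts = self.final_counts()
        return all(
            c == 0 for s, c in zip(self.crn.species, counts) if s.y != self.crn.exit_row
        )

    def to_csv(self, path) -> None:
        """Long-format event log: time, species, count (changed species only)."""
        counts = self.initial_counts.copy()
        idx = self.crn.index
        with open(path, "w") as fh:
            fh.write("time,species,count\n")
            for s, c in zip(self.crn.species, counts):
                fh.write(f"0,{s.name},{c}\n")
            for t, e in zip(self.times, self.events):
                r = self.crn.reactions[e]
                i, j = idx[r.reactant], idx[r.product]
                counts[i] -= 1
                counts[j] += 1
                fh.write(f"{t},{r.reactant.name},{counts[i]}\n")
                fh.write(f"{t},{r.product.name},{counts[j]}\n")


def simulate_ssa(
    crn: CRN,
    initial_counts: Mapping[Union[Species, str], int],
    seed: int,
    t_end: float = np.inf,
    max_events: Optional[int] = None,
) -> Trajectory:
    """Gillespie direct-method simulation until absorption, ``t_end`` or ``max_events``.

    ``initial_counts`` maps species (or species names) to non-negative copy
    numbers; unlisted species start at zero.  Deterministic for a fixed seed.
    """
    if not crn.reactions:
        raise ValueError("cannot simulate an empty CRN")
    index = crn.index
    counts = np.zeros(len(crn.species), dtype=np.int64)
    for key, c in initial_counts.items():
        sp = Species.from_name(key) if isinstance(key, str) else key
        if c < 0:
            raise ValueError(f"negative initial count for {sp.name}")
        counts[index[sp]] = c

    rates = np.array([r.rate for r in crn.reactions])
    react = np.array([index[r.reactant] for r in crn.reactions], dtype=np.intp)
    prod = np.array([index[r.product] for r in crn.reactions], dtype=np.intp)

    rng = np.random.default_rng(seed)
    t = 0.0
    times: list[float] = []
    events: list[int] = []
    initial = counts.copy()
    while True:
        if max_events is not None and len(events) >= max_events:
            break
        props = rates * counts[react]
        total = props.sum()
        if total <= 0.0:
            break
        t_next = t + rng.exponential(1.0 / total)
        if t_next > t_end:
            break
        t = t_next
        e = int(np.searchsorted(np.cumsum(props), rng.random() * total, side="right"))
        e = min(e, len(props) - 1)
        counts[react[e]] -= 1
        counts[prod[e]] += 1
        times.append(t)
        events.append(e)
    return Trajectory(
        crn=crn,
        seed=seed,
        initial_counts=initial,
        times=np.asarray(times),
        events=np.asarray(events, dtype=np.intp),
    )


def exit_counts(traj: Trajectory, net: Optional[GridNetwork] = None) -> dict[int, int]:
    """Final agent counts per exit column; requires a fully absorbed trajectory."""
    if not traj.is_absorbed():
        raise ValueError(
            "trajectory not fully absorbed: agents remain in transit "
            "(increase t_end or max_events)"
        )
    counts = traj.final_counts()
    out: dict[int, int] = {}
    for s, c in zip(traj.crn.species, counts):
        if s.y == traj.crn.exit_row:
            out[s.x] = out.get(s.x, 0) + int(c)
    return out
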
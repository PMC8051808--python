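"""Domain types for discrete Bayesian belief networks.

A network is a directed acyclic graph of categorical nodes. Each node carries
an ordered list of state labels (2-5 of them, keeping elicited tables small
enough for experts to fill) and a conditional probability table (CPT) with one
probability row per combination of parent states.

CPT row ordering convention: rows are indexed row-major over the parents *as
listed*, i.e. the first parent varies slowest. This matches the on-disk YAML
format, so files are portable across tools that adopt the same convention.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import yaml

#: Evidence is a plain mapping node name -> state label.
EvidenceMap = Mapping[str, str]

#: Row sums must match 1 to this tolerance to count as normalized.
NORMALIZATION_TOL = 1e-9
#: Rows off by at most this much are silently renormalized on load; anything
#: worse is rejected, since "fixing" a badly scaled expert table would mask a
#: data-entry error.
RENORMALIZE_TOL = 1e-6

MIN_STATES = 2
MAX_STATES = 5

_FORBIDDEN_NAME_CHARS = ("\t", ",", "\n")


class StructuralError(ValueError):
    """The network violates a structural contract (e.g. contains a cycle)."""


@dataclass(frozen=True)
class CPT:
    """Conditional distribution of a node's states per parent combination.

    ``values`` has shape ``(n_rows, n_states)`` where ``n_rows`` is the
    product of the parent state counts (1 for a root node).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError("CPT values must be a 2-D array of row distributions")
        object.__setattr__(self, "values", arr)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_states(self) -> int:
        return self.values.shape[1]

    def row(self, index: int) -> np.ndarray:
        return self.values[index]

    def normalized(self) -> "CPT":
        """Return a copy with rows renormalized, when within ``RENORMALIZE_TOL``.

        Rows further from 1 are left untouched; ``validate_network`` reports
        them as violations.
        """
        vals = self.values.copy()
        sums = vals.sum(axis=1)
        fixable = np.abs(sums - 1.0) <= RENORMALIZE_TOL
        vals[fixable] = vals[fixable] / sums[fixable, None]
        return CPT(vals)


@dataclass
class NodeSpec:
    """One categorical node: states, parents and its CPT.

    ``provenance`` records how the CPT was obtained (``data``, ``expert`` or
    ``expert_calibrated``); ``discretization`` optionally carries the numeric
    bin edges and units used to derive states from continuous measurements.
    """

    name: str
    states: tuple[str, ...]
    parents: tuple[str, ...] = ()
    cpt: Optional[CPT] = None
    provenance: str = "expert"
    discretization: Optional[dict] = None

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        self.parents = tuple(self.parents)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(
                f"node {self.name!r} has no state {state!r}; states are {list(self.states)}"
            ) from None


class NetworkSpec:
    """A directed network of :class:`NodeSpec` objects, keyed by name.

    Edges are implied by each node's parent list. Construction does not
    validate; run :func:`validate_network` to collect violations.
    """

    def __init__(self, nodes: Sequence[NodeSpec]):
        self.nodes: dict[str, NodeSpec] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise ValueError(f"duplicate node name {node.name!r}")
            self.nodes[node.name] = node

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def __iter__(self) -> Iterator[NodeSpec]:
        return iter(self.nodes.values())

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, name: str) -> NodeSpec:
        try:
            return self.nodes[name]
        except KeyError:
            raise KeyError(f"unknown node {name!r}") from None

    def card(self, name: str) -> int:
        return self.node(name).n_states

    def parent_cards(self, name: str) -> tuple[int, ...]:
        return tuple(self.card(p) for p in self.node(name).parents)

    def children(self, name: str) -> list[str]:
        return [n.name for n in self if name in n.parents]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for node in self:
            for parent in node.parents:
                g.add_edge(parent, node.name)
        return g

    def cpt_row_index(self, name: str, assignment: EvidenceMap) -> int:
        """Row index of ``name``'s CPT under a (super)assignment of its parents."""
        node = self.node(name)
        if not node.parents:
            return 0
        idx = tuple(self.node(p).state_index(assignment[p]) for p in node.parents)
        return int(np.ravel_multi_index(idx, self.parent_cards(name)))

    def parent_combinations(self, name: str) -> Iterator[tuple[str, ...]]:
        """Parent-state combinations in CPT row order (first parent slowest)."""
        node = self.node(name)
        yield from itertools.product(*(self.node(p).states for p in node.parents))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        blocks = []
        for node in self:
            block: dict = {
                "name": node.name,
                "states": list(node.states),
                "parents": list(node.parents),
                "provenance": node.provenance,
            }
            if node.cpt is not None:
                block["cpt"] = [[float(v) for v in row] for row in node.cpt.values]
            if node.discretization is not None:
                block["discretization"] = node.discretization
            blocks.append(block)
        return {"format": "lakebbn-network/1", "nodes": blocks}

    @classmethod
    def from_dict(cls, payload: dict) -> "NetworkSpec":
        nodes = []
        for block in payload["nodes"]:
            cpt = None
            if "cpt" in block and block["cpt"] is not None:
                cpt = CPT(np.asarray(block["cpt"], dtype=float)).normalized()
            nodes.append(
                NodeSpec(
                    name=block["name"],
                    states=tuple(block["states"]),
                    parents=tuple(block.get("parents", ())),
                    cpt=cpt,
                    provenance=block.get("provenance", "expert"),
                    discretization=block.get("discretization"),
                )
            )
        return cls(nodes)


def save_network(spec: NetworkSpec, path) -> None:
    """Write a network to YAML. Round-trip read->write->read is stable."""
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False, default_flow_style=None)


def load_network(path) -> NetworkSpec:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return NetworkSpec.from_dict(payload)


# ---------------------------------------------------------------------------
# structural validation


def validate_network(spec: NetworkSpec) -> list[str]:
    """Collect every structural violation; an empty list means the network is
    usable by inference.

    Reported: cycles (as node sequences), dangling parent references,
    state-count violations, duplicate state labels, forbidden name characters,
    missing/ill-shaped CPTs, non-normalized or negative CPT rows. Diagnoses
    rather than throws so callers can report everything at once.
    """
    problems: list[str] = []

    for node in spec:
        if any(ch in node.name for ch in _FORBIDDEN_NAME_CHARS):
            problems.append(f"node name {node.name!r} contains a tab/comma/newline")
        if not (MIN_STATES <= node.n_states <= MAX_STATES):
            problems.append(
                f"node {node.name!r} has {node.n_states} states; "
                f"allowed range is {MIN_STATES}..{MAX_STATES}"
            )
        if len(set(node.states)) != node.n_states:
            problems.append(f"node {node.name!r} has duplicate state labels")
        for parent in node.parents:
            if parent not in spec:
                problems.append(
                    f"node {node.name!r} references unknown parent {parent!r}"
                )

    # Cycles are detected on the subgraph of resolvable edges.
    g = nx.DiGraph()
    g.add_nodes_from(spec.nodes)
    for node in spec:
        for parent in node.parents:
            if parent in spec:
                g.add_edge(parent, node.name)
    for cycle in nx.simple_cycles(g):
        problems.append("cycle: " + " -> ".join(cycle + [cycle[0]]))

    for node in spec:
        if node.cpt is None:
            problems.append(f"node {node.name!r} has no CPT")
            continue
        expected_rows = 1
        dangling = False
        for parent in node.parents:
            if parent not in spec:
                dangling = True
                break
            expected_rows *= spec.card(parent)
        if not dangling and node.cpt.n_rows != expected_rows:
            problems.append(
                f"node {node.name!r} CPT has {node.cpt.n_rows} rows, "
                f"expected {expected_rows}"
            )
        if node.cpt.n_states != node.n_states:
            problems.append(
                f"node {node.name!r} CPT has {node.cpt.n_states} columns, "
                f"expected {node.n_states}"
            )
        if np.any(node.cpt.values < 0) or np.any(node.cpt.values > 1 + NORMALIZATION_TOL):
            problems.append(f"node {node.name!r} CPT has entries outside [0, 1]")
        sums = node.cpt.values.sum(axis=1)
        for i, s in enumerate(sums):
            if abs(s - 1.0) > NORMALIZATION_TOL:
                problems.append(
                    f"node {node.name!r} CPT row {i} sums to {s:.12g}, not 1"
                )

    return problems


def topological_order(spec: NetworkSpec) -> list[str]:
    """Parents-before-children order, ties broken lexicographically.

    Raises :class:`StructuralError` naming a cycle if the graph is cyclic.
    """
    g = spec.graph()
    try:
        return list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        names = [edge[0] for edge in cycle] + [cycle[0][0]]
        raise StructuralError("network contains a cycle: " + " -> ".join(names)) from None


def joint_probability(spec: NetworkSpec, full_assignment: EvidenceMap) -> float:
    """Chain-rule joint probability of a complete state assignment.

    P(x_1..x_n) = prod_i P(x_i | parents(x_i)); every node must be assigned.
    """
    missing = [n.name for n in spec if n.name not in full_assignment]
    if missing:
        raise ValueError(f"assignment misses nodes: {missing}")
    prob = 1.0
    for node in spec:
        if node.cpt is None:
            raise StructuralError(f"node {node.name!r} has no CPT")
        row = spec.cpt_row_index(node.name, full_assignment)
        col = node.state_index(full_assignment[node.name])
        prob *= float(node.cpt.values[row, col])
    return prob


def check_evidence(spec: NetworkSpec, evidence: EvidenceMap) -> None:
    """Raise ``KeyError`` if any evidenced node or state is unknown."""
    for name, state in evidence.items():
        spec.node(name).state_index(state)
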
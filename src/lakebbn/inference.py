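"""Exact posterior inference by variable elimination.

Given evidence E on some nodes, the posterior of a target node H is

    P(H | E) = P(H, E) / P(E),

obtained by summing the chain-rule joint over all unobserved nodes. The sum
is organised as variable elimination over factors: each CPT becomes a factor,
evidence rows are selected out, and unobserved non-target nodes are summed
out one at a time in a min-degree order on the moralized graph. The result is
independent of the elimination order; only the cost depends on it.

``enumerate_joint_oracle`` recomputes the same posterior by brute-force
summation over every complete assignment; it exists as an independent
correctness check for tests and small runs.

All arithmetic is in linear space with double precision: the networks this
package targets (tens of nodes, <=5 states) stay far from underflow.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

from .core import EvidenceMap, NetworkSpec, check_evidence

ORACLE_STATE_SPACE_GUARD = 1_000_000


class ImpossibleEvidenceError(ValueError):
    """The evidence combination has probability zero under the model."""


class Factor:
    """A nonnegative table over the joint states of ``scope`` (one axis per node)."""

    __slots__ = ("scope", "table")

    def __init__(self, scope: list[str], table: np.ndarray):
        self.scope = list(scope)
        self.table = np.asarray(table, dtype=float)
        if self.table.ndim != len(self.scope):
            raise ValueError("factor table rank must equal scope length")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Factor(scope={self.scope}, shape={self.table.shape})"

    def multiply(self, other: "Factor") -> "Factor":
        scope = list(self.scope)
        for v in other.scope:
            if v not in scope:
                scope.append(v)
        return Factor(scope, self._aligned(scope) * other._aligned(scope))

    def _aligned(self, scope: list[str]) -> np.ndarray:
        """Broadcastable view of the table over a superset scope."""
        perm = [self.scope.index(v) for v in scope if v in self.scope]
        table = np.transpose(self.table, perm)
        shape, i = [], 0
        for v in scope:
            if v in self.scope:
                shape.append(table.shape[i])
                i += 1
            else:
                shape.append(1)
        return table.reshape(shape)

    def sum_out(self, var: str) -> "Factor":
        axis = self.scope.index(var)
        scope = self.scope[:axis] + self.scope[axis + 1:]
        return Factor(scope, self.table.sum(axis=axis))

    def reduce(self, var: str, index: int) -> "Factor":
        axis = self.scope.index(var)
        scope = self.scope[:axis] + self.scope[axis + 1:]
        return Factor(scope, np.take(self.table, index, axis=axis))


def _cpt_factor(spec: NetworkSpec, name: str) -> Factor:
    node = spec.node(name)
    if node.cpt is None:
        raise ValueError(f"node {name!r} has no CPT")
    scope = list(node.parents) + [name]
    shape = tuple(spec.card(p) for p in node.parents) + (node.n_states,)
    return Factor(scope, node.cpt.values.reshape(shape))


def _relevant_nodes(spec: NetworkSpec, target: str, evidence: EvidenceMap) -> set[str]:
    """Ancestral closure of target and evidence; barren nodes sum to one and drop."""
    g = spec.graph()
    keep = {target, *evidence}
    for name in list(keep):
        keep |= nx.ancestors(g, name)
    return keep


def elimination_order(
    spec: NetworkSpec, target: str, evidence: EvidenceMap | None = None
) -> list[str]:
    """Min-degree elimination order on the moralized relevant subgraph.

    Evidence nodes are excluded (their factors are sliced, not summed), the
    target is kept last and excluded from the returned order. Ties break
    lexicographically so the order is deterministic.
    """
    evidence = dict(evidence or {})
    relevant = _relevant_nodes(spec, target, evidence)
    to_eliminate = relevant - {target} - set(evidence)

    # moral graph over non-evidence relevant nodes
    g = nx.Graph()
    g.add_nodes_from(relevant - set(evidence))
    for name in relevant:
        family = [v for v in (*spec.node(name).parents, name)
                  if v in relevant and v not in evidence]
        for a, b in itertools.combinations(family, 2):
            g.add_edge(a, b)

    order: list[str] = []
    candidates = set(to_eliminate)
    while candidates:
        pick = min(candidates, key=lambda v: (g.degree(v), v))
        order.append(pick)
        neighbors = [u for u in g.neighbors(pick) if u != pick]
        for a, b in itertools.combinations(neighbors, 2):
            g.add_edge(a, b)
        g.remove_node(pick)
        candidates.remove(pick)
    return order


class PosteriorDistribution:
    """Posterior P(node | evidence): state labels paired with probabilities."""

    def __init__(self, node: str, states: tuple[str, ...], probabilities: np.ndarray):
        self.node = node
        self.states = tuple(states)
        self.probabilities = np.asarray(probabilities, dtype=float)

    def __getitem__(self, state: str) -> float:
        return float(self.probabilities[self.states.index(state)])

    def as_dict(self) -> dict[str, float]:
        return {s: float(p) for s, p in zip(self.states, self.probabilities)}

    def __repr__(self) -> str:  # pragma: no cover
        inner = ", ".join(f"{s}={p:.4g}" for s, p in self.as_dict().items())
        return f"PosteriorDistribution({self.node}: {inner})"


def posterior(
    spec: NetworkSpec,
    target: str,
    evidence: EvidenceMap | None = None,
    order: list[str] | None = None,
) -> PosteriorDistribution:
    """Exact P(target | evidence) by variable elimination.

    Conditioning a node on its own evidenced state yields a point mass (after
    confirming the evidence is possible). Zero-probability evidence raises
    :class:`ImpossibleEvidenceError` rather than returning NaN.
    """
    evidence = dict(evidence or {})
    check_evidence(spec, evidence)
    node = spec.node(target)

    if target in evidence:
        rest = {k: v for k, v in evidence.items() if k != target}
        sub = posterior(spec, target, rest, order=None)
        idx = node.state_index(evidence[target])
        if sub.probabilities[idx] == 0.0:
            raise ImpossibleEvidenceError(
                f"evidence {evidence} has zero probability under the model"
            )
        probs = np.zeros(node.n_states)
        probs[idx] = 1.0
        return PosteriorDistribution(target, node.states, probs)

    relevant = _relevant_nodes(spec, target, evidence)
    factors: list[Factor] = []
    for name in relevant:
        f = _cpt_factor(spec, name)
        for ev_name, ev_state in evidence.items():
            if ev_name in f.scope:
                f = f.reduce(ev_name, spec.node(ev_name).state_index(ev_state))
        factors.append(f)

    if order is None:
        order = elimination_order(spec, target, evidence)

    for var in order:
        with_var = [f for f in factors if var in f.scope]
        if not with_var:
            continue
        product = with_var[0]
        for f in with_var[1:]:
            product = product.multiply(f)
        factors = [f for f in factors if var not in f.scope]
        factors.append(product.sum_out(var))

    result = Factor([], np.array(1.0))
    for f in factors:
        result = result.multiply(f)
    # everything except the target has been eliminated or reduced
    for var in list(result.scope):
        if var != target:  # pragma: no cover - defensive; order covers all vars
            result = result.sum_out(var)

    if not result.scope:
        raise RuntimeError("target vanished from all factors")  # pragma: no cover
    table = result.table
    z = float(table.sum())
    if z == 0.0:
        raise ImpossibleEvidenceError(
            f"evidence {evidence} has zero probability under the model"
        )
    return PosteriorDistribution(target, node.states, table / z)


def enumerate_joint_oracle(
    spec: NetworkSpec, target: str, evidence: EvidenceMap | None = None
) -> PosteriorDistribution:
    """Posterior by explicit summation over all complete assignments.

    Independent of the variable-elimination path; guarded to state spaces of
    at most ``ORACLE_STATE_SPACE_GUARD`` free combinations.
    """
    evidence = dict(evidence or {})
    check_evidence(spec, evidence)
    names = list(spec.nodes)
    node = spec.node(target)

    free = [n for n in names if n not in evidence]
    size = math.prod(spec.card(n) for n in free) if free else 1
    if size > ORACLE_STATE_SPACE_GUARD:
        raise ValueError(
            f"state space of {size} free combinations exceeds the oracle guard "
            f"of {ORACLE_STATE_SPACE_GUARD}"
        )

    choices = [
        [evidence[n]] if n in evidence else list(spec.node(n).states) for n in names
    ]
    accum = np.zeros(node.n_states)
    from .core import joint_probability  # local import avoids cycle at module load

    for combo in itertools.product(*choices):
        assignment = dict(zip(names, combo))
        p = joint_probability(spec, assignment)
        accum[node.state_index(assignment[target])] += p

    z = float(accum.sum())
    if z == 0.0:
        raise ImpossibleEvidenceError(
            f"evidence {evidence} has zero probability under the model"
        )
    if target in evidence:
        probs = np.zeros(node.n_states)
        probs[node.state_index(evidence[target])] = 1.0
        return PosteriorDistribution(target, node.states, probs)
    return PosteriorDistribution(target, node.states, accum / z)
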
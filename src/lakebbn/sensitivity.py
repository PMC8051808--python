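"""Sensitivity analysis: entropy/mutual-information "sensitivity to findings"
and CPT-perturbation "sensitivity to parameters".

Sensitivity to findings ranks candidate driver nodes Y by the mutual
information they carry about a target X,

    MI(X; Y) = H(X) - H(X | Y) = H(X) - sum_y P(y) H(X | Y=y),

with all distributions taken from exact inference under an explicit (default
empty) evidence context. Entropies use the base-2 logarithm, so MI is in
bits, matching the convention of common BBN tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy as _scipy_entropy

from .core import CPT, EvidenceMap, NetworkSpec
from .inference import ImpossibleEvidenceError, posterior


def entropy(dist) -> float:
    """Shannon entropy in bits; 0*log(0) is taken as 0."""
    p = np.asarray(dist, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    return float(_scipy_entropy(p, base=2))


def mutual_information(
    spec: NetworkSpec, target: str, query: str, evidence: EvidenceMap | None = None
) -> float:
    """MI(target; query | evidence) in bits, from exact posteriors.

    Terms with P(query=y | evidence) = 0 contribute nothing and are skipped.
    Tiny negative values from floating-point cancellation are clamped to 0.
    """
    evidence = dict(evidence or {})
    if target == query:
        raise ValueError("target and query must differ")
    if target in evidence or query in evidence:
        raise ValueError("target and query must not be evidenced")

    marginal = posterior(spec, target, evidence)
    h_target = entropy(marginal.probabilities)
    query_dist = posterior(spec, query, evidence)

    h_conditional = 0.0
    for state, p_y in zip(query_dist.states, query_dist.probabilities):
        if p_y <= 0.0:
            continue
        cond = posterior(spec, target, {**evidence, query: state})
        h_conditional += float(p_y) * entropy(cond.probabilities)

    return max(0.0, h_target - h_conditional)


@dataclass
class SensitivityReport:
    """Per-node MI about a target, ranked descending (ties lexicographic).

    ``drivers`` marks the queried nodes that are ancestors of the target;
    ``driver_ranking`` restricts the ranking to them. Diagnosing which
    *upstream* factor most influences a node is the usual reading of a
    sensitivity-to-findings chart, since a tightly coupled descendant is
    always highly informative without being a controllable cause.
    """

    target: str
    mi: dict[str, float]
    drivers: frozenset[str] = frozenset()

    @property
    def ranking(self) -> list[str]:
        return sorted(self.mi, key=lambda n: (-self.mi[n], n))

    @property
    def driver_ranking(self) -> list[str]:
        return [n for n in self.ranking if n in self.drivers]

    def top(self, k: int) -> list[str]:
        return self.ranking[:k]

    def top_drivers(self, k: int) -> list[str]:
        return self.driver_ranking[:k]

    def as_rows(self) -> list[tuple[str, float]]:
        return [(n, self.mi[n]) for n in self.ranking]


def sensitivity_to_findings(
    spec: NetworkSpec, target: str, evidence: EvidenceMap | None = None
) -> SensitivityReport:
    """MI of every non-evidence, non-target node on the target.

    Deterministic: identical inputs produce identical reports.
    """
    import networkx as nx

    evidence = dict(evidence or {})
    mi = {}
    for node in spec:
        if node.name == target or node.name in evidence:
            continue
        mi[node.name] = mutual_information(spec, target, node.name, evidence)
    ancestors = nx.ancestors(spec.graph(), target)
    return SensitivityReport(
        target=target, mi=mi, drivers=frozenset(ancestors & set(mi))
    )


def cpt_perturbation_sensitivity(
    spec: NetworkSpec,
    node: str,
    target: str,
    delta: float,
    target_state: str | None = None,
) -> float:
    """Max absolute change in P(target = adverse state) under row perturbations.

    For each CPT row of ``node`` and each extreme child state in turn, a
    fraction ``delta`` of extra mass is added on that state and the row is
    renormalized: row' = (row + delta * e_i) / (1 + delta). The target
    posterior (empty evidence) is recomputed and the largest absolute change
    of the monitored state's probability is returned. The symmetric scheme
    makes results comparable across nodes.
    """
    if not (0.0 < delta < 1.0):
        raise ValueError("delta must be in (0, 1)")
    perturbed_node = spec.node(node)
    tstates = spec.node(target).states
    state = target_state if target_state is not None else tstates[0]
    col = spec.node(target).state_index(state)

    baseline = posterior(spec, target).probabilities[col]
    original = perturbed_node.cpt
    if original is None:
        raise ValueError(f"node {node!r} has no CPT")

    worst = 0.0
    extremes = (0, perturbed_node.n_states - 1)
    try:
        for row_idx in range(original.n_rows):
            for extreme in extremes:
                vals = original.values.copy()
                vals[row_idx, extreme] += delta
                vals[row_idx] /= 1.0 + delta
                perturbed_node.cpt = CPT(vals)
                try:
                    shifted = posterior(spec, target).probabilities[col]
                except ImpossibleEvidenceError:  # pragma: no cover - empty evidence
                    continue
                worst = max(worst, abs(float(shifted - baseline)))
    finally:
        perturbed_node.cpt = original
    return worst
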
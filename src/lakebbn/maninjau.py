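"""The Lake Maninjau mass-fish-kill network.

Thirty-five categorical nodes link weather physics (season, wind, rainfall,
lake stability) through stratification chemistry (oxygen, BOD, phosphate,
sulphide) and cage-farm management (cage count, stocking, feeding) to two
impact outputs: mass fish kills (MFK) of the caged tilapia and the
disappearance of the native *Gobiopterus* sp. The MFK mechanism is
wind-driven upwelling of anoxic, H2S-rich deep water into the epilimnion.

The structure and states live in ``data/maninjau_network.yaml``; CPTs are
generated from the expert-rule parameters in ``data/maninjau_cpt_params.yaml``
(see that file's header for the rule: additive parent risk scores pushed
through an exponential-weight normalizer with one sharpness scalar per node).
Both files are plain YAML, so alternative expert tables can be dropped in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .core import CPT, NetworkSpec, NodeSpec, validate_network
from .sensitivity import mutual_information

logger = logging.getLogger(__name__)

MFK = "Mass fish kills"
GOBIOPTERUS = "Gobiopterus disappearance"

_DATA = resources.files("lakebbn") / "data"


def _load_packaged(name: str) -> dict:
    with (_DATA / name).open() as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# discretization of raw observations


@dataclass(frozen=True)
class Discretizer:
    """Maps a numeric observation to a state label.

    ``kind="bins"`` uses half-open bins [low, high) over ascending ``edges``
    (the top bin is closed only by +inf). ``kind="compass"`` maps a bearing
    in degrees onto 45-degree sectors centred on N/NE/E/SE, the remaining
    half circle being "Other directions".
    """

    node: str
    states: tuple[str, ...]
    severity: tuple[str, ...]
    edges: tuple[float, ...] = ()
    units: str = ""
    kind: str = "bins"

    def __call__(self, value: float) -> str:
        if value < 0:
            raise ValueError(f"{self.node}: negative value {value!r}")
        if self.kind == "compass":
            return self._compass(value)
        idx = int(np.searchsorted(self.edges, value, side="right")) - 1
        idx = min(max(idx, 0), len(self.states) - 1)
        return self.states[idx]

    def _compass(self, degrees: float) -> str:
        bearing = float(degrees) % 360.0
        sectors = {"North": 0.0, "North East": 45.0, "East": 90.0, "South East": 135.0}
        for state, centre in sectors.items():
            delta = (bearing - centre + 180.0) % 360.0 - 180.0
            if -22.5 <= delta < 22.5:
                return state
        return "Other directions"

    def severity_rank(self, state: str) -> int:
        return self.severity.index(state)


def load_discretizers(path=None) -> dict[str, Discretizer]:
    if path is None:
        payload = _load_packaged("discretizers.yaml")
    else:
        with open(path) as fh:
            payload = yaml.safe_load(fh)
    out = {}
    for node, block in payload["discretizers"].items():
        out[node] = Discretizer(
            node=node,
            states=tuple(block["states"]),
            severity=tuple(block.get("severity", block["states"])),
            edges=tuple(block.get("edges", ())),
            units=block.get("units", ""),
            kind=block.get("kind", "bins"),
        )
    return out


def discretize_observation(
    record: Mapping,
    discretizers: dict[str, Discretizer] | None = None,
    wet_months: Sequence[int] = (10, 11, 12, 1, 2, 3),
) -> dict[str, str]:
    """Map one raw daily record to a case row of state labels.

    Recognised numeric fields: ``wind_speed_kmh``, ``wind_direction_deg``,
    ``rainfall_mm``; categorical passthroughs: ``cloud`` (truthy -> Yes),
    ``radiation`` (Low/Medium/High -> Light intensity); ``date`` (anything
    with a ``month``) sets Season from the wet-month calendar. Missing fields
    simply yield no entry (missing states are allowed in case tables).
    """
    disc = discretizers if discretizers is not None else load_discretizers()
    row: dict[str, str] = {}
    if record.get("wind_speed_kmh") is not None:
        row["Windspeed"] = disc["Windspeed"](float(record["wind_speed_kmh"]))
    if record.get("wind_direction_deg") is not None:
        row["Wind Direction"] = disc["Wind Direction"](float(record["wind_direction_deg"]))
    if record.get("rainfall_mm") is not None:
        row["Rainfall intensity"] = disc["Rainfall intensity"](float(record["rainfall_mm"]))
    if record.get("cloud") is not None:
        row["Cloudy"] = "Yes" if record["cloud"] else "No"
    if record.get("radiation") is not None:
        row["Light intensity"] = str(record["radiation"])
    date = record.get("date")
    if date is not None and hasattr(date, "month"):
        row["Season"] = "Wet" if date.month in set(wet_months) else "Dry"
    return row


def summarize_high_frequency(
    records: Iterable[Mapping],
    discretizers: dict[str, Discretizer] | None = None,
) -> list[dict]:
    """Collapse an intra-day measurement stream to one record per calendar day.

    Wind speed and direction become the modal *discretized* class of the day
    (ties break toward the more severe class); rainfall becomes the daily
    maximum. Days without records are simply absent; empty groups are logged.
    """
    disc = discretizers if discretizers is not None else load_discretizers()
    by_day: dict = {}
    for rec in records:
        ts = rec["timestamp"]
        day = ts.date() if hasattr(ts, "date") else ts
        by_day.setdefault(day, []).append(rec)

    daily = []
    for day in sorted(by_day):
        group = by_day[day]
        if not group:  # pragma: no cover - defensive
            logger.warning("no records for %s; day omitted", day)
            continue
        entry: dict = {"date": day}
        for field_name, node in (
            ("wind_speed_kmh", "Windspeed"),
            ("wind_direction_deg", "Wind Direction"),
        ):
            values = [r[field_name] for r in group if r.get(field_name) is not None]
            if not values:
                continue
            counts: dict[str, int] = {}
            for v in values:
                counts[disc[node](float(v))] = counts.get(disc[node](float(v)), 0) + 1
            best = max(counts, key=lambda s: (counts[s], disc[node].severity_rank(s)))
            entry[node] = best
        rain = [r["rainfall_mm"] for r in group if r.get("rainfall_mm") is not None]
        if rain:
            entry["rainfall_mm"] = float(max(rain))
            entry["Rainfall intensity"] = disc["Rainfall intensity"](entry["rainfall_mm"])
        daily.append(entry)
    return daily


# ---------------------------------------------------------------------------
# expert-rule CPT generation


@dataclass
class ExpertRule:
    """Parameters generating one node's CPT from ordinal risk scores.

    ``adversity`` scores each child state's contribution toward the MFK
    outcome in [0, 1]. Each parent edge has a weight (and optional inversion
    for edges where the parent's adverse state is protective for this child);
    the parent's own state adversities act as the risk scores. The optional
    anchor blends in a baseline risk. ``structural_zeros`` force whole rows
    to a point mass exactly.
    """

    node: str
    adversity: tuple[float, ...]
    weights: dict[str, float] = field(default_factory=dict)
    invert: frozenset[str] = frozenset()
    anchor_value: float = 0.5
    anchor_weight: float = 0.0
    sharpness: float = 1.0
    prior: tuple[float, ...] | None = None
    structural_zeros: tuple[tuple[tuple[tuple[str, str], ...], str], ...] = ()


def _parse_rules(payload: dict) -> dict[str, ExpertRule]:
    rules = {}
    for node, block in payload["nodes"].items():
        weights: dict[str, float] = {}
        invert = set()
        for parent, w in (block.get("weights") or {}).items():
            if isinstance(w, Mapping):
                weights[parent] = float(w["weight"])
                if w.get("invert"):
                    invert.add(parent)
            else:
                weights[parent] = float(w)
        anchor = block.get("anchor") or {}
        zeros = []
        for z in block.get("structural_zeros") or ():
            when = tuple(sorted((str(k), str(v)) for k, v in z["when"].items()))
            zeros.append((when, str(z["state"])))
        rules[node] = ExpertRule(
            node=node,
            adversity=tuple(float(a) for a in block["adversity"]),
            weights=weights,
            invert=frozenset(invert),
            anchor_value=float(anchor.get("value", 0.5)),
            anchor_weight=float(anchor.get("weight", 0.0)),
            sharpness=float(block.get("sharpness", 1.0)),
            prior=tuple(float(p) for p in block["prior"]) if "prior" in block else None,
            structural_zeros=tuple(zeros),
        )
    return rules


def generate_expert_cpt(
    rule: ExpertRule, node: NodeSpec, parent_rules: Mapping[str, ExpertRule]
) -> CPT:
    """Build the CPT of ``node`` from its expert rule.

    Each row is exp(-sharpness * (a_i - r)^2) normalized over child states i,
    with r the anchored weighted mean of parent-state risk scores. Structural
    zeros override matching rows with an exact point mass; conflicting zero
    constraints for the same row are a configuration error.
    """
    k = node.n_states
    if len(rule.adversity) != k:
        raise ValueError(
            f"{node.name}: adversity has {len(rule.adversity)} entries for {k} states"
        )
    if not node.parents:
        if rule.prior is None:
            raise ValueError(f"root node {node.name} needs a prior")
        prior = np.asarray(rule.prior, dtype=float)
        return CPT(prior[None, :] / prior.sum())

    missing = [p for p in node.parents if p not in rule.weights]
    if missing:
        raise ValueError(f"{node.name}: no weight for parents {missing}")
    unknown = [p for p in rule.weights if p not in node.parents]
    if unknown:
        raise ValueError(f"{node.name}: weights name non-parents {unknown}")

    child_adv = np.asarray(rule.adversity, dtype=float)
    total_weight = rule.anchor_weight + sum(rule.weights.values())
    if total_weight <= 0:
        raise ValueError(f"{node.name}: total rule weight must be positive")

    import itertools as _it

    parent_states = []
    for p in node.parents:
        prule = parent_rules.get(p)
        if prule is None:
            raise ValueError(f"{node.name}: parent {p!r} has no rule (adversity unknown)")
        parent_states.append(list(enumerate(prule.adversity)))

    rows = []
    zero_rows: dict[int, str] = {}
    combos = list(_it.product(*parent_states))
    # resolve structural zeros to row indices
    for when, forced_state in rule.structural_zeros:
        cond = dict(when)
        bad = [p for p in cond if p not in node.parents]
        if bad:
            raise ValueError(f"{node.name}: structural zero names non-parents {bad}")
        for row_idx, combo in enumerate(combos):
            match = True
            for p, s in cond.items():
                pos = node.parents.index(p)
                pnode_states = _parent_state_labels(parent_rules, p)
                if pnode_states[combo[pos][0]] != s:
                    match = False
                    break
            if match:
                if row_idx in zero_rows and zero_rows[row_idx] != forced_state:
                    raise ValueError(
                        f"{node.name}: conflicting structural zeros for row {row_idx} "
                        f"({zero_rows[row_idx]!r} vs {forced_state!r})"
                    )
                zero_rows[row_idx] = forced_state

    for row_idx, combo in enumerate(combos):
        if row_idx in zero_rows:
            row = np.zeros(k)
            row[node.state_index(zero_rows[row_idx])] = 1.0
            rows.append(row)
            continue
        risk = rule.anchor_weight * rule.anchor_value
        for (state_idx, adv), p in zip(combo, node.parents):
            score = 1.0 - adv if p in rule.invert else adv
            risk += rule.weights[p] * score
        r = risk / total_weight
        logits = -rule.sharpness * (child_adv - r) ** 2
        row = np.exp(logits - logits.max())
        rows.append(row / row.sum())
    return CPT(np.vstack(rows))


def _parent_state_labels(parent_rules, name) -> tuple[str, ...]:
    # The rules file does not carry state labels; they come from the structure
    # file via build_network, which stores them on the rule for lookups.
    labels = getattr(parent_rules[name], "_state_labels", None)
    if labels is None:
        raise ValueError(f"state labels for {name!r} not attached; use build_network")
    return labels


# ---------------------------------------------------------------------------
# network assembly


def build_network(
    structure: dict | None = None, params: dict | None = None
) -> NetworkSpec:
    """Assemble a network from a structure payload and expert-rule payload."""
    structure = structure if structure is not None else _load_packaged("maninjau_network.yaml")
    params = params if params is not None else _load_packaged("maninjau_cpt_params.yaml")
    rules = _parse_rules(params)

    nodes = []
    for block in structure["nodes"]:
        nodes.append(
            NodeSpec(
                name=block["name"],
                states=tuple(str(s) for s in block["states"]),
                parents=tuple(block.get("parents", ())),
                provenance=block.get("provenance", "expert"),
                discretization=block.get("discretization"),
            )
        )
    spec = NetworkSpec(nodes)

    for node in spec:
        if node.name not in rules:
            raise ValueError(f"no CPT parameters for node {node.name!r}")
        rules[node.name]._state_labels = node.states  # type: ignore[attr-defined]

    for node in spec:
        node.cpt = generate_expert_cpt(rules[node.name], node, rules)

    problems = validate_network(spec)
    if problems:  # pragma: no cover - config regression guard
        raise ValueError("generated network is invalid: " + "; ".join(problems))
    return spec


def build_default_network() -> NetworkSpec:
    """The shipped 35-node Lake Maninjau network with default expert CPTs."""
    return build_network()


def load_cpt_params() -> dict:
    return _load_packaged("maninjau_cpt_params.yaml")


def load_structure() -> dict:
    return _load_packaged("maninjau_network.yaml")


# ---------------------------------------------------------------------------
# sharpness calibration


class InfeasibleCalibrationError(ValueError):
    """No grid value satisfies the requested mutual-information orderings."""


def calibrate_sharpness(
    node: str,
    target: str,
    orderings: Sequence[tuple[str, str]],
    grid: Sequence[float] = (0.5, 1, 2, 3, 4, 5, 6, 8, 10, 12),
    structure: dict | None = None,
    params: dict | None = None,
) -> float:
    """Smallest sharpness for ``node`` satisfying MI ranking constraints.

    Each ordering ``(better, worse)`` requires MI(target; better) >
    MI(target; worse) on the rebuilt network. If the current configured
    sharpness already satisfies every constraint it is returned unchanged;
    otherwise the grid is scanned in ascending order. Infeasibility raises
    with the violated orderings listed per attempted value.
    """
    params = dict(params if params is not None else load_cpt_params())
    current = float(params["nodes"][node].get("sharpness", 1.0))

    def violated(sharpness: float) -> list[tuple[str, str]]:
        trial = {
            "format": params.get("format"),
            "nodes": {
                name: ({**block, "sharpness": sharpness} if name == node else block)
                for name, block in params["nodes"].items()
            },
        }
        spec = build_network(structure, trial)
        bad = []
        for better, worse in orderings:
            if not mutual_information(spec, target, better) > mutual_information(
                spec, target, worse
            ):
                bad.append((better, worse))
        return bad

    for a, b in orderings:
        if (b, a) in orderings:
            raise InfeasibleCalibrationError(
                f"contradictory orderings: {(a, b)} and {(b, a)}"
            )

    if not violated(current):
        return current
    report = {}
    for s in sorted(grid):
        bad = violated(s)
        if not bad:
            return float(s)
        report[s] = bad
    lines = [f"  sharpness={s}: violated {bad}" for s, bad in report.items()]
    raise InfeasibleCalibrationError(
        f"no sharpness in grid satisfies orderings for {node!r}:\n" + "\n".join(lines)
    )
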
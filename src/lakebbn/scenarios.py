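"""Management-scenario engine.

A scenario is a named evidence map: lake-condition settings (H2S, internal
phosphate release, anoxic-layer width) plus a management intervention (cage
count, feeding practice, aeration represented as forcing epilimnion DO
high). Each scenario is appraised under two weather envelopes — a benign
dry-season envelope and an adverse wet-season envelope — by enumerating
every admissible weather combination and reporting the min/max posterior
probability of the adverse state of each output node. The min/max range is
coded to a YES / NO / NO-YES verdict against the validation module's optimum
cut-off.

The long-term horizon is represented purely by evidence flips (phosphate
release and anoxic layer relaxing to their benign states), not by
time-stepping: the network is static.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core import NetworkSpec
from .inference import ImpossibleEvidenceError, posterior
from .maninjau import GOBIOPTERUS, MFK

logger = logging.getLogger(__name__)

OUTPUT_NODES = {MFK: "Yes", GOBIOPTERUS: "Yes"}


@dataclass(frozen=True)
class WeatherEnvelope:
    """Admissible weather states over which a scenario's posterior ranges."""

    name: str
    season: tuple[str, ...]
    windspeed: tuple[str, ...]
    rainfall: tuple[str, ...]

    def combinations(self):
        for s in self.season:
            for w in self.windspeed:
                for r in self.rainfall:
                    yield {"Season": s, "Windspeed": w, "Rainfall intensity": r}


GOOD_WEATHER = WeatherEnvelope(
    name="good",
    season=("Dry",),
    windspeed=("Calm",),
    rainfall=("No rain", "Light rain", "Moderate rain"),
)
BAD_WEATHER = WeatherEnvelope(
    name="bad",
    season=("Wet",),
    windspeed=("Strong", "Gale-Storm"),
    rainfall=("Moderate rain", "Heavy rain"),
)
DEFAULT_ENVELOPES = (GOOD_WEATHER, BAD_WEATHER)


@dataclass(frozen=True)
class ScenarioDef:
    id: str
    description: str
    lake_condition: dict = field(default_factory=dict)
    intervention: dict = field(default_factory=dict)
    horizon: str = "short_term"

    @property
    def evidence(self) -> dict:
        return {**self.lake_condition, **self.intervention}


#: Current-condition evidence for the short-term scenario family: the lake is
#: sulphide-rich with high internal phosphorus loading.
CURRENT_CONDITION = {"H2S": "High", "PO4 Released from hypolimnion": "High"}


def scenario_catalogue() -> list[ScenarioDef]:
    """The ten appraised management scenarios (1a-1f short-term, 2a-2d long-term)."""
    return [
        ScenarioDef(
            "1a", "Business as usual",
            lake_condition=dict(CURRENT_CONDITION),
            intervention={"Number of active cages": "High"},
        ),
        ScenarioDef(
            "1b", "Without cage farms",
            lake_condition=dict(CURRENT_CONDITION),
            intervention={"Number of active cages": "Zero"},
        ),
        ScenarioDef(
            "1c", "Cage farms capped at 6,000 units",
            lake_condition=dict(CURRENT_CONDITION),
            intervention={"Number of active cages": "Medium"},
        ),
        ScenarioDef(
            "1d", "Cage farms with reduction of internal P loading",
            lake_condition={"H2S": "High", "PO4 Released from hypolimnion": "Low"},
            intervention={"Number of active cages": "High"},
        ),
        ScenarioDef(
            "1e", "Cage farms with epilimnion aeration",
            lake_condition=dict(CURRENT_CONDITION),
            intervention={"Number of active cages": "High", "DO epilimnion": "High"},
        ),
        ScenarioDef(
            "1f", "Cage farms with internal-P reduction and aeration",
            lake_condition={"H2S": "High", "PO4 Released from hypolimnion": "Low"},
            intervention={"Number of active cages": "High", "DO epilimnion": "High"},
        ),
        ScenarioDef(
            "2a", "Business as usual",
            lake_condition=dict(CURRENT_CONDITION),
            intervention={"Number of active cages": "High"},
            horizon="long_term",
        ),
        ScenarioDef(
            "2b", "Without cage farms, lake recovered",
            lake_condition={
                "PO4 Released from hypolimnion": "Low",
                "Anoxic layer": "Narrow",
            },
            intervention={"Number of active cages": "Zero"},
            horizon="long_term",
        ),
        ScenarioDef(
            "2c", "6,000 cage units, no internal-P action",
            lake_condition=dict(CURRENT_CONDITION),
            intervention={"Number of active cages": "Medium"},
            horizon="long_term",
        ),
        ScenarioDef(
            "2d", "6,000 cage units, better feeding and internal-P control",
            lake_condition={
                "PO4 Released from hypolimnion": "Low",
                "Anoxic layer": "Narrow",
            },
            intervention={
                "Number of active cages": "Medium",
                "Feeding management": "Twice-Emerge",
            },
            horizon="long_term",
        ),
    ]


def coded_verdict(lo: float, hi: float, cutoff: float) -> str:
    """NO if the whole range is below the cut-off, YES if at or above, else NO/YES."""
    if hi < cutoff:
        return "NO"
    if lo >= cutoff:
        return "YES"
    return "NO/YES"


@dataclass
class ScenarioResult:
    scenario: ScenarioDef
    cutoff: float
    #: {output node: {envelope name: (min, max)}}
    ranges: dict[str, dict[str, tuple[float, float]]]

    def verdict(self, output: str, envelope: str) -> str:
        lo, hi = self.ranges[output][envelope]
        return coded_verdict(lo, hi, self.cutoff)


def run_scenario(
    spec: NetworkSpec,
    scenario: ScenarioDef,
    envelopes=DEFAULT_ENVELOPES,
    cutoff: float = 0.26,
) -> ScenarioResult:
    """Posterior min/max of both outputs across each envelope's weather states.

    Impossible weather combinations (zero probability under the scenario
    evidence) are skipped with a log entry; if an envelope has none left the
    scenario fails.
    """
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError("cutoff must lie in [0, 1]")
    ranges: dict[str, dict[str, tuple[float, float]]] = {
        out: {} for out in OUTPUT_NODES
    }
    for envelope in envelopes:
        per_output: dict[str, list[float]] = {out: [] for out in OUTPUT_NODES}
        for weather in envelope.combinations():
            evidence = {**scenario.evidence, **weather}
            try:
                for out, adverse in OUTPUT_NODES.items():
                    per_output[out].append(posterior(spec, out, evidence)[adverse])
            except ImpossibleEvidenceError:
                logger.info(
                    "scenario %s: weather %s impossible under evidence; skipped",
                    scenario.id, weather,
                )
                continue
        if not any(per_output.values()):
            raise ImpossibleEvidenceError(
                f"scenario {scenario.id}: every weather combination in envelope "
                f"{envelope.name!r} is impossible"
            )
        for out, values in per_output.items():
            ranges[out][envelope.name] = (min(values), max(values))
    return ScenarioResult(scenario=scenario, cutoff=cutoff, ranges=ranges)


def run_catalogue(
    spec: NetworkSpec, envelopes=DEFAULT_ENVELOPES, cutoff: float = 0.26
) -> list[ScenarioResult]:
    return [run_scenario(spec, s, envelopes, cutoff) for s in scenario_catalogue()]


def compare_scenarios(
    results: list[ScenarioResult], baseline_id: str, envelope: str = "bad"
) -> dict[str, list[tuple[str, float]]]:
    """Reduction of the adverse-envelope max probability relative to a baseline.

    Returns, per output node, (scenario id, reduction) pairs ranked by
    decreasing reduction.
    """
    if not results:
        raise ValueError("empty result list")
    by_id = {r.scenario.id: r for r in results}
    if baseline_id not in by_id:
        raise ValueError(f"unknown baseline scenario {baseline_id!r}")
    baseline = by_id[baseline_id]
    report: dict[str, list[tuple[str, float]]] = {}
    for out in OUTPUT_NODES:
        base_hi = baseline.ranges[out][envelope][1]
        deltas = [
            (r.scenario.id, base_hi - r.ranges[out][envelope][1]) for r in results
        ]
        report[out] = sorted(deltas, key=lambda t: (-t[1], t[0]))
    return report
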
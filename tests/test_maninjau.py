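import datetime as dt

import numpy as np
import pytest

from lakebbn.core import NodeSpec, validate_network
from lakebbn.inference import posterior
from lakebbn.maninjau import (
    GOBIOPTERUS,
    MFK,
    ExpertRule,
    InfeasibleCalibrationError,
    calibrate_sharpness,
    discretize_observation,
    generate_expert_cpt,
    load_discretizers,
    summarize_high_frequency,
)

#: Expected state catalogue of the shipped lake network.
EXPECTED_STATES = {
    "Season": ("Dry", "Wet"),
    "Rainfall intensity": ("No rain", "Light rain", "Moderate rain", "Heavy rain"),
    "Cloudy": ("Yes", "No"),
    "Light intensity": ("Low", "Medium", "High"),
    "Windspeed": ("Calm", "Moderate", "Strong", "Gale-Storm"),
    "Wind Direction": ("North", "North East", "East", "South East", "Other directions"),
    "Water current velocity": ("Fast", "Medium", "Slow"),
    "SSI": ("High", "Medium", "Low"),
    "Mixing": ("Yes", "No"),
    "Water transparency": ("Low", "High"),
    "Anoxic layer": ("Wide", "Narrow"),
    "Epilimnion zone after mixing": ("Not sufficient DO", "Sufficient DO"),
    "Anoxic hypolimnion": ("Yes", "No"),
    "BOD epilimnion": ("High", "Low"),
    "BOD metalimnion": ("High", "Low"),
    "PO4 Concentration Epilimnion": ("High", "Low"),
    "PO4 Released from hypolimnion": ("High", "Low"),
    "Reactive Fe Concentration": ("Low", "High"),
    "Chlo-a epilimnion": ("High", "Low"),
    "Chlo-a metalimnion": ("High", "Low"),
    "H2S": ("High", "Low"),
    "Respiration rate epilimnion": ("High", "Low"),
    "Respiration rate metalimnion": ("High", "Low"),
    "GPP epilimnion": ("High", "Low"),
    "GPP metalimnion": ("High", "Low"),
    "DO epilimnion": ("High", "Low"),
    "DO metalimnion": ("High", "Low"),
    "Stocking density": ("Low", "Medium", "High"),
    "Number of active cages": ("Zero", "Low", "Medium", "High"),
    "Feeding management": (
        "None", "Once-Floating", "Twice-Floating", "Once-Emerge", "Twice-Emerge"
    ),
    "Organic sediment run off": ("Low", "Medium", "High"),
    "Feed": ("High", "Medium", "Low"),
    "Accumulated fish feed": ("High", "Low"),
    "Mass fish kills": ("Yes", "No"),
    "Gobiopterus disappearance": ("Yes", "No"),
}


class TestDefaultNetwork:
    def test_thirty_five_nodes_and_valid(self, lake_network):
        assert len(lake_network) == 35
        assert validate_network(lake_network) == []

    def test_state_catalogue(self, lake_network):
        actual = {n.name: n.states for n in lake_network}
        assert actual == EXPECTED_STATES

    def test_light_intensity_feeds_oxygen_not_algae(self, lake_network):
        # the photosynthesis edge, rerouted to break the algae-light loop
        assert "Light intensity" in lake_network.node("DO epilimnion").parents
        assert "Light intensity" not in lake_network.node("Chlo-a epilimnion").parents

    def test_outputs_have_expected_parents(self, lake_network):
        assert lake_network.node(MFK).parents == (
            "Epilimnion zone after mixing", "H2S", "Number of active cages",
        )
        assert lake_network.node(GOBIOPTERUS).parents == (
            "Epilimnion zone after mixing", "H2S",
        )

    def test_no_mass_fish_kill_without_cages(self, lake_network):
        """Structural zero: an empty lake cannot lose caged fish."""
        for extra in ({}, {"Windspeed": "Gale-Storm", "H2S": "High"}):
            dist = posterior(
                lake_network, MFK, {"Number of active cages": "Zero", **extra}
            )
            assert dist["Yes"] == 0.0


class TestDiscretization:
    def test_wind_speed_classes(self):
        disc = load_discretizers()["Windspeed"]
        assert disc(25.0) == "Moderate"
        assert disc(19.5) == "Calm"  # half-open [0, 20)
        assert disc(20.0) == "Moderate"
        assert disc(55.0) == "Gale-Storm"

    def test_rainfall_classes(self):
        disc = load_discretizers()["Rainfall intensity"]
        assert disc(0.0) == "No rain"
        assert disc(12.0) == "Heavy rain"
        assert disc(10.0) == "Heavy rain"  # top bin closed below at 10

    def test_compass_sectors(self):
        disc = load_discretizers()["Wind Direction"]
        assert disc(0.0) == "North"
        assert disc(350.0) == "North"
        assert disc(45.0) == "North East"
        assert disc(135.0) == "South East"
        assert disc(200.0) == "Other directions"

    def test_full_record(self):
        row = discretize_observation(
            {
                "date": dt.date(2019, 12, 5),
                "wind_speed_kmh": 25.0,
                "wind_direction_deg": 90.0,
                "rainfall_mm": 0.0,
                "cloud": True,
            }
        )
        assert row == {
            "Windspeed": "Moderate",
            "Wind Direction": "East",
            "Rainfall intensity": "No rain",
            "Cloudy": "Yes",
            "Season": "Wet",
        }

    def test_missing_fields_are_simply_absent(self):
        row = discretize_observation({"wind_speed_kmh": 3.0})
        assert row == {"Windspeed": "Calm"}

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            discretize_observation({"wind_speed_kmh": -1.0})
        with pytest.raises(ValueError):
            discretize_observation({"rainfall_mm": -0.5})


class TestHighFrequencySummary:
    @staticmethod
    def records(day, speeds, rains=()):
        out = []
        for i, s in enumerate(speeds):
            out.append(
                {
                    "timestamp": dt.datetime(2019, 7, day, i // 6, (i % 6) * 10),
                    "wind_speed_kmh": s,
                    "wind_direction_deg": 10.0,
                    "rainfall_mm": rains[i] if i < len(rains) else 0.0,
                }
            )
        return out

    def test_clear_mode_wins(self):
        daily = summarize_high_frequency(
            self.records(1, [5.0] * 100 + [35.0] * 44)
        )
        assert daily[0]["Windspeed"] == "Calm"

    def test_tie_breaks_toward_more_severe_class(self):
        daily = summarize_high_frequency(self.records(2, [5.0] * 72 + [35.0] * 72))
        assert daily[0]["Windspeed"] == "Strong"

    def test_daily_rainfall_is_the_maximum(self):
        daily = summarize_high_frequency(
            self.records(3, [5.0, 5.0, 5.0], rains=[0.0, 3.0, 12.0])
        )
        assert daily[0]["rainfall_mm"] == 12.0
        assert daily[0]["Rainfall intensity"] == "Heavy rain"

    def test_one_row_per_day_sorted(self):
        stream = self.records(5, [5.0] * 6) + self.records(4, [35.0] * 6)
        daily = summarize_high_frequency(stream)
        assert [d["date"].day for d in daily] == [4, 5]


class TestExpertRules:
    @staticmethod
    def binary_child(parent_rule, sharpness, zeros=()):
        node = NodeSpec(name="Child", states=("Bad", "Good"), parents=("P",))
        rule = ExpertRule(
            node="Child",
            adversity=(1.0, 0.0),
            weights={"P": 1.0},
            sharpness=sharpness,
            structural_zeros=zeros,
        )
        return node, rule, {"P": parent_rule}

    @staticmethod
    def parent_rule(adversities=(0.0, 1.0), labels=("lo", "hi")):
        rule = ExpertRule(node="P", adversity=tuple(adversities))
        rule._state_labels = tuple(labels)
        return rule

    def test_zero_sharpness_gives_uniform_rows(self):
        node, rule, parents = self.binary_child(self.parent_rule(), sharpness=0.0)
        cpt = generate_expert_cpt(rule, node, parents)
        np.testing.assert_allclose(cpt.values, 0.5)

    def test_large_sharpness_orders_point_masses_with_risk(self):
        node, rule, parents = self.binary_child(self.parent_rule(), sharpness=500.0)
        cpt = generate_expert_cpt(rule, node, parents)
        # benign parent state -> Good (column 1); adverse -> Bad (column 0)
        assert cpt.values[0, 1] > 0.999
        assert cpt.values[1, 0] > 0.999

    def test_rows_always_normalized(self):
        node, rule, parents = self.binary_child(self.parent_rule(), sharpness=3.7)
        cpt = generate_expert_cpt(rule, node, parents)
        np.testing.assert_allclose(cpt.values.sum(axis=1), 1.0, atol=1e-12)

    def test_structural_zero_is_exact(self):
        zeros = (((("P", "lo"),), "Good"),)
        node, rule, parents = self.binary_child(
            self.parent_rule(), sharpness=2.0, zeros=zeros
        )
        cpt = generate_expert_cpt(rule, node, parents)
        assert cpt.values[0].tolist() == [0.0, 1.0]

    def test_conflicting_structural_zeros_rejected(self):
        zeros = (
            ((("P", "lo"),), "Good"),
            ((("P", "lo"),), "Bad"),
        )
        node, rule, parents = self.binary_child(
            self.parent_rule(), sharpness=2.0, zeros=zeros
        )
        with pytest.raises(ValueError, match="conflicting"):
            generate_expert_cpt(rule, node, parents)

    def test_missing_parent_weight_rejected(self):
        node = NodeSpec(name="Child", states=("Bad", "Good"), parents=("P",))
        rule = ExpertRule(node="Child", adversity=(1.0, 0.0), weights={})
        with pytest.raises(ValueError, match="no weight"):
            generate_expert_cpt(rule, node, {"P": self.parent_rule()})


class TestCalibrateSharpness:
    def test_satisfied_objective_returns_current_value(self):
        current = calibrate_sharpness(
            node="Mixing",
            target="Mixing",
            orderings=[("Windspeed", "Rainfall intensity")],
            grid=(2.0, 12.0),
        )
        assert current == 12.0  # the shipped default, already feasible

    def test_contradictory_orderings_reported_infeasible(self):
        with pytest.raises(InfeasibleCalibrationError, match="contradictory"):
            calibrate_sharpness(
                node="Mixing",
                target="Mixing",
                orderings=[("Windspeed", "SSI"), ("SSI", "Windspeed")],
                grid=(2.0,),
            )

    def test_unsatisfiable_objective_lists_violations(self):
        # rainfall can never out-inform the direct windspeed parent
        with pytest.raises(InfeasibleCalibrationError, match="Rainfall intensity"):
            calibrate_sharpness(
                node="Mixing",
                target="Mixing",
                orderings=[("Rainfall intensity", "Windspeed")],
                grid=(1.0, 6.0),
            )
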
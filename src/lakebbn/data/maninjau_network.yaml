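# Lake Maninjau mass-fish-kill network: structure and states.
#
# 35 categorical nodes covering weather physics, lake stratification
# chemistry, cage-farm management and the two impact outputs. CPTs are not
# stored here; they are generated from maninjau_cpt_params.yaml (expert
# rules) by lakebbn.maninjau.build_default_network. Edit this file (or drop
# in a replacement) to change structure or states.
#
# Numeric discretizations use half-open bins [low, high); the top bin is
# unbounded. Edges list has one more entry than states.
format: lakebbn-structure/1
nodes:
  # ---- physics / weather ----
  - name: Season
    states: [Dry, Wet]
    parents: []
    provenance: data
  - name: Rainfall intensity
    states: [No rain, Light rain, Moderate rain, Heavy rain]
    parents: [Season]
    provenance: data
    discretization: {units: mm/day, edges: [0, 1, 5, 10, .inf]}
  - name: Cloudy
    states: ["Yes", "No"]
    parents: [Season]
    provenance: data
  - name: Light intensity
    states: [Low, Medium, High]
    parents: [Cloudy]
    provenance: data
  - name: Windspeed
    states: [Calm, Moderate, Strong, Gale-Storm]
    parents: [Season]
    provenance: data
    discretization: {units: km/h, edges: [0, 20, 30, 50, .inf]}
  - name: Wind Direction
    states: [North, North East, East, South East, Other directions]
    parents: []
    provenance: data
    discretization: {units: degrees, kind: compass}
  - name: Water current velocity
    states: [Fast, Medium, Slow]
    parents: [Windspeed]
    provenance: data
  - name: SSI
    states: [High, Medium, Low]
    parents: [Light intensity, Rainfall intensity]
    provenance: expert
  - name: Mixing
    states: ["Yes", "No"]
    parents: [Windspeed, Wind Direction, Water current velocity, SSI]
    provenance: expert_calibrated
  - name: Water transparency
    states: [Low, High]
    parents: [Chlo-a epilimnion]
    provenance: data
    discretization: {units: m, edges: [0, 2, .inf]}
  - name: Anoxic layer
    states: [Wide, Narrow]
    parents: [DO epilimnion, DO metalimnion]
    provenance: expert
  - name: Epilimnion zone after mixing
    states: [Not sufficient DO, Sufficient DO]
    parents: [Mixing, Anoxic layer]
    provenance: expert
    discretization: {units: mg/l DO, edges: [0, 1.5, .inf]}
  # Hypolimnetic anoxia is driven by degradation of settling organic load.
  # A metalimnion-DO parent would close a feedback loop (anoxia -> phosphate
  # release -> metalimnion algae -> metalimnion DO), which a belief network
  # cannot represent, so the oxygen feedback is left out.
  - name: Anoxic hypolimnion
    states: ["Yes", "No"]
    parents: [BOD metalimnion]
    provenance: expert

  # ---- chemistry / biology ----
  - name: BOD epilimnion
    states: [High, Low]
    parents: [Accumulated fish feed, Organic sediment run off]
    provenance: expert
    discretization: {units: mg/l, edges: [0, 3, .inf], bin_states: [Low, High]}
  - name: BOD metalimnion
    states: [High, Low]
    parents: [Accumulated fish feed]
    provenance: expert
    discretization: {units: mg/l, edges: [0, 3, .inf], bin_states: [Low, High]}
  - name: PO4 Concentration Epilimnion
    states: [High, Low]
    parents: [Accumulated fish feed, Organic sediment run off, PO4 Released from hypolimnion]
    provenance: expert
    discretization: {units: mg/l, edges: [0, 0.2, .inf], bin_states: [Low, High]}
  - name: PO4 Released from hypolimnion
    states: [High, Low]
    parents: [Anoxic hypolimnion, Reactive Fe Concentration]
    provenance: expert
  - name: Reactive Fe Concentration
    states: [Low, High]
    parents: []
    provenance: expert
  - name: Chlo-a epilimnion
    states: [High, Low]
    parents: [PO4 Concentration Epilimnion]
    provenance: data
    discretization: {units: mg/l, edges: [0, 3, .inf], bin_states: [Low, High]}
  - name: Chlo-a metalimnion
    states: [High, Low]
    parents: [PO4 Released from hypolimnion]
    provenance: expert
    discretization: {units: mg/l, edges: [0, 3, .inf], bin_states: [Low, High]}
  - name: H2S
    states: [High, Low]
    parents: [Anoxic hypolimnion, Reactive Fe Concentration]
    provenance: data
    discretization: {units: mg/l, edges: [0, 0.002, .inf], bin_states: [Low, High]}
  - name: Respiration rate epilimnion
    states: [High, Low]
    parents: [Chlo-a epilimnion]
    provenance: expert_calibrated
  - name: Respiration rate metalimnion
    states: [High, Low]
    parents: [Chlo-a metalimnion]
    provenance: expert
  - name: GPP epilimnion
    states: [High, Low]
    parents: [Chlo-a epilimnion]
    provenance: expert_calibrated
  - name: GPP metalimnion
    states: [High, Low]
    parents: [Chlo-a metalimnion, Water transparency]
    provenance: expert_calibrated
  - name: DO epilimnion
    states: [High, Low]
    parents: [Light intensity, GPP epilimnion, Respiration rate epilimnion, BOD epilimnion]
    provenance: data
    discretization: {units: mg/l, edges: [0, 3.5, .inf], bin_states: [Low, High]}
  - name: DO metalimnion
    states: [High, Low]
    parents: [BOD metalimnion, GPP metalimnion, Respiration rate metalimnion]
    provenance: data
    discretization: {units: mg/l, edges: [0, 3.5, .inf], bin_states: [Low, High]}

  # ---- human dimension (input nodes) ----
  - name: Stocking density
    states: [Low, Medium, High]
    parents: []
    provenance: expert
    discretization: {units: seeds/m^2, edges: [0, 200, 500, 800]}
  - name: Number of active cages
    states: [Zero, Low, Medium, High]
    parents: []
    provenance: expert
    discretization: {units: units, edges: [0, 1, 2000, 6000, .inf]}
  - name: Feeding management
    states: [None, Once-Floating, Twice-Floating, Once-Emerge, Twice-Emerge]
    parents: []
    provenance: expert
  - name: Organic sediment run off
    states: [Low, Medium, High]
    parents: [Rainfall intensity]
    provenance: expert
    discretization: {units: tonnes/ha/year, edges: [0, 61, 181, .inf]}
  - name: Feed
    states: [High, Medium, Low]
    parents: [Feeding management, Stocking density, Number of active cages]
    provenance: expert
    discretization: {units: kg/unit/cycle, edges: [500, 1500, 2500, .inf], bin_states: [Low, Medium, High]}
  - name: Accumulated fish feed
    states: [High, Low]
    parents: [Feed]
    provenance: expert

  # ---- outputs ----
  - name: Mass fish kills
    states: ["Yes", "No"]
    parents: [Epilimnion zone after mixing, H2S, Number of active cages]
    provenance: expert_calibrated
  - name: Gobiopterus disappearance
    states: ["Yes", "No"]
    parents: [Epilimnion zone after mixing, H2S]
    provenance: expert_calibrated
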
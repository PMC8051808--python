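# Expert-rule parameterisation of the Lake Maninjau network CPTs.
#
# Each node's states carry an "adversity" score in [0, 1]: the degree to
# which that state pushes the lake toward a mass-fish-kill outcome (0 benign,
# 1 adverse). A child's CPT row for a parent-state combination is generated
# from the risk level
#
#     r = (w0 * v0 + sum_p w_p * a_p) / (w0 + sum_p w_p)
#
# where a_p is the parent state's adversity (1 - a_p when the edge is marked
# invert), and (v0, w0) is an optional anchor pulling r toward a baseline.
# Row probabilities are a softmax over child states i with adversity a_i:
#
#     p_i  proportional to  exp(-sharpness * (a_i - r)^2)
#
# sharpness -> 0 gives uniform rows; large sharpness gives a point mass on
# the state whose adversity is closest to r. Structural zeros override whole
# rows exactly. Root nodes carry their priors directly.
#
# All numbers here are this package's defaults; swap the file to plug in an
# alternative expert table.
format: lakebbn-cpt-params/1
nodes:
  Season:
    adversity: [0.0, 1.0]
    prior: [0.5, 0.5]
  Rainfall intensity:
    adversity: [0.0, 0.33, 0.67, 1.0]
    weights: {Season: 1.0}
    anchor: {value: 0.35, weight: 1.5}
    sharpness: 3.0
  Cloudy:
    adversity: [1.0, 0.0]
    weights: {Season: 1.0}
    anchor: {value: 0.4, weight: 1.3}
    sharpness: 2.5
  Light intensity:
    adversity: [1.0, 0.5, 0.0]
    weights: {Cloudy: 1.0}
    anchor: {value: 0.35, weight: 0.6}
    sharpness: 3.0
  Windspeed:
    # Wide Moderate->Strong gap: upwelling risk switches on at strong wind.
    adversity: [0.0, 0.28, 0.72, 1.0]
    weights: {Season: 0.7}
    anchor: {value: 0.08, weight: 2.8}
    sharpness: 6.0
  Wind Direction:
    adversity: [0.9, 0.6, 0.45, 0.6, 0.4]
    prior: [0.18, 0.14, 0.12, 0.16, 0.40]
  Water current velocity:
    adversity: [1.0, 0.5, 0.0]
    weights: {Windspeed: 1.5}
    anchor: {value: 0.3, weight: 0.5}
    sharpness: 4.0
  SSI:
    adversity: [0.0, 0.5, 1.0]
    weights: {Light intensity: 0.4, Rainfall intensity: 3.0}
    anchor: {value: 0.35, weight: 0.4}
    sharpness: 6.0
  Mixing:
    adversity: [1.0, 0.0]
    weights: {Windspeed: 4.0, Wind Direction: 0.5, Water current velocity: 1.2, SSI: 2.4}
    anchor: {value: 0.1, weight: 1.0}
    sharpness: 12.0
  Water transparency:
    adversity: [1.0, 0.0]
    weights: {Chlo-a epilimnion: 1.5}
    anchor: {value: 0.35, weight: 0.6}
    sharpness: 4.0
  Anoxic layer:
    adversity: [1.0, 0.0]
    weights: {DO epilimnion: 1.8, DO metalimnion: 1.2}
    anchor: {value: 0.25, weight: 0.5}
    sharpness: 5.0
  Epilimnion zone after mixing:
    adversity: [1.0, 0.0]
    weights: {Mixing: 3.5, Anoxic layer: 1.6}
    anchor: {value: 0.0, weight: 1.4}
    sharpness: 7.0
  Anoxic hypolimnion:
    adversity: [1.0, 0.0]
    weights: {BOD metalimnion: 1.6}
    anchor: {value: 0.35, weight: 0.6}
    sharpness: 4.0
  BOD epilimnion:
    adversity: [1.0, 0.0]
    weights: {Accumulated fish feed: 1.2, Organic sediment run off: 0.8}
    anchor: {value: 0.3, weight: 0.5}
    sharpness: 4.0
  BOD metalimnion:
    adversity: [1.0, 0.0]
    weights: {Accumulated fish feed: 1.4}
    anchor: {value: 0.3, weight: 0.6}
    sharpness: 4.0
  PO4 Concentration Epilimnion:
    adversity: [1.0, 0.0]
    weights: {Accumulated fish feed: 1.0, Organic sediment run off: 0.6, PO4 Released from hypolimnion: 1.4}
    anchor: {value: 0.25, weight: 0.5}
    sharpness: 4.0
  PO4 Released from hypolimnion:
    adversity: [1.0, 0.0]
    weights: {Anoxic hypolimnion: 1.4, Reactive Fe Concentration: 0.8}
    anchor: {value: 0.25, weight: 0.5}
    sharpness: 4.0
  Reactive Fe Concentration:
    adversity: [1.0, 0.0]
    prior: [1.0, 0.0]
  Chlo-a epilimnion:
    adversity: [1.0, 0.0]
    weights: {PO4 Concentration Epilimnion: 1.5}
    anchor: {value: 0.35, weight: 0.6}
    sharpness: 4.0
  Chlo-a metalimnion:
    adversity: [1.0, 0.0]
    weights: {PO4 Released from hypolimnion: 1.4}
    anchor: {value: 0.3, weight: 0.6}
    sharpness: 4.0
  H2S:
    adversity: [1.0, 0.0]
    weights: {Anoxic hypolimnion: 1.5, Reactive Fe Concentration: 0.8}
    anchor: {value: 0.25, weight: 0.6}
    sharpness: 4.0
  Respiration rate epilimnion:
    adversity: [1.0, 0.0]
    weights: {Chlo-a epilimnion: 1.5}
    anchor: {value: 0.3, weight: 0.6}
    sharpness: 4.0
  Respiration rate metalimnion:
    adversity: [1.0, 0.0]
    weights: {Chlo-a metalimnion: 1.2}
    anchor: {value: 0.3, weight: 0.6}
    sharpness: 4.0
  GPP epilimnion:
    # High GPP is the benign state for dissolved oxygen; algal biomass raises
    # GPP, hence the inverted edge.
    adversity: [0.0, 1.0]
    weights: {Chlo-a epilimnion: {weight: 1.2, invert: true}}
    anchor: {value: 0.4, weight: 0.6}
    sharpness: 3.0
  GPP metalimnion:
    adversity: [0.0, 1.0]
    weights: {Chlo-a metalimnion: {weight: 1.0, invert: true}, Water transparency: 1.0}
    anchor: {value: 0.4, weight: 0.5}
    sharpness: 3.0
  DO epilimnion:
    adversity: [0.0, 1.0]
    weights: {Light intensity: 0.8, GPP epilimnion: 1.0, Respiration rate epilimnion: 1.0, BOD epilimnion: 1.2}
    anchor: {value: 0.35, weight: 0.6}
    sharpness: 4.0
  DO metalimnion:
    adversity: [0.0, 1.0]
    weights: {BOD metalimnion: 1.2, GPP metalimnion: 1.0, Respiration rate metalimnion: 1.0}
    anchor: {value: 0.4, weight: 0.6}
    sharpness: 4.0
  Stocking density:
    adversity: [0.0, 0.5, 1.0]
    prior: [0.2, 0.5, 0.3]
  Number of active cages:
    # Low/Medium/High carry equal adversity: the direct effect on mass fish
    # kills is exposure of caged stock, present whenever any farm operates.
    adversity: [0.0, 1.0, 1.0, 1.0]
    prior: [0.01, 0.04, 0.15, 0.8]
  Feeding management:
    adversity: [0.0, 1.0, 0.8, 0.5, 0.2]
    prior: [0.02, 0.18, 0.45, 0.15, 0.2]
  Organic sediment run off:
    adversity: [0.0, 0.5, 1.0]
    weights: {Rainfall intensity: 1.2}
    anchor: {value: 0.35, weight: 0.8}
    sharpness: 3.0
  Feed:
    # Feed states are kg per cage unit per cycle: driven by feeding practice
    # and stocking density; cage count carries zero weight (per-unit feed
    # does not depend on how many units operate).
    adversity: [1.0, 0.5, 0.0]
    weights: {Feeding management: 1.2, Stocking density: 1.0, Number of active cages: 0.0}
    anchor: {value: 0.4, weight: 0.5}
    sharpness: 3.0
  Accumulated fish feed:
    adversity: [1.0, 0.0]
    weights: {Feed: 1.4}
    anchor: {value: 0.35, weight: 0.6}
    sharpness: 4.0
  Mass fish kills:
    adversity: [1.0, 0.0]
    weights: {Epilimnion zone after mixing: 3.5, H2S: 1.2, Number of active cages: 0.4}
    anchor: {value: 0.0, weight: 1.25}
    sharpness: 7.0
    structural_zeros:
      - when: {Number of active cages: Zero}
        state: "No"
  Gobiopterus disappearance:
    adversity: [1.0, 0.0]
    weights: {Epilimnion zone after mixing: 3.0, H2S: 1.5}
    anchor: {value: 0.15, weight: 0.5}
    sharpness: 5.0
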
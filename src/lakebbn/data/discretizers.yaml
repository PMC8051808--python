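# Discretization of raw daily observations into network states.
#
# Numeric bins are half-open [low, high); the top bin is closed only by
# +inf. "severity" lists states from least to most severe and is used to
# break ties when summarizing high-frequency records to a daily mode.
format: lakebbn-discretizers/1
discretizers:
  Windspeed:
    units: km/h
    edges: [0, 20, 30, 50, .inf]
    states: [Calm, Moderate, Strong, Gale-Storm]
    severity: [Calm, Moderate, Strong, Gale-Storm]
  Rainfall intensity:
    units: mm/day
    edges: [0, 1, 5, 10, .inf]
    states: [No rain, Light rain, Moderate rain, Heavy rain]
    severity: [No rain, Light rain, Moderate rain, Heavy rain]
  Wind Direction:
    kind: compass
    units: degrees
    # 45-degree sectors centred on N, NE, E, SE; the remaining half circle
    # maps to "Other directions".
    states: [North, North East, East, South East, Other directions]
    severity: [Other directions, South East, East, North East, North]
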
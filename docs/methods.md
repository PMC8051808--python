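# Methods

## The model

The lake is represented as a discrete Bayesian belief network: 35
categorical nodes (2–5 states each, keeping elicited tables small enough
for experts to fill) in a directed acyclic graph, one conditional
probability table (CPT) per node, joint distribution given by the chain
rule. Posteriors are computed exactly by variable elimination; no
approximate inference is used anywhere, so every result is deterministic
given the network and evidence.

The causal story runs in four layers:

1. **Weather physics.** Season drives rainfall, cloud cover and wind speed;
   cloud drives light; light and rainfall drive the lake's stratification
   stability (the Schmidt-stability node, used only as a discrete
   high/medium/low state); wind drives surface current. Wind speed, wind
   direction, current and stability jointly determine **Mixing** — whether
   the water column overturns that day.
2. **Stratification chemistry.** Per-cage feed intensity (set by feeding
   practice and stocking density) accumulates as waste, raising
   biochemical oxygen demand; together with rainfall-driven organic runoff
   this depresses epilimnion and metalimnion oxygen. Metalimnetic oxygen
   demand sustains a hypolimnetic anoxic zone which, in this
   naturally sulphur-rich, iron-poor system, releases H2S and phosphate;
   released phosphate fertilises algae whose respiration further depresses
   oxygen (internal phosphorus loading). Epilimnion and metalimnion oxygen
   set the width of the anoxic layer.
3. **The upwelling gate.** "Epilimnion zone after mixing" codes whether
   surface water holds enough oxygen after a mixing event (threshold
   1.5 mg/l): it needs both a mixing day and a wide anoxic layer to go bad.
4. **Outputs.** Mass fish kills (MFK) of the caged stock depend on the
   post-mixing epilimnion, H2S, and the number of active cages (no cages,
   no caged fish to kill — an exact structural zero). The disappearance of
   the native *Gobiopterus* sp. depends on the same water-column state but
   not on cage count.

Two feedback loops had to be cut to keep the graph acyclic, both by
rerouting to the dominant direction of influence: light intensity connects
directly to epilimnion oxygen (photosynthesis) rather than to algal
biomass, and hypolimnetic anoxia is driven by metalimnetic organic load
(BOD) alone rather than also by metalimnetic oxygen — the reverse path
(anoxia → phosphate release → metalimnion algae → metalimnion oxygen)
remains, and a static network cannot carry both directions.

## Expert-rule CPTs

Published sources give the CPT *provenance* for each node but not the
numbers, so the package generates defaults from a compact, fully inspectable
rule (all parameters in `maninjau_cpt_params.yaml`). Every state of every
node carries an **adversity** score in [0, 1] — its ordinal contribution
toward the fish-kill outcome. For a child node, each parent-state
combination yields a risk level

    r = (w0·v0 + Σp wp·ap) / (w0 + Σp wp)

where `ap` is the parent state's adversity (inverted, `1 − ap`, on edges
where the parent's adverse state protects the child — e.g. algal biomass
*raises* gross primary production), `wp` the edge weight, and `(v0, w0)` an
optional anchor blending in a baseline. The row distribution is a softmax
over child states i with adversities `ai`:

    pi ∝ exp(−s·(ai − r)²)

with one sharpness scalar `s` per node. `s → 0` gives uniform rows; large
`s` gives a point mass on the state whose adversity matches the combined
risk, so rows order monotonically with total parent risk. Structural zeros
(cage count Zero → MFK No) override whole rows exactly. For a binary child
this reduces to a logistic response `P(adverse) = σ(s(2r − 1))`.

The default weights and sharpness values were fixed by the package's
calibration procedure (`calibrate_sharpness` grid-searches a node's
sharpness until required mutual-information orderings hold), against the
qualitative behaviour the system is known to exhibit: the two upwelling
nodes are the dominant drivers of both outputs; among weather drivers of
mixing, wind speed ranks first, followed by current velocity, stability and
rainfall; adverse-weather posteriors strictly exceed benign-weather
posteriors in every scenario; and interventions order 1f ≤ 1e ≤ 1a and
1f ≤ 1d ≤ 1a for fish-kill risk. Cage count is given zero weight on the
per-unit feed node (feed per cage does not depend on how many cages
operate), which makes cage count act on MFK only through its direct
exposure edge; this reproduces two observed behaviours exactly: capping
cages at 6,000 leaves short-term risk unchanged, and removing cages leaves
the native-fish output untouched in the short term.

## Discretization and daily summarization

Numeric observations map to states through half-open bins [low, high), top
bin unbounded: wind speed (km/h) 0–20–30–50–∞ for Calm / Moderate / Strong
/ Gale-Storm (a simplified Beaufort classing; 19.5 km/h is Calm under the
declared convention), rainfall (mm/day) 0–1–5–10–∞, wind bearing by
45°-sectors centred on N/NE/E/SE with the remaining half-circle as "Other
directions". High-frequency logger streams are collapsed to one record per
calendar day: modal discretized wind speed and direction (ties resolved
toward the more severe class, so a 50/50 calm/strong day counts as strong)
and maximum rainfall.

## Sensitivity analysis

Sensitivity to findings reports MI(target; query | context) in bits
(base-2 logarithms, matching common BBN-tool convention; the context is
empty by default), computed entirely from exact posteriors. The report
ranks all non-evidence nodes and separately exposes the **driver ranking**
restricted to the target's ancestors: a tightly coupled descendant is
always highly informative without being a controllable cause, so
driver-restricted rankings are what the calibration orderings above refer
to. Sensitivity to parameters perturbs one CPT row at a time, moving a
fraction δ of mass onto each extreme state in turn (`row' = (row + δ·ei) /
(1 + δ)`) and reports the largest change in the target's adverse-state
posterior; the symmetric scheme makes scores comparable across nodes.

## Accuracy evaluation

Predicted event probabilities are coded positive at a cut-off c by `p ≥ c`
(inclusive; the convention is declared since published grids cannot
distinguish it). The default grid is integer percents 1..96. Pearson
chi-square is computed without continuity correction — the published
statistic for the hold-out table (tn=87, fp=2, fn=2, tp=9) is 63.315,
which pins the uncorrected form (Yates' correction would give ≈55.4) — with
the df=1 upper-tail p-value; the optimum cut-off is the smallest grid point
attaining the maximal chi-square (minimum-P-value criterion), degenerate
cut-offs (a zero table margin) being flagged and never selected. Error rate
is (fp+fn)/n, TSS = sensitivity + specificity − 1, and the ROC is the
empirical curve over all distinct prediction values with trapezoidal area,
which equals the probability a random positive outranks a random negative
with ties counting one half (verified against both a pairwise oracle and
scikit-learn in the tests).

## Scenarios

A scenario is a named evidence map: lake-condition settings (H2S, internal
phosphate release, anoxic-layer width) plus an intervention (cage count,
feeding practice, aeration). Short-term scenarios pin the current degraded
condition (H2S high, phosphate release high); long-term recovery scenarios
flip phosphate release and the anoxic layer to their benign states instead
of time-stepping — the network is static and the horizon is represented
purely by evidence. Aeration is modelled as evidence that epilimnion
dissolved oxygen is high, since oxygen infusion acts on the water column
rather than on any single mechanism node. Each scenario is evaluated over
two weather envelopes — benign (dry season, calm wind, up to moderate
rain) and adverse (wet season, strong to gale wind, moderate to heavy
rain) — by enumerating every admissible weather combination and reporting
the min/max posterior of each output, coded NO (max below cut-off), YES
(min at or above), or NO/YES (cut-off inside the range). Impossible
combinations are skipped with a log entry; a scenario whose envelope
empties out fails loudly.

## Synthetic data

The study's raw drivers (decade-scale agency weather series, lakeside
logger records, fish-kill dates) are not publicly deposited, so seeded
generators emulate their structure. Daily weather draws a class from
per-season categorical targets (matched to the model's seasonal CPTs, so
generated series are consistent with the network they exercise) and then a
numeric value inside the class's bin (exponential tail for the top bin);
the wet-season calendar is October–March. Day-to-day persistence is
available but off by default — daily-summarized records are treated as
independent days. Validation sets mirror a two-variable accuracy test: each
of n days carries wind speed and direction evidence only, the prediction is
the model's MFK posterior given that evidence, and the label is drawn from
the same conditional; the weather mix is resampled until the positive count
lands within ±20% of the target (default 10 of 100, roughly the study-scale
event rate), with the default window straddling the dry/wet transition so
both calm and stormy days appear. CPT learning uses complete-family counts
with a Dirichlet pseudo-count (default 1), so unobserved rows remain valid
(uniform) distributions.

Passing self-validation on such data shows the pipeline is internally
consistent — a model scored on data it generated must beat chance — but it
cannot show the lake model is *true*: real weather has autocorrelation,
observation error and regime shifts the generators do not emulate, and the
real CPTs are unpublished.

## Numerical conventions

- Probability arithmetic in linear double precision; the factor tables at
  this scale are far from underflow (asserted ≥ 1e-30 in tests).
- CPT rows must sum to 1 within 1e-9; rows within 1e-6 are renormalized on
  load, anything worse is reported as a violation rather than silently
  fixed (a badly scaled expert table is a data error).
- Zero-probability evidence raises an explicit impossible-evidence error,
  never NaN or a silent uniform.
- Elimination order: min-degree on the moralized graph of the ancestral
  closure of target and evidence, ties lexicographic; correctness is
  order-independent (property-tested), only cost varies.
- All ranking ties (MI reports, cut-off selection) break deterministically:
  lexicographic for names, smallest value for cut-offs.
- All randomness flows through explicit integer seeds; identical inputs
  produce identical outputs byte-for-byte.

## Parameter-recovery check

CPTs re-learned from 10,000 forward-sampled days must sit within total
variation 0.05 of the generating rows on every *well-observed* row, defined
as ≥500 family observations: at that occupancy the binomial sampling noise
(sd ≤ 0.022) is small against the band, so the check detects genuine
learning defects. At lower occupancies (e.g. 50 observations, sd ≈ 0.07)
the band would be violated by sampling noise alone regardless of
implementation correctness.

## Known limitations

- The network is static: no feedback loops (two were cut, see above), no
  within-event dynamics, no lag between load reduction and water-quality
  response; the long-term scenarios are evidence flips, not projections.
- The default CPT numbers are a calibrated expert-rule reconstruction, not
  the (unpublished) elicited tables; all conclusions shipped with the
  package are orderings and structural facts that are robust to the rule's
  parameters, and the YAML configs are the single source to swap in better
  numbers.
- Reactive iron is shipped with a degenerate prior (Low with probability
  1), mirroring its single printed state, but keeps a second state so it
  remains a usable lever.
- Scenario ranges are min/max over envelope weather combinations; they
  carry no probability weighting within the envelope.
- No confidence intervals on AUC/TSS are produced; evaluation mirrors a
  single hold-out design.
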
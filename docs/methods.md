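# Methods

## Model

`dietmcda` implements an additive multi-attribute value model. A model is a
value tree of criteria spread over four sustainability dimensions (health,
environmental, economic, social). Each criterion is operationalized by a
*descriptor of performance*: an ordered list of levels, indexed from the
most attractive (L1) downward, with exactly one level flagged **Good** and
one flagged **Neutral**, Good at least as attractive as Neutral. The
attractiveness order is authoritative; the numeric performance attached to
the levels may ascend or descend along it (profitability improves with
larger % margin change, water use improves with fewer litres).

A cardinal value scale attaches a value to every level, anchored at
Neutral = 0 and Good = 100 and non-increasing with decreasing
attractiveness. Partial values for arbitrary quantitative performance are
obtained by linear interpolation *on the performance axis* between adjacent
anchors; beyond the extreme anchors the terminal segment's slope is
extended without clamping. Both conventions were confirmed against the
published case-study partials (e.g. the affordability partials 346.67 and
396.7 exceed the top anchor value 300, which only the unclamped terminal
slope produces). Categorical descriptors use exact label lookup; there is
nothing to interpolate between labels.

Global scores are `V(a) = Σ_j w_j v_j(a)` with strictly positive weights
summing to 1 (checked to 1e−9). Missing performance cells contribute 0
points — the Neutral reference — with a logged warning and an entry in the
result's missing-cell list. This matches the case-study treatment of the
Danish accessibility column, which is blank in the published score table
yet consistent with the published totals only under zero contribution.

## MACBETH scale and weight derivation

Qualitative pairwise judgments ("the improvement from L4 to L3 is
*moderately* more attractive…") in the seven semantic categories — null,
very weak, weak, moderate, strong, very strong, extreme — are compiled into
a judgment matrix and turned into cardinal values by linear programming:

* one variable v(e) ≥ 0 per entity;
* a pair (a, b) judged in category k ≥ 1: v(a) − v(b) ≥ k·δ with δ = 1;
* null judgments force v(a) = v(b);
* for two judged pairs whose categories are strictly ordered, the stronger
  pair's difference exceeds the weaker pair's by at least δ;
* contiguous category ranges ("weak to moderate") use the range's lower
  bound for the magnitude constraint and its upper bound when deciding
  whether another pair is strictly stronger.

**Consistency is feasibility** of this system. On inconsistency the checker
reports every judgment whose single removal restores feasibility (an
approximation of the irreducible infeasible subset that is exact for simple
cycles).

The LP optimum is not unique. For determinism the solver first minimizes
the largest entity value, then, holding that bound, minimizes the sum of
entity values (two HiGHS solves). This min-max/min-sum pair was chosen over
sequential lexicographic minimization because it needs a fixed number of
solves and the subsequent affine re-anchoring (Neutral → 0, Good → 100 for
scales; normalization to Σw = 1 for swing weights) removes the remaining
non-uniqueness in all anchored quantities the package reports. The δ used
by commercial implementations is not published; any δ > 0 yields the same
anchored scales for complete consistent matrices, so δ = 1 is used.

Swing weighting derives weights from judgments over the Neutral→Good swings
of all criteria, with every swing kept ≥ δ (each improvement is worth
something, hence weights are strictly positive) and the elicited swing
ranking enforced as ordering constraints; a matrix that contradicts the
ranking raises "ranking violated". The engine does **not** attempt to
re-derive the case-study scales or weights: the judgment matrices behind
them are unpublished, so the published scales are shipped as fixtures and
the engine is validated property-based (see Testing).

## Case-study fixtures

The packaged case study evaluates replacing 0/25/50/75/100 % of beef
consumption with pulses in Portugal and Denmark: 14 criteria, published
cardinal scales and weights, published performance evidence, and the
published partial/global scores for cross-checking. Encoding choices:

* **Performance units.** Economic performances are % change versus the
  baseline scenario (the published convention). Affordability performance
  is the % reduction of the purchasing-power-parity price relative to the
  reference scenario; the published PPP prices are rounded too coarsely to
  reproduce the published partials exactly, so the fixture stores values
  back-derived from the published partials by inverse interpolation
  (flagged "inferred" in the model provenance). The unitless
  environment-related-health performances are back-derived the same way, as
  no evidence row is published for them. Diet-related health performance is
  the change in DALYs per 100,000 inhabitants; its value scale is negative
  linear (one DALY averted = one point).
* **Categorical cells** store level codes (L1…Ln) whose meaning is kept in
  the level descriptions; the Danish accessibility column is blank
  (missing) throughout.
* **Known quirks, annotated in the fixtures rather than repaired:** the
  published local-economic-development scale prints +66.67 for its worst
  level, which duplicates L2, breaks monotonicity and contradicts the
  published partial scores, so the fixture stores −66.67 as a flagged sign
  typo. Two local-development criteria share an identical descriptor but
  carry different weights (0.0403 / 0.0081) and are kept distinct. Two
  fair-practices levels share identical wording and differ only in value.
  Three published overall scores (PT 0 %, DK 100 %, DK 0 %) are **not**
  reproducible from their own published partials and weights (recomputation
  gives ≈16.35, ≈91.9, ≈−3.1); they are recorded but never asserted.
  Curiously the PT 0 % published total (16.99) *does* match recomputation
  from the performance evidence (16.986), suggesting a typo in that row's
  published pollution partial (5 versus a recomputed 12.5).

Intermediate substitution scenarios are constructed by linear blending,
`(1−f)·reference + f·endpoint`, of quantitative cells (categorical cells
copy the nearer endpoint, ties to the reference). The published
intermediate environmental cells agree with this rule to last-digit
rounding; the published DALY columns are mildly sublinear in f, so health
cells are carried as published rather than blended.

## Sensitivity and robustness

Varying one weight w on criterion j while rescaling the others by
`(1−w)/(1−w_j⁰)` keeps Σw = 1 and makes every global score affine in w:
`V_a(w) = (1−w)·R_a + w·v_j(a)` with
`R_a = (V_a(w_j⁰) − w_j⁰·v_j(a))/(1−w_j⁰)`. Crossovers of the top-ranked
alternative are found by walking the upper envelope of these lines;
crossover weights are exact roots of pairwise line differences. A tangency
exactly at w = 1 (two alternatives tying at the boundary) is not counted as
a change of recommendation. Proportional renormalization is the standard
convention for single-weight sensitivity displays and is what makes one
straight line per alternative possible.

Robustness models uncertainty as closed intervals on partial values. For an
ordered pair (a, b): *dominates* if every interval of a lies at or above
b's; *robustly preferred* if the box-minimum of V(a) − V(b) is ≥ 0,
computed exactly at the vertex (lower bounds for a, upper bounds for b);
*preferred* if only the nominal comparison favours a. The shipped
case-study analysis puts ±25-point intervals (a quarter of the
Neutral→Good range) on the three criteria whose inputs are the most
judgment-dependent — diet-related health, environment-related health, and
acceptance — for every scenario; the interval choice is recorded in the
analysis output. At that magnitude the full pairwise matrix in both
countries is unchanged and 100 % substitution stays robustly preferred.
The magnitude matters: the three criteria carry total weight 0.25, so
symmetric ±h intervals can erode a pairwise gap by up to 2·h·0.25 points,
and the tightest gap (PT, 100 % vs 75 %: 22.3 points) admits h up to ≈44.6.
Intervals on *weights* are not supported: after Σw = 1 renormalization the
feasible weight region is no longer a box and the vertex argument does not
transfer.

## Synthetic generators

`synth_model` draws random valid models (monotone quantitative descriptors
of mixed orientation, occasional categorical criteria, anchored scales,
positive normalized weights). `generate_consistent_matrix` draws a hidden
cardinal scale, bins all pairwise differences into the six positive
categories by fixed thresholds (equal sixths of the largest difference),
and returns both matrix and hidden scale; the binning guarantees LP
feasibility because a strictly stronger category always corresponds to a
strictly larger hidden difference. All generators take an explicit seed and
no global random state is used. These synthetic instances exercise the
algebra of the engine — they do not emulate the behavioural texture of real
elicitation (hesitation ranges, near-inconsistent cycles, agenda effects),
so passing property tests demonstrates correctness of the computation, not
of any elicitation protocol.

## Numerical choices

Anchor and aggregation identities are enforced to 1e−9; crossover roots are
exact closed forms checked against a 10⁻³ grid scan; reported precision is
2 decimals while all internal computation is double precision. Ranking ties
are broken by input order (stable sort). LP feasibility tolerances are
HiGHS defaults; the stage-2 cap on the maximum entity value is relaxed by
1e−9 to avoid spurious infeasibility at the stage-1 optimum.

## Test-problem sizes

Property tests run on matrices of 4–5 entities (up to 100 seeds for the
consistency property), models of 3–6 criteria, and brute-force oracles on
instances small enough for exhaustive enumeration (grid feasibility search
on ≤4 entities; 2⁶–2⁹ vertex enumeration for robustness). These sizes make
every oracle exact while keeping the whole suite in a few seconds.

## Known limitations

* Single-level additive value trees only; no Choquet or other non-additive
  aggregation, and no group-preference aggregation across panels.
* The MACBETH LP family here is the published canonical one; commercial
  implementations may differ in objective and spacing parameter, and the
  published case-study scales cannot adjudicate between formulations.
* No inconsistency-repair suggestions and no interval/robust MACBETH
  scales.
* DALY estimation and per-kg environmental footprints are inputs, not
  computed: the package evaluates evidence, it does not produce it.
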
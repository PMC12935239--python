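# dietmcda

Multicriteria value measurement for dietary substitution policy — a Python
toolkit for building, applying and stress-testing additive multi-attribute
value (MAVT) models in the MACBETH tradition, packaged with a reusable
beef-to-pulses substitution case study for Portugal (PT) and Denmark (DK).

## Who this is for

Risk–benefit and food-system analysts who need to integrate health,
environmental, economic and social evidence about a dietary shift into a
single, transparent score per policy scenario — and to show decision makers
how stable that recommendation is to the value judgments behind it.

## The model

Each evaluation criterion *j* carries a *descriptor of performance* (an
ordered set of plausible performance levels, most attractive first) with two
reference levels: **Neutral** (minimally acceptable, 0 points) and **Good**
(100 points). A piecewise-linear value function over the descriptor anchors
converts a scenario's performance into a partial value `v_j(a)`;
extrapolation beyond the extreme anchors continues the terminal segment's
slope. Global scores aggregate additively,

```
V(a) = Σ_j  w_j · v_j(a),     Σ_j w_j = 1,  w_j > 0,
```

with swing weights `w_j` comparing the attractiveness of the Neutral→Good
improvement across criteria.

Cardinal scales and swing weights can be *derived from qualitative
judgments*: pairwise differences of attractiveness expressed in the seven
MACBETH semantic categories (null … extreme) define a linear program whose
feasibility is the consistency check and whose solution, affinely
re-anchored to Neutral = 0 / Good = 100, is the value scale
(`derive_scale`, `derive_weights`, `check_consistency`).

Two stress tests accompany every evaluation:

* **weight sensitivity** — vary one weight over [0, 1], rescale the others
  proportionally; every scenario's score is then affine in the varied
  weight, so ranking crossovers are exact line intersections;
* **robustness** — put closed intervals around partial values; the minimum
  of `V(a) − V(b)` over the box is attained at a vertex (lower bounds for
  *a*, upper bounds for *b*), giving an exact pairwise dominance matrix.

## Worked example

```python
>>> import dietmcda as dm
>>> study = dm.case_study("PT")          # 14-criterion model + evidence
>>> result = dm.evaluate(study.model, study.performance,
...                      study.printed_overrides())
>>> [(s, round(result.globals_[s], 2)) for s in result.ranking]
[('100%', 102.37), ('75%', 80.06), ('50%', 57.05), ('25%', 40.89), ('0%', 16.35)]
```

Full substitution of beef by pulses scores 102.37 points in Portugal —
more than the distance from a minimally acceptable (0) to a good (100)
profile — and the score rises monotonically with the substitution fraction,
so every increment of substitution is beneficial on balance. The same holds
for Denmark (`dm.case_study("DK")`), where the blank accessibility column
contributes 0 points and is reported in `result.missing_cells`.

Stability of the recommendation:

```python
>>> dm.recommendation_stability(study.model, study.printed_partials,
...                             "diet_health").stable
True
>>> prof = dm.weight_sensitivity(study.model, study.printed_partials,
...                              "local_communities")
>>> [(round(x.weight, 3), x.outgoing, x.incoming) for x in prof.crossovers]
[(0.317, '100%', '50%')]
```

No admissible change of the diet-related-health weight alters the top
choice; the impact-on-local-communities weight would need to rise from
0.0081 to 0.317 before 50% substitution overtakes 100%.

The same operations are available from the shell:

```bash
dietmcda case-study --country DK --recompute
dietmcda sensitivity --model model.json --partials partials.csv \
    --criterion water_use --plot fig.png
dietmcda scenarios --reference ref.csv --endpoint end.csv \
    --fractions 0.25,0.5,0.75,1.0 --out scenarios.csv
```

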
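# readacross

A Python toolkit for guided chemical-safety read-across: identifying
analogue candidates by combined structure- and property-based
similarity, scoring the reliability of the toxicity studies behind
them, combining both into a quantitative read-across reliability by
weight of evidence, estimating NOAEL bounds from structural
neighbours, and running the non-cancer Threshold of Toxicological
Concern (TTC) decision tree.

It is aimed at computational toxicologists and risk assessors who need
a transparent, scriptable version of the analogue-selection and
weight-of-evidence arithmetic used in regulatory read-across workflows
for cosmetics- and food-related chemicals.

## The statistics at the core

**Similarity.** Structure similarity is the Tanimoto coefficient
T(A,B) = |A∩B| / |A∪B| over fingerprint bit sets (path-based,
166 structural keys, or SMARTS chemotype libraries). Property
similarity operates on property vectors standardised against a
reference population, z = (x − μ)/σ, as either

- Pearson similarity = (1 + r) / 2, with r the Pearson correlation, or
- Euclidean similarity = 1 / (1 + d), with d the Euclidean distance.

**Analogue Quality** combines N similarity measures as a geometric
mean, AQ = (∏ sᵢ)^(1/N) — conventionally two fingerprint Tanimotos
plus one property measure.

**Study reliability.** A study is graded 1–5 by counting failures
among sixteen minimum-inclusion rules (0 fails → 5, 1–2 → 4, 3–4 → 3,
>4 → 2, summary-only → 1); crossing the grade with a 1–5 expert
opinion score in a lookup grid yields the Study Reliability Likelihood
(SRL ∈ [0.5, 1]).

**Read-across reliability** is the joint probability AQ × SRL, with a
belief/plausibility interval from combining both scores as discounted
Dempster–Shafer mass functions. A candidate qualifies as an analogue
only when AQ ≥ 0.7 and SRL ≥ 0.7; SRL < 0.5 marks the study as
unusable. NOAEL bounds for the target are mean ± z·sd over neighbour
NOAELs (normal assumption; log-normal and mean-CI modes available).

**TTC.** Exposure (µg/kg-bw/day × body weight) is compared to the
Cramer-class threshold after cohort-of-concern (metals, polyhalogenated
dibenzodioxins/furans/biphenyls — immediate fail) and organophosphate
branches. Comparisons are strict: exposure equal to the threshold fails.

## Worked example

```python
from readacross import WorkflowConfig, generate_fixture_library, run_guided_workflow

bundle = generate_fixture_library("hair_dyes")
report = run_guided_workflow(WorkflowConfig(bundle=bundle))
for row in report.step(6)["rows"]:
    print(row["compound_id"], row["role"], row["read_across_reliability"])
```

prints

```
CMS-23938 target None
CMS-60520 analogue 0.75
CMS-72054 similar 0.56
CMS-43204 similar 0.55
```

The target hair dye has no data of its own. Of three similar
structures, only CMS-60520 clears both 0.7 qualification floors
(AQ 0.83 × SRL 0.90 → read-across reliability 0.75) and is promoted to
analogue; its 90-day rat NOAEL of 17 mg/kg-bw/day becomes the surrogate
endpoint value for the target. The other two candidates stay "similar":
their analogue quality is too low, and both additionally fire the
nitroaromatic reproductive-toxicant alert that the target lacks.

More narrative walk-throughs live in `examples/` (similarity tables,
reliability grading, TTC tree, alert profiling) — each runs standalone
with `python examples/<name>.py`.

A thin CLI wraps the same API:

```bash
readacross ttc --smiles "O=S(=O)([O-])c1cccc2ccccc12.[Na+]" \
    --cramer-class III --exposure 0.35 --body-weight 60
readacross readacross --fixture hair_dyes --out report/ --format csv_bundle
```

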
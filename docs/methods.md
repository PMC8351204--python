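# Methods

## Scope and model

The package implements the quantitative core of a guided read-across
workflow: (1) analogue identification by combined structure- and
property-based similarity, (2) study-quality scoring, (3) weight-of-
evidence combination into a read-across reliability, (4) NOAEL bound
estimation from structural neighbours, and (5) the non-cancer TTC
decision tree. It deliberately does not implement a chemical database,
structure curation, or the internal logic of the Cramer classification
tree (Cramer class is an input, optionally via a pluggable classifier,
because published tree implementations are known to disagree and the
assignment is an expert-reviewable input rather than part of this
package's contribution).

## Similarity and Analogue Quality

Structure similarity is Tanimoto over explicit bit sets. Two
fingerprints are bundled: the RDKit path fingerprint (2048 bits) and
the 166 MACCS-type structural keys; any SMARTS library can also act as
an interpretable chemotype fingerprint. Two empty bit sets are defined
as similarity 1.0: structures that set no bits are indistinguishable
to that fingerprint, and returning 0 would make a fingerprint with no
coverage claim maximal dissimilarity.

Property similarity operates on z-standardised vectors. Pearson
similarity (1+r)/2 requires ≥ 3 properties and non-constant vectors;
a zero-variance vector makes r undefined and raises an explicit error
rather than silently returning 0.5. Euclidean similarity is
1/(1+distance). Analogue Quality is the geometric mean of the chosen
measures — by default two fingerprint Tanimotos plus one property
measure, but the operation accepts any N ≥ 1. The geometric mean is
the right aggregator here because the measures are ratios on [0,1] and
a single near-zero measure should dominate (AQ(…,0,…) = 0).

Reported tables are rounded half-up to 2 decimals; all internal
arithmetic keeps full precision. This matters: the worked hair-dye
example's read-across reliabilities (0.75/0.55/0.56) only reproduce
when full-precision AQ values (0.8320/0.6118/0.6258) are multiplied by
the study reliability before rounding — rounding AQ first would give
0.57 instead of 0.56 for the third candidate.

Similarity search enforces a floor of 0.65 on the threshold (default
0.7): hits below that level are too weak to support analogue reasoning
in this workflow, and accepting lower thresholds would silently change
the meaning of a "hit list". Ranking ties are broken by compound id
for deterministic output.

## Descriptors and standardisation

Descriptors are computed with RDKit: non-strict rotatable-bond count,
molecular weight, TPSA, Crippen logP, BertzCT as the molecular
complexity measure, H-bond donors/acceptors, molar refractivity.
Because published workflows often use a different (sometimes
proprietary) descriptor engine, every value can be overridden per
compound from an external CSV; external values carry an "external"
provenance flag and always win over computed ones, so exact
reproduction of an externally exported table never depends on
descriptor-engine agreement. Descriptors and fingerprints are computed
on the largest organic fragment of multi-component records, so salts
are profiled through their organic component.

The bundled paraben reference statistics are back-solved from the
fixture's paired raw/standardised vectors by per-property least-squares
fit of z = (x − μ)/σ. This fit reproduces all 20 printed standardised
values within ±0.01 (16 of them within ±0.005). TPSA is constant
across the four parabens, so its σ is unidentifiable from the fixture;
it is pinned at 40 Å² with μ chosen to reproduce the constant z. The
fixture is example-calibrated: real analyses must supply reference
statistics from a large population (the standardisation these fixtures
emulate used >10,000 structures).

## Structural alerts and enrichment

The default alert library is a small curated SMARTS set covering the
chemistry of the bundled worked example: quinone/pro-quinone precursors
(ortho/para aminophenols and phenylenediamines), aromatic nitro and
aromatic amine DNA-binder alerts, and a reproductive-toxicant
nitroaromatic pattern (nitro para to an aromatic amine or hydroxyl).
It is a demonstration vocabulary, not a validated alert set; full
published chemotype libraries load through the same CSV/JSON format.

Chemotype/endpoint association is summarised by a two-proportion
z statistic with pooled variance (endpoint rate inside the chemotype
subset vs the complement). The statistic behind the published
enrichment heat maps is not formally defined anywhere we could pin
down, so this standard choice is a documented assumption. The
colour-legend bins partition the line as z ≤ −2, (−2,−1], (−1,1],
(1,2), [2,∞); the legend's overlapping boundary at z = 1 is resolved
by giving the neutral bin its closed upper bound, reading "−1 < z ≤ 1"
literally.

## Study reliability

The grade mapping (failures among 16 rules → grade 1–5) and the 5×5
likelihood grid are fixed defaults; the grid's values lie in
[0.5, 1.0] — even the weakest summary-only record retains roughly
coin-flip weight rather than zero, reflecting that it exists and was
curated. The sixteen rules' texts are organisation-specific, so rule
outcomes are supplied as booleans (or a 16-character P/F string);
opinion scores are expert judgement and are never computed. Custom
grids are accepted but validated for completeness, [0,1] bounds and
monotonicity in both grade and opinion.

## Weight of evidence

The read-across reliability point estimate is the product AQ × SRL —
a joint probability of two independent evidence sources. The interval
estimate builds discounted Dempster–Shafer mass functions
m(reliable) = δ·s, m(not) = δ·(1−s), m(either) = 1−δ over the frame
{reliable, not reliable} with default discount δ = 0.9, and combines
them by Dempster's rule. The discount is the analyst's cap on how
much of a score is committed to the singletons; δ = 0 gives the
vacuous mass (total ignorance), and the belief/plausibility interval
narrows as δ → 1. Published DST intervals for this workflow depend on
a parameterisation that is not reproducible from open sources, so the
DST layer is validated property-wise (vacuous identity, commutativity,
normalisation to 1 within 1e−9, belief ≤ plausibility) rather than
against printed interval endpoints.

Qualification floors: AQ ≥ 0.7 and SRL ≥ 0.7 for "analogue" status
(inclusive, matching the similarity-search default threshold);
SRL < 0.5 is "data unusable" and takes precedence over any AQ.

## NOAEL bounds

Default mode `normal_sd` is mean ± z·sd of the neighbour NOAELs
(z = Φ⁻¹(0.975) at the default 95% level), the literal reading of
"assuming a normal distribution of NOAEL values"; `normal_mean_ci`
(sd/√n) and `lognormal_sd` are provided because dose data are often
log-normal and the choice cannot be adjudicated without the original
neighbour set. The lower bound is clipped at 0. One value is an error
by design: the caller should report that analogue's NOAEL as a
surrogate without an interval, which is exactly what the workflow's
Step 7 does when only one qualified analogue carries a NOAEL.
Neighbour selection is Tanimoto ≥ 0.7 under a chemotype fingerprint by
default, with optional exclusion of compounds firing a profile alert
the target lacks (e.g. reproductive toxicants).

## Fixtures and what passing tests show

The paraben and hair-dye fixtures carry externally attached similarity
and property values (the published exported tables), cleanly separating
"reproduce the workflow arithmetic exactly" from "toolkit-dependent
descriptor computation" — fingerprint Tanimotos from different toolkit
versions legitimately differ, so they are fixture inputs, not computed
assertions. The hair-dye SMILES are synthetic surrogate structures
(the source tables print no structures), chosen as plausible
nitroaromatic amine hair-dye chemistry so the bundled alert library
reproduces the published category pattern; nothing numeric is derived
from them. Consequently, passing tests demonstrate the correctness of
the similarity/reliability/evidence arithmetic and the workflow
plumbing — not the validity of any particular fingerprint, alert set,
or descriptor engine on real inventories.

The `random_homologues` generator emulates a homologous series
(alkyl benzenes/phenols/anilines, chain lengths 1–8, log-normal NOAELs
around e³ ≈ 20 mg/kg-bw/day with σ = 0.8) with seed-deterministic
output. It emulates graded structural similarity and plausible NOAEL
spread; it does not emulate multi-scaffold chemistry, activity cliffs,
or correlated study quality, so it stress-tests search and neighbour
recovery, not biological realism. The scientific pipeline itself is
fully deterministic; the generator is the package's only source of
randomness.

## Numerical and design choices

- Rounding for report tables is half-up at 2 dp (matches every printed
  value checked in the worked examples; the source's rounding rule is
  unstated, so this is a reconstruction).
- TTC thresholds: Class III = 90 µg/person/day is fixed by the worked
  example; Class I (1800), Class II (540) and the organophosphate
  threshold (18) are editable configuration defaults from the standard
  published non-cancer TTC scheme. Threshold comparison is strict.
- The cohort-of-concern metal rule treats monoatomic group-1/2 ions in
  salts with an organic fragment as counterions (the worked TTC example
  is a sodium salt and is not cohort-of-concern); any other metal atom
  triggers the metal-containing group. "Polyhalogenated" cores require
  ≥ 2 aromatic halogens (configurable).
- Workflow Step 5 keeps the most reliable study per compound when
  several are supplied; multi-study DST aggregation beyond pairwise
  chaining is out of scope.
- CAS numbers are validated by the standard weighted-checksum rule;
  validation failures are warnings on load, not errors, since many
  inventory records carry legacy identifiers.

## Known limitations

- The bundled alert library is illustrative; category flags from it
  must not be read as validated hazard calls.
- The reliability grid is a modelled default, not a measured quantity;
  organisations with their own quality schemes should supply a custom
  grid (validated on load).
- NOAEL bound estimation ignores study design differences between
  neighbours (species, duration, route); it is a rough, transparent
  first estimate, not a replacement for expert dose-response review.
- The DST interval depends on the discount choice; it should be read
  as a sensitivity band around the joint-probability point estimate,
  not as a calibrated probability interval.
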
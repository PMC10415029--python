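# Methods

## Problem setting

A wearable camera mounted on eyeglasses captures one egocentric image every
`capture_interval` seconds (10 or 15 s in the deployments this engine
targets) across a participant-day. An upstream classifier — outside the
scope of this package — assigns each image a binary food-intake label. The
engine's job begins at those labels: find eating-episode boundaries, limit
human review to episode images, attach food items from food-composition
databases, and turn annotator portion estimates into grams, kilocalories,
and nutrient amounts at item, episode, and day level.

## Episode segmentation

Candidate episodes are maximal runs of consecutive intake-labeled images in
the ordered stream. Two runs merge when the non-intake time between them —
from the last intake capture of one run *plus one capture interval* to the
first intake capture of the next — is at most `merge_gap` seconds. After
merging, episodes carried by fewer than `min_images` intake images are
dropped; the dropped images remain queryable (`dropped_intake_images`), so
filtering reports rather than silently discards. An episode spans
`[first intake timestamp, last intake timestamp + capture_interval)`; all
point-in-episode queries use this half-open convention, which makes episodes
pairwise disjoint and gives every intake image exactly one home (before
filtering).

Defaults: `merge_gap = 60 s`, `min_images = 1`. Sixty seconds tolerates
short within-meal pauses (a few missed captures at a 15 s cadence) without
bridging genuinely separate eating occasions; both are parameters, not
claims, and are exposed on the API and CLI. The gap definition and the
filter-after-merge order are this package's choices; the unit tests pin them
against an independent brute-force oracle (enumerate runs, merge pairwise to
fixpoint, then filter) over randomized label sequences.

Review-efficiency metrics count the images *inside episode boundaries* as
"detected" (that is what an annotator is steered to), and carry the count of
individually intake-labeled images alongside, since the two differ once
merging spans non-intake captures. `pct_reviewed + pct_reduction = 100`
holds exactly before display rounding; displayed percentages round half away
from zero to integers, while machine-readable output keeps full precision.

## Food-composition databases

Each supported CSV dialect (USDA-SR-like, FNDDS-like, branded-products-like,
FAO-table-like) is described by a declarative column map — id, description,
group, energy column and unit, nutrient columns with units, and the paired
portion-description/portion-weight columns — shipped as package data and
extensible by a user YAML with the same shape. Loading is lossless for
well-formed rows; rows lacking an id, a description, or a parseable
non-negative energy value are skipped and counted by reason. Energy must be
present because every downstream summary is energy-led; it is standardized
to kilocalories at load time (1 kcal = 4.184 kJ, applied as an exact
rational). Other nutrient values stay in their database-native units with a
unit string; no cross-database standardization is attempted, since national
tables largely describe composite local recipes. Number parsing accepts
thousands separators and simple fractions; any other non-numeric cell
becomes an explicitly *missing* value, never zero.

Search ranks case-insensitively in four tiers — exact description match,
prefix, all query tokens present, raw substring — with ties broken by
(database priority, food id), so identical queries always return identical
orderings. The tier scheme is this package's design choice. A `gram`
portion (1 g per unit) is synthesized for every record whose source lacks
one, so any food can be quantified in grams directly.

## Consumed-amount and nutrient arithmetic

For an item served as amount *a* of portion *p* (gram weight `w_p`) with
leftover *b* of portion *q*:

* consumed amount = `(a·w_p − b·w_q) / w_p`, expressed in the initial
  portion's units. When `p = q` this reduces exactly to `a − b` (one cup
  minus a third of a cup is two thirds of a cup); routing through grams
  merely generalizes the subtraction to mixed units.
* consumed grams `g = a·w_p − b·w_q`; a leftover exceeding the initial in
  grams is a validation error.
* energy and each stated nutrient scale linearly: `x_consumed = x_100g ·
  g / 100`.

All amounts, gram weights, and nutrient values are `fractions.Fraction`s:
annotators enter fractions ("1/3"), and exact arithmetic makes the
conservation property — item totals = episode totals = daily totals —an
identity rather than a tolerance. Floats appear only at the reporting edge
(grams/kcal/nutrients at 2 decimals, amounts at 4 significant digits).
Nutrients missing from a source record are excluded from sums and surfaced
as completeness flags at every aggregation level. Database-usage statistics
count each annotated item by its source database; percentages are of all
annotated items.

## Annotation model

AEEps carry a free-text meal label (breakfast/lunch/dinner/snack are
conventions, not an enumeration), optional explicit start/end, linked image
ids (set semantics), and food items. Times left unset auto-populate from the
linked images — earliest timestamp to latest plus one capture interval — and
re-linking the same set is idempotent; explicitly set times are never
overwritten by linking. AEEps may overlap in time and an image may be linked
to two AEEps (a drink can span a meal); both situations produce a warning,
not an error. The time-link lookup resolves any instant within the day to
the image captured at or before it, the SDEEp containing it, and the AEEps
containing it.

Annotations persist as versioned JSON with the project embedded, fraction
amounts serialized losslessly, and derived consumed quantities stored so a
reload is field-identical without needing the database registry. A schema
version other than the current one, or a truncated file, is a format error.
Interactive review is replaced by a batch *annotation script* (JSON) of
SDEEp verdicts and AEEp/item commands.

## Synthetic data

The generator produces the two inputs everything else consumes.

*Toy databases.* A seeded ground-truth table (description, group, integer
kcal per 100 g, one-decimal macronutrients, optional micronutrients missing
with probability 0.15, one to three household portions) is encoded into any
dialect, so dialect-equivalence is testable field by field. The branded
encoding stores energy in kJ and the SR encoding writes thousands
separators for values ≥ 1000, deliberately exercising the loader.

*Simulated days.* Defaults mirror the deployment regime this engine was
built around: a 15 s capture interval over a 45,135 s day (3,009 images)
with three true episodes of 900/1,260/900 s — 204 in-episode images, i.e. a
6.78 % review fraction. Labels are independent per-image Bernoulli draws:
probability `1 − fn_rate` of a 1 inside a true episode, `fp_rate` outside.
Episode offsets snap to the capture grid and ground truth is returned in the
segmenter's boundary convention, so noise-free recovery is exact by
construction — that equality is a correctness check of the segmentation
path, not an empirical claim. What the simulator does **not** model: blur
and lighting, correlated classifier errors (real misclassifications cluster
in time), irregular capture cadence, and annotator behaviour. Passing tests
therefore validate the bookkeeping and arithmetic of the pipeline, not
real-world detection accuracy.

The episode evaluator matches detected to true episodes by temporal overlap
(any overlap by default; optionally requiring a minimum fraction of the
shorter interval) and reports episode-level precision/recall/F1 plus
per-image occupancy confusion counts. Undefined precision (nothing
detected) or recall (no truth) is reported as 0 with a cleared
`*_defined` flag.

## Numerical and degenerate-input choices

* Display rounding: half away from zero; durations render `hh:mm:ss`.
* Zero consumed grams yields an all-zero vector with no completeness flags.
* All-zero label streams yield an empty episode list, not an error; review
  metrics over zero images raise.
* Duplicate food ids within one CSV keep the first row and count the rest.
* Food ids sort as strings in search tie-breaks (source-native ids are
  opaque text).
* Timestamps are timezone-aware ISO 8601 throughout; comparisons use
  instants.

## Problem sizes used in the checked examples

The test suite and the reproduction script work at these scales, chosen to
exercise the properties at full day realism while staying quick: 1,000
random label sequences of length 10–5,000 against the segmentation oracle;
100 randomly annotated days for exact conservation and export fidelity;
20 noise-free plus 200 noisy simulated days (fp = 0.02, fn = 0.17) for
recovery and recall, with the recall band derived from the per-episode
probability `1 − fn^k` of at least one surviving intake label.

## Known limitations

* Portion estimation is the annotator's; nothing infers amounts from pixels.
* No nutrient imputation or recipe decomposition; totals over incomplete
  nutrients are flagged, not corrected.
* Cross-database duplicates are not reconciled — the same food in two
  registered databases appears twice in search, distinguished by source.
* The in-memory registry holds full databases; the design targets
  study-sized tables (10²–10⁵ rows), not streaming use.
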
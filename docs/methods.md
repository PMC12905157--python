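# Methods

This note records the exact computational conventions of the crosswalk
analysis, the rationale for the defaults, and the scope of what the
synthetic-data checks do and do not establish.

## 1. Inputs and preprocessing

**Schema flattening.** Each metadata model is reduced to a long table
with one row per (class, property). Two dialects are supported: a
canonical TSV (columns `model`, `class`, `property`, `requirement`,
`range_kind`, optional `vocabulary`) and LinkML-style YAML. For LinkML,
slots are resolved through `is_a` inheritance and mixins with
class-level `slot_usage` overrides taking precedence; the tree root and
mixin classes themselves are not emitted. Requirement levels map
`required: true` → `required`, `recommended: true` → `recommended`,
anything else → `optional`. Range kinds are derived in this order:
ontology annotation → `ontology`; `pattern` → `pattern`; enum range →
`controlled_vocabulary`; `boolean`/`integer` ranges as themselves; a
class-valued range → `not_controllable`; otherwise `free_text`.
Circular or dangling inheritance is a hard error, not a warning.

**Exclusion rules.** Rules have a category (`non_defined`, `linking`,
`framework_specific`), a glob matcher (`fnmatch`), and an optional
`Class.property` scope. Rules apply in order with first-match
precedence. Filtering partitions a table exactly (every record is
included or excluded, never both, never dropped), is idempotent, and is
monotone in the rule list; these invariants are property-tested.
Exclusion counts *e(C)* are retained per class because they enter the
coverage denominator.

## 2. Coverage statistics

**Eq. 1 (mappability rate).** For class *C* toward model *i*,
`P(C,i) = m(C,i) / (t(C) − e(C))`. The denominator depends only on the
source-side class: *t* and *e* come from the filter outcome, *m* from
the mapping set. A mapping whose subject is an excluded property is an
integrity error; a class whose properties are all excluded is omitted
with a warning (its rate is undefined). Any SKOS predicate other than
`noMatch` counts as mapped; duplicate records for one subject count
once, with `exactMatch > closeMatch > broadMatch > narrowMatch`
precedence used only to pick a representative object.

**Eq. 2 (forward class means).** The per-class mean over target models:
the sum of `P(C,i)` divided by the number of target models. All target
crosswalks must cover the same class set; a mismatch is an error rather
than a silent NaN.

**Eq. 3 (backward model means).** For each related model, the
unweighted mean of its per-class rates over its included classes. The
number of classes is reported alongside the mean because models differ
in class count.

**Chi-squared.** Matched/unmatched counts per model form a 2×k table
passed to `scipy.stats.chi2_contingency` with `correction=False`:
the classical Pearson statistic, chosen because this kind of analysis
compares more than two groups, where Yates' correction does not apply; a
warning is attached when any expected count is below 5.

**Standard classes and Kruskal–Wallis.** Class-level rates are grouped
into four standard classes via a configurable map. Aggregation within a
standard class is **pooled** by default (`Σm / Σ(t−e)`), because the
per-class denominators vary widely and a mean of rates would let tiny
classes dominate; `mean` aggregation is available as an option. Groups
of per-model pooled rates are compared with `scipy.stats.kruskal`
(chi-squared approximation to H's null distribution, the standard
small-sample convention). If every observation across groups is the same
constant the test is degenerate; we return H = 0, p = 1 with a warning
instead of propagating scipy's error.

## 3. Consensus properties

The presence–absence matrix has one row per included source property and
one boolean column per related model (true iff some non-`noMatch`
forward record maps it into that model). Rows are sorted by class then
property so outputs are byte-stable. A property is consensus at
threshold *k* if its row sum is ≥ *k*; the default *k* = 3 of 4 related
models requires a majority without demanding unanimity, which would be
overly sensitive to a single sparse model. Consensus properties are
classified by range kind: `controlled_vocabulary`, `ontology`,
`pattern`, `boolean`, `integer` are *controllable*; `free_text` and
`not_controllable` are *descriptive*; missing range kinds are reported
as *unspecified*, never silently lumped.

## 4. Information-gap complexes

A related-model property is **unmapped** when all of its backward
records are `noMatch`. A property with both a match and a `noMatch`
record is treated as mapped with an integrity warning; an included
property with no record at all is treated as unmapped with a warning
(missing curation must surface, not vanish). Cross-mappings among
unmapped properties define an undirected graph; complexes are its
connected components (transitive closure — curators need not map every
pair). Self-referential records are retained as annotations but never
create edges. The complex label is the lexicographically first curated
comment, falling back to the lexicographically smallest member property
name. `all_required` is true iff every member with a *specified*
requirement is required; it is vacuously true when no member specifies
one, and the membership table carries the raw requirements so a reader
can tell the two cases apart. The headline boolean asks whether any
complex spans all related models with all members required.

## 5. Synthetic generator

The generator draws a latent pool of concepts, assigns each model a
random subset (per-model sharing probability), partitions each model's
concepts into classes, renders property names as lexical variants, and
injects excluded bookkeeping properties (`alias`, `attributes`,
`ega accession`) matched by the bundled synthetic ruleset. Curated
mapping sets are derived from the latent structure with a per-source
dropout rate that turns true matches into `noMatch` records — the model
of imperfect curation. Cross-mapping edges chain the properties of each
concept absent from the source model. All draws come from one
`numpy.random.default_rng(seed)`; identical configs yield byte-identical
files.

Defaults (5 models, concept pool 120, sharing 0.55, 8–12 classes,
requirement distribution 0.45/0.20/0.25/0.10 over
required/recommended/optional/unspecified, injection rate 0.25,
predicate distribution 0.7/0.2/0.05/0.05 over
exact/close/broad/narrow, dropout 0.05) were fixed before any acceptance
run and produce mid-range coverage with non-trivial consensus and gap
structure.

**What the synthetic checks establish.** At zero dropout the pipeline
provably recovers the planted consensus set and the exact gap-complex
partition, and every coverage cell equals a record-by-record brute-force
recount — i.e. the *counting* is correct. Recall degrades monotonically
with dropout, as it must. These checks validate the machinery, not any
claim about real metadata models: real coverage numbers depend entirely
on the curated mappings supplied.

**Reference scenario.** `reference_scenario_config(seed)` emulates a
realistic study regime: the source model carries every concept
(sharing 1.0), the four related models share uniformly (0.45), and
curation dropout is heterogeneous per related model
(0.03/0.21/0.29/0.60). Uniform target sharing makes forward mappability
homogeneous (chi-squared non-significant), while heterogeneous dropout
makes backward mappability differ strongly (p ≪ 0.001) with mean
coverages near 0.99/0.72/0.63/0.37 — the qualitative signature of a
source model designed as a superset of its ecosystem. The parameters
were chosen from this structural argument, not tuned against outputs.
Because the source contains all concepts, this scenario's cross set is
empty and its gap complexes are singletons; multi-model complexes are
exercised by the default configuration instead.

## 6. Numerical conventions

* All rates are kept as exact floats of integer ratios; rounding to
  percentages happens only at presentation (reports, CLI messages).
* JSON outputs are written with sorted keys, two-space indent and a
  trailing newline; TSVs without index columns — reruns are
  byte-identical.
* SSSOM files round-trip byte-stably: read → write reproduces the file,
  with predicate/justification tokens normalised to their canonical
  prefixed forms on first write.
* Seeds are integers below 2³¹; sub-seeds are drawn from a
  `default_rng` stream of the top-level seed.

## 7. Limitations

* The LinkML reader covers the subset of the dialect used by typical
  archive schemas (classes, slots, is_a, mixins, slot_usage, enums,
  pattern and ontology annotations); it is not a full LinkML validator.
* Statistical tests inherit scipy's small-sample caveats; expected-count
  warnings are attached but the tests still run.
* The synthetic generator models curation error only as independent
  dropout; correlated curator effects are out of scope.
* Headline numbers of any particular published study can only be checked
  with that study's deposited data converted to the canonical formats
  (see the README's reproduction section).
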
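# Methods

## Evidence model

The pipeline consumes four tab-separated tables shaped like the AACT
(Aggregate Analysis of ClinicalTrials.gov) export subset relevant to
disease–target inference: `studies` (NCT ID, study type, intervention type,
start/completion dates), `study_references` (NCT ID, PMID, reference type,
citation), `study_drug_targets` (NCT ID, drug name, structure identifiers,
UniProt, gene symbol, TDL) and `study_diseases` (NCT ID, DOID, disease
name). The pipe-delimited AACT export flavour is supported via
`dialect="aact_pipe"`. Named-entity recognition and compound→target
mapping are out of scope: the drug-target and disease annotation tables are
consumed as given.

Only interventional drug studies contribute evidence; observational and
non-drug studies are filtered out (each filter can be relaxed by flag).
The join crosses every disease annotation of an eligible trial with every
drug-target annotation of the same trial, and replicates the resulting row
once per linked publication so that provenance is complete at row level.
All downstream metrics deduplicate (trials by NCT ID, publications by PMID,
drugs by normalized name), so replication can never inflate a count — a
property the test suite checks directly. Annotation rows pointing at an
unknown NCT ID are skipped and tallied in a skip report rather than
failing the run, since partial registry extracts are common.

Drug names are normalized by lowercasing and whitespace-collapsing before
distinct-counting; registry drug naming is highly synonymous and
case/spacing variants are the cheapest class of duplicate to remove.
No structure-based (SMILES/InChIKey) deduplication is attempted.

## Recency weighting (nStudyNewness)

Each trial of age `t` years contributes `w = 2·exp(−t/h)`; the half-life is
`h = 5` years for trials at most 10 years old and `h = 10` years for older
trials, and the pair's `nStudyNewness` is the sum of `w` over its distinct
trials. A trial's age is anchored on its completion date, falling back to
the start date for trials without one; trials with neither date still count
toward `nStud` but are excluded from `nStudyNewness` with a warning, since
the decay needs an age. Ages are measured in days divided by 365.25 and
floored at zero (future-dated completion dates occur in real registries).

Two deliberate literalisms deserve a note. First, the piecewise half-life
is discontinuous at `t = 10`: the weight is `2e^{-2} ≈ 0.271` at exactly 10
years but `≈ 2e^{-1} ≈ 0.736` just beyond, so a slightly-older trial is
rewarded. The rule is implemented exactly as stated rather than smoothed,
and both branches plus the jump are pinned by tests; anyone wanting a
continuous schedule can set `h_recent = h_old`. Second, the "as of" date
defaults to `"auto"`, which resolves to the latest reference date among
the loaded studies — this keeps runs reproducible with no wall-clock
dependence; an explicit snapshot date can be passed instead
(`--as-of YYYY-MM-DD`).

## Publication weighting (nPublicationWeighted)

Study–publication links carry a reference type: RESULT (direct findings,
weight 1.0), BACKGROUND (context, 0.5), DERIVED (secondary findings, 0.25).
A publication attached to a pair under several types counts once at its
maximum weight. References without a PMID remain visible in provenance but
are excluded from `nPub` and the weighted sum — without an identifier they
cannot be deduplicated. Unknown reference-type strings are reported at
parse time and mapped to the lowest (DERIVED) weight at scoring time rather
than raising: registry data is noisy, and undervaluing a stray row is the
conservative failure mode. Publications are not themselves time-decayed;
only studies are.

## Rank aggregation

All six metrics are ranked descending over the pair table with averaged
ties; averaging keeps each metric's rank sum at exactly `N(N+1)/2`, so tied
groups are not biased in either direction. The mean of the six ranks is
converted to an ascending percentile and subtracted from 100, yielding a
score in `[0, 100)` on which the best-evidenced pair scores highest
(`100·(1−1/N)` when unique). Output ties are broken lexicographically by
(DOID, gene symbol), making the table deterministic and invariant to input
row order.

Ranking is global over the whole pair table by default; a per-disease view
is a filter of the global table, but `per_disease=True` (or
`--per-disease`) instead restricts the rank pool to each disease's own
pairs for users who want within-query percentiles. Ranking `nDiseases`
descending means multi-disease genes rank better, which cuts against
target specificity; the direction is kept as specified for all six metrics
but is configurable per metric via `ascending_metrics`.

Scores are serialized with 5 decimal places.

## Validation

Inferred (DOID, gene) associations are expanded through a DOID↔CUI
crosswalk into (CUI, gene) space — one output pair per mapped CUI,
deduplicated, with unmapped DOIDs dropped and counted. Both sides are then
restricted to the CUIs they share before anything is counted, and the
report gives per-side association and gene counts, the overlap, and the
percentage of the right-hand (external reference) set recovered, rounded
to 2 decimal places. Gene symbols are uppercased on both sides, as symbol
case is the dominant source of spurious mismatch. When a CUI maps back to
several DOIDs no back-projection is attempted; comparison happens purely
in CUI space. The report also exposes the complementary share of
left-hand associations absent from the reference set, since "unique to the
inferred set" can be read against either side.

## Synthetic corpus generator

The generator emits the complete file layout the pipeline consumes. Its
defaults describe a desk-scale registry slice: 500 trials with dates drawn
uniformly over 1995–2024 (so both decay branches are exercised), 20
diseases, 50 genes, 60 drugs each targeting one gene, 10% observational
trials, 5% non-drug interventions, 5% undated trials, Poisson(1.2)
references per trial with a 0.3/0.5/0.2 RESULT/BACKGROUND/DERIVED mix and
5% of references lacking PMIDs. Planted (disease, gene, strength) pairs
receive `strength` dedicated recent trials with RESULT-heavy references, so
a 10× planted pair should dominate every metric within its disease. Each
table draws from its own random stream spawned from the master seed, so
adding a table never perturbs the others, and a fixed seed yields
byte-identical files. A JSON manifest records every planted pair and its
trial IDs.

What the generator does not emulate: real AACT free-text fields, true drug
polypharmacology (each synthetic background drug targets exactly one gene),
the registry's historical growth curve, or realistic disease co-annotation
structure. Passing the planted-signal tests therefore shows that the
ranking recovers strong multi-metric evidence against diffuse background —
not that it is robust to the correlated annotation noise of real registry
extracts.

## Numerical and degenerate-input choices

- Ages in years use the mean Julian year (365.25 days).
- Empty metric inputs are exact zeros (empty newness/publication sums);
  an empty pair table or empty rank input is a hard error.
- A single-pair table scores 0 (its percentile is 100) — the score is a
  relative quantity and says nothing in isolation.
- Percentages with a zero denominator report 0 rather than raising.
- Enum parsing is case-insensitive; malformed dates and unknown enum values
  are reported with 1-based row numbers and treated as absent/verbatim.

## Problem sizes

The bundled checks run on generated corpora of 120–510 trials producing
roughly 100–550 scored pairs, with the planted-signal check repeated over
20 seeds; these sizes give stable rank behaviour while keeping the whole
suite interactive. The acceptance script uses a ~300-trial corpus yielding
about 100 pairs.
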
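# trialtarget

Scoring and ranking of disease–target associations inferred from aggregated
clinical-trial evidence.

Clinical trial registries (ClinicalTrials.gov, via its relational AACT
export) implicitly link diseases to protein targets: a trial tests a drug,
the drug engages one or more protein-coding genes, and the trial is
annotated with the diseases it studies. `trialtarget` materialises those
links as evidence rows, aggregates them into per-pair metrics, and ranks
every (disease, gene) pair on a 0–100 scale so that the best-supported
associations surface first. It is aimed at target-illumination work: finding
understudied but evidence-backed proteins worth a closer look for a given
disease.

## The scoring model

For each disease–gene pair *j*, six evidence metrics are computed from the
deduplicated evidence rows:

- `nStud`, `nPub`, `nDrug` — distinct trials, publications (by PMID), and
  normalized drug names supporting the pair;
- `nDiseases` — distinct diseases linked to the gene anywhere in the corpus;
- `nStudyNewness` — recency-weighted trial count. A trial of age *t* years
  contributes `w = 2·exp(−t/h)`, with half-life `h = 5` years for trials at
  most 10 years old and `h = 10` years for older ones;
- `nPublicationWeighted` — publications weighted by reference type
  (RESULT 1.0, BACKGROUND 0.5, DERIVED 0.25), each PMID counted once at its
  maximum weight.

Each metric *m* is ranked descending over all pairs (ties averaged), giving
ranks `R_{m,j}`. With `K = 6` metrics and `N` pairs:

```
meanRank_j           = (1/K) · Σ_m R_{m,j}
percentileMeanRank_j = Rank(meanRank_j) / N · 100      (ascending)
meanRankScore_j      = 100 − percentileMeanRank_j
```

so the pair with the strongest aggregate evidence has the highest
`meanRankScore` (at most `100·(1 − 1/N)`).

An agreement-based validation step projects the inferred (DOID, gene)
associations into UMLS CUI space through a DOID↔CUI crosswalk and compares
them, restricted to shared CUIs, against an external curated (CUI, gene)
reference set, reporting the overlap count and the percentage of the
reference set recovered.

## Worked example

Generate a seeded synthetic corpus (120 trials, one disease–gene pair
planted with 10 dedicated recent trials), score it, and validate against the
bundled external reference set:

```
$ trialtarget synth --seed 1 --n-studies 120 --planted "DOID:2,GENE:5,x10" --out-dir demo
wrote 700 rows across 6 tables to demo

$ trialtarget score --studies demo/studies.tsv --references demo/study_references.tsv \
    --drug-targets demo/study_drug_targets.tsv --diseases demo/study_diseases.tsv \
    --out-dir demo/out
150 pairs scored; top: DOID:1007 GENE009 meanRankScore=99.33333
```

The head of `demo/out/associations.tsv` (columns abridged):

```
doid       gene_symbol  nStud  nPub  nStudyNewness  nPublicationWeighted  meanRankScore
DOID:1007  GENE009      2      4     0.91295        2.50000               99.33333
DOID:1002  GENE005      10     24    16.87697       21.00000              98.66667
DOID:1009  GENE005      3      2     0.97517        1.00000               98.00000
```

The planted pair (DOID:1002, GENE005) dominates the raw evidence — 10
trials, 24 publications, `nStudyNewness` 16.9 — and lands in the top three
of 150 pairs globally (rank 1 within its own disease); with
`score --per-disease` ranking is restricted to each disease's pairs.

```
$ trialtarget validate --associations demo/out/associations.tsv \
    --crosswalk demo/doid_cui.tsv --external demo/external_associations.tsv \
    --out-dir demo/val
20 shared CUIs; 11 overlapping associations (21.57% of the external set)
```

`demo/val/overlap_report.json` holds the full report (per-side association
and gene counts over shared CUIs, overlap, percentage recovered, and the
share of inferred associations absent from the reference set).

Every subcommand writes a `run_manifest.json` with the resolved
configuration, input digests and row counts. `trialtarget provenance
--doid ... --gene ...` dumps the trial/publication rows behind any single
association.

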
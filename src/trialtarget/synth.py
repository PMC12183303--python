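"""Seeded generator of AACT-shaped fixture tables with planted signal.

The generator emits the full file layout the pipeline consumes — studies,
study references, drug-target links, study-disease links, a DOID<->CUI
crosswalk and an external (cui, gene) association table — plus a JSON
manifest recording every planted disease-gene pair. Background evidence
is sparse and diffuse (most pairs rest on one or two trials); planted
pairs receive a configurable multiple of dedicated recent trials with
RESULT-heavy references, so they should dominate every evidence metric
and surface at the top of the ranking. Each table draws from its own
random stream spawned from the master seed, so adding one table never
perturbs the others and a fixed seed yields byte-identical files.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from .evidence import (
    DrugTargetLink,
    InterventionType,
    ReferenceRecord,
    ReferenceType,
    StudyDiseaseLink,
    StudyRecord,
    StudyType,
    TDL,
    write_table,
)

_REF_TYPES = (ReferenceType.RESULT, ReferenceType.BACKGROUND, ReferenceType.DERIVED)
_TDLS = (TDL.Tclin, TDL.Tchem, TDL.Tbio, TDL.Tdark)
_TDL_PROBS = (0.2, 0.35, 0.33, 0.12)


@dataclass(frozen=True)
class SynthConfig:
    """Shape of the synthetic corpus.

    Defaults emulate a desk-scale registry slice: a few hundred trials
    over three decades (so both decay half-life branches are exercised),
    a modest disease and gene vocabulary, ~10% observational studies, and
    on average a little over one linked publication per study with a
    RESULT/BACKGROUND/DERIVED mix dominated by background references.
    ``planted_pairs`` lists (disease index, gene index, strength): a
    strength-s pair receives s dedicated recent trials on top of any
    background evidence.
    """

    seed: int = 0
    n_studies: int = 500
    n_genes: int = 50
    n_diseases: int = 20
    n_drugs: int = 60
    frac_observational: float = 0.1
    frac_nondrug: float = 0.05
    frac_undated: float = 0.05
    date_range: tuple[int, int] = (1995, 2024)
    refs_per_study: float = 1.2  # Poisson mean
    type_mix: tuple[float, float, float] = (0.3, 0.5, 0.2)  # RESULT, BACKGROUND, DERIVED
    planted_pairs: tuple[tuple[int, int, float], ...] = ()
    frac_planted_external: float = 0.8
    n_external_noise: int = 50

    def __post_init__(self) -> None:
        if abs(sum(self.type_mix) - 1.0) > 1e-9:
            raise ValueError("type_mix probabilities must sum to 1")
        for frac in (self.frac_observational, self.frac_nondrug, self.frac_undated, self.frac_planted_external):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        for di, gi, s in self.planted_pairs:
            if not (0 <= di < self.n_diseases and 0 <= gi < self.n_genes):
                raise ValueError(f"planted pair ({di}, {gi}) outside disease/gene range")
            if s <= 0:
                raise ValueError("planted strength must be positive")


def doid_label(i: int) -> str:
    return f"DOID:{1000 + i}"


def gene_label(j: int) -> str:
    return f"GENE{j:03d}"


def cui_label(i: int) -> str:
    return f"C{7000000 + i:07d}"


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _random_date(rng: np.random.Generator, lo: date, hi: date) -> date:
    return lo + timedelta(days=int(rng.integers(0, (hi - lo).days + 1)))


def _inchikey(rng: np.random.Generator) -> str:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    pick = lambda n: "".join(letters[k] for k in rng.integers(0, 26, n))
    return f"{pick(14)}-{pick(10)}-N"


def generate(config: SynthConfig, out_dir: str | Path) -> dict:
    """Write the fixture tables under ``out_dir`` and return the manifest.

    Files written: studies.tsv, study_references.tsv,
    study_drug_targets.tsv, study_diseases.tsv, doid_cui.tsv,
    external_associations.tsv, manifest.json.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lo = date(config.date_range[0], 1, 1)
    hi = date(config.date_range[1], 12, 31)

    # Drugs: each targets one gene (round-robin), plus one dedicated drug per planted pair.
    rng_drug = _rng(config.seed, 1)
    drug_gene: list[tuple[str, int]] = [
        (f"drug {k:03d}", k % config.n_genes) for k in range(config.n_drugs)
    ]
    drug_meta = {
        name: (
            "C" * (1 + k % 12),
            _inchikey(rng_drug),
            f"P{10000 + gi:05d}",
            _TDLS[rng_drug.choice(len(_TDLS), p=_TDL_PROBS)],
        )
        for k, (name, gi) in enumerate(drug_gene)
    }
    planted_drugs: dict[tuple[int, int], str] = {}
    for di, gi, _ in config.planted_pairs:
        name = f"planted drug {di:02d} {gi:03d}"
        planted_drugs[(di, gi)] = name
        drug_meta[name] = ("C" * 6, _inchikey(rng_drug), f"P{10000 + gi:05d}", TDL.Tbio)

    # Background studies with their disease and drug links.
    rng_study = _rng(config.seed, 2)
    rng_link = _rng(config.seed, 3)
    studies: list[StudyRecord] = []
    drug_links: list[DrugTargetLink] = []
    disease_links: list[StudyDiseaseLink] = []
    interventional_ncts: list[str] = []

    for i in range(config.n_studies):
        nct = f"NCT{10000000 + i:08d}"
        observational = rng_study.random() < config.frac_observational
        nondrug = (not observational) and rng_study.random() < config.frac_nondrug
        undated = rng_study.random() < config.frac_undated
        start = _random_date(rng_study, lo, hi)
        completion = start + timedelta(days=int(rng_study.integers(180, 1500)))
        studies.append(
            StudyRecord(
                nct_id=nct,
                study_type=StudyType.OBSERVATIONAL if observational else StudyType.INTERVENTIONAL,
                intervention_type=InterventionType.OTHER if nondrug else InterventionType.DRUG,
                start_date=None if undated else start,
                completion_date=None if undated else min(completion, hi),
            )
        )
        if not observational and not nondrug:
            interventional_ncts.append(nct)

        n_drugs_here = 1 + int(rng_link.random() < 0.3)
        for k in rng_link.choice(config.n_drugs, size=n_drugs_here, replace=False):
            name, gi = drug_gene[int(k)]
            smiles, ikey, uniprot, tdl = drug_meta[name]
            drug_links.append(
                DrugTargetLink(
                    nct_id=nct, drug_name=name, gene_symbol=gene_label(gi),
                    smiles=smiles, inchikey=ikey, uniprot=uniprot, tdl=tdl,
                )
            )
        n_dis_here = 1 + int(rng_link.random() < 0.3)
        for d in rng_link.choice(config.n_diseases, size=n_dis_here, replace=False):
            disease_links.append(
                StudyDiseaseLink(nct_id=nct, doid=doid_label(int(d)), disease_name=f"disease {int(d):02d}")
            )

    # Planted studies: recent, interventional, one dedicated drug, one disease.
    rng_plant = _rng(config.seed, 4)
    recent_lo = max(lo, hi - timedelta(days=int(5 * 365.25)))
    planted_ncts: dict[tuple[int, int], list[str]] = {}
    counter = config.n_studies
    for di, gi, strength in config.planted_pairs:
        n_extra = max(1, round(strength))
        planted_ncts[(di, gi)] = []
        for _ in range(n_extra):
            nct = f"NCT{10000000 + counter:08d}"
            counter += 1
            start = _random_date(rng_plant, recent_lo, hi)
            studies.append(
                StudyRecord(
                    nct_id=nct,
                    study_type=StudyType.INTERVENTIONAL,
                    intervention_type=InterventionType.DRUG,
                    start_date=start,
                    completion_date=min(start + timedelta(days=365), hi),
                )
            )
            name = planted_drugs[(di, gi)]
            smiles, ikey, uniprot, tdl = drug_meta[name]
            drug_links.append(
                DrugTargetLink(
                    nct_id=nct, drug_name=name, gene_symbol=gene_label(gi),
                    smiles=smiles, inchikey=ikey, uniprot=uniprot, tdl=tdl,
                )
            )
            disease_links.append(
                StudyDiseaseLink(nct_id=nct, doid=doid_label(di), disease_name=f"disease {di:02d}")
            )
            planted_ncts[(di, gi)].append(nct)
            interventional_ncts.append(nct)

    # References: Poisson count per interventional study; planted studies get
    # RESULT-heavy references so the publication metrics also separate.
    rng_ref = _rng(config.seed, 5)
    planted_set = {n for ncts in planted_ncts.values() for n in ncts}
    references: list[ReferenceRecord] = []
    pmid_counter = 30000000
    for s in studies:
        n_refs = int(rng_ref.poisson(config.refs_per_study))
        if s.nct_id in planted_set:
            n_refs = max(n_refs, 2)
        for _ in range(n_refs):
            if s.nct_id in planted_set:
                rtype = ReferenceType.RESULT if rng_ref.random() < 0.7 else ReferenceType.BACKGROUND
            else:
                rtype = _REF_TYPES[rng_ref.choice(3, p=config.type_mix)]
            pmid_counter += 1
            pmid = None if rng_ref.random() < 0.05 else str(pmid_counter)
            year = (s.completion_date or s.start_date or hi).year
            references.append(
                ReferenceRecord(
                    nct_id=s.nct_id,
                    pmid=pmid,
                    reference_type=rtype,
                    citation=f"Author {pmid_counter % 97} et al. ({year}) study of {s.nct_id}.",
                )
            )

    # Crosswalk: every disease gets one CUI; ~10% get a second.
    rng_xw = _rng(config.seed, 6)
    crosswalk: list[tuple[str, str]] = []
    for d in range(config.n_diseases):
        crosswalk.append((doid_label(d), cui_label(d)))
        if rng_xw.random() < 0.1:
            crosswalk.append((doid_label(d), cui_label(1000 + d)))

    # External associations: most planted pairs, plus random noise pairs.
    rng_ext = _rng(config.seed, 7)
    external: set[tuple[str, str, str]] = set()
    for di, gi, _ in config.planted_pairs:
        if rng_ext.random() < config.frac_planted_external:
            external.add((cui_label(di), f"condition {di:02d}", gene_label(gi)))
    while len(external) < len(config.planted_pairs) * config.frac_planted_external + config.n_external_noise:
        di = int(rng_ext.integers(0, config.n_diseases))
        gi = int(rng_ext.integers(0, config.n_genes))
        external.add((cui_label(di), f"condition {di:02d}", gene_label(gi)))

    write_table(studies, "studies", out_dir / "studies.tsv")
    write_table(references, "references", out_dir / "study_references.tsv")
    write_table(drug_links, "drug_targets", out_dir / "study_drug_targets.tsv")
    write_table(disease_links, "diseases", out_dir / "study_diseases.tsv")

    import pandas as pd

    pd.DataFrame(sorted(set(crosswalk)), columns=["doid", "cui"]).to_csv(
        out_dir / "doid_cui.tsv", sep="\t", index=False
    )
    pd.DataFrame(sorted(external), columns=["cui", "condition_name", "gene_symbol"]).to_csv(
        out_dir / "external_associations.tsv", sep="\t", index=False
    )

    manifest = {
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items() if k != "planted_pairs"},
            "planted_pairs": [list(p) for p in config.planted_pairs],
        },
        "planted": [
            {
                "doid": doid_label(di),
                "gene_symbol": gene_label(gi),
                "strength": s,
                "nct_ids": planted_ncts[(di, gi)],
                "expected": "dominates nStud, nStudyNewness and the publication metrics within its disease",
            }
            for di, gi, s in config.planted_pairs
        ],
        "counts": {
            "studies": len(studies),
            "references": len(references),
            "drug_links": len(drug_links),
            "disease_links": len(disease_links),
            "crosswalk": len(set(crosswalk)),
            "external": len(external),
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
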
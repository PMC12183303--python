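"""Per-pair evidence metrics.

Six metrics summarise the evidence behind each disease-gene pair:

* ``nStud`` — distinct trials; ``nPub`` — distinct publications (by PMID);
  ``nDrug`` — distinct normalized drug names; ``nDiseases`` — distinct
  diseases linked to the gene anywhere in the evidence set.
* ``nStudyNewness`` — a recency-weighted study count. Each trial of age
  ``t`` years contributes ``w = 2 * exp(-t / h)`` with half-life ``h = 5``
  years for trials at most 10 years old and ``h = 10`` years for older
  ones, so a brand-new trial counts double and weight decays exponentially
  with age. Note the piecewise half-life makes the weight jump upward just
  past the 10-year threshold; the rule is applied literally (see the
  methods note).
* ``nPublicationWeighted`` — publications weighted by reference type:
  RESULT 1.0 (direct findings), BACKGROUND 0.5 (context), DERIVED 0.25
  (secondary). A publication attached under several types counts once at
  its maximum weight.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

from .evidence import (
    EvidenceRow,
    ReferenceType,
    StudyRecord,
    TDL,
    normalize_drug_name,
)

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


class NoUsableDateError(ValueError):
    """The study has neither a completion nor a start date."""


@dataclass(frozen=True)
class DecayConfig:
    """Half-life schedule for the recency weight, in years."""

    h_recent: float = 5.0
    h_old: float = 10.0
    age_threshold: float = 10.0
    as_of_date: date | str = "auto"

    def __post_init__(self) -> None:
        if self.h_recent <= 0 or self.h_old <= 0 or self.age_threshold <= 0:
            raise ValueError("half-lives and age threshold must be positive")


@dataclass(frozen=True)
class ReferenceWeights:
    """Per-reference-type publication weights, highest for direct findings."""

    result: float = 1.0
    background: float = 0.5
    derived: float = 0.25

    def __post_init__(self) -> None:
        for w in (self.result, self.background, self.derived):
            if not 0 < w <= 1:
                raise ValueError("weights must lie in (0, 1]")
        if not self.result >= self.background >= self.derived:
            raise ValueError("expected result >= background >= derived")


METRIC_NAMES = ("nDiseases", "nDrug", "nStud", "nPub", "nStudyNewness", "nPublicationWeighted")


@dataclass(frozen=True)
class PairMetrics:
    doid: str
    gene_symbol: str
    nDiseases: int
    nDrug: int
    nStud: int
    nPub: int
    nStudyNewness: float
    nPublicationWeighted: float
    drugs: tuple[str, ...] = ()
    tdl: TDL | None = None
    disease_name: str = ""
    uniprot: str | None = None

    def metric_vector(self) -> dict[str, float]:
        return {m: float(getattr(self, m)) for m in METRIC_NAMES}


def resolve_as_of(studies: Iterable[StudyRecord], config: DecayConfig) -> date:
    """Resolve the "as of" snapshot date.

    ``"auto"`` picks the latest reference date (completion, else start)
    across the loaded studies, so ages are reproducible without a
    wall-clock dependence.
    """
    if isinstance(config.as_of_date, date):
        return config.as_of_date
    dates = [s.reference_date for s in studies if s.reference_date is not None]
    if not dates:
        raise NoUsableDateError("no study carries a date; cannot resolve as_of_date='auto'")
    return max(dates)


def study_age(study: StudyRecord, as_of: date) -> float:
    """Age of a study in years at ``as_of``, floored at zero.

    The completion date anchors the age; studies still marked as ongoing
    fall back to their start date. Future-dated studies count as age 0.
    """
    ref = study.reference_date
    if ref is None:
        raise NoUsableDateError(f"study {study.nct_id} has no usable date")
    return max(0.0, (as_of - ref).days / DAYS_PER_YEAR)


def decay_weight(t: float, config: DecayConfig = DecayConfig()) -> float:
    """Recency weight ``2 * exp(-t/h)`` with the piecewise half-life schedule."""
    if t < 0:
        raise ValueError(f"study age must be non-negative, got {t}")
    h = config.h_recent if t <= config.age_threshold else config.h_old
    return 2.0 * math.exp(-t / h)


def n_study_newness(ages: Iterable[float], config: DecayConfig = DecayConfig()) -> float:
    """Sum of decay weights over a pair's unique studies (empty sum is 0)."""
    return sum(decay_weight(t, config) for t in ages)


def reference_weight(
    reference_type: ReferenceType | str | None,
    weights: ReferenceWeights = ReferenceWeights(),
) -> float:
    """Weight of a single study-publication link by its reference type.

    Unrecognized type strings are conservatively given the lowest (DERIVED)
    weight with a warning: registry exports are noisy and a hard failure on
    one stray row would be disproportionate.
    """
    if isinstance(reference_type, ReferenceType):
        return {
            ReferenceType.RESULT: weights.result,
            ReferenceType.BACKGROUND: weights.background,
            ReferenceType.DERIVED: weights.derived,
        }[reference_type]
    logger.warning("unknown reference type %r; using the DERIVED weight", reference_type)
    return weights.derived


def n_publication_weighted(
    refs: Iterable[tuple[str, ReferenceType | str]],
    weights: ReferenceWeights = ReferenceWeights(),
) -> float:
    """Reference-type-weighted publication score for one pair.

    Publications are deduplicated by PMID, keeping the maximum weight when
    the same publication is attached under several reference types.
    """
    best: dict[str, float] = {}
    for pmid, rtype in refs:
        w = reference_weight(rtype, weights)
        if w > best.get(pmid, 0.0):
            best[pmid] = w
    return sum(best.values())


def attach_study_ages(
    evidence: Sequence[EvidenceRow],
    studies: Sequence[StudyRecord],
    config: DecayConfig = DecayConfig(),
) -> list[EvidenceRow]:
    """Fill ``study_age_years`` on evidence rows from the studies table.

    Rows whose study carries no date keep ``study_age_years=None`` (they
    still count toward nStud but are excluded from nStudyNewness) with a
    warning per affected study.
    """
    as_of = resolve_as_of(studies, config)
    by_nct = {s.nct_id: s for s in studies}
    ages: dict[str, float | None] = {}
    out = []
    for row in evidence:
        if row.nct_id not in ages:
            study = by_nct.get(row.nct_id)
            if study is None or study.reference_date is None:
                logger.warning("study %s has no usable date; excluded from nStudyNewness", row.nct_id)
                ages[row.nct_id] = None
            else:
                ages[row.nct_id] = study_age(study, as_of)
        out.append(dataclasses.replace(row, study_age_years=ages[row.nct_id]))
    return out


def compute_pair_metrics(
    evidence: Sequence[EvidenceRow],
    decay: DecayConfig = DecayConfig(),
    weights: ReferenceWeights = ReferenceWeights(),
    studies: Sequence[StudyRecord] | None = None,
) -> list[PairMetrics]:
    """Aggregate evidence rows into the six metrics per (disease, gene) pair.

    Every count deduplicates the replicated provenance rows: trials by
    NCT ID, publications by PMID (references without a PMID stay in
    provenance but do not count toward nPub), drugs by normalized name.
    ``nDiseases`` counts the distinct diseases linked to the gene across
    the whole evidence set, so it is constant across a gene's pairs.
    Pairs with no references are still emitted (nPub = 0).

    Pass ``studies`` to have ages attached on the fly when the evidence
    rows do not carry them yet.
    """
    if studies is not None:
        evidence = attach_study_ages(evidence, studies, decay)

    doids_per_gene: dict[str, set[str]] = {}
    for row in evidence:
        doids_per_gene.setdefault(row.gene_symbol, set()).add(row.doid)

    groups: dict[tuple[str, str], list[EvidenceRow]] = {}
    for row in evidence:
        groups.setdefault((row.doid, row.gene_symbol), []).append(row)

    out: list[PairMetrics] = []
    for (doid, gene), rows in sorted(groups.items()):
        ncts = {r.nct_id for r in rows}
        ages = {r.nct_id: r.study_age_years for r in rows if r.study_age_years is not None}
        pubs = [(r.pmid, r.reference_type) for r in rows if r.pmid]
        drugs = sorted({normalize_drug_name(r.drug_name) for r in rows})
        tdls = [r.tdl for r in rows if r.tdl is not None]
        names = [r.disease_name for r in rows if r.disease_name]
        uniprots = [r.uniprot for r in rows if r.uniprot]
        out.append(
            PairMetrics(
                doid=doid,
                gene_symbol=gene,
                nDiseases=len(doids_per_gene[gene]),
                nDrug=len(drugs),
                nStud=len(ncts),
                nPub=len({p for p, _ in pubs}),
                nStudyNewness=n_study_newness(ages.values(), decay),
                nPublicationWeighted=n_publication_weighted(pubs, weights),
                drugs=tuple(drugs),
                tdl=min(tdls, key=lambda t: list(TDL).index(t)) if tdls else None,
                disease_name=names[0] if names else "",
                uniprot=uniprots[0] if uniprots else None,
            )
        )
    return out
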
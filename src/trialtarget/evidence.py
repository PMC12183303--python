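"""Domain records, table IO and the evidence join.

The evidence model mirrors a small subset of the AACT (Aggregate Analysis of
ClinicalTrials.gov) relational export: one table of studies, one of
study-publication references, and two annotation tables linking studies to
drug targets (via named drugs) and to diseases (via Disease Ontology IDs).
Joining them on the trial identifier yields one evidence row per
(disease, gene, trial, drug[, publication]) tuple — the atomic unit of
provenance that every downstream metric is computed from.
"""
from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, fields as dc_fields
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DOID_PATTERN = re.compile(r"^DOID:\d+$")


class StudyType(str, enum.Enum):
    INTERVENTIONAL = "INTERVENTIONAL"
    OBSERVATIONAL = "OBSERVATIONAL"


class InterventionType(str, enum.Enum):
    DRUG = "DRUG"
    BIOLOGICAL = "BIOLOGICAL"
    DEVICE = "DEVICE"
    PROCEDURE = "PROCEDURE"
    BEHAVIORAL = "BEHAVIORAL"
    OTHER = "OTHER"


class ReferenceType(str, enum.Enum):
    RESULT = "RESULT"
    BACKGROUND = "BACKGROUND"
    DERIVED = "DERIVED"


class TDL(str, enum.Enum):
    """Target development level: how well characterised a protein is as a drug target."""

    Tclin = "Tclin"
    Tchem = "Tchem"
    Tbio = "Tbio"
    Tdark = "Tdark"


@dataclass(frozen=True)
class StudyRecord:
    nct_id: str
    study_type: StudyType | str
    intervention_type: InterventionType | str
    start_date: date | None = None
    completion_date: date | None = None

    @property
    def reference_date(self) -> date | None:
        """Completion date when present, else start date; None when undated."""
        return self.completion_date if self.completion_date is not None else self.start_date


@dataclass(frozen=True)
class ReferenceRecord:
    nct_id: str
    pmid: str | None
    reference_type: ReferenceType | str
    citation: str = ""


@dataclass(frozen=True)
class DrugTargetLink:
    nct_id: str
    drug_name: str
    gene_symbol: str
    smiles: str | None = None
    inchikey: str | None = None
    uniprot: str | None = None
    tdl: TDL | None = None


@dataclass(frozen=True)
class StudyDiseaseLink:
    nct_id: str
    doid: str
    disease_name: str = ""


@dataclass(frozen=True)
class EvidenceRow:
    """One joined (disease, gene, study, drug[, publication]) tuple."""

    doid: str
    gene_symbol: str
    nct_id: str
    drug_name: str
    pmid: str | None = None
    reference_type: ReferenceType | str | None = None
    study_age_years: float | None = None
    disease_name: str = ""
    uniprot: str | None = None
    tdl: TDL | None = None
    citation: str = ""


@dataclass(frozen=True)
class ParseIssue:
    row: int  # 1-based data row number (header excluded)
    column: str
    message: str


@dataclass
class TableParse:
    records: list
    issues: list[ParseIssue]


@dataclass
class SkipReport:
    """Link rows dropped during the evidence join, keyed by reason."""

    missing_study: list[tuple[str, str]]  # (table, nct_id)
    non_interventional: int = 0
    non_drug: int = 0

    @property
    def n_skipped_links(self) -> int:
        return len(self.missing_study)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.missing_study, columns=["table", "nct_id"])


def normalize_drug_name(name: str) -> str:
    """Lowercase and collapse internal whitespace so synonymous spellings collapse."""
    return " ".join(name.strip().lower().split())


_DELIMS = {"tsv": "\t", "aact_pipe": "|"}

_SCHEMAS: dict[str, tuple[type, tuple[str, ...]]] = {
    "studies": (StudyRecord, ("nct_id", "study_type", "intervention_type", "start_date", "completion_date")),
    "references": (ReferenceRecord, ("nct_id", "pmid", "reference_type", "citation")),
    "drug_targets": (DrugTargetLink, ("nct_id", "drug_name", "smiles", "inchikey", "uniprot", "gene_symbol", "tdl")),
    "diseases": (StudyDiseaseLink, ("nct_id", "doid", "disease_name")),
    "crosswalk": (None, ("doid", "cui")),
    "external": (None, ("cui", "condition_name", "gene_symbol")),
}

TABLE_KINDS = tuple(_SCHEMAS)


def _parse_date(raw: str, row: int, column: str, issues: list[ParseIssue]) -> date | None:
    if not raw:
        return None
    try:
        return date.fromisoformat(raw)
    except ValueError:
        issues.append(ParseIssue(row, column, f"malformed date {raw!r}"))
        return None


def _parse_enum(raw: str, enum_cls, row: int, column: str, issues: list[ParseIssue]):
    """Case-insensitive enum lookup; unknown values are reported and kept verbatim."""
    if not raw:
        return None
    try:
        return enum_cls[raw.strip().upper()] if enum_cls is not TDL else TDL(raw.strip().capitalize())
    except (KeyError, ValueError):
        issues.append(ParseIssue(row, column, f"unrecognized {enum_cls.__name__} value {raw!r}"))
        return raw


def _read_frame(path: str | Path, table_kind: str, dialect: str) -> pd.DataFrame:
    if table_kind not in _SCHEMAS:
        raise ValueError(f"unknown table_kind {table_kind!r}; expected one of {TABLE_KINDS}")
    if dialect not in _DELIMS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {tuple(_DELIMS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=_DELIMS[dialect], dtype=str, keep_default_na=False)
    _, columns = _SCHEMAS[table_kind]
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {', '.join(missing)}")
    if frame.empty:
        logger.warning("%s: no data rows", path.name)
    return frame


def read_table(path: str | Path, table_kind: str, dialect: str = "tsv") -> TableParse:
    """Read one evidence table into typed records.

    ``dialect`` is ``"tsv"`` (tab-separated, the default) or ``"aact_pipe"``
    (the pipe-delimited AACT export flavour). Empty cells denote absent
    values. Unparseable enum values and malformed dates are reported in the
    returned :class:`TableParse` issues with 1-based data row numbers;
    missing required columns raise ``ValueError``.
    """
    frame = _read_frame(path, table_kind, dialect)
    issues: list[ParseIssue] = []
    records: list = []

    if table_kind == "studies":
        for i, r in enumerate(frame.itertuples(index=False), start=1):
            records.append(
                StudyRecord(
                    nct_id=r.nct_id,
                    study_type=_parse_enum(r.study_type, StudyType, i, "study_type", issues),
                    intervention_type=_parse_enum(r.intervention_type, InterventionType, i, "intervention_type", issues),
                    start_date=_parse_date(r.start_date, i, "start_date", issues),
                    completion_date=_parse_date(r.completion_date, i, "completion_date", issues),
                )
            )
    elif table_kind == "references":
        for i, r in enumerate(frame.itertuples(index=False), start=1):
            records.append(
                ReferenceRecord(
                    nct_id=r.nct_id,
                    pmid=r.pmid or None,
                    reference_type=_parse_enum(r.reference_type, ReferenceType, i, "reference_type", issues),
                    citation=r.citation,
                )
            )
    elif table_kind == "drug_targets":
        for i, r in enumerate(frame.itertuples(index=False), start=1):
            records.append(
                DrugTargetLink(
                    nct_id=r.nct_id,
                    drug_name=normalize_drug_name(r.drug_name),
                    gene_symbol=r.gene_symbol.strip().upper(),
                    smiles=r.smiles or None,
                    inchikey=r.inchikey or None,
                    uniprot=r.uniprot or None,
                    tdl=_parse_enum(r.tdl, TDL, i, "tdl", issues),
                )
            )
    elif table_kind == "diseases":
        for i, r in enumerate(frame.itertuples(index=False), start=1):
            if not DOID_PATTERN.match(r.doid):
                issues.append(ParseIssue(i, "doid", f"identifier {r.doid!r} does not match DOID:<int>"))
            records.append(StudyDiseaseLink(nct_id=r.nct_id, doid=r.doid, disease_name=r.disease_name))
    else:  # crosswalk / external: plain frames, consumed by the validation module
        records = list(frame.itertuples(index=False, name="Row"))

    for issue in issues:
        logger.warning("%s row %d [%s]: %s", Path(path).name, issue.row, issue.column, issue.message)
    return TableParse(records=records, issues=issues)


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, enum.Enum):
        return value.value
    return str(value)


def write_table(records: Sequence, table_kind: str, path: str | Path, dialect: str = "tsv") -> None:
    """Write typed records back to disk; inverse of :func:`read_table`."""
    _, columns = _SCHEMAS[table_kind]
    rows = [{c: _cell(getattr(r, c)) for c in columns} for r in records]
    pd.DataFrame(rows, columns=list(columns)).to_csv(path, sep=_DELIMS[dialect], index=False)


def build_evidence(
    studies: Sequence[StudyRecord],
    references: Sequence[ReferenceRecord],
    drug_links: Sequence[DrugTargetLink],
    disease_links: Sequence[StudyDiseaseLink],
    *,
    require_interventional: bool = True,
    require_drug: bool = True,
) -> tuple[list[EvidenceRow], SkipReport]:
    """Join the four tables into disease-gene evidence rows.

    Only interventional drug studies contribute (both filters can be relaxed
    through the flags). For each eligible study, every linked disease is
    crossed with every linked drug target; when the study has references the
    row is replicated once per reference so provenance is row-complete —
    downstream metrics dedupe by trial and publication, so replication never
    inflates counts. Link rows whose trial is absent from the studies table
    are skipped and tallied in the returned :class:`SkipReport`.

    The output is sorted, hence invariant to input row order.
    """
    by_nct = {s.nct_id: s for s in studies}
    skip = SkipReport(missing_study=[])

    eligible: set[str] = set()
    for s in studies:
        if require_interventional and s.study_type is not StudyType.INTERVENTIONAL:
            skip.non_interventional += 1
            continue
        if require_drug and s.intervention_type is not InterventionType.DRUG:
            skip.non_drug += 1
            continue
        eligible.add(s.nct_id)

    refs_by_nct: dict[str, list[ReferenceRecord]] = {}
    for ref in references:
        if ref.nct_id not in by_nct:
            skip.missing_study.append(("references", ref.nct_id))
            continue
        refs_by_nct.setdefault(ref.nct_id, []).append(ref)

    drugs_by_nct: dict[str, list[DrugTargetLink]] = {}
    for dl in drug_links:
        if dl.nct_id not in by_nct:
            skip.missing_study.append(("drug_targets", dl.nct_id))
            continue
        drugs_by_nct.setdefault(dl.nct_id, []).append(dl)

    diseases_by_nct: dict[str, list[StudyDiseaseLink]] = {}
    for sl in disease_links:
        if sl.nct_id not in by_nct:
            skip.missing_study.append(("diseases", sl.nct_id))
            continue
        diseases_by_nct.setdefault(sl.nct_id, []).append(sl)

    rows: set[EvidenceRow] = set()
    for nct in eligible:
        for dis in diseases_by_nct.get(nct, ()):
            for drug in drugs_by_nct.get(nct, ()):
                base = dict(
                    doid=dis.doid,
                    gene_symbol=drug.gene_symbol,
                    nct_id=nct,
                    drug_name=drug.drug_name,
                    disease_name=dis.disease_name,
                    uniprot=drug.uniprot,
                    tdl=drug.tdl,
                )
                refs = refs_by_nct.get(nct)
                if refs:
                    for ref in refs:
                        rows.add(
                            EvidenceRow(
                                pmid=ref.pmid,
                                reference_type=ref.reference_type,
                                citation=ref.citation,
                                **base,
                            )
                        )
                else:
                    rows.add(EvidenceRow(**base))

    ordered = sorted(
        rows,
        key=lambda r: (r.doid, r.gene_symbol, r.nct_id, r.drug_name, r.pmid or "", str(r.reference_type or "")),
    )
    return ordered, skip


_EVIDENCE_COLUMNS = (
    "doid",
    "gene_symbol",
    "nct_id",
    "drug_name",
    "pmid",
    "reference_type",
    "study_age_years",
    "disease_name",
    "uniprot",
    "tdl",
    "citation",
)


def evidence_to_frame(rows: Iterable[EvidenceRow]) -> pd.DataFrame:
    data = [{f.name: getattr(r, f.name) for f in dc_fields(EvidenceRow)} for r in rows]
    frame = pd.DataFrame(data, columns=list(_EVIDENCE_COLUMNS))
    for col in ("reference_type", "tdl"):
        frame[col] = frame[col].map(lambda v: v.value if isinstance(v, enum.Enum) else v)
    return frame


def write_evidence(rows: Iterable[EvidenceRow], path: str | Path) -> None:
    evidence_to_frame(rows).to_csv(path, sep="\t", index=False)
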
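"""Agreement-based comparison of two disease-gene association sets.

Disease vocabularies differ between resources: the trial-derived
associations are keyed by Disease Ontology IDs (DOIDs) while curated
external references (e.g. MedlinePlus Genetics) are keyed by UMLS Concept
Unique Identifiers (CUIs). A DOID<->CUI crosswalk projects both sets into
CUI space; the comparison is then restricted to the CUIs present on both
sides before counting shared (cui, gene) associations. The headline
number is the percentage of the external (right-hand) set recovered.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

Assoc = tuple[str, str]  # (identifier, gene_symbol)


@dataclass(frozen=True)
class OverlapReport:
    n_cui_left: int
    n_cui_right: int
    n_cui_shared: int
    n_assoc_left: int
    n_assoc_right: int
    n_gene_left: int
    n_gene_right: int
    n_overlap: int
    pct_of_right: float
    pct_left_unique: float  # share of left-hand associations (over shared CUIs) absent from right

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def read_crosswalk(path: str | Path, dialect: str = "tsv") -> set[Assoc]:
    sep = {"tsv": "\t", "aact_pipe": "|"}[dialect]
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("doid", "cui"):
        if col not in frame.columns:
            raise ValueError(f"{Path(path).name}: missing required column(s) {col}")
    return {(r.doid, r.cui) for r in frame.itertuples(index=False)}


def read_external_associations(path: str | Path, dialect: str = "tsv") -> set[Assoc]:
    """External (cui, gene) associations; gene symbols uppercased on read."""
    sep = {"tsv": "\t", "aact_pipe": "|"}[dialect]
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("cui", "gene_symbol"):
        if col not in frame.columns:
            raise ValueError(f"{Path(path).name}: missing required column(s) {col}")
    return {(r.cui, r.gene_symbol.strip().upper()) for r in frame.itertuples(index=False)}


def to_cui_associations(
    assocs: Iterable[Assoc],
    crosswalk: Iterable[Assoc],
) -> tuple[set[Assoc], int]:
    """Expand (doid, gene) pairs into CUI space via the crosswalk.

    Each DOID maps to zero or more CUIs; every mapping produces one
    (cui, gene) pair, deduplicated. Returns the expanded set and the count
    of distinct unmapped DOIDs (dropped from the comparison). Gene symbols
    are uppercased so symbol-case differences cannot masquerade as
    disagreement.
    """
    cuis_by_doid: dict[str, set[str]] = {}
    for doid, cui in crosswalk:
        cuis_by_doid.setdefault(doid, set()).add(cui)
    if not cuis_by_doid:
        logger.warning("empty crosswalk: no associations can be mapped to CUIs")

    out: set[Assoc] = set()
    unmapped: set[str] = set()
    for doid, gene in assocs:
        cuis = cuis_by_doid.get(doid)
        if not cuis:
            unmapped.add(doid)
            continue
        gene = gene.strip().upper()
        out.update((cui, gene) for cui in cuis)
    return out, len(unmapped)


def overlap_percentage(n_overlap: int, n_right: int) -> float:
    """Percentage of right-hand associations recovered, to 2 decimal places."""
    if n_right == 0:
        return 0.0
    return round(100.0 * n_overlap / n_right, 2)


def overlap_report(left: set[Assoc], right: set[Assoc]) -> OverlapReport:
    """Compare two (cui, gene) association sets over their shared CUIs.

    Both sets are first restricted to CUIs appearing on both sides; counts
    and the overlap refer to the restricted sets. ``pct_of_right`` is the
    share of the right-hand set's restricted associations also present on
    the left.
    """
    cuis_left = {c for c, _ in left}
    cuis_right = {c for c, _ in right}
    shared = cuis_left & cuis_right
    rl = {(c, g) for c, g in left if c in shared}
    rr = {(c, g) for c, g in right if c in shared}
    n_overlap = len(rl & rr)
    return OverlapReport(
        n_cui_left=len(cuis_left),
        n_cui_right=len(cuis_right),
        n_cui_shared=len(shared),
        n_assoc_left=len(rl),
        n_assoc_right=len(rr),
        n_gene_left=len({g for _, g in rl}),
        n_gene_right=len({g for _, g in rr}),
        n_overlap=n_overlap,
        pct_of_right=overlap_percentage(n_overlap, len(rr)),
        pct_left_unique=round(100.0 * (1 - n_overlap / len(rl)), 2) if rl else 0.0,
    )


def integrity_counts(
    assocs: Iterable[Assoc],
    crosswalk: Iterable[Assoc] = (),
    external: Iterable[Assoc] = (),
) -> dict[str, int]:
    """Distinct-entity counts used as a sanity check before comparison."""
    assocs = set(assocs)
    crosswalk = set(crosswalk)
    external = set(external)
    return {
        "n_doid": len({d for d, _ in assocs}),
        "n_gene": len({g for _, g in assocs}),
        "n_assoc": len(assocs),
        "n_crosswalk_doid": len({d for d, _ in crosswalk}),
        "n_crosswalk_cui": len({c for _, c in crosswalk}),
        "n_external_cui": len({c for c, _ in external}),
        "n_external_gene": len({g for _, g in external}),
        "n_external_assoc": len(external),
    }


def write_shared_associations(left: set[Assoc], right: set[Assoc], path: str | Path) -> None:
    """Dump the shared-CUI associations of both sides for inspection."""
    cuis = {c for c, _ in left} & {c for c, _ in right}
    rows = sorted(
        {(c, g, "left", (c, g) in right) for c, g in left if c in cuis}
        | {(c, g, "right", (c, g) in left) for c, g in right if c in cuis}
    )
    pd.DataFrame(rows, columns=["cui", "gene_symbol", "side", "in_both"]).to_csv(
        path, sep="\t", index=False
    )
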
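"""Rank aggregation of the six evidence metrics into a 0-100 score.

For each metric m, pair j receives a descending rank R_{m,j} (largest
value -> rank 1, ties averaged). The mean rank over the K=6 metrics is
then converted to a percentile,

    percentileMeanRank_j = Rank(meanRank_j) / N * 100,

with Rank ascending so that a low mean rank (strong evidence on most
metrics) yields a low percentile, and finally

    meanRankScore_j = 100 - percentileMeanRank_j,

a 0-100 scale on which the best-supported pair scores highest. With N
pairs the unique best score is 100 * (1 - 1/N); a score of exactly 100 is
unattainable.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .scoring import METRIC_NAMES, PairMetrics

SCORE_DECIMALS = 5  # serialization precision of meanRankScore


@dataclass(frozen=True)
class AssociationScore:
    doid: str
    gene_symbol: str
    metrics: PairMetrics
    rank_per_metric: Mapping[str, float]
    mean_rank: float
    percentile_mean_rank: float
    mean_rank_score: float


def rank_descending(values: Sequence[float]) -> np.ndarray:
    """Descending average ranks: the largest value gets rank 1, ties averaged.

    Average ranking keeps the rank sum exactly N(N+1)/2, so tied groups are
    not biased up or down.
    """
    if len(values) == 0:
        raise ValueError("cannot rank an empty list")
    return rankdata([-v for v in values], method="average")


def mean_rank(ranks: Mapping[str, float], k: int | None = None) -> float:
    """Arithmetic mean of a pair's per-metric ranks."""
    if k is None:
        k = len(ranks)
    if k == 0:
        raise ValueError("mean rank undefined for zero metrics")
    if len(ranks) != k:
        raise ValueError(f"expected {k} ranks, got {len(ranks)}")
    return sum(ranks.values()) / k


def mean_rank_score(mean_ranks: Sequence[float]) -> np.ndarray:
    """Map mean ranks to the 0-100 score, jointly over all pairs."""
    if len(mean_ranks) == 0:
        raise ValueError("cannot score an empty list")
    asc = rankdata(mean_ranks, method="average")
    percentile = asc / len(mean_ranks) * 100.0
    return 100.0 - percentile


def score_associations(
    pair_metrics: Sequence[PairMetrics],
    metrics: Sequence[str] = METRIC_NAMES,
    ascending_metrics: Sequence[str] = (),
    per_disease: bool = False,
) -> list[AssociationScore]:
    """Rank all pairs jointly on each metric and aggregate into scores.

    All six metrics are ranked descending by default (more evidence is
    better); ``ascending_metrics`` flips the direction for chosen metrics
    (e.g. ranking ``nDiseases`` ascending to favour disease-specific
    genes). ``per_disease`` restricts the rank pool to each disease's own
    pairs instead of the global table — the view a single-disease query
    presents. Output is sorted by descending meanRankScore with ties
    broken lexicographically by (doid, gene_symbol), so it is
    deterministic and invariant to input row order.
    """
    if not pair_metrics:
        raise ValueError("no pairs to score")
    if per_disease:
        out: list[AssociationScore] = []
        by_doid: dict[str, list[PairMetrics]] = {}
        for p in pair_metrics:
            by_doid.setdefault(p.doid, []).append(p)
        for group in by_doid.values():
            out.extend(score_associations(group, metrics, ascending_metrics, per_disease=False))
        out.sort(key=lambda a: (-a.mean_rank_score, a.doid, a.gene_symbol))
        return out
    ranks_by_metric = {
        m: (
            rankdata([float(getattr(p, m)) for p in pair_metrics], method="average")
            if m in ascending_metrics
            else rank_descending([float(getattr(p, m)) for p in pair_metrics])
        )
        for m in metrics
    }
    mean_ranks = [
        mean_rank({m: ranks_by_metric[m][j] for m in metrics}) for j in range(len(pair_metrics))
    ]
    scores = mean_rank_score(mean_ranks)
    percentiles = 100.0 - scores
    out = [
        AssociationScore(
            doid=p.doid,
            gene_symbol=p.gene_symbol,
            metrics=p,
            rank_per_metric={m: float(ranks_by_metric[m][j]) for m in metrics},
            mean_rank=float(mean_ranks[j]),
            percentile_mean_rank=float(percentiles[j]),
            mean_rank_score=float(scores[j]),
        )
        for j, p in enumerate(pair_metrics)
    ]
    out.sort(key=lambda a: (-a.mean_rank_score, a.doid, a.gene_symbol))
    return out


def associations_to_frame(assocs: Sequence[AssociationScore]) -> pd.DataFrame:
    rows = []
    for a in assocs:
        p = a.metrics
        rows.append(
            {
                "doid": a.doid,
                "disease_name": p.disease_name,
                "gene_symbol": a.gene_symbol,
                "uniprot": p.uniprot or "",
                "tdl": p.tdl.value if p.tdl else "",
                "nDiseases": p.nDiseases,
                "nDrug": p.nDrug,
                "nStud": p.nStud,
                "nPub": p.nPub,
                "nStudyNewness": round(p.nStudyNewness, SCORE_DECIMALS),
                "nPublicationWeighted": round(p.nPublicationWeighted, SCORE_DECIMALS),
                "meanRank": round(a.mean_rank, SCORE_DECIMALS),
                "meanRankScore": round(a.mean_rank_score, SCORE_DECIMALS),
                "drugs": ";".join(p.drugs),
            }
        )
    return pd.DataFrame(rows)


def write_associations(assocs: Sequence[AssociationScore], path: str | Path) -> None:
    associations_to_frame(assocs).to_csv(path, sep="\t", index=False, float_format=f"%.{SCORE_DECIMALS}f")


def write_scatter(assocs: Sequence[AssociationScore], path: str | Path) -> None:
    """Score-vs-publication-count export (colored by TDL in the dashboards)."""
    frame = pd.DataFrame(
        {
            "doid": [a.doid for a in assocs],
            "gene_symbol": [a.gene_symbol for a in assocs],
            "meanRankScore": [round(a.mean_rank_score, SCORE_DECIMALS) for a in assocs],
            "nPub": [a.metrics.nPub for a in assocs],
            "tdl": [a.metrics.tdl.value if a.metrics.tdl else "" for a in assocs],
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format=f"%.{SCORE_DECIMALS}f")
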
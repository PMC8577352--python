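"""Cutoff-anchored normalization of raw statistics to marker gene scores.

Each endpoint is mapped to [0, 1] by a two-segment piecewise-linear function
anchored at the author-declared significance cutoff, which always lands on
exactly 0.5.  For a lower-is-more-significant endpoint the declared range
minimum maps to 1 and the maximum to 0 (mirrored for the opposite
direction); observed values outside the declared range are clamped first.
The per-endpoint preliminary scores of a (gene, cell type) pair are then
averaged within the source into its marker gene score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from markerscore.errors import ValidationError
from markerscore.io import Direction, EndpointDefinition, SourceMetadata, StatRecord


@dataclass(frozen=True)
class ScoreRecord:
    """Marker gene score for one (gene, cell type, source, species)."""

    gene_id: str
    cell_type_id: str
    source_id: str
    species: str
    marker_gene_score: float
    n_endpoints: int

    def __post_init__(self):
        if not 0.0 <= self.marker_gene_score <= 1.0:
            raise ValidationError(f"marker_gene_score {self.marker_gene_score} outside [0, 1]")
        if self.n_endpoints < 1:
            raise ValidationError("n_endpoints must be >= 1")


def normalize_statistic(value: float, ep: EndpointDefinition) -> float:
    """Map a raw statistic onto the [0, 1] preliminary score.

    The significant extreme of the declared range maps to 1.0, the cutoff to
    exactly 0.5, and the opposite extreme to 0.0, linearly within each
    segment.  Values outside the declared range are clamped to the nearest
    bound, which keeps the map total, bounded and monotone even when a
    curated table exceeds its declared range.
    """
    if not math.isfinite(value):
        raise ValidationError(f"endpoint {ep.endpoint_name!r}: non-finite value {value!r}")
    v = min(max(value, ep.range_min), ep.range_max)
    cut = ep.significance_cutoff
    if ep.direction is Direction.LOWER:
        if v <= cut:
            return 1.0 - 0.5 * (v - ep.range_min) / (cut - ep.range_min)
        return 0.5 * (ep.range_max - v) / (ep.range_max - cut)
    if v >= cut:
        return 1.0 - 0.5 * (ep.range_max - v) / (ep.range_max - cut)
    return 0.5 * (v - ep.range_min) / (cut - ep.range_min)


def denormalize_score(score: float, ep: EndpointDefinition) -> float:
    """Inverse of :func:`normalize_statistic` on [0, 1] (used for simulation)."""
    if not 0.0 <= score <= 1.0:
        raise ValidationError(f"score {score} outside [0, 1]")
    cut = ep.significance_cutoff
    if ep.direction is Direction.LOWER:
        if score >= 0.5:
            return ep.range_min + 2.0 * (1.0 - score) * (cut - ep.range_min)
        return ep.range_max - 2.0 * score * (ep.range_max - cut)
    if score >= 0.5:
        return ep.range_max - 2.0 * (1.0 - score) * (ep.range_max - cut)
    return ep.range_min + 2.0 * score * (cut - ep.range_min)


def score_source(records: Iterable[StatRecord], meta: SourceMetadata) -> list[ScoreRecord]:
    """Average per-endpoint preliminary scores into marker gene scores.

    One ScoreRecord per (gene, cell type, species) observed in the source.
    Endpoints absent for a pair are simply omitted from the mean -- some
    sources only release their significant results, so absence is not
    evidence.  Mouse and human samples of one source stay separate records
    because species medians are needed downstream.
    """
    groups: dict[tuple[str, str, str], dict[str, float]] = {}
    for rec in records:
        if rec.source_id != meta.source_id:
            raise ValidationError(
                f"record for source {rec.source_id!r} passed to score_source of "
                f"{meta.source_id!r}"
            )
        ep = meta.endpoints.get(rec.endpoint_name)
        if ep is None:
            raise ValidationError(
                f"source {meta.source_id!r}: unknown endpoint {rec.endpoint_name!r}"
            )
        key = (rec.gene_id, rec.cell_type_id, rec.species)
        seen = groups.setdefault(key, {})
        if rec.endpoint_name in seen:
            raise ValidationError(
                f"duplicate statistic for gene {rec.gene_id!r}, cell type "
                f"{rec.cell_type_id!r}, species {rec.species!r}, endpoint "
                f"{rec.endpoint_name!r} in source {meta.source_id!r}"
            )
        seen[rec.endpoint_name] = normalize_statistic(rec.value, ep)

    out = []
    for (gene_id, cell_type_id, species), prelim in sorted(groups.items()):
        scores = list(prelim.values())
        out.append(ScoreRecord(
            gene_id=gene_id,
            cell_type_id=cell_type_id,
            source_id=meta.source_id,
            species=species,
            marker_gene_score=sum(scores) / len(scores),
            n_endpoints=len(scores),
        ))
    return out


SCORE_COLUMNS = [
    "gene_id", "cell_type_id", "source_id", "species", "marker_gene_score", "n_endpoints",
]


def write_scores(scores: Iterable[ScoreRecord], path) -> None:
    import pandas as pd

    rows = [
        {
            "gene_id": s.gene_id,
            "cell_type_id": s.cell_type_id,
            "source_id": s.source_id,
            "species": s.species,
            "marker_gene_score": repr(s.marker_gene_score),
            "n_endpoints": s.n_endpoints,
        }
        for s in scores
    ]
    pd.DataFrame(rows, columns=SCORE_COLUMNS).to_csv(path, index=False)


def read_scores(path) -> list[ScoreRecord]:
    import pandas as pd

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in SCORE_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    return [
        ScoreRecord(
            gene_id=row.gene_id,
            cell_type_id=row.cell_type_id,
            source_id=row.source_id,
            species=row.species,
            marker_gene_score=float(row.marker_gene_score),
            n_endpoints=int(row.n_endpoints),
        )
        for row in df.itertuples(index=False)
    ]


def score_all(
    records: Iterable[StatRecord],
    sources: dict[str, SourceMetadata],
) -> list[ScoreRecord]:
    """Score every source's records; records are grouped by source first."""
    by_source: dict[str, list[StatRecord]] = {}
    for rec in records:
        by_source.setdefault(rec.source_id, []).append(rec)
    out: list[ScoreRecord] = []
    for source_id in sorted(by_source):
        if source_id not in sources:
            raise ValidationError(f"no metadata for source {source_id!r}")
        out.extend(score_source(by_source[source_id], sources[source_id]))
    return out
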
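"""Standardized tabular formats: domain types, readers, writers, validation.

All persistence is flat CSV/JSON, long format, UTF-8, '.' decimal separator.
Every statistic is one row of the stats table; every source declares its
statistical endpoints (range, direction, author significance cutoff) in a
sources config; gene identity is a pre-built mouse-human ortholog
cross-reference joined on a unified ``gene_id``.
"""

from __future__ import annotations

import enum
import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from markerscore.errors import (
    AmbiguousSymbolError,
    ConfigurationError,
    ValidationError,
)

SPECIES = ("mouse", "human")

STAT_COLUMNS = ["gene_id", "cell_type_id", "source_id", "endpoint_name", "value", "species"]
XREF_COLUMNS = ["gene_id", "mouse_symbol", "human_symbol", "entrez_ids", "ensembl_ids"]


class Direction(str, enum.Enum):
    """Which end of an endpoint's range carries significance."""

    LOWER = "lower_more_significant"
    HIGHER = "higher_more_significant"


@dataclass(frozen=True)
class EndpointDefinition:
    """How one statistical endpoint of one source maps onto [0, 1].

    The author-declared ``significance_cutoff`` is the anchor mapped to a
    preliminary score of exactly 0.5; the significant extreme of
    ``[range_min, range_max]`` maps to 1 and the opposite extreme to 0.
    """

    endpoint_name: str
    direction: Direction
    range_min: float
    range_max: float
    significance_cutoff: float

    def __post_init__(self):
        if not (math.isfinite(self.range_min) and math.isfinite(self.range_max)
                and math.isfinite(self.significance_cutoff)):
            raise ConfigurationError(
                f"endpoint {self.endpoint_name!r}: range and cutoff must be finite"
            )
        if not self.range_min < self.range_max:
            raise ConfigurationError(
                f"endpoint {self.endpoint_name!r}: range_min ({self.range_min}) must be "
                f"< range_max ({self.range_max})"
            )
        if not self.range_min < self.significance_cutoff < self.range_max:
            raise ConfigurationError(
                f"endpoint {self.endpoint_name!r}: significance_cutoff "
                f"({self.significance_cutoff}) must lie strictly inside "
                f"[{self.range_min}, {self.range_max}]; a cutoff at a range bound "
                "would make one scaling segment degenerate"
            )


@dataclass
class SourceMetadata:
    """Contextual data for one source (publication/analysis)."""

    source_id: str
    species: frozenset[str]
    endpoints: dict[str, EndpointDefinition]
    sample_type: str = ""
    expression_method: str = ""
    statistical_method: str = ""

    def __post_init__(self):
        bad = set(self.species) - set(SPECIES)
        if bad:
            raise ConfigurationError(f"source {self.source_id!r}: unknown species {sorted(bad)}")
        if not self.endpoints:
            raise ConfigurationError(f"source {self.source_id!r}: endpoints must be non-empty")
        for name, ep in self.endpoints.items():
            if name != ep.endpoint_name:
                raise ConfigurationError(
                    f"source {self.source_id!r}: endpoint keyed {name!r} is named "
                    f"{ep.endpoint_name!r}"
                )


@dataclass(frozen=True)
class GeneRecord:
    """One unified mouse-human ortholog-pair entry of the cross-reference."""

    gene_id: str
    mouse_symbol: str | None = None
    human_symbol: str | None = None
    entrez_ids: tuple[str, ...] = ()
    ensembl_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if not (self.mouse_symbol or self.human_symbol):
            raise ValidationError(
                f"gene {self.gene_id!r}: at least one of mouse_symbol/human_symbol required"
            )


@dataclass(frozen=True)
class StatRecord:
    """One extracted statistic for a (gene, cell type, source, endpoint)."""

    gene_id: str
    cell_type_id: str
    source_id: str
    endpoint_name: str
    value: float
    species: str


class GeneXref:
    """Gene cross-reference: unified gene_id <-> mouse/human symbols and ids."""

    def __init__(self, records: Iterable[GeneRecord]):
        self.records: dict[str, GeneRecord] = {}
        by_symbol: dict[tuple[str, str], list[str]] = {}
        for rec in records:
            if rec.gene_id in self.records:
                raise ValidationError(f"duplicate gene_id {rec.gene_id!r} in cross-reference")
            self.records[rec.gene_id] = rec
            for species, sym in (("mouse", rec.mouse_symbol), ("human", rec.human_symbol)):
                if sym:
                    by_symbol.setdefault((species, sym.casefold()), []).append(rec.gene_id)
        self._by_symbol = by_symbol

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def __len__(self) -> int:
        return len(self.records)

    def resolve(self, symbol: str, species: str) -> str | None:
        """Case-insensitive exact symbol lookup; None when absent.

        Raises
        ------
        AmbiguousSymbolError
            If the symbol maps to more than one gene_id within the species.
        """
        if species not in SPECIES:
            raise ValidationError(f"unknown species {species!r}")
        hits = self._by_symbol.get((species, symbol.casefold()), [])
        if len(hits) > 1:
            raise AmbiguousSymbolError(symbol, species, hits)
        return hits[0] if hits else None


def resolve_gene_id(symbol: str, species: str, genes: GeneXref) -> str | None:
    """Resolve a species symbol to the unified gene_id (None if not found)."""
    return genes.resolve(symbol, species)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: file is empty") from None
    for col in required:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    return df


def _split_list(cell: str) -> tuple[str, ...]:
    return tuple(x for x in cell.split(";") if x) if cell else ()


def load_gene_xref(path: str | Path) -> GeneXref:
    """Read the gene cross-reference CSV (list fields ';'-delimited)."""
    df = _read_csv(path, XREF_COLUMNS)
    recs = [
        GeneRecord(
            gene_id=row.gene_id,
            mouse_symbol=row.mouse_symbol or None,
            human_symbol=row.human_symbol or None,
            entrez_ids=_split_list(row.entrez_ids),
            ensembl_ids=_split_list(row.ensembl_ids),
        )
        for row in df.itertuples(index=False)
    ]
    return GeneXref(recs)


def write_gene_xref(genes: GeneXref, path: str | Path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "mouse_symbol": r.mouse_symbol or "",
            "human_symbol": r.human_symbol or "",
            "entrez_ids": ";".join(r.entrez_ids),
            "ensembl_ids": ";".join(r.ensembl_ids),
        }
        for r in genes.records.values()
    ]
    pd.DataFrame(rows, columns=XREF_COLUMNS).to_csv(path, index=False)


def _source_from_dict(obj: Mapping) -> SourceMetadata:
    eps = {}
    for ep in obj["endpoints"]:
        d = EndpointDefinition(
            endpoint_name=ep["endpoint_name"],
            direction=Direction(ep["direction"]),
            range_min=float(ep["range_min"]),
            range_max=float(ep["range_max"]),
            significance_cutoff=float(ep["significance_cutoff"]),
        )
        if d.endpoint_name in eps:
            raise ConfigurationError(
                f"source {obj['source_id']!r}: duplicate endpoint {d.endpoint_name!r}"
            )
        eps[d.endpoint_name] = d
    return SourceMetadata(
        source_id=obj["source_id"],
        species=frozenset(obj["species"]),
        endpoints=eps,
        sample_type=obj.get("sample_type", ""),
        expression_method=obj.get("expression_method", ""),
        statistical_method=obj.get("statistical_method", ""),
    )


def load_sources(path: str | Path) -> dict[str, SourceMetadata]:
    """Read source metadata from JSON (list of sources) or long-format CSV.

    CSV columns: source_id,species,sample_type,expression_method,
    statistical_method,endpoint_name,direction,range_min,range_max,
    significance_cutoff -- one endpoint per row, species ';'-delimited.
    """
    path = Path(path)
    sources: dict[str, SourceMetadata] = {}
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        for obj in data:
            meta = _source_from_dict(obj)
            if meta.source_id in sources:
                raise ConfigurationError(f"duplicate source_id {meta.source_id!r}")
            sources[meta.source_id] = meta
        return sources

    df = _read_csv(path, [
        "source_id", "species", "endpoint_name", "direction",
        "range_min", "range_max", "significance_cutoff",
    ])
    for source_id, grp in df.groupby("source_id", sort=True):
        eps: dict[str, EndpointDefinition] = {}
        for row in grp.itertuples(index=False):
            d = EndpointDefinition(
                endpoint_name=row.endpoint_name,
                direction=Direction(row.direction),
                range_min=float(row.range_min),
                range_max=float(row.range_max),
                significance_cutoff=float(row.significance_cutoff),
            )
            if d.endpoint_name in eps:
                raise ConfigurationError(
                    f"source {source_id!r}: duplicate endpoint {d.endpoint_name!r}"
                )
            eps[d.endpoint_name] = d
        first = grp.iloc[0]
        sources[str(source_id)] = SourceMetadata(
            source_id=str(source_id),
            species=frozenset(_split_list(first["species"])),
            endpoints=eps,
            sample_type=first.get("sample_type", ""),
            expression_method=first.get("expression_method", ""),
            statistical_method=first.get("statistical_method", ""),
        )
    return sources


def write_sources(sources: Mapping[str, SourceMetadata], path: str | Path) -> None:
    """Write source metadata as JSON (the canonical config dialect)."""
    data = []
    for meta in sources.values():
        data.append({
            "source_id": meta.source_id,
            "species": sorted(meta.species),
            "sample_type": meta.sample_type,
            "expression_method": meta.expression_method,
            "statistical_method": meta.statistical_method,
            "endpoints": [
                {
                    "endpoint_name": ep.endpoint_name,
                    "direction": ep.direction.value,
                    "range_min": ep.range_min,
                    "range_max": ep.range_max,
                    "significance_cutoff": ep.significance_cutoff,
                }
                for ep in meta.endpoints.values()
            ],
        })
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True) + "\n")


def load_stat_table(
    path: str | Path,
    sources: Mapping[str, SourceMetadata],
    genes: GeneXref | None = None,
) -> tuple[list[StatRecord], Counter]:
    """Load and validate the long-format statistics CSV.

    Rows failing validation are never silently dropped: they are counted per
    reason in the returned report (``unknown_source``, ``unknown_endpoint``,
    ``unmapped_gene``, ``non_finite_value``, ``unknown_species``), mirroring
    exclusion-with-accounting of unmappable entities during curation.

    Parameters
    ----------
    genes
        Optional cross-reference; when given, rows whose gene_id is absent
        from it are rejected as ``unmapped_gene``.
    """
    df = _read_csv(path, STAT_COLUMNS)
    records: list[StatRecord] = []
    report: Counter = Counter()
    for row in df.itertuples(index=False):
        if row.source_id not in sources:
            report["unknown_source"] += 1
            continue
        if row.endpoint_name not in sources[row.source_id].endpoints:
            report["unknown_endpoint"] += 1
            continue
        if genes is not None and row.gene_id not in genes:
            report["unmapped_gene"] += 1
            continue
        if row.species not in SPECIES:
            report["unknown_species"] += 1
            continue
        try:
            value = float(row.value)
        except ValueError:
            value = math.nan
        if not math.isfinite(value):
            report["non_finite_value"] += 1
            continue
        records.append(StatRecord(
            gene_id=row.gene_id,
            cell_type_id=row.cell_type_id,
            source_id=row.source_id,
            endpoint_name=row.endpoint_name,
            value=value,
            species=row.species,
        ))
    return records, report


def write_stat_table(records: Iterable[StatRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "cell_type_id": r.cell_type_id,
            "source_id": r.source_id,
            "endpoint_name": r.endpoint_name,
            "value": repr(r.value),
            "species": r.species,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=STAT_COLUMNS).to_csv(path, index=False)
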
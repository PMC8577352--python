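"""Marker gene classification across sources and species.

The decision flow per gene:

1. **Aggregate** per-source marker gene scores for each (gene, cell type)
   pair: mean, median, fraction of sources at or above 0.5, and per-species
   medians.  A source contributes one value per pair (the mean of its
   per-species records) so dual-species sources are not double-weighted.
2. **Gate**: a gene reported in fewer than 4 cell types is indeterminate --
   too sparse to judge specificity -- unless some single cell type was
   analyzed by at least 4 separate sources (2 for rare cell types such as
   pancreatic epsilon cells), which rescues highly specific genes that are
   simply never tested elsewhere.
3. **Count and label**: X = number of cell types whose aggregated score is
   significant.  X=0 -> non-marker.  X=1 -> marker for that cell type,
   with the specificity propagated up its ontology branch.  X>=2 -> count
   the distinct higher-level groups Y of those cell types: Y=1 means the
   gene marks the higher-level cell type itself (not the subtypes); Y>=2
   with X within the 2-cell-type cap can still be a dual marker
   (configurable), otherwise the gene lacks specificity and is a
   non-marker.
4. **Species call** per marker cell type: specificity to one species
   requires a 3-fold difference in median score between species with the
   larger median exceeding 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from statistics import median
from typing import Iterable, Mapping, Sequence

import pandas as pd

from markerscore.errors import ConfigurationError, OntologyError, ValidationError
from markerscore.ontology import CellOntology
from markerscore.scoring import ScoreRecord

LABELS = ("marker", "higher_level_marker", "non_marker", "indeterminate")
SPECIES_CALLS = ("both", "mouse_specific", "human_specific", "insufficient")

_FRAC_TOL = 1e-9  # guards 2/3 comparisons against float division noise


@dataclass(frozen=True)
class AggregatedPair:
    """Cross-source summary for one (gene, cell type) pair."""

    gene_id: str
    cell_type_id: str
    mean_score: float
    median_score: float
    frac_significant_sources: float
    n_sources: int
    n_significant_sources: int
    per_species_median: Mapping[str, float]


@dataclass
class GeneClassification:
    """Final call for one gene."""

    gene_id: str
    label: str
    marker_cell_types: tuple[str, ...] = ()
    propagated_cell_types: tuple[str, ...] = ()
    species_call: dict[str, str] = field(default_factory=dict)
    X: int = 0
    Y: int = 0
    n_sources: int = 0


@dataclass
class ClassifyConfig:
    """Tunable thresholds of the classification algorithm."""

    rule: str = "mean"                 # "mean" | "two_thirds"
    dual_marker_policy: str = "allow"  # "allow" | "forbid"
    max_marker_types: int = 2
    min_cell_types: int = 4
    min_sources_common: int = 4
    min_sources_rare: int = 2
    fold: float = 3.0
    min_median: float = 0.5
    rare_cell_types: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.rule not in ("mean", "two_thirds"):
            raise ConfigurationError(f"unknown significance rule {self.rule!r}")
        if self.dual_marker_policy not in ("allow", "forbid"):
            raise ConfigurationError(f"unknown dual_marker_policy {self.dual_marker_policy!r}")
        self.rare_cell_types = frozenset(self.rare_cell_types)

    @classmethod
    def from_json(cls, path) -> "ClassifyConfig":
        data = json.loads(open(path).read())
        return cls(**data)


def aggregate_pairs(scores: Iterable[ScoreRecord]) -> list[AggregatedPair]:
    """Summarize per-source scores per (gene, cell type) pair.

    Each source contributes one value to the cross-source mean/median/
    fraction: the mean of its per-species ScoreRecords for the pair.
    Per-species medians are taken over the species-resolved records.
    """
    by_pair: dict[tuple[str, str], dict[str, list[ScoreRecord]]] = {}
    for s in scores:
        by_pair.setdefault((s.gene_id, s.cell_type_id), {}).setdefault(s.source_id, []).append(s)

    out = []
    for (gene_id, cell_type_id), by_source in sorted(by_pair.items()):
        source_values = []
        per_species: dict[str, list[float]] = {}
        for source_id in sorted(by_source):
            recs = by_source[source_id]
            source_values.append(
                sum(r.marker_gene_score for r in recs) / len(recs)
            )
            for r in recs:
                per_species.setdefault(r.species, []).append(r.marker_gene_score)
        n_sig = sum(1 for v in source_values if v >= 0.5)
        out.append(AggregatedPair(
            gene_id=gene_id,
            cell_type_id=cell_type_id,
            mean_score=sum(source_values) / len(source_values),
            median_score=median(source_values),
            frac_significant_sources=n_sig / len(source_values),
            n_sources=len(source_values),
            n_significant_sources=n_sig,
            per_species_median={sp: median(vs) for sp, vs in sorted(per_species.items())},
        ))
    return out


def gate_indeterminate(
    pairs: Sequence[AggregatedPair],
    rare_types: frozenset[str] | set[str] = frozenset(),
    min_cell_types: int = 4,
    min_sources_common: int = 4,
    min_sources_rare: int = 2,
) -> bool:
    """Return True when the gene has enough data to classify (else indeterminate).

    A gene reported in fewer than ``min_cell_types`` distinct cell types is
    indeterminate unless a single cell type was analyzed by enough separate
    sources (the rescue threshold is lower for rare cell types).
    """
    if not pairs:
        return False
    gene_ids = {p.gene_id for p in pairs}
    if len(gene_ids) != 1:
        raise ValidationError(f"gate_indeterminate expects one gene, got {sorted(gene_ids)}")
    if len({p.cell_type_id for p in pairs}) >= min_cell_types:
        return True
    for p in pairs:
        need = min_sources_rare if p.cell_type_id in rare_types else min_sources_common
        if p.n_sources >= need:
            return True
    return False


def _is_significant(pair: AggregatedPair, rule: str) -> bool:
    if rule == "mean":
        return pair.mean_score >= 0.5
    if rule == "two_thirds":
        return pair.frac_significant_sources >= (2.0 / 3.0) - _FRAC_TOL
    raise ConfigurationError(f"unknown significance rule {rule!r}")


def classify_gene(
    pairs: Sequence[AggregatedPair],
    tree: CellOntology,
    rule: str = "mean",
    dual_marker_policy: str = "allow",
    max_marker_types: int = 2,
) -> GeneClassification:
    """Apply the X/Y decision flow to one gene's aggregated pairs.

    Assumes the gene already passed :func:`gate_indeterminate`.  Ties at
    exactly 0.5 count as significant.  ``dual_marker_policy="forbid"`` is
    the stricter reading under which any spread over >=2 higher-level
    groups voids the marker call; ``"allow"`` (default) permits up to
    ``max_marker_types`` cell types in distinct groups as a dual marker.
    """
    gene_ids = {p.gene_id for p in pairs}
    if len(gene_ids) != 1:
        raise ValidationError(f"classify_gene expects one gene, got {sorted(gene_ids)}")
    gene_id = gene_ids.pop()
    for p in pairs:
        if p.cell_type_id not in tree:
            raise OntologyError(f"cell type {p.cell_type_id!r} not in the pruned tree")

    n_sources = max(p.n_sources for p in pairs)

    significant = sorted({p.cell_type_id for p in pairs if _is_significant(p, rule)})
    X = len(significant)

    if X == 0:
        return GeneClassification(gene_id=gene_id, label="non_marker", X=0, Y=0,
                                  n_sources=n_sources)

    groups = sorted({tree.higher_level_group(c) for c in significant})
    Y = len(groups)

    if X == 1:
        markers = tuple(significant)
    elif Y == 1:
        # subtypes within one higher-level group: the gene marks the group,
        # NOT the individual subtypes
        markers = (groups[0],)
    elif dual_marker_policy == "allow" and X <= max_marker_types:
        markers = tuple(significant)
    else:
        return GeneClassification(gene_id=gene_id, label="non_marker", X=X, Y=Y,
                                  n_sources=n_sources)

    label = "higher_level_marker" if (X >= 2 and Y == 1) else "marker"
    propagated = sorted(
        set().union(*(tree.ancestors(m)[1:] for m in markers)) - set(markers)
    )
    return GeneClassification(
        gene_id=gene_id,
        label=label,
        marker_cell_types=markers,
        propagated_cell_types=tuple(propagated),
        X=X,
        Y=Y,
        n_sources=n_sources,
    )


def species_specificity(
    per_species_median: Mapping[str, float],
    fold: float = 3.0,
    min_median: float = 0.5,
) -> str:
    """Call mouse/human specificity from per-species median scores.

    One observed species -> "insufficient".  Otherwise the higher-median
    species is called specific iff its median exceeds ``min_median`` and is
    at least ``fold`` times the lower one (a zero lower median counts as an
    infinite fold); otherwise the marker holds in both species.
    """
    for sp, v in per_species_median.items():
        if v < 0:
            raise ValidationError(f"negative median {v} for species {sp!r}")
    if len(per_species_median) < 2:
        return "insufficient"
    (sp_a, a), (sp_b, b) = sorted(per_species_median.items())
    hi_sp, hi, lo = (sp_a, a, b) if a >= b else (sp_b, b, a)
    if hi > min_median and (lo == 0.0 or hi / lo >= fold):
        if hi == lo:  # equal medians can never differ fold-wise (fold >= 1)
            return "both"
        return f"{hi_sp}_specific"
    return "both"


def _pooled_species_medians(
    sig_pairs: Sequence[AggregatedPair],
) -> dict[str, float]:
    """Combine per-species medians of several subtype pairs (median of medians)."""
    pooled: dict[str, list[float]] = {}
    for p in sig_pairs:
        for sp, v in p.per_species_median.items():
            pooled.setdefault(sp, []).append(v)
    return {sp: median(vs) for sp, vs in sorted(pooled.items())}


@dataclass
class ClassificationSummary:
    """Corpus tallies over one classification run."""

    n_genes: int = 0
    labels: dict[str, int] = field(default_factory=lambda: {l: 0 for l in LABELS})
    markers_per_cell_type: dict[str, int] = field(default_factory=dict)
    manual_review_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def classify_all(
    scores: Iterable[ScoreRecord],
    tree: CellOntology,
    config: ClassifyConfig | None = None,
) -> tuple[list[GeneClassification], ClassificationSummary]:
    """Aggregate -> gate -> classify -> species-call every gene.

    Genes failing the sparsity gate are labelled indeterminate even if some
    pair is individually significant: the gate precedes counting.  Genes
    whose significant cell types span more than two higher-level groups are
    listed for manual review (their branch assignments may predate pruning)
    in addition to receiving their automatic label.
    """
    config = config or ClassifyConfig()
    pairs = aggregate_pairs(scores)
    by_gene: dict[str, list[AggregatedPair]] = {}
    for p in pairs:
        by_gene.setdefault(p.gene_id, []).append(p)

    results: list[GeneClassification] = []
    summary = ClassificationSummary()
    for gene_id in sorted(by_gene):
        gene_pairs = by_gene[gene_id]
        if not gate_indeterminate(
            gene_pairs,
            rare_types=config.rare_cell_types,
            min_cell_types=config.min_cell_types,
            min_sources_common=config.min_sources_common,
            min_sources_rare=config.min_sources_rare,
        ):
            cls = GeneClassification(
                gene_id=gene_id,
                label="indeterminate",
                n_sources=max(p.n_sources for p in gene_pairs),
            )
        else:
            cls = classify_gene(
                gene_pairs,
                tree,
                rule=config.rule,
                dual_marker_policy=config.dual_marker_policy,
                max_marker_types=config.max_marker_types,
            )
            by_ct = {p.cell_type_id: p for p in gene_pairs}
            for mct in cls.marker_cell_types:
                if mct in by_ct:
                    medians = dict(by_ct[mct].per_species_median)
                else:
                    # higher-level marker: pool the significant subtype pairs
                    sig = [
                        p for p in gene_pairs
                        if _is_significant(p, config.rule)
                        and tree.higher_level_group(p.cell_type_id) == mct
                    ]
                    medians = _pooled_species_medians(sig)
                cls.species_call[mct] = species_specificity(
                    medians, fold=config.fold, min_median=config.min_median
                )
            if cls.Y > 2:
                summary.manual_review_genes.append(gene_id)

        results.append(cls)
        summary.n_genes += 1
        summary.labels[cls.label] += 1
        for mct in cls.marker_cell_types:
            summary.markers_per_cell_type[mct] = summary.markers_per_cell_type.get(mct, 0) + 1
    summary.markers_per_cell_type = dict(sorted(summary.markers_per_cell_type.items()))
    return results, summary


MARKER_COLUMNS = [
    "gene_id", "label", "marker_cell_types", "propagated_cell_types",
    "species_call", "X", "Y", "n_sources",
]


def write_classifications(results: Iterable[GeneClassification], path) -> None:
    rows = [
        {
            "gene_id": c.gene_id,
            "label": c.label,
            "marker_cell_types": ";".join(c.marker_cell_types),
            "propagated_cell_types": ";".join(c.propagated_cell_types),
            "species_call": ";".join(c.species_call.get(m, "") for m in c.marker_cell_types),
            "X": c.X,
            "Y": c.Y,
            "n_sources": c.n_sources,
        }
        for c in results
    ]
    pd.DataFrame(rows, columns=MARKER_COLUMNS).to_csv(path, index=False)
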
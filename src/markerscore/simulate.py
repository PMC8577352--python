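"""Synthetic fixture generator with planted ground-truth markers.

The generator works at the statistics layer, not the read layer: it first
draws the *latent preliminary score* it intends each (gene, cell type,
source) observation to have, then inverse-maps that score through each
endpoint's cutoff-anchored linear scale to a raw value on the endpoint's
own units.  Re-normalizing the written table therefore recovers the latent
scores exactly when ``noise_sd = 0``, and every planted label is decodable
by construction.

Planted classes
---------------
marker
    significant (latent ~ U[0.75, 0.95]) in one leaf cell type across all
    sources, non-significant (latent ~ U[0.05, 0.35]) in three decoy leaves.
species-specific marker
    as above, but the off-species sources observe a low latent
    (~ U[0.15, 0.25]) while the specific species observes ~ U[0.85, 0.95],
    giving a >= 3-fold median split with the cross-species mean still
    significant.
higher-level marker
    significant in two sibling leaves of one higher-level group (plus two
    decoys elsewhere), so X = 2 and Y = 1.
non-marker
    non-significant everywhere across four leaves.

The ontology is a balanced tree (configurable depth and branching) whose
depth-1 nodes are the higher-level groups; sources are single-species and
alternate mouse/human; each source carries 1-3 endpoints with heterogeneous
ranges, cutoffs and directions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from markerscore.errors import ConfigurationError
from markerscore.io import (
    Direction,
    EndpointDefinition,
    GeneRecord,
    GeneXref,
    SourceMetadata,
    StatRecord,
    write_gene_xref,
    write_sources,
    write_stat_table,
)
from markerscore.ontology import CellOntology, CellTypeNode
from markerscore.scoring import denormalize_score


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 500
    n_sources: int = 6
    ontology_depth: int = 3
    children_per_node: int = 3
    planted_marker_fraction: float = 0.30
    planted_higher_level_fraction: float = 0.15
    planted_species_specific_fraction: float = 0.20
    noise_sd: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("planted_marker_fraction", "planted_higher_level_fraction",
                     "planted_species_specific_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_genes", "n_sources"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.ontology_depth < 2 or self.children_per_node < 2:
            raise ConfigurationError(
                "ontology_depth and children_per_node must be >= 2 so the tree "
                "has higher-level groups with multiple subtypes"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.planted_marker_fraction + self.planted_higher_level_fraction > 1.0:
            raise ConfigurationError("planted fractions exceed 1")

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class GroundTruthEntry:
    label: str
    cell_types: tuple[str, ...]
    species_call: str  # expected call for each marker cell type; "" for non-markers


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    sources: dict[str, SourceMetadata]
    genes: GeneXref
    ontology: CellOntology
    stats: list[StatRecord]
    truth: dict[str, GroundTruthEntry]
    warnings: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        """Write exactly the CSV/JSON dialects the other modules read."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sources(self.sources, outdir / "sources.json")
        write_gene_xref(self.genes, outdir / "genes.csv")
        self.ontology.write(outdir / "tree.csv")
        # raw node/edge tables in the pruning-input dialect
        frame = self.ontology.to_frame()
        frame[["node_id", "name", "is_higher_level", "is_rare", "keep"]].to_csv(
            outdir / "nodes.csv", index=False)
        edges = frame[frame.parent_id != ""][["node_id", "parent_id"]]
        edges.rename(columns={"node_id": "child_id"}).to_csv(
            outdir / "edges.csv", index=False)
        write_stat_table(self.stats, outdir / "stats.csv")
        truth = {g: asdict(t) for g, t in sorted(self.truth.items())}
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
        meta = {"config": asdict(self.config), "warnings": self.warnings}
        (outdir / "sim_meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def _build_ontology(depth: int, branching: int) -> CellOntology:
    nodes = [CellTypeNode("CT:0", name="somatic cell")]
    edges: list[tuple[str, str]] = []
    frontier = ["CT:0"]
    for level in range(1, depth + 1):
        nxt = []
        for parent in frontier:
            for k in range(branching):
                cid = f"{parent}.{k}"
                nodes.append(CellTypeNode(
                    cid,
                    name=f"cell type {cid[3:]}",
                    is_higher_level=(level == 1),
                ))
                edges.append((parent, cid))
                nxt.append(cid)
        frontier = nxt
    # flag the last leaf rare so rare-type gating is exercised by fixtures
    rare = frontier[-1]
    nodes = [
        CellTypeNode(n.cell_type_id, n.name, n.is_higher_level, is_rare=(n.cell_type_id == rare))
        for n in nodes
    ]
    return CellOntology(nodes, edges)


_ENDPOINT_TEMPLATES = ("lfc", "adj_p", "auc", "enrichment")


def _make_endpoint(kind: str, rng: np.random.Generator) -> EndpointDefinition:
    if kind == "lfc":
        return EndpointDefinition("lfc", Direction.LOWER, -9.0, 0.0,
                                  round(float(rng.uniform(-4.0, -1.0)), 2))
    if kind == "adj_p":
        return EndpointDefinition("adj_p", Direction.LOWER, 0.0, 1.0,
                                  float(rng.choice([0.01, 0.05, 0.1])))
    if kind == "auc":
        return EndpointDefinition("auc", Direction.HIGHER, 0.0, 1.0,
                                  round(float(rng.uniform(0.6, 0.8)), 2))
    return EndpointDefinition("enrichment", Direction.HIGHER, 0.0, 50.0,
                              round(float(rng.uniform(10.0, 30.0)), 1))


def _make_sources(n_sources: int, rng: np.random.Generator) -> dict[str, SourceMetadata]:
    sources = {}
    for i in range(n_sources):
        sid = f"S{i + 1:02d}"
        species = "mouse" if i % 2 == 0 else "human"
        k = int(rng.integers(1, 4))
        kinds = rng.choice(len(_ENDPOINT_TEMPLATES), size=k, replace=False)
        eps = {}
        for j in sorted(kinds):
            ep = _make_endpoint(_ENDPOINT_TEMPLATES[j], rng)
            eps[ep.endpoint_name] = ep
        sources[sid] = SourceMetadata(
            source_id=sid,
            species=frozenset([species]),
            endpoints=eps,
            sample_type="normal tissue",
            expression_method="scRNA-seq",
            statistical_method="differential expression",
        )
    return sources


def _make_genes(n_genes: int) -> GeneXref:
    recs = []
    for i in range(n_genes):
        recs.append(GeneRecord(
            gene_id=f"G{i:05d}",
            mouse_symbol=f"Simgene{i}",
            human_symbol=f"SIMGENE{i}",
            entrez_ids=(str(100000 + i),),
            ensembl_ids=(f"ENSMUSG{i:011d}", f"ENSG{i:011d}"),
        ))
    return GeneXref(recs)


# latent preliminary-score bands per planted role
_SIG = (0.75, 0.95)
_NONSIG = (0.05, 0.35)
_SPEC_ON = (0.85, 0.95)
_SPEC_OFF = (0.15, 0.25)


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate a self-consistent dataset with planted ground truth.

    Reproducible: the same config (including seed) yields identical output,
    file-for-file and byte-for-byte when written.
    """
    rng = np.random.default_rng(config.seed)
    ontology = _build_ontology(config.ontology_depth, config.children_per_node)
    sources = _make_sources(config.n_sources, rng)
    genes = _make_genes(config.n_genes)

    leaves = sorted(i for i in ontology.nodes if not ontology.children[i])
    groups = {leaf: ontology.higher_level_group(leaf) for leaf in leaves}
    group_ids = sorted(set(groups.values()))
    leaves_by_group = {g: [l for l in leaves if groups[l] == g] for g in group_ids}

    species_counts = {"mouse": 0, "human": 0}
    for meta in sources.values():
        for sp in meta.species:
            species_counts[sp] += 1
    both_species = species_counts["mouse"] > 0 and species_counts["human"] > 0
    base_call = "both" if both_species else "insufficient"

    n = config.n_genes
    n_marker = round(config.planted_marker_fraction * n)
    n_higher = round(config.planted_higher_level_fraction * n)
    n_spec = round(config.planted_species_specific_fraction * n_marker) if both_species else 0

    warnings = []
    for cls_name, count in (("marker", n_marker), ("higher_level", n_higher),
                            ("species_specific", n_spec)):
        if count == 0:
            warnings.append(f"config implies 0 planted {cls_name} genes")
    if not both_species and config.planted_species_specific_fraction > 0:
        warnings.append("species-specific planting skipped: only one species among sources")

    # species-specific genes target whichever species has more sources; on a
    # tie they alternate, so the cross-species mean stays significant
    majority = ("mouse" if species_counts["mouse"] >= species_counts["human"] else "human")
    tie = species_counts["mouse"] == species_counts["human"]

    gene_ids = sorted(genes.records)
    truth: dict[str, GroundTruthEntry] = {}
    stats: list[StatRecord] = []
    spec_counter = 0

    def draw(lo_hi: tuple[float, float]) -> float:
        return float(rng.uniform(*lo_hi))

    def emit(gene_id: str, cell_type: str, latent_by_species: dict[str, float]) -> None:
        for sid in sorted(sources):
            meta = sources[sid]
            (species,) = meta.species
            latent = latent_by_species[species]
            for ep in meta.endpoints.values():
                s = latent
                if config.noise_sd > 0:
                    s = float(np.clip(latent + rng.normal(0.0, config.noise_sd), 0.0, 1.0))
                if config.missing_rate > 0 and rng.random() < config.missing_rate:
                    continue
                stats.append(StatRecord(
                    gene_id=gene_id,
                    cell_type_id=cell_type,
                    source_id=sid,
                    endpoint_name=ep.endpoint_name,
                    value=denormalize_score(s, ep),
                    species=species,
                ))

    def pick_decoys(exclude: set[str], k: int) -> list[str]:
        pool = [l for l in leaves if l not in exclude]
        idx = rng.choice(len(pool), size=k, replace=False)
        return [pool[i] for i in sorted(idx)]

    for gi, gene_id in enumerate(gene_ids):
        if gi < n_marker:
            target = leaves[int(rng.integers(len(leaves)))]
            decoys = pick_decoys({target}, 3)
            if gi < n_spec:
                on = majority if not tie else ("mouse" if spec_counter % 2 == 0 else "human")
                spec_counter += 1
                call = f"{on}_specific"
                emit(gene_id, target, {
                    sp: draw(_SPEC_ON) if sp == on else draw(_SPEC_OFF)
                    for sp in ("mouse", "human")
                })
            else:
                call = base_call
                emit(gene_id, target, {sp: draw(_SIG) for sp in ("mouse", "human")})
            for d in decoys:
                emit(gene_id, d, {sp: draw(_NONSIG) for sp in ("mouse", "human")})
            truth[gene_id] = GroundTruthEntry("marker", (target,), call)
        elif gi < n_marker + n_higher:
            g = group_ids[int(rng.integers(len(group_ids)))]
            members = leaves_by_group[g]
            idx = rng.choice(len(members), size=2, replace=False)
            subtypes = [members[i] for i in sorted(idx)]
            decoys = pick_decoys(set(members), 2)
            for st in subtypes:
                emit(gene_id, st, {sp: draw(_SIG) for sp in ("mouse", "human")})
            for d in decoys:
                emit(gene_id, d, {sp: draw(_NONSIG) for sp in ("mouse", "human")})
            truth[gene_id] = GroundTruthEntry("higher_level_marker", (g,), base_call)
        else:
            cts = pick_decoys(set(), 4)
            for ct in cts:
                emit(gene_id, ct, {sp: draw(_NONSIG) for sp in ("mouse", "human")})
            truth[gene_id] = GroundTruthEntry("non_marker", (), "")

    return SimulatedDataset(
        config=config,
        sources=sources,
        genes=genes,
        ontology=ontology,
        stats=stats,
        truth=truth,
        warnings=warnings,
    )


def recovery_rate(results, truth: dict[str, GroundTruthEntry]) -> float:
    """Fraction of truth genes whose label, cell types and species call match.

    For marker/higher-level genes the marker cell types must match the
    planted ones exactly, and every species call must equal the planted
    expectation; non-marker and indeterminate genes match on label alone.
    """
    by_gene = {c.gene_id: c for c in results}
    hits = 0
    for gene_id, t in truth.items():
        c = by_gene.get(gene_id)
        if c is None or c.label != t.label:
            continue
        if t.label in ("marker", "higher_level_marker"):
            if tuple(sorted(c.marker_cell_types)) != tuple(sorted(t.cell_types)):
                continue
            if any(call != t.species_call for call in c.species_call.values()):
                continue
        hits += 1
    return hits / len(truth) if truth else 1.0
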
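"""End-to-end pipeline: stats -> scores -> classifications, with a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

from markerscore.classify import (
    ClassifyConfig,
    classify_all,
    write_classifications,
)
from markerscore.errors import ValidationError
from markerscore.io import load_gene_xref, load_sources, load_stat_table
from markerscore.ontology import CellOntology
from markerscore.scoring import score_all, write_scores

log = logging.getLogger("markerscore")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    stats_path: str | Path,
    sources_path: str | Path,
    tree_path: str | Path,
    outdir: str | Path,
    config: ClassifyConfig | None = None,
    genes_path: str | Path | None = None,
) -> dict:
    """Score and classify a stats table; write markers, summary and manifest.

    Equivalent to composing score_all -> classify_all, and idempotent for
    fixed inputs and config (only the manifest timestamp changes between
    reruns).  Returns the manifest dict.
    """
    from markerscore import __version__

    config = config or ClassifyConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    inputs = {"stats": Path(stats_path), "sources": Path(sources_path),
              "tree": Path(tree_path)}
    if genes_path is not None:
        inputs["genes"] = Path(genes_path)
    for name, p in inputs.items():
        if not p.exists():
            raise ValidationError(f"{name} input file not found: {p}")

    sources = load_sources(inputs["sources"])
    tree = CellOntology.read(inputs["tree"])
    genes = load_gene_xref(inputs["genes"]) if "genes" in inputs else None
    records, report = load_stat_table(inputs["stats"], sources, genes)
    log.info("load: %d records accepted, %d rejected %s",
             len(records), sum(report.values()), dict(report))

    scores = score_all(records, sources)
    log.info("score: %d score records from %d sources", len(scores), len(sources))
    write_scores(scores, outdir / "scores.csv")

    results, summary = classify_all(scores, tree, config)
    log.info("classify: %d genes -> %s", summary.n_genes, summary.labels)
    write_classifications(results, outdir / "markers.csv")
    summary_dict = summary.to_dict()
    summary_dict["rejected_rows"] = dict(report)
    (outdir / "summary.json").write_text(json.dumps(summary_dict, indent=1, sort_keys=True) + "\n")

    manifest = {
        "tool_version": __version__,
        "config": asdict(config) | {"rare_cell_types": sorted(config.rare_cell_types)},
        "input_digests": {name: _digest(p) for name, p in inputs.items()},
        "row_counts": {
            "stats_in": len(records) + sum(report.values()),
            "stats_accepted": len(records),
            "stats_rejected": dict(report),
            "scores": len(scores),
            "genes_classified": summary.n_genes,
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
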
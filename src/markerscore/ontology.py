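"""Hierarchical cell-type ontology: pruning a raw DAG to a classification tree.

Cell Ontology is_a relationships form a multi-rooted DAG in which one cell
type (e.g. microglial cell) can hang under several branches (glial cell,
macrophage, myeloid cell).  Classification needs a tree/forest, so the raw
edge list is pruned deterministically:

1. every multi-parent node keeps exactly one parent -- the first match in a
   curator-supplied priority list, else the lexicographically smallest
   parent id (a reproducible stand-in for manual curation);
2. any remaining cycle is broken at the edge whose child has the
   lexicographically smallest id;
3. intermediate nodes with exactly one child that add no branching are
   collapsed away (roots, leaves and explicitly kept nodes are protected),
   repeatedly until a fixpoint.

Every removed edge and node is recorded in a pruning report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from markerscore.errors import OntologyError, ValidationError


@dataclass(frozen=True)
class CellTypeNode:
    cell_type_id: str
    name: str = ""
    is_higher_level: bool = False
    is_rare: bool = False
    keep: bool = False


@dataclass
class PruningReport:
    """Accounting of what pruning removed, and why."""

    removed_edges: list[dict] = field(default_factory=list)
    removed_nodes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"removed_edges": self.removed_edges, "removed_nodes": self.removed_nodes}


class CellOntology:
    """A pruned cell-type tree/forest with parent pointers.

    Invariants: acyclic; every non-root node has exactly one parent; every
    node reaches a root; no unprotected intermediate node has exactly one
    child.
    """

    def __init__(self, nodes: Iterable[CellTypeNode], edges: Iterable[tuple[str, str]]):
        self.nodes: dict[str, CellTypeNode] = {}
        for n in nodes:
            if n.cell_type_id in self.nodes:
                raise OntologyError(f"duplicate cell_type_id {n.cell_type_id!r}")
            self.nodes[n.cell_type_id] = n
        self.parent: dict[str, str] = {}
        self.children: dict[str, list[str]] = {i: [] for i in self.nodes}
        for parent, child in edges:
            for x in (parent, child):
                if x not in self.nodes:
                    raise OntologyError(f"edge references undeclared node {x!r}")
            if child in self.parent:
                raise OntologyError(f"node {child!r} has more than one parent")
            self.parent[child] = parent
            self.children[parent].append(child)
        for cs in self.children.values():
            cs.sort()
        self.roots = frozenset(i for i in self.nodes if i not in self.parent)
        # reject cycles: a ring has no root, so its members never reach one
        for node in self.nodes:
            self.ancestors(node)

    def __contains__(self, cell_type_id: str) -> bool:
        return cell_type_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def ancestors(self, cell_type_id: str) -> list[str]:
        """Path from the node (inclusive) up to its root."""
        if cell_type_id not in self.nodes:
            raise OntologyError(f"unknown cell_type_id {cell_type_id!r}")
        path = [cell_type_id]
        seen = {cell_type_id}
        while path[-1] in self.parent:
            nxt = self.parent[path[-1]]
            if nxt in seen:
                raise OntologyError(f"cycle through {nxt!r}: node cannot reach a root")
            path.append(nxt)
            seen.add(nxt)
        return path

    def higher_level_group(self, cell_type_id: str) -> str:
        """Nearest ancestor (including self) flagged is_higher_level.

        Falls back to the branch root when no ancestor carries the flag, so
        every cell type belongs to exactly one group.
        """
        path = self.ancestors(cell_type_id)
        for anc in path:
            if self.nodes[anc].is_higher_level:
                return anc
        return path[-1]

    def edges(self) -> list[tuple[str, str]]:
        return sorted((p, c) for c, p in self.parent.items())

    # -- persistence --------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "node_id": n.cell_type_id,
                "name": n.name,
                "parent_id": self.parent.get(n.cell_type_id, ""),
                "is_higher_level": int(n.is_higher_level),
                "is_rare": int(n.is_rare),
                "keep": int(n.keep),
            }
            for n in sorted(self.nodes.values(), key=lambda n: n.cell_type_id)
        ]
        return pd.DataFrame(
            rows, columns=["node_id", "name", "parent_id", "is_higher_level", "is_rare", "keep"]
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path) -> "CellOntology":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        for col in ("node_id", "parent_id"):
            if col not in df.columns:
                raise ValidationError(f"{path}: missing required column {col!r}")
        nodes = [
            CellTypeNode(
                cell_type_id=row.node_id,
                name=getattr(row, "name_", getattr(row, "name", "")) or "",
                is_higher_level=_flag(getattr(row, "is_higher_level", "0")),
                is_rare=_flag(getattr(row, "is_rare", "0")),
                keep=_flag(getattr(row, "keep", "0")),
            )
            for row in df.itertuples(index=False)
        ]
        edges = [
            (row.parent_id, row.node_id)
            for row in df.itertuples(index=False)
            if row.parent_id
        ]
        return cls(nodes, edges)


def _flag(x) -> bool:
    return str(x).strip().lower() in {"1", "true", "yes"}


def load_node_table(path: str | Path) -> list[CellTypeNode]:
    """Read the node annotation CSV: node_id,name,is_higher_level,is_rare,keep."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "node_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'node_id'")
    out = []
    for _, row in df.iterrows():
        out.append(CellTypeNode(
            cell_type_id=row["node_id"],
            name=row.get("name", "") or "",
            is_higher_level=_flag(row.get("is_higher_level", "0")),
            is_rare=_flag(row.get("is_rare", "0")),
            keep=_flag(row.get("keep", "0")),
        ))
    return out


def load_edge_table(path: str | Path) -> list[tuple[str, str]]:
    """Read the edge CSV: child_id,parent_id -> list of (parent, child)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("child_id", "parent_id"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    return [(row.parent_id, row.child_id) for row in df.itertuples(index=False)]


def load_parent_priority(path: str | Path) -> dict[str, list[str]]:
    """Read the priority CSV: child_id,parent_id ordered by preference."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("child_id", "parent_id"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    priority: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        priority.setdefault(row.child_id, []).append(row.parent_id)
    return priority


def read_obo(path: str | Path) -> tuple[list[CellTypeNode], list[tuple[str, str]]]:
    """Read an OBO-subset file, keeping only is_a relationships.

    Returns raw nodes/edges suitable for :func:`prune_to_tree`; annotation
    flags default to False and must be supplied separately if needed.
    """
    import obonet

    graph = obonet.read_obo(path)
    nodes = [
        CellTypeNode(cell_type_id=i, name=data.get("name", ""))
        for i, data in graph.nodes(data=True)
    ]
    # obonet orients is_a edges child -> parent
    edges = [
        (parent, child)
        for child, parent, key in graph.edges(keys=True)
        if key == "is_a"
    ]
    return nodes, edges


def prune_to_tree(
    nodes: Iterable[CellTypeNode],
    raw_edges: Iterable[tuple[str, str]],
    parent_priority: Mapping[str, Sequence[str]] | None = None,
    keep: Iterable[str] = (),
) -> tuple[CellOntology, PruningReport]:
    """Reduce a raw (possibly cyclic, multi-parent) edge list to a tree/forest.

    Parameters
    ----------
    nodes
        Declared cell-type nodes; an edge endpoint absent here is an error.
    raw_edges
        (parent, child) pairs; duplicates are merged.
    parent_priority
        Per-child ordered parent preference used to resolve multi-parent
        nodes; children absent from the map fall back to the
        lexicographically smallest parent.
    keep
        Extra node ids protected from chain collapsing (in addition to nodes
        whose ``keep`` flag is set).

    Returns
    -------
    (CellOntology, PruningReport)
        The pruned tree and the record of every removed edge and node.
    """
    parent_priority = dict(parent_priority or {})
    node_map = {}
    for n in nodes:
        if n.cell_type_id in node_map:
            raise OntologyError(f"duplicate cell_type_id {n.cell_type_id!r}")
        node_map[n.cell_type_id] = n
    keep_ids = set(keep) | {i for i, n in node_map.items() if n.keep}

    edge_set = set()
    for p, c in raw_edges:
        for x in (p, c):
            if x not in node_map:
                raise OntologyError(f"edge ({p!r} -> {c!r}) references undeclared node {x!r}")
        edge_set.add((p, c))

    report = PruningReport()

    # 1) single-parent resolution
    parents: dict[str, set[str]] = {}
    for p, c in edge_set:
        parents.setdefault(c, set()).add(p)
    parent: dict[str, str] = {}
    for c in sorted(parents):
        ps = parents[c]
        chosen = None
        for pref in parent_priority.get(c, ()):
            if pref in ps:
                chosen = pref
                break
        if chosen is None:
            chosen = min(ps)
        for p in sorted(ps - {chosen}):
            report.removed_edges.append({"parent": p, "child": c, "reason": "multi_parent"})
        parent[c] = chosen

    # 2) cycle breaking: with one parent per node every cycle is a simple
    # ring; cut it at the edge whose child id sorts first
    g = nx.DiGraph()
    g.add_nodes_from(node_map)
    g.add_edges_from((p, c) for c, p in parent.items())
    for ring in nx.simple_cycles(g):
        child = min(ring)
        report.removed_edges.append(
            {"parent": parent[child], "child": child, "reason": "cycle"}
        )
        del parent[child]

    # 3) chain collapsing to fixpoint
    children: dict[str, set[str]] = {i: set() for i in node_map}
    for c, p in parent.items():
        children[p].add(c)
    alive = set(node_map)
    changed = True
    while changed:
        changed = False
        for n in sorted(alive):
            if n not in parent:           # root
                continue
            if n in keep_ids:
                continue
            ch = children[n]
            if len(ch) != 1:              # leaf or branching node
                continue
            (only_child,) = ch
            p = parent[n]
            parent[only_child] = p
            children[p].discard(n)
            children[p].add(only_child)
            del parent[n]
            del children[n]
            alive.discard(n)
            report.removed_nodes.append(n)
            changed = True
    report.removed_nodes.sort()

    tree = CellOntology(
        [node_map[i] for i in sorted(alive)],
        [(p, c) for c, p in parent.items()],
    )
    return tree, report
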
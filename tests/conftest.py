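import pytest

from markerscore.io import Direction, EndpointDefinition, SourceMetadata
from markerscore.ontology import CellOntology, CellTypeNode


@pytest.fixture
def lfc_endpoint():
    """Log fold change enrichment: range [-9, 0], cutoff -2, lower significant."""
    return EndpointDefinition("lfc", Direction.LOWER, -9.0, 0.0, -2.0)


@pytest.fixture
def adjp_endpoint():
    """Adjusted p-value: range [0, 1], cutoff 0.05, lower significant."""
    return EndpointDefinition("adj_p", Direction.LOWER, 0.0, 1.0, 0.05)


@pytest.fixture
def source1(lfc_endpoint, adjp_endpoint):
    """The two-endpoint example source used throughout the docs."""
    return SourceMetadata(
        source_id="source1",
        species=frozenset({"mouse"}),
        endpoints={"lfc": lfc_endpoint, "adj_p": adjp_endpoint},
        sample_type="normal tissue",
        expression_method="scRNA-seq",
        statistical_method="wilcoxon",
    )


@pytest.fixture
def cell_tree():
    """Small hand-built ontology.

    somatic-cell
      connective-tissue-cell*      (higher level)
        fibroblast, osteoblast, chondrocyte
      t-cell*                      (higher level)
        cd4-t, cd8-t
      pancreatic-epsilon-cell      (rare, no flagged ancestor -> root group)
    """
    nodes = [
        CellTypeNode("somatic-cell", "somatic cell"),
        CellTypeNode("connective-tissue-cell", "connective tissue cell", is_higher_level=True),
        CellTypeNode("t-cell", "T cell", is_higher_level=True),
        CellTypeNode("fibroblast", "fibroblast"),
        CellTypeNode("osteoblast", "osteoblast"),
        CellTypeNode("chondrocyte", "chondrocyte"),
        CellTypeNode("cd4-t", "CD4-positive T cell"),
        CellTypeNode("cd8-t", "CD8-positive T cell"),
        CellTypeNode("pancreatic-epsilon-cell", "pancreatic epsilon cell", is_rare=True),
    ]
    edges = [
        ("somatic-cell", "connective-tissue-cell"),
        ("somatic-cell", "t-cell"),
        ("somatic-cell", "pancreatic-epsilon-cell"),
        ("connective-tissue-cell", "fibroblast"),
        ("connective-tissue-cell", "osteoblast"),
        ("connective-tissue-cell", "chondrocyte"),
        ("t-cell", "cd4-t"),
        ("t-cell", "cd8-t"),
    ]
    return CellOntology(nodes, edges)
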
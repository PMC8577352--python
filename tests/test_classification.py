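"""Classification algorithm: aggregation, gating, X/Y decision flow, species calls."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from markerscore.classify import (
    AggregatedPair,
    ClassifyConfig,
    aggregate_pairs,
    classify_all,
    classify_gene,
    gate_indeterminate,
    species_specificity,
)
from markerscore.errors import OntologyError
from markerscore.scoring import ScoreRecord


def _score(gene, ct, source, score, species="mouse"):
    return ScoreRecord(gene, ct, source, species, score, 1)


def _pair(gene, ct, mean=0.0, frac=0.0, n_sources=4, medians=None):
    n_sig = round(frac * n_sources)
    return AggregatedPair(
        gene_id=gene, cell_type_id=ct, mean_score=mean, median_score=mean,
        frac_significant_sources=frac, n_sources=n_sources,
        n_significant_sources=n_sig,
        per_species_median=medians or {"mouse": mean},
    )


class TestAggregatePairs:
    def test_single_source(self):
        (p,) = aggregate_pairs([_score("G1", "c", "s1", 0.75)])
        assert (p.mean_score, p.median_score) == (0.75, 0.75)
        assert p.frac_significant_sources == 1.0
        assert p.n_sources == 1

    def test_three_sources(self):
        scores = [_score("G1", "c", s, v) for s, v in [("s1", 0.9), ("s2", 0.5), ("s3", 0.1)]]
        (p,) = aggregate_pairs(scores)
        assert p.mean_score == pytest.approx(0.5)
        assert p.frac_significant_sources == pytest.approx(2 / 3)

    def test_per_species_medians(self):
        scores = [
            _score("G1", "c", "s1", 0.9, "mouse"),
            _score("G1", "c", "s2", 0.8, "mouse"),
            _score("G1", "c", "s3", 0.2, "human"),
        ]
        (p,) = aggregate_pairs(scores)
        assert p.per_species_median == {"mouse": pytest.approx(0.85), "human": 0.2}

    def test_dual_species_source_contributes_one_value(self):
        # one source with mouse 1.0 + human 0.0 must not outweigh a
        # single-species source: it contributes its within-source mean, 0.5
        scores = [
            _score("G1", "c", "s1", 1.0, "mouse"),
            _score("G1", "c", "s1", 0.0, "human"),
            _score("G1", "c", "s2", 0.3, "mouse"),
        ]
        (p,) = aggregate_pairs(scores)
        assert p.n_sources == 2
        assert p.mean_score == pytest.approx(0.4)  # (0.5 + 0.3) / 2

    def test_empty_input_is_empty_output(self):
        assert aggregate_pairs([]) == []


class TestGate:
    def test_three_cell_types_one_source_each_is_indeterminate(self):
        pairs = [_pair("G", f"c{i}", n_sources=1) for i in range(3)]
        assert gate_indeterminate(pairs) is False

    def test_rescued_by_four_sources_on_one_cell_type(self):
        pairs = [_pair("G", "c0", n_sources=4), _pair("G", "c1", n_sources=1)]
        assert gate_indeterminate(pairs) is True

    def test_rare_cell_type_needs_only_two_sources(self):
        pairs = [_pair("G", "pancreatic-epsilon-cell", n_sources=2)]
        assert gate_indeterminate(pairs, rare_types={"pancreatic-epsilon-cell"}) is True
        assert gate_indeterminate(pairs) is False

    def test_enough_cell_types_proceeds_regardless_of_sources(self):
        pairs = [_pair("G", f"c{i}", n_sources=1) for i in range(5)]
        assert gate_indeterminate(pairs) is True


class TestClassifyGene:
    def test_no_significant_pairs_is_non_marker(self, cell_tree):
        pairs = [_pair("G", ct, mean=0.3) for ct in ("fibroblast", "cd4-t", "cd8-t", "osteoblast")]
        cls = classify_gene(pairs, cell_tree)
        assert cls.label == "non_marker" and cls.X == 0

    def test_single_cell_type_marker_with_propagation(self, cell_tree):
        pairs = [_pair("G", "fibroblast", mean=0.8)] + [
            _pair("G", ct, mean=0.2) for ct in ("cd4-t", "cd8-t", "osteoblast")]
        cls = classify_gene(pairs, cell_tree)
        assert cls.label == "marker"
        assert cls.marker_cell_types == ("fibroblast",)
        assert cls.propagated_cell_types == ("connective-tissue-cell", "somatic-cell")

    def test_subtypes_of_one_group_become_higher_level_marker(self, cell_tree):
        pairs = [
            _pair("G", ct, mean=0.9)
            for ct in ("fibroblast", "osteoblast", "chondrocyte")
        ] + [_pair("G", "cd4-t", mean=0.1)]
        cls = classify_gene(pairs, cell_tree)
        assert cls.label == "higher_level_marker"
        # the group itself, NOT the subtypes
        assert cls.marker_cell_types == ("connective-tissue-cell",)
        assert cls.propagated_cell_types == ("somatic-cell",)
        assert (cls.X, cls.Y) == (3, 1)

    def test_three_cell_types_across_groups_is_non_marker(self, cell_tree):
        pairs = [
            _pair("G", ct, mean=0.9) for ct in ("fibroblast", "osteoblast", "cd4-t")
        ] + [_pair("G", "cd8-t", mean=0.1)]
        cls = classify_gene(pairs, cell_tree)
        assert cls.label == "non_marker"
        assert (cls.X, cls.Y) == (3, 2)

    def test_two_cell_types_across_groups_is_dual_marker(self, cell_tree):
        pairs = [
            _pair("G", "fibroblast", mean=0.9), _pair("G", "cd4-t", mean=0.8),
            _pair("G", "cd8-t", mean=0.1), _pair("G", "osteoblast", mean=0.1),
        ]
        cls = classify_gene(pairs, cell_tree)
        assert cls.label == "marker"
        assert cls.marker_cell_types == ("cd4-t", "fibroblast")
        assert set(cls.propagated_cell_types) == {
            "connective-tissue-cell", "t-cell", "somatic-cell"}

    def test_forbid_policy_voids_dual_markers(self, cell_tree):
        pairs = [
            _pair("G", "fibroblast", mean=0.9), _pair("G", "cd4-t", mean=0.8),
            _pair("G", "cd8-t", mean=0.1), _pair("G", "osteoblast", mean=0.1),
        ]
        cls = classify_gene(pairs, cell_tree, dual_marker_policy="forbid")
        assert cls.label == "non_marker"

    def test_tie_at_half_counts_significant(self, cell_tree):
        pairs = [_pair("G", "fibroblast", mean=0.5)] + [
            _pair("G", ct, mean=0.1) for ct in ("cd4-t", "cd8-t", "osteoblast")]
        assert classify_gene(pairs, cell_tree).label == "marker"

    def test_two_thirds_rule_uses_source_fractions(self, cell_tree):
        pairs = [
            _pair("G", "fibroblast", mean=0.4, frac=2 / 3, n_sources=3),
            _pair("G", "cd4-t", mean=0.9, frac=1 / 3, n_sources=3),
            _pair("G", "cd8-t", mean=0.1, frac=0.0),
            _pair("G", "osteoblast", mean=0.1, frac=0.0),
        ]
        cls = classify_gene(pairs, cell_tree, rule="two_thirds")
        assert cls.label == "marker"
        assert cls.marker_cell_types == ("fibroblast",)

    def test_unknown_cell_type_errors(self, cell_tree):
        with pytest.raises(OntologyError):
            classify_gene([_pair("G", "astrocyte", mean=0.9)], cell_tree)


class TestSpeciesSpecificity:
    @pytest.mark.parametrize("medians,expected", [
        ({"mouse": 0.9, "human": 0.2}, "mouse_specific"),   # ratio 4.5, hi > 0.5
        ({"mouse": 0.6, "human": 0.6}, "both"),             # equal medians
        ({"mouse": 0.9, "human": 0.0}, "mouse_specific"),   # zero -> infinite fold
        ({"human": 0.8}, "insufficient"),                   # one species only
        ({"mouse": 0.2, "human": 0.9}, "human_specific"),
        ({"mouse": 0.9, "human": 0.4}, "both"),             # ratio 2.25 < 3
        ({"mouse": 0.45, "human": 0.1}, "both"),            # hi below 0.5
        ({"mouse": 0.5, "human": 0.1}, "both"),             # hi must EXCEED 0.5
    ])
    def test_rule_table(self, medians, expected):
        assert species_specificity(medians) == expected

    def test_negative_median_is_contract_violation(self):
        with pytest.raises(Exception):
            species_specificity({"mouse": -0.1, "human": 0.5})

    @settings(max_examples=100, deadline=None)
    @given(m=st.floats(0, 1), h=st.floats(0, 1))
    def test_swap_symmetry(self, m, h):
        call = species_specificity({"mouse": m, "human": h})
        swapped = species_specificity({"mouse": h, "human": m})
        flip = {"mouse_specific": "human_specific", "human_specific": "mouse_specific"}
        assert swapped == flip.get(call, call)


# ---------------------------------------------------------------------------
# independent brute-force oracle of the decision table
# ---------------------------------------------------------------------------

def oracle_decision(sig_cell_types, group_of, policy="allow", max_marker_types=2):
    """Literal restatement of the decision flow, independent of classify_gene."""
    X = len(sig_cell_types)
    if X == 0:
        return "non_marker", frozenset()
    if X == 1:
        return "marker", frozenset(sig_cell_types)
    groups = {group_of[c] for c in sig_cell_types}
    if len(groups) == 1:
        return "higher_level_marker", frozenset(groups)
    if policy == "allow" and X <= max_marker_types:
        return "marker", frozenset(sig_cell_types)
    return "non_marker", frozenset()


GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


def _grid_instances(cell_types, max_n=4):
    for n in range(1, min(len(cell_types), max_n) + 1):
        for values in itertools.product(GRID, repeat=n):
            yield list(zip(cell_types[:n], values))


@pytest.mark.parametrize("rule", ["mean", "two_thirds"])
@pytest.mark.parametrize("policy", ["allow", "forbid"])
def test_classify_gene_matches_brute_force_oracle(cell_tree, rule, policy):
    """Decision-table agreement on a grid of small instances (deeper sweep in acceptance)."""
    cell_types = ["fibroblast", "osteoblast", "cd4-t", "cd8-t"]
    group_of = {c: cell_tree.higher_level_group(c) for c in cell_types}
    for inst in _grid_instances(cell_types):
        pairs = [
            _pair("G", ct, mean=v, frac=v, n_sources=4) for ct, v in inst
        ]
        sig = frozenset(
            ct for ct, v in inst
            if (v >= 0.5 if rule == "mean" else v >= 2 / 3 - 1e-9)
        )
        want_label, want_markers = oracle_decision(sig, group_of, policy)
        got = classify_gene(pairs, cell_tree, rule=rule, dual_marker_policy=policy)
        assert got.label == want_label, (inst, rule, policy)
        assert frozenset(got.marker_cell_types) == want_markers


class TestClassifyAll:
    def test_empty_scores(self, cell_tree):
        results, summary = classify_all([], cell_tree)
        assert results == []
        assert summary.n_genes == 0 and all(v == 0 for v in summary.labels.values())

    def test_labels_partition_genes(self, cell_tree):
        scores = []
        # marker gene across 4 cell types
        for i, ct in enumerate(["fibroblast", "cd4-t", "cd8-t", "osteoblast"]):
            for s in ("s1", "s2"):
                scores.append(_score("G1", ct, s, 0.9 if ct == "fibroblast" else 0.1))
        # sparse gene: 1 cell type, 1 source
        scores.append(_score("G2", "fibroblast", "s1", 0.9))
        results, summary = classify_all(scores, cell_tree)
        assert summary.n_genes == len(results) == 2
        assert sum(summary.labels.values()) == 2
        by_gene = {c.gene_id: c.label for c in results}
        assert by_gene == {"G1": "marker", "G2": "indeterminate"}

    def test_gate_precedes_counting(self, cell_tree):
        # significant pair, but sparse: indeterminate wins
        scores = [_score("G1", "fibroblast", "s1", 1.0)]
        results, _ = classify_all(scores, cell_tree)
        assert results[0].label == "indeterminate"

    def test_rare_cell_type_rescue_via_config(self, cell_tree):
        scores = [
            _score("G1", "pancreatic-epsilon-cell", s, 0.9) for s in ("s1", "s2")]
        cfg = ClassifyConfig(rare_cell_types=frozenset({"pancreatic-epsilon-cell"}))
        results, _ = classify_all(scores, cell_tree, cfg)
        assert results[0].label == "marker"

    def test_species_call_attached_to_marker(self, cell_tree):
        scores = []
        for s, sp, v in [("s1", "mouse", 0.9), ("s2", "mouse", 0.95),
                         ("s3", "human", 0.2), ("s4", "human", 0.1)]:
            scores.append(_score("G1", "fibroblast", s, v, sp))
        for ct in ("cd4-t", "cd8-t", "osteoblast"):
            for s in ("s1", "s2", "s3", "s4"):
                scores.append(_score("G1", ct, s, 0.2))
        results, _ = classify_all(scores, cell_tree)
        (cls,) = results
        assert cls.label == "marker"
        assert cls.species_call == {"fibroblast": "mouse_specific"}

    def test_higher_level_species_call_pools_subtypes(self, cell_tree):
        scores = []
        for ct in ("fibroblast", "osteoblast"):
            for s, sp in [("s1", "mouse"), ("s2", "mouse"), ("s3", "human"), ("s4", "human")]:
                scores.append(_score("G1", ct, s, 0.9, sp))
        for ct in ("cd4-t", "cd8-t"):
            for s in ("s1", "s2", "s3", "s4"):
                scores.append(_score("G1", ct, s, 0.1))
        results, _ = classify_all(scores, cell_tree)
        (cls,) = results
        assert cls.label == "higher_level_marker"
        assert cls.species_call == {"connective-tissue-cell": "both"}

    def test_manual_review_report_for_many_groups(self, cell_tree):
        # significant in 3 branch groups -> automatic non-marker, flagged for review
        scores = []
        for ct in ("fibroblast", "cd4-t", "pancreatic-epsilon-cell", "osteoblast"):
            for s in ("s1", "s2"):
                v = 0.1 if ct == "osteoblast" else 0.9
                scores.append(_score("G1", ct, s, v))
        results, summary = classify_all(scores, cell_tree)
        assert results[0].label == "non_marker"
        assert summary.manual_review_genes == ["G1"]
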
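import random

import pytest

from ghsieve.io_formats import LeafAnnotation, LeafKind, parse_newick_support
from ghsieve.origin_filters import ThresholdConfig
from ghsieve.phylo_classifier import classify_origins, collapse_low_support

from _oracles import (
    build_support_tree,
    colored_topologies,
    oracle_classify,
    shape_colors,
)

CFG = ThresholdConfig()


def ann(queries=(), fungi=(), metazoa=(), plants=(), genome=()):
    table = {}
    for q in queries:
        table[q] = LeafAnnotation(LeafKind.QUERY, genome_verified=q in genome)
    for name, sfam in [(f, "Fungi") for f in fungi] + \
                      [(m, "Metazoa") for m in metazoa] + \
                      [(p, "Viridiplantae") for p in plants]:
        table[name] = LeafAnnotation(LeafKind.REFERENCE, superfamily=sfam)
    return table


def tree(newick, annotation):
    return parse_newick_support(newick, annotation)


class TestCollapse:
    def test_weak_edge_contracts_into_polytomy(self):
        t = tree("((q1,q2)40,(f1,f2)80);",
                 ann(queries=["q1", "q2"], fungi=["f1", "f2"]))
        collapsed = collapse_low_support(t, 50)
        # q1, q2 reattach to the root; the fungal clade survives
        root_leaf_names = {c.name for c in collapsed.root.children if c.is_leaf}
        assert root_leaf_names == {"q1", "q2"}
        kept = [c for c in collapsed.root.children if not c.is_leaf]
        assert len(kept) == 1 and kept[0].support == 80

    def test_threshold_zero_is_identity(self):
        t = tree("((q1,q2)40,(f1,f2)80);",
                 ann(queries=["q1", "q2"], fungi=["f1", "f2"]))
        assert collapse_low_support(t, 0).to_newick() == t.to_newick()

    def test_threshold_101_flattens_all_supported_edges(self):
        t = tree("((q1,q2)90,(f1,f2)80);",
                 ann(queries=["q1", "q2"], fungi=["f1", "f2"]))
        collapsed = collapse_low_support(t, 101)
        assert all(c.is_leaf for c in collapsed.root.children)
        assert len(collapsed.root.children) == 4

    def test_unsupported_edges_are_retained(self):
        t = tree("((q1,q2),(f1,f2)80);",
                 ann(queries=["q1", "q2"], fungi=["f1", "f2"]))
        collapsed = collapse_low_support(t, 50)
        assert len(collapsed.root.children) == 2  # absent support: keep

    def test_leaves_never_removed_and_no_weak_edge_survives(self):
        rng = random.Random(3)
        for shape in rng.sample(colored_topologies(6), 50):
            support = rng.choice([20, 45, 50, 80])
            t = build_support_tree(shape, support)
            collapsed = collapse_low_support(t, 50)
            assert sorted(collapsed.leaf_names()) == sorted(t.leaf_names())
            stack = [collapsed.root]
            while stack:
                node = stack.pop()
                for child in node.children:
                    if not child.is_leaf and child.support is not None:
                        assert child.support >= 50
                    stack.append(child)


class TestWorkedExamples:
    def test_query_pair_beside_fungal_clade_is_contamination(self):
        t = tree("((q1,q2)90,(f1,f2)80);",
                 ann(queries=["q1", "q2"], fungi=["f1", "f2"]))
        decisions = classify_origins(t, CFG)
        assert {d.label.value for d in decisions.values()} == {"EC"}
        assert decisions["q1"].enclosing_superfamilies == {"Fungi"}

    def test_single_query_nested_with_fungal_reference_is_contamination(self):
        t = tree("((q1,f1)85,(p1,p2)90);",
                 ann(queries=["q1"], fungi=["f1"], plants=["p1", "p2"]))
        decisions = classify_origins(t, CFG)
        assert decisions["q1"].label.value == "EC"

    def test_genome_verified_member_rescues_entire_clade(self):
        t = tree("((q1,q2)90,(f1,f2)80);",
                 ann(queries=["q1", "q2"], fungi=["f1", "f2"], genome=["q1"]))
        decisions = classify_origins(t, CFG)
        assert decisions["q1"].label.value == "G"
        assert decisions["q2"].label.value == "G"  # rescued without own hit

    def test_non_prone_neighbor_kept_as_host_with_review(self):
        t = tree("((q1,m1)88,(f1,f2)80);",
                 ann(queries=["q1"], metazoa=["m1"], fungi=["f1", "f2"]))
        decisions = classify_origins(t, CFG)
        assert decisions["q1"].label.value == "E"
        assert decisions["q1"].label.review_flag
        # strict mode turns the same neighborhood into a contamination call
        strict = classify_origins(t, CFG, strict_mode=True)
        assert strict["q1"].label.value == "EC"

    def test_collapse_then_classify_on_weak_query_clade(self):
        t = tree("((q1,q2)40,(f1,f2)80);",
                 ann(queries=["q1", "q2"], fungi=["f1", "f2"]))
        decisions = classify_origins(collapse_low_support(t, 50), CFG)
        # after collapsing, each query hangs individually off the root whose
        # only reference superfamily is Fungi
        assert {d.label.value for d in decisions.values()} == {"EC"}


class TestClassifierContract:
    def test_tree_without_references_is_unclassifiable(self):
        t = tree("((q1,q2)90,q3);", ann(queries=["q1", "q2", "q3"]))
        with pytest.raises(ValueError, match="no references"):
            classify_origins(t, CFG)

    def test_every_query_leaf_classified_exactly_once(self):
        t = tree("(((q1,q2)90,(f1,f2)80)70,(q3,(p1,p2)85)60);",
                 ann(queries=["q1", "q2", "q3"], fungi=["f1", "f2"],
                     plants=["p1", "p2"]))
        decisions = classify_origins(t, CFG)
        assert sorted(decisions) == ["q1", "q2", "q3"]

    def test_clade_coherence(self):
        """Leaves sharing a maximal pure-query clade share a label."""
        from ghsieve.io_formats import LeafKind as LK

        rng = random.Random(5)
        for shape in rng.sample(colored_topologies(6), 40):
            colors = shape_colors(shape)
            if "Q" not in colors and "Qg" not in colors:
                continue
            if "F" not in colors and "M" not in colors:
                continue
            t = build_support_tree(shape, 90)
            decisions = classify_origins(t, CFG)

            def pure_query_clades(node):
                """Maximal subtrees whose leaves are all queries."""
                leaves = node.leaves()
                if all(t.leaf_annotation[l.name].kind is LK.QUERY
                       for l in leaves):
                    return [frozenset(l.name for l in leaves)]
                out = []
                for child in node.children:
                    out.extend(pure_query_clades(child))
                return out

            for clade in pure_query_clades(t.root):
                calls = {
                    (decisions[name].label.value,
                     decisions[name].label.review_flag)
                    for name in clade
                }
                assert len(calls) == 1, clade

    def test_rescue_dominance(self):
        """Adding a genome flag to any query leaf can move labels only
        toward G, never away from it."""
        rng = random.Random(7)
        samples = rng.sample(colored_topologies(5), 60)
        for shape in samples:
            colors = shape_colors(shape)
            if not any(c in ("Q", "Qg") for c in colors):
                continue
            if not any(c in ("F", "M") for c in colors):
                continue
            base_tree = build_support_tree(shape, 90)
            base = classify_origins(base_tree, CFG)
            query_leaves = list(base)
            flagged_leaf = rng.choice(query_leaves)
            upgraded = build_support_tree(shape, 90)
            table = dict(upgraded.leaf_annotation)
            table[flagged_leaf] = LeafAnnotation(
                LeafKind.QUERY, genome_verified=True)
            upgraded = type(upgraded)(upgraded.root, table)
            after = classify_origins(upgraded, CFG)
            for leaf in query_leaves:
                if after[leaf].label.value != base[leaf].label.value:
                    assert after[leaf].label.value == "G"

    def test_collapse_soundness_supports_above_threshold_interchangeable(self):
        """Classification of the collapsed tree does not depend on the exact
        values of supports at or above the threshold."""
        rng = random.Random(11)
        annotation = ann(queries=["q1", "q2", "q3"], fungi=["f1"],
                         metazoa=["m1"])
        newick_template = "(((q1,q2){a},f1){b},(q3,m1){c});"
        reference = None
        for _ in range(15):
            supports = {k: rng.randint(50, 100) for k in "abc"}
            t = tree(newick_template.format(**supports), annotation)
            decisions = classify_origins(collapse_low_support(t, 50), CFG)
            summary = {k: (d.label.value, d.label.review_flag)
                       for k, d in decisions.items()}
            if reference is None:
                reference = summary
            assert summary == reference


class TestOracleSpotCheck:
    """Random subsample of the exhaustive oracle comparison (the complete
    enumeration is exercised by the acceptance suite)."""

    def test_matches_brute_force_on_sampled_topologies(self):
        rng = random.Random(13)
        for n in (3, 4, 5):
            for shape in rng.sample(colored_topologies(n),
                                    min(80, len(colored_topologies(n)))):
                colors = shape_colors(shape)
                if not any(c in ("Q", "Qg") for c in colors):
                    continue
                if not any(c in ("F", "M") for c in colors):
                    continue
                for support in (90, None):
                    t = build_support_tree(shape, support)
                    got = {
                        k: (d.label.value, d.label.review_flag)
                        for k, d in classify_origins(t, CFG).items()
                    }
                    assert got == oracle_classify(t)
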
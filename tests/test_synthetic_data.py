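import numpy as np
import pytest

from ghsieve.gh_catalog import build_keyword_index, extract_gh_candidates, load_catalog
from ghsieve.io_formats import TrueOrigin
from ghsieve.origin_filters import ThresholdConfig, flag_prokaryotic
from ghsieve.phylo_classifier import classify_origins, collapse_low_support
from ghsieve.refdb_curation import build_verified_db
from ghsieve.synthetic_data import (
    SimulationConfig,
    mutate,
    percent_identity,
    simulate_families,
    simulate_study,
    simulate_transcriptome,
    simulate_tree,
    surrogate_evalue,
)


class TestPrimitives:
    def test_zero_divergence_is_identity(self):
        rng = np.random.default_rng(0)
        assert mutate("MKVLAW", 0.0, rng) == "MKVLAW"

    def test_full_divergence_changes_every_position(self):
        rng = np.random.default_rng(0)
        original = "MKVLAWMKVLAW"
        mutated = mutate(original, 1.0, rng)
        assert all(a != b for a, b in zip(original, mutated))

    def test_percent_identity_counts_matches(self):
        assert percent_identity("MKVL", "MKVA") == 75.0
        with pytest.raises(ValueError):
            percent_identity("MK", "MKV")

    @pytest.mark.parametrize("identity,expected", [
        (100.0, 1e-50), (10.0, 1e-5), (50.0, 1e-25),
    ])
    def test_surrogate_evalue_formula(self, identity, expected):
        assert surrogate_evalue(identity) == pytest.approx(expected, rel=1e-12)


class TestDeterminism:
    def test_same_seed_gives_identical_study(self):
        cfg = SimulationConfig(seed=5)
        a, b = simulate_study(cfg), simulate_study(cfg)
        assert [t.peptide for t in a.transcriptome.transcripts] == \
               [t.peptide for t in b.transcriptome.transcripts]
        assert a.transcriptome.annotations == b.transcriptome.annotations
        assert a.general_hits == b.general_hits
        assert {g: t.to_newick() for g, t in a.trees.items()} == \
               {g: t.to_newick() for g, t in b.trees.items()}
        assert a.expression == b.expression

    def test_different_seeds_differ(self):
        a = simulate_study(SimulationConfig(seed=5))
        b = simulate_study(SimulationConfig(seed=6))
        assert [t.peptide for t in a.transcriptome.transcripts] != \
               [t.peptide for t in b.transcriptome.transcripts]


class TestFamilies:
    def test_counts_and_curation_survival(self):
        cfg = SimulationConfig(seed=2)
        families = simulate_families(cfg)
        assert len(families.families) == cfg.n_families
        catalog = families.catalog()
        # per family: 4 retained eukaryotic references + 1 designated reject
        assert len(catalog) == cfg.n_families * 5
        db = build_verified_db(catalog)
        assert len(db.entries()) == cfg.n_families * 4
        assert len(families.verified_references()) == cfg.n_families * 4

    def test_reference_divergence_orders_similarity(self):
        cfg = SimulationConfig(seed=3)
        fam = simulate_families(cfg).families[0]
        euk = fam.euk_refs[0]
        bact = fam.bacterial_refs[0]
        assert percent_identity(fam.ancestor, euk.peptide) > \
               percent_identity(fam.ancestor, bact.peptide)


class TestTranscriptome:
    def test_planted_keyword_recall_is_total_and_decoys_silent(self):
        cfg = SimulationConfig(seed=4)
        tr = simulate_transcriptome(cfg, simulate_families(cfg))
        index = build_keyword_index(load_catalog())
        candidates = extract_gh_candidates(tr.annotations, index)
        extracted = candidates.all_transcripts()
        planted = set(tr.family_of)
        assert planted <= extracted                      # 100% recall
        decoys = set(tr.annotations) - planted
        assert extracted & decoys == set()               # no decoy fires

    def test_group_sizes_match_configuration(self):
        cfg = SimulationConfig(seed=4)
        tr = simulate_transcriptome(cfg, simulate_families(cfg))
        by_origin = {}
        for rec in tr.transcripts:
            by_origin[rec.true_origin] = by_origin.get(rec.true_origin, 0) + 1
        assert by_origin[TrueOrigin.HOST] == cfg.n_host_gh
        assert by_origin[TrueOrigin.PROKARYOTE] == cfg.n_prok
        assert by_origin[TrueOrigin.FUNGUS] == cfg.n_fungal
        assert by_origin[TrueOrigin.OTHER_EUKARYOTE] == cfg.n_other_euk
        assert by_origin[None] == cfg.n_decoy

    def test_isoforms_share_gene_and_differ_in_sequence(self):
        cfg = SimulationConfig(seed=4)
        tr = simulate_transcriptome(cfg, simulate_families(cfg))
        by_gene = {}
        for rec in tr.transcripts:
            by_gene.setdefault(rec.gene_id, []).append(rec)
        multi = [v for v in by_gene.values() if len(v) > 1]
        assert multi  # isoform duplicates were inserted
        for group in multi:
            peptides = {r.peptide for r in group}
            assert len(peptides) == len(group)
            assert len({r.true_origin for r in group}) == 1


class TestHitTables:
    def test_prokaryotic_filter_recovers_planted_contaminants(self):
        study = simulate_study(SimulationConfig(seed=6))
        planted = {
            t.transcript_id for t in study.transcriptome.transcripts
            if t.true_origin is TrueOrigin.PROKARYOTE
        }
        candidates = study.transcriptome.candidates()
        flagged, _ = flag_prokaryotic(candidates, study.general_hits)
        recall = len(flagged & planted) / len(planted)
        precision = len(flagged & planted) / len(flagged)
        assert recall >= 0.95 and precision >= 0.95

    def test_genome_hits_cover_only_designated_hosts(self):
        study = simulate_study(SimulationConfig(seed=6))
        queried = {h.query_id for h in study.genome_hits}
        assert queried == study.transcriptome.genome_hit_ids
        hosts = {
            t.transcript_id for t in study.transcriptome.transcripts
            if t.true_origin is TrueOrigin.HOST
        }
        assert queried <= hosts


class TestTrees:
    def test_distractor_edges_collapse_at_default_threshold(self):
        cfg = SimulationConfig(seed=8)
        study = simulate_study(cfg)
        distractor_fams = [f for f in study.families.families if f.has_distractor]
        assert distractor_fams
        for fam in distractor_fams:
            tree = study.trees[fam.ghf]
            supports = {
                n.support
                for n in _iter_nodes(tree.root)
                if n.support is not None
            }
            assert cfg.support_low in supports
            collapsed = collapse_low_support(tree, 50)
            remaining = {
                n.support
                for n in _iter_nodes(collapsed.root)
                if n.support is not None
            }
            assert cfg.support_low not in remaining

    def test_planted_fungal_contaminant_classified_as_contamination(self):
        cfg = SimulationConfig(seed=8)
        study = simulate_study(cfg)
        fungal = {
            t.transcript_id for t in study.transcriptome.transcripts
            if t.true_origin is TrueOrigin.FUNGUS
        }
        tcfg = ThresholdConfig()
        for ghf, tree in study.trees.items():
            decisions = classify_origins(
                collapse_low_support(tree, 50), tcfg,
                prone_taxa=cfg.contaminant_superfamilies,
            )
            for tid in fungal & set(decisions):
                assert decisions[tid].label.value == "EC"

    def test_distance_mode_recovers_generating_split_on_four_leaves(self):
        """Neighbor joining on additive distances must recover the planted
        split; the oracle scores all three 4-leaf topologies by
        least-squares against the distance matrix."""
        cfg = SimulationConfig(seed=9, n_host_gh=2, n_prok=0, n_fungal=0,
                               n_other_euk=0, n_families=1,
                               refs_per_superfamily=1)
        study = simulate_study(cfg, tree_mode="distance")
        (tree,) = study.trees.values()
        leaves = sorted(tree.leaf_names())
        peptides = {}
        for rec in study.transcriptome.transcripts:
            if rec.transcript_id in leaves:
                peptides[rec.transcript_id] = rec.peptide
        for ref in study.families.families[0].euk_refs:
            peptides[ref.accession] = ref.peptide
        assert len(peptides) == 4

        def dist(a, b):
            return 1.0 - percent_identity(peptides[a], peptides[b]) / 100.0

        # oracle: evaluate the three unrooted quartet splits by how well a
        # star-plus-internal-edge least-squares fit explains the distances
        best_split, best_score = None, None
        for split in [((leaves[0], leaves[1]), (leaves[2], leaves[3])),
                      ((leaves[0], leaves[2]), (leaves[1], leaves[3])),
                      ((leaves[0], leaves[3]), (leaves[1], leaves[2]))]:
            (a, b), (c, d) = split
            # four-point condition residual for this pairing
            s1 = dist(a, b) + dist(c, d)
            s2 = min(dist(a, c) + dist(b, d), dist(a, d) + dist(b, c))
            score = s1 - s2
            if best_score is None or score < best_score:
                best_split, best_score = split, score

        def split_of_tree():
            for node in _iter_nodes(tree.root):
                if not node.is_leaf and node is not tree.root:
                    inside = frozenset(l.name for l in node.leaves())
                    if len(inside) == 2:
                        return inside
            return None

        got = split_of_tree()
        assert got in (frozenset(best_split[0]), frozenset(best_split[1]))

    def test_distance_mode_needs_four_leaves(self):
        cfg = SimulationConfig(seed=9, n_host_gh=1, n_prok=0, n_fungal=0,
                               n_other_euk=0, n_families=1,
                               refs_per_superfamily=1)
        families = simulate_families(cfg)
        tr = simulate_transcriptome(cfg, families)
        with pytest.raises(ValueError, match="at least 4"):
            # 1 host + 2 references = 3 leaves
            simulate_tree(cfg, families.families[0], tr, mode="distance")


class TestExpression:
    def test_zero_slope_gives_negligible_correlation(self):
        cfg = SimulationConfig(seed=10, n_host_gh=2000, n_prok=0, n_fungal=0,
                               n_other_euk=0, n_decoy=0, beta1=0.0,
                               beta1_by_type={}, tpm_zero_fraction=0.0,
                               isoform_interval=0)
        study = simulate_study(cfg)
        x = np.array([np.log2(r.tpm) for r in study.expression])
        y = np.array([float(r.signal_peptide) for r in study.expression])
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.1

    def test_positive_slope_detected_by_association_report(self):
        from ghsieve.expression_models import association_report

        cfg = SimulationConfig(seed=11, n_host_gh=500, n_prok=0, n_fungal=0,
                               n_other_euk=0, n_decoy=0, n_families=1,
                               beta1_by_type={"CELLULASE": 1.2},
                               tpm_zero_fraction=0.0, isoform_interval=0)
        study = simulate_study(cfg)
        report = association_report(study.expression)
        row = report[report.enzyme_type == "CELLULASE"].iloc[0]
        assert row["status"] == "ok"
        assert row["beta1"] > 0 and row["wald_p"] < 0.05


def _iter_nodes(root):
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(node.children)
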
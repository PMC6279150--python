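"""Monophyly tests, scenario classification, pattern counting, consensus networks."""

import numpy as np
import pytest

from coralphy import coalsim, concordance, treeio
from coralphy.concordance import GroupMap, Scenario
from coralphy.treeio import Split

G = GroupMap(
    {
        "O1": "OUTGROUP",
        "O2": "OUTGROUP",
        "S": "SPORO",
        "R1": "RHODO",
        "R2": "RHODO",
        "H1": "HAPA",
        "H2": "HAPA",
        "C1": "CORA",
        "C2": "CORA",
    }
)

SPORO_FIRST_NWK = (
    "((O1,O2),(S,((R1,R2)100,((H1,H2)100,(C1,C2)100)100)100)100);"
)
SPORO_RHODO_FIRST_NWK = (
    "((O1,O2),((S,(R1,R2)100)100,((H1,H2)100,(C1,C2)100)100)100);"
)


class TestIsMonophyletic:
    def test_singleton_always_monophyletic(self):
        t = treeio.parse_newick("(((R1,R2)99,S)80,(O1,O2));")
        assert concordance.is_monophyletic(t, {"S"}, 50)

    def test_supported_clade(self):
        t = treeio.parse_newick("(((R1,R2)99,S)80,(O1,O2));")
        assert concordance.is_monophyletic(t, {"R1", "R2"}, 50)
        assert not concordance.is_monophyletic(t, {"S", "R1"}, 50)

    def test_threshold_excludes_weak_clade(self):
        t = treeio.parse_newick("(((R1,R2)40,S)80,(O1,O2));")
        assert not concordance.is_monophyletic(t, {"R1", "R2"}, 50)
        assert concordance.is_monophyletic(t, {"R1", "R2"}, 40)

    def test_missing_taxon_identified(self):
        t = treeio.parse_newick("(((R1,R2)99,S)80,(O1,O2));")
        with pytest.raises(concordance.MissingTaxonError, match="ZZ"):
            concordance.is_monophyletic(t, {"R1", "ZZ"}, 50)

    def test_deep_divergence_pattern(self):
        """A gene tree placing one order sister to all other ingroup taxa with
        high support marks the six-taxon remainder clade as monophyletic —
        the nad5-style pattern of a Sporolithales-first gene."""
        t = treeio.parse_newick(
            "((O1,O2),(S,((R1,R2)90,((H1,H2)95,(C1,C2)97)92)99)85);"
        )
        rooted = treeio.root_with_outgroup(t, {"O1", "O2"})
        six = {"R1", "R2", "H1", "H2", "C1", "C2"}
        assert concordance.is_monophyletic(rooted, six, 50)


class TestClassifyEarlyDivergence:
    def test_sporo_first(self):
        t = treeio.parse_newick(SPORO_FIRST_NWK)
        assert concordance.classify_early_divergence(t, G) is Scenario.SPORO_FIRST

    def test_sporo_rhodo_first(self):
        t = treeio.parse_newick(SPORO_RHODO_FIRST_NWK)
        assert (
            concordance.classify_early_divergence(t, G)
            is Scenario.SPORO_RHODO_FIRST
        )

    def test_low_first_branch_support_unresolved(self):
        t = treeio.parse_newick(
            "((O1,O2),(S,((R1,R2)100,((H1,H2)100,(C1,C2)100)100)40)100);"
        )
        assert concordance.classify_early_divergence(t, G) is Scenario.UNRESOLVED

    def test_rhodo_first(self):
        t = treeio.parse_newick(
            "((O1,O2),((R1,R2)100,(S,((H1,H2)100,(C1,C2)100)100)90)100);"
        )
        assert concordance.classify_early_divergence(t, G) is Scenario.RHODO_FIRST

    def test_deeper_relationships_ignored(self):
        # H/C intermingled deeper in the tree must not affect the early rule
        t = treeio.parse_newick(
            "((O1,O2),(S,((R1,R2)100,((H1,C1)100,(H2,C2)100)100)90)100);"
        )
        assert concordance.classify_early_divergence(t, G) is Scenario.SPORO_FIRST


class TestClassifyFullTopology:
    def test_fully_supported_sporo_first(self):
        t = treeio.parse_newick(SPORO_FIRST_NWK)
        assert concordance.classify_full_topology(t, G) is Scenario.SPORO_FIRST

    def test_one_weak_branch_unresolved(self):
        t = treeio.parse_newick(
            "((O1,O2),(S,((R1,R2)49,((H1,H2)100,(C1,C2)100)100)100)100);"
        )
        assert concordance.classify_full_topology(t, G) is Scenario.UNRESOLVED

    def test_intermingled_groups_unresolved(self):
        t = treeio.parse_newick(
            "((O1,O2),(S,((R1,R2)100,((H1,C1)100,(H2,C2)100)100)100)100);"
        )
        assert concordance.classify_full_topology(t, G) is Scenario.UNRESOLVED

    def test_reduced_taxon_set_still_classifies(self):
        # one Hapalidiales taxon missing; all four groups still represented
        t = treeio.parse_newick(
            "((O1,O2),(S,((R1,R2)100,(H1,(C1,C2)100)100)100)100);"
        )
        assert concordance.classify_full_topology(t, G) is Scenario.SPORO_FIRST

    @pytest.mark.parametrize("seed", range(30))
    def test_full_rule_implies_early_rule(self, seed, coralline9_model):
        """Whenever the strict rule resolves, the early rule agrees."""
        rng = np.random.default_rng(seed)
        gt = coalsim.simulate_gene_tree(coralline9_model, rng)
        for nd in gt.preorder_internal_node_iter():
            treeio.set_support(nd, int(rng.integers(0, 101)))
        full = concordance.classify_full_topology(gt, coralline9_model.groups)
        if full is not Scenario.UNRESOLVED:
            early = concordance.classify_early_divergence(
                gt, coralline9_model.groups
            )
            assert early is full


class TestCountNodeSupport:
    def make_trees(self):
        return [
            treeio.parse_newick("(((R1,R2)80,S)70,(O1,O2));"),
            treeio.parse_newick("(((R1,R2)55,S)70,(O1,O2));"),
            treeio.parse_newick("(((R1,S)90,R2)70,(O1,O2));"),
        ]

    def test_counts(self):
        (res,) = concordance.count_node_support(
            self.make_trees(), [{"R1", "R2"}], G, 50
        )
        assert (res.n_supporting, res.n_total) == (2, 3)
        assert sorted(res.supports) == [55, 80]

    def test_missing_taxon_reduces_total(self):
        trees = self.make_trees() + [
            treeio.parse_newick("((R1,S)70,(O1,O2));")  # R2 absent
        ]
        (res,) = concordance.count_node_support(trees, [{"R1", "R2"}], G, 50)
        assert res.n_total == 3

    def test_threshold_monotonicity(self):
        trees = self.make_trees()
        counts = [
            concordance.count_node_support(trees, [{"R1", "R2"}], G, ms)[0]
            .n_supporting
            for ms in (0, 50, 60, 90)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_true_clade_dominates_under_long_stem(self):
        """With a long stem, the species-tree clade out-supports any
        conflicting same-size clade across simulated gene trees."""
        model = coalsim.coralline9(stem=2.0)
        trees = []
        for i in range(200):
            gt = coalsim.simulate_gene_tree(model, np.random.default_rng(i))
            for nd in gt.preorder_internal_node_iter():
                treeio.set_support(nd, 100)
            trees.append(gt)
        true_clade = {"R1", "R2", "H1", "H2", "C1", "C2"}
        rivals = [
            {"S1", "R1", "R2", "H1", "H2", "C1"},
            {"S1", "R2", "H1", "H2", "C1", "C2"},
        ]
        res = concordance.count_node_support(
            trees, [true_clade] + rivals, model.groups, 50
        )
        assert all(res[0].n_supporting >= r.n_supporting for r in res[1:])


class TestConflictProportion:
    @pytest.mark.parametrize(
        "args,expected",
        [((1, 22, 18, 195), 8.7), ((0, 22, 0, 195), 0.0), ((22, 22, 195, 195), 100.0)],
    )
    def test_values(self, args, expected):
        assert concordance.conflict_proportion(*args) == expected

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            concordance.conflict_proportion(0, 0, 0, 0)


class TestConsensusNetwork:
    X = "((A,B),(C,D),E);"
    Y = "((A,C),(B,D),E);"

    def test_identical_trees(self):
        trees = [treeio.parse_newick(self.X) for _ in range(5)]
        system = concordance.consensus_network(trees, cutoff=0.2)
        assert {s.frequency for s in system.splits} == {1.0}
        assert len(system.splits) == 2

    def test_conflicting_splits_below_and_above_majority(self):
        trees = [treeio.parse_newick(self.X)] * 3 + [
            treeio.parse_newick(self.Y)
        ] * 2
        low = concordance.consensus_network(trees, cutoff=0.2)
        freqs = {
            (tuple(sorted(s.side_a)), round(s.frequency, 2)) for s in low.splits
        }
        assert (("A", "B"), 0.6) in freqs
        assert (("A", "C"), 0.4) in freqs
        high = concordance.consensus_network(trees, cutoff=0.5)
        sides = {tuple(sorted(s.side_a)) for s in high.splits}
        assert ("A", "B") in sides and ("A", "C") not in sides

    def test_cutoff_one_is_strict_consensus(self):
        # X and Y share no nontrivial split, so the strict consensus is empty
        trees = [treeio.parse_newick(self.X)] * 3 + [
            treeio.parse_newick(self.Y)
        ] * 2
        assert concordance.consensus_network(trees, cutoff=1.0).splits == []
        # while five identical trees keep every split at frequency 1
        same = [treeio.parse_newick(self.X)] * 5
        strict = concordance.consensus_network(same, cutoff=1.0)
        assert len(strict.splits) == 2
        assert all(s.frequency == 1.0 for s in strict.splits)

    def test_order_invariance(self, rng):
        trees = [treeio.parse_newick(self.X)] * 3 + [
            treeio.parse_newick(self.Y)
        ] * 2
        a = concordance.consensus_network(trees, 0.2)
        perm = list(rng.permutation(len(trees)))
        b = concordance.consensus_network([trees[i] for i in perm], 0.2)
        assert {(s, s.frequency) for s in a.splits} == {
            (s, s.frequency) for s in b.splits
        }

    def test_taxon_mismatch_lists_difference(self):
        trees = [
            treeio.parse_newick("((A,B),(C,D));"),
            treeio.parse_newick("((A,B),(C,E));"),
        ]
        with pytest.raises(ValueError, match="D.*E|E.*D"):
            concordance.consensus_network(trees, 0.2)

    def test_nexus_serialization(self, tmp_path):
        trees = [treeio.parse_newick(self.X)] * 3 + [
            treeio.parse_newick(self.Y)
        ] * 2
        system = concordance.consensus_network(trees, 0.2)
        out = tmp_path / "splits.nex"
        concordance.write_splits_nexus(system, out)
        text = out.read_text()
        assert text.startswith("#NEXUS")
        assert "BEGIN SPLITS;" in text and "NSPLITS=" in text
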
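"""Distances, NJ, pruning likelihood, bootstrap, RELL tests, TIGER rates."""

import math

import numpy as np
import pytest

from coralphy import coalsim, mlcore, treeio
from coralphy.mlcore import Alignment, SiteLikelihoodMatrix

from conftest import random_binary_tree


class TestDistances:
    def test_identical_sequences_zero(self):
        assert mlcore.jc_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_jc_closed_form(self):
        # p = 0.05 over 100 sites
        a = "A" * 100
        b = "C" * 5 + "A" * 95
        d = mlcore.jc_distance(a, b)
        assert d == pytest.approx(-(3 / 4) * math.log(1 - (4 / 3) * 0.05))
        assert d == pytest.approx(0.05174, abs=1e-5)

    def test_saturation_error(self):
        a = "A" * 4
        b = "CCCA"
        with pytest.raises(mlcore.SaturationError):
            mlcore.jc_distance(a, b)  # p = 0.75

    def test_gaps_excluded_from_comparison(self):
        assert mlcore.jc_distance("AC-T", "ACG-") == 0.0
        with pytest.raises(ValueError):
            mlcore.p_distance("--", "AA")

    def test_poisson_distance(self):
        a = "A" * 100
        b = "C" * 10 + "A" * 90
        assert mlcore.poisson_distance(a, b) == pytest.approx(
            -(19 / 20) * math.log(1 - (20 / 19) * 0.1)
        )


class TestNeighborJoining:
    ADDITIVE = np.array(
        [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float
    )

    def test_additive_recovery_topology_and_lengths(self):
        # generating tree ((A:1,B:2):1,(C:3,D:1))
        t = mlcore.neighbor_joining(self.ADDITIVE, list("ABCD"))
        assert treeio.splits(t, 0) == {
            treeio.Split(frozenset("AB"), frozenset("CD"))
        }
        # path lengths reproduce the input distances exactly
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        labels = list("ABCD")
        for i in range(4):
            for j in range(i + 1, 4):
                assert pdm.patristic_distance(
                    taxa[labels[i]], taxa[labels[j]]
                ) == pytest.approx(self.ADDITIVE[i, j])

    def test_three_taxa_exact(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        t = mlcore.neighbor_joining(d, list("ABC"))
        lengths = {
            lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 0.0, "B": 2.0, "C": 3.0})

    def test_asymmetric_matrix_rejected(self):
        bad = self.ADDITIVE.copy()
        bad[0, 1] = 99
        with pytest.raises(ValueError):
            mlcore.neighbor_joining(bad, list("ABCD"))

    @pytest.mark.parametrize("seed", range(5))
    def test_taxon_permutation_invariance(self, seed):
        rng = np.random.default_rng(300 + seed)
        n = 7
        base = rng.uniform(0.1, 1.0, size=(n, n))
        d = base + base.T
        np.fill_diagonal(d, 0.0)
        labels = [f"T{i}" for i in range(n)]
        ref = treeio.splits(mlcore.neighbor_joining(d, labels), 0)
        perm = rng.permutation(n)
        got = treeio.splits(
            mlcore.neighbor_joining(
                d[np.ix_(perm, perm)], [labels[i] for i in perm]
            ),
            0,
        )
        assert got == ref

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_scikit_bio(self, seed):
        """Independent oracle: scikit-bio's NJ yields the same unrooted topology."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(400 + seed)
        t = random_binary_tree(rng, n_taxa=8, with_supports=False)
        pdm = t.phylogenetic_distance_matrix()
        labels = sorted(x.label for x in t.taxon_namespace)
        taxa = {x.label: x for x in t.taxon_namespace}
        d = np.array(
            [
                [
                    0.0
                    if a == b
                    else pdm.patristic_distance(taxa[a], taxa[b])
                    for b in labels
                ]
                for a in labels
            ]
        )
        ours = treeio.splits(mlcore.neighbor_joining(d, labels), 0)
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        theirs = treeio.splits(treeio.parse_newick(str(sk_tree)), 0)
        assert ours == theirs


class TestFelsensteinLikelihood:
    def test_zero_length_identical_site(self):
        t = treeio.parse_newick("(A:0.0,B:0.0);")
        aln = Alignment(["A", "B"], ["A", "A"])
        assert mlcore.felsenstein_loglik(t, aln)[0] == pytest.approx(
            math.log(0.25)
        )

    def test_pairwise_closed_form(self):
        d = 0.37
        t = treeio.parse_newick(f"(A:{d / 2},B:{d / 2});")
        aln = Alignment(["A", "B"], ["AC", "AG"])
        ll = mlcore.felsenstein_loglik(t, aln)
        same = 0.25 * (0.25 + 0.75 * math.exp(-4 * d / 3))
        diff = 0.25 * (0.25 - 0.25 * math.exp(-4 * d / 3))
        assert ll[0] == pytest.approx(math.log(same))
        assert ll[1] == pytest.approx(math.log(diff))

    def test_rerooting_invariance(self, coralline9_model, rng):
        gt = coalsim.simulate_gene_tree(coralline9_model, rng)
        for nd in gt.preorder_node_iter():
            if nd.edge.length:
                nd.edge.length *= 0.05
        aln = coalsim.simulate_alignment(gt, 300, 1.0, rng)
        ll1 = mlcore.felsenstein_loglik(gt, aln).sum()
        rerooted = treeio.root_with_outgroup(gt, {"O1", "O2"})
        ll2 = mlcore.felsenstein_loglik(rerooted, aln).sum()
        assert abs(ll1 - ll2) / abs(ll1) < 1e-8

    def test_negative_length_errors(self):
        t = treeio.parse_newick("(A:0.1,B:0.1);")
        next(t.leaf_node_iter()).edge.length = -0.5
        with pytest.raises(ValueError):
            mlcore.felsenstein_loglik(t, Alignment(["A", "B"], ["A", "A"]))

    def test_poisson_amino_acid_model(self):
        t = treeio.parse_newick("(A:0.0,B:0.0);")
        aln = Alignment(["A", "B"], ["W", "W"], mlcore.AA_ALPHABET)
        assert mlcore.felsenstein_loglik(t, aln, "poisson")[0] == pytest.approx(
            math.log(1 / 20)
        )


class TestOptimizeBranchLengths:
    def test_pairwise_mle_matches_jc_distance(self):
        seq_a = ("ACGT" * 50)[:200]
        seq_b = seq_a[:180] + "TGCA" * 5
        aln = Alignment(["A", "B"], [seq_a, seq_b])
        start = treeio.parse_newick("(A:0.05,B:0.05);")
        opt = mlcore.optimize_branch_lengths(start, aln, tolerance=1e-9)
        total = sum(
            nd.edge.length
            for nd in opt.preorder_node_iter()
            if nd.edge.length
        )
        assert total == pytest.approx(
            mlcore.jc_distance(seq_a, seq_b), abs=1e-4
        )

    def test_identical_sequences_collapse_lengths(self):
        aln = Alignment(["A", "B", "C"], ["ACGT", "ACGT", "ACGT"])
        start = treeio.parse_newick("(A:0.2,B:0.3,C:0.1);")
        opt = mlcore.optimize_branch_lengths(start, aln)
        for nd in opt.preorder_node_iter():
            if nd.edge.length is not None:
                assert nd.edge.length < 1e-4

    def test_likelihood_non_decreasing(self, coralline9_model, rng):
        gt = coalsim.simulate_gene_tree(coralline9_model, rng)
        for nd in gt.preorder_node_iter():
            if nd.edge.length:
                nd.edge.length *= 0.05
        aln = coalsim.simulate_alignment(gt, 200, 1.0, rng)
        before = mlcore.felsenstein_loglik(gt, aln).sum()
        opt = mlcore.optimize_branch_lengths(gt, aln, tolerance=1e-6)
        after = mlcore.felsenstein_loglik(opt, aln).sum()
        assert after >= before - 1e-9


class TestBootstrapSupports:
    def test_seed_determinism(self, coralline9_model):
        g = coalsim.simulate_gene_set(coralline9_model, 1, seed=5).genes[0]
        t1 = mlcore.bootstrap_supports(g.alignment, 50, seed=7)
        t2 = mlcore.bootstrap_supports(g.alignment, 50, seed=7)
        assert treeio.write_newick(t1) == treeio.write_newick(t2)

    def test_single_replicate_supports_binary(self, coralline9_model):
        g = coalsim.simulate_gene_set(coralline9_model, 1, seed=6).genes[0]
        t = mlcore.bootstrap_supports(g.alignment, 1, seed=3)
        sups = {
            treeio.get_support(nd)
            for nd in t.preorder_internal_node_iter()
            if treeio.get_support(nd) is not None
        }
        assert sups <= {0, 100}

    def test_clean_long_alignment_high_support(self):
        model = coalsim.coralline9(stem=3.0)
        rng = np.random.default_rng(8)
        aln = coalsim.simulate_alignment(model.tree, 10000, 0.02, rng)
        t = mlcore.bootstrap_supports(aln, 100, seed=1)
        sups = [
            treeio.get_support(nd)
            for nd in t.preorder_internal_node_iter()
            if treeio.get_support(nd) is not None
        ]
        assert sups and min(sups) >= 95

    def test_two_seeds_agree_on_clean_data(self):
        model = coalsim.coralline9(stem=3.0)
        rng = np.random.default_rng(9)
        aln = coalsim.simulate_alignment(model.tree, 10000, 0.02, rng)
        s1 = treeio.split_support_map(mlcore.bootstrap_supports(aln, 200, seed=1))
        s2 = treeio.split_support_map(mlcore.bootstrap_supports(aln, 200, seed=2))
        assert s1.keys() == s2.keys()
        for k in s1:
            assert abs(s1[k] - s2[k]) <= 3


class TestRellTopologyTests:
    def test_identical_rows_no_signal(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=200)
        M = SiteLikelihoodMatrix(["a", "b"], np.vstack([row, row]))
        res = mlcore.rell_topology_test(M, 500, seed=1)
        assert res.delta == pytest.approx([0.0, 0.0])
        assert np.all(res.p_kh == 1.0) and np.all(res.p_sh == 1.0)
        # AU cannot favor either of two indistinguishable topologies
        assert np.all(res.p_au >= 0.3)

    def test_dominant_topology(self):
        S = 100
        M = SiteLikelihoodMatrix(
            ["good", "bad"], np.vstack([np.zeros(S), np.full(S, -10.0)])
        )
        res = mlcore.rell_topology_test(M, 1000, seed=2)
        assert res.p_kh[0] == pytest.approx(1.0)
        assert res.p_au[0] == pytest.approx(1.0)
        assert res.p_kh[1] < 0.01
        assert res.p_au[1] < 0.01

    def test_p_values_in_unit_interval_and_sh_conservative(self):
        rng = np.random.default_rng(3)
        M = SiteLikelihoodMatrix(
            [f"t{i}" for i in range(4)], rng.normal(size=(4, 300))
        )
        res = mlcore.rell_topology_test(M, 500, seed=4)
        for arr in (res.p_kh, res.p_sh, res.p_au):
            assert np.all((arr >= 0) & (arr <= 1))
        assert np.all(res.p_sh >= res.p_kh)
        assert res.delta[int(np.argmax(res.loglik))] == 0.0

    def test_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        M = SiteLikelihoodMatrix(["x", "y"], rng.normal(size=(2, 40)))
        p = tmp_path / "sitelk.tsv"
        M.to_tsv(p)
        back = SiteLikelihoodMatrix.from_tsv(p)
        assert back.names == ["x", "y"]
        np.testing.assert_allclose(back.loglik, M.loglik)


def brute_force_tiger(aln: Alignment, gaps="exclude"):
    """Direct transcription of the site-agreement definition, per site pair."""
    s = aln.state_matrix()

    def partition(j):
        groups = {}
        for taxon in range(aln.n_taxa):
            st = s[taxon, j]
            if st < 0 and gaps == "exclude":
                continue
            groups.setdefault(int(st), set()).add(taxon)
        return list(groups.values())

    parts = [partition(j) for j in range(aln.n_sites)]
    rates = []
    for i in range(aln.n_sites):
        vals = []
        for j in range(aln.n_sites):
            if j == i:
                continue
            if not parts[j]:
                vals.append(1.0)
                continue
            hits = sum(
                1
                for b in parts[j]
                if any(b <= a for a in parts[i])
            )
            vals.append(hits / len(parts[j]))
        rates.append(sum(vals) / len(vals))
    return np.array(rates)


class TestTigerRates:
    def test_constant_site_scores_one(self):
        aln = Alignment(["w", "x", "y"], ["AAC", "AGC", "ATA"])
        prof = mlcore.tiger_site_rates(aln)
        assert prof.rates[0] == pytest.approx(1.0)

    def test_identical_pattern_pair_scores_one(self):
        aln = Alignment(["w", "x", "y", "z"], ["AA", "AA", "CC", "CC"])
        np.testing.assert_allclose(mlcore.tiger_site_rates(aln).rates, 1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(600 + seed)
        chars = "ACGT-"
        aln = Alignment(
            [f"t{i}" for i in range(5)],
            [
                "".join(rng.choice(list(chars), size=7))
                for _ in range(5)
            ],
        )
        np.testing.assert_allclose(
            mlcore.tiger_site_rates(aln).rates, brute_force_tiger(aln)
        )

    def test_site_permutation_equivariance(self, rng):
        aln = Alignment(
            [f"t{i}" for i in range(4)],
            ["ACGTAC", "AGGTAC", "ACCTGC", "ACGAGT"],
        )
        base = mlcore.tiger_site_rates(aln).rates
        perm = rng.permutation(aln.n_sites)
        permuted = aln.take_sites(perm.tolist())
        np.testing.assert_allclose(
            mlcore.tiger_site_rates(permuted).rates, base[perm]
        )

    def test_taxon_order_invariance(self):
        aln = Alignment(
            ["a", "b", "c", "d"], ["ACGTAC", "AGGTAC", "ACCTGC", "ACGAGT"]
        )
        flipped = Alignment(
            ["d", "c", "b", "a"],
            list(reversed(aln.sequences)),
        )
        np.testing.assert_allclose(
            mlcore.tiger_site_rates(flipped).rates,
            mlcore.tiger_site_rates(aln).rates,
        )

    def test_single_site_rejected(self):
        with pytest.raises(ValueError):
            mlcore.tiger_site_rates(Alignment(["a", "b", "c"], ["A", "C", "G"]))


class TestSubsampleByRate:
    def test_full_keep_is_identity(self):
        aln = Alignment(["a", "b", "c"], ["ACGTA", "ACGTC", "AGGTA"])
        prof = mlcore.tiger_site_rates(aln)
        sub = mlcore.subsample_by_rate(aln, prof, 1.0)
        assert sub.sequences == aln.sequences

    def test_kept_rates_dominate_removed(self, rng):
        aln = Alignment(
            [f"t{i}" for i in range(4)],
            ["".join(rng.choice(list("ACGT"), size=10)) for _ in range(4)],
        )
        prof = mlcore.tiger_site_rates(aln)
        sub = mlcore.subsample_by_rate(aln, prof, 0.5)
        assert sub.n_sites == 5
        kept = sorted(prof.ranking[:5].tolist())
        assert min(prof.rates[kept]) >= max(
            prof.rates[[i for i in range(10) if i not in kept]]
        )

    def test_order_preserved(self):
        aln = Alignment(["a", "b", "c"], ["AACGT", "ACCGT", "AACTT"])
        prof = mlcore.tiger_site_rates(aln)
        sub = mlcore.subsample_by_rate(aln, prof, 0.6)
        # kept columns appear in original order: check they are a subsequence
        for row_full, row_sub in zip(aln.sequences, sub.sequences):
            it = iter(row_full)
            assert all(ch in it for ch in row_sub)
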
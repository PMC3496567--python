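"""MLST: codon masking, Nei-Gojobori synonymous distances (hand-computed
oracle), minimum-evolution trees on additive matrices, clock linearization
and divergence dating."""

import dendropy
import numpy as np
import pytest

from supragenome import mlst, simulate
from supragenome.genecontent import DistanceMatrix
from supragenome.mlst import MLST_LOCI


def _loci(per_locus):
    """Build a loci mapping with the same strain set for all 6 loci."""
    return {name: dict(per_locus) for name in MLST_LOCI}


class TestConcatAndMask:
    def test_gap_free_concatenation_length(self):
        loci = _loci({"s1": "ATGAAA", "s2": "ATGAAG"})
        prof = mlst.concat_and_mask(loci)
        assert prof.length == 6 * len(MLST_LOCI)
        assert prof.n_codons_removed == 0

    def test_gapped_codon_removed_for_all_strains(self):
        loci = _loci({"s1": "ATGAAA", "s2": "ATGAAG"})
        loci["pgm"] = {"s1": "AT-AAA", "s2": "ATGAAG"}
        prof = mlst.concat_and_mask(loci)
        assert prof.n_codons_removed == 1
        assert prof.length == 6 * len(MLST_LOCI) - 3

    def test_matches_column_scan_oracle(self):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT-N"))
        strains = ["a", "b", "c"]
        n_cod = 30
        seqs = {
            s: "".join(bases[rng.choice(6, p=[0.23, 0.23, 0.23, 0.23, 0.04, 0.04],
                                        size=3 * n_cod)])
            for s in strains
        }
        loci = {name: ({s: seqs[s] for s in strains} if name == MLST_LOCI[0]
                       else {s: "ATG" for s in strains})
                for name in MLST_LOCI}
        prof = mlst.concat_and_mask(loci)
        # oracle: direct scan of codon columns in the first locus
        keep = [c for c in range(n_cod)
                if all(set(seqs[s][3 * c : 3 * c + 3]) <= set("ACGT")
                       for s in strains)]
        expected = {s: "".join(seqs[s][3 * c : 3 * c + 3] for c in keep) + "ATG" * 5
                    for s in strains}
        assert prof.sequences == expected

    def test_length_not_multiple_of_three_rejected(self):
        loci = _loci({"s1": "ATGA", "s2": "ATGA"})
        with pytest.raises(ValueError, match="divisible by 3"):
            mlst.concat_and_mask(loci)

    def test_missing_strain_rejected(self):
        loci = _loci({"s1": "ATGAAA", "s2": "ATGAAA"})
        del loci["polA"]["s2"]
        with pytest.raises(ValueError, match="strain set"):
            mlst.concat_and_mask(loci)


class TestNgSynDistance:
    def test_identical_sequences_zero(self):
        assert mlst.ng_syn_distance("ATGAAATTT", "ATGAAATTT") == 0.0

    def test_hand_computed_phenylalanine_example(self):
        """Six TTT codons vs one TTC + five TTT: each TTT carries 1/3 of a
        synonymous site (third position), so S = 2, one synonymous
        difference, p_S = 1/2, dS = -0.75 ln(1/3) = 0.8239."""
        a = "TTT" * 6
        b = "TTC" + "TTT" * 5
        assert mlst.ng_syn_distance(a, b) == pytest.approx(0.8239, abs=1e-4)

    def test_symmetry_on_random_codon_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = simulate._random_coding_seq(40, rng)
            b = simulate._evolve(a, 0.05, rng)
            assert mlst.ng_syn_distance(a, b) == pytest.approx(
                mlst.ng_syn_distance(b, a), abs=1e-12)

    def test_invariant_under_codon_permutation(self):
        rng = np.random.default_rng(7)
        a = simulate._random_coding_seq(30, rng)
        b = simulate._evolve(a, 0.05, rng)
        perm = rng.permutation(30)
        ap = "".join(a[3 * i : 3 * i + 3] for i in perm)
        bp = "".join(b[3 * i : 3 * i + 3] for i in perm)
        assert mlst.ng_syn_distance(a, b) == pytest.approx(
            mlst.ng_syn_distance(ap, bp), abs=1e-12)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            mlst.ng_syn_distance("ATGTAAAAA", "ATGTACAAA")

    def test_saturation_rejected(self):
        # all third positions differ synonymously: p_S = 1 >= 3/4
        with pytest.raises(ValueError, match="saturation"):
            mlst.ng_syn_distance("TTT" * 4, "TTC" * 4)

    def test_transition_weighting_changes_site_counts(self):
        # with R > 1 the synonymous transition TTT->TTC gets more site mass,
        # lowering p_S and hence dS
        a, b = "TTT" * 6, "TTC" + "TTT" * 5
        assert mlst.ng_syn_distance(a, b, R=5.0) < mlst.ng_syn_distance(a, b, R=1.0)


def _tree_distances(tree: mlst.PhyloTree):
    labels = tree.labels
    out = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                out[i, j] = out[j, i] = tree.leaf_distance(a, b)
    return out


class TestMeTree:
    def test_additive_four_taxon_matrix_recovered_exactly(self):
        """An additive matrix from a known 4-taxon tree is inverted
        exactly: same topology, same path lengths."""
        # tree: ((A:2,B:3):1,(C:4,D:5)) with internal edge 1
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 5, 7, 8],
            [5, 0, 8, 9],
            [7, 8, 0, 9],
            [8, 9, 9, 0],
        ], dtype=float)
        dm = DistanceMatrix(labels=labels, d=d)
        tree = mlst.me_tree(dm)
        np.testing.assert_allclose(_tree_distances(tree), d, atol=1e-9)
        assert tree.splits() == {frozenset({"A", "B"})}

    def test_simulated_clock_tree_topology_and_support(self):
        """Distances from a 6-taxon clock simulation recover the true
        topology with strong bootstrap support."""
        nwk = ("((A:1e6,B:1e6):2e6,((C:1.2e6,D:1.2e6):0.8e6,E:2e6):1e6,"
               "F:3e6);")
        tree0 = dendropy.Tree.get(data=nwk, schema="newick")
        loci, _ = simulate.simulate_mlst(
            tree0, {l: 900 for l in MLST_LOCI}, clock_rate=2e-8, seed=3)
        prof = mlst.concat_and_mask(loci)
        dm = mlst.syn_distance_matrix(prof)
        tree = mlst.me_tree(dm, bootstrap_n=200, seed=1,
                            alignment=prof.sequences)
        splits = tree.splits()
        assert frozenset({"A", "B"}) in splits
        assert frozenset({"C", "D"}) in splits
        assert all(v >= 0.95 for v in tree.supports.values())

    def test_no_bootstrap_means_no_supports(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = mlst.me_tree(DistanceMatrix(labels=list("ABC"), d=d))
        assert tree.supports == {}

    def test_too_few_taxa_rejected(self):
        d = np.array([[0, 1], [1, 0]], dtype=float)
        with pytest.raises(ValueError, match=">= 3"):
            mlst.me_tree(DistanceMatrix(labels=list("AB"), d=d))


class TestLinearize:
    def test_ultrametric_tree_unchanged(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):2,(C:2,D:2):1);",
                                 schema="newick")
        lin = mlst.linearize(tree)
        ages = {",".join(sorted(l.taxon.label for l in nd.leaf_iter())): nd.age
                for nd in lin.preorder_node_iter() if not nd.is_leaf()}
        assert ages["A,B"] == pytest.approx(1.0, abs=1e-9)
        assert ages["C,D"] == pytest.approx(2.0, abs=1e-9)
        assert ages["A,B,C,D"] == pytest.approx(3.0, abs=1e-9)

    def test_two_leaf_averaging(self):
        tree = dendropy.Tree.get(data="(A:0.1,B:0.3);", schema="newick")
        lin = mlst.linearize(tree)
        root_age = lin.seed_node.age
        assert root_age == pytest.approx(0.2, abs=1e-9)
        for leaf in lin.leaf_node_iter():
            assert leaf.edge.length == pytest.approx(0.2, abs=1e-9)

    def test_result_is_ultrametric(self):
        tree = dendropy.Tree.get(
            data="((A:0.11,B:0.09):0.2,(C:0.14,D:0.18):0.17);", schema="newick")
        lin = mlst.linearize(tree)
        depths = []
        for leaf in lin.leaf_node_iter():
            d, cur = 0.0, leaf
            while cur.parent_node is not None:
                d += cur.edge.length
                cur = cur.parent_node
            depths.append(d)
        assert np.ptp(depths) < 1e-9


class TestDivergenceTime:
    def test_zero_height_zero_years(self):
        assert mlst.divergence_time(0.0) == 0.0

    def test_analytic_scaling(self):
        assert mlst.divergence_time(4.7e-3) == pytest.approx(1e6)

    def test_major_cluster_magnitude(self):
        """A per-lineage height of 7.05e-3 substitutions/site maps to
        1.5 Myr at the enterobacterial calibration rate."""
        assert mlst.divergence_time(7.05e-3) / 1e6 == pytest.approx(1.5)

    def test_negative_height_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            mlst.divergence_time(-0.1)


class TestClockRecovery:
    def test_pipeline_recovers_node_ages(self):
        """simulate -> dS -> ME tree -> linearize -> date: node ages within
        15% of truth (median over seeds) at ~5 kb."""
        nwk = "((A:1e6,B:1e6):2e6,((C:1.5e6,D:1.5e6):0.5e6,E:2e6):1e6);"
        tree0 = dendropy.Tree.get(data=nwk, schema="newick")
        rel_errs = []
        for seed in range(6):
            loci, truth = simulate.simulate_mlst(
                tree0, {l: 900 for l in MLST_LOCI}, clock_rate=2e-8, seed=seed)
            prof = mlst.concat_and_mask(loci)
            dm = mlst.syn_distance_matrix(prof)
            tree = mlst.me_tree(dm)
            lin = mlst.linearize(tree)
            ages = {k: mlst.divergence_time(getattr(nd, "age"), rate=2e-8)
                    for nd, k in (
                        (nd, ",".join(sorted(l.taxon.label
                                             for l in nd.leaf_iter())))
                        for nd in lin.preorder_node_iter() if not nd.is_leaf())}
            for clade, true_age in truth["node_ages_years"].items():
                if clade in ages and true_age > 0:
                    rel_errs.append(abs(ages[clade] - true_age) / true_age)
        assert np.median(rel_errs) < 0.15
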
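"""Orthology: built-in aligner, RBH with brute-force oracle, synteny
rescue on constructed fixtures, and both clustering engines."""

import itertools

import numpy as np
import pytest

from supragenome import align, orthology
from supragenome.io import GeneFeature, Genome, PairHit


def _hit(q, s, pid=100.0, alen=100, qlen=100, slen=100, bits=200.0, ev=1e-50):
    return PairHit(query_id=q, subject_id=s, pct_identity=pid, aln_len=alen,
                   q_len=qlen, s_len=slen, bitscore=bits, evalue=ev)


class TestAlignPair:
    def test_identical_sequence_full_identity(self):
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACDEFGHIKLMNPQRSTVWY"))[
            rng.integers(0, 20, size=100)])
        h = align.align_pair(seq, seq)
        assert h.pct_identity == 100.0 and h.aln_len == 100

    def test_ten_substitutions_in_100mer(self):
        """Point mutations that stay negatively scored against the original
        residue leave a single full-length local alignment: 90% identity."""
        rng = np.random.default_rng(1)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        seq = "".join(aas[rng.integers(0, 20, size=100)])
        pos = rng.choice(100, size=10, replace=False)
        mut = list(seq)
        for p in pos:
            choices = [a for a in aas if a != mut[p]]
            mut[p] = choices[int(rng.integers(0, 19))]
        h = align.align_pair(seq, "".join(mut))
        assert h.aln_len == 100
        assert h.pct_identity == pytest.approx(90.0)

    def test_non_amino_acid_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            align.align_pair("MKV1", "MKV")

    def test_no_positive_window_returns_sentinel(self):
        # glycine runs vs tryptophan runs: every substitution scores < 0
        assert align.align_pair("GGGGG", "WWWWW") is align.NO_HIT


def _brute_force_rbh(hits, genome_of, id_min=80.0, cov_min=0.80):
    """Independent RBH enumeration: for every ordered (feature, genome)
    pick the best hit by (bitscore, identity, subject id); emit mutual
    pairs passing cutoffs."""
    features = sorted({h.query_id for h in hits} | {h.subject_id for h in hits})
    out = set()
    for a, b in itertools.combinations(features, 2):
        ga, gb = genome_of[a], genome_of[b]
        if ga == gb:
            continue

        def best_of(x, target_genome):
            cands = [h for h in hits if h.query_id == x
                     and genome_of[h.subject_id] == target_genome]
            if not cands:
                return None
            return min(cands, key=lambda h: (-h.bitscore, -h.pct_identity,
                                             h.subject_id))

        ha, hb = best_of(a, gb), best_of(b, ga)
        if ha is None or hb is None:
            continue
        if ha.subject_id != b or hb.subject_id != a:
            continue
        ok = all(
            h.pct_identity >= id_min
            and h.aln_len >= cov_min * h.q_len
            and h.aln_len >= cov_min * h.s_len
            for h in (ha, hb)
        )
        if ok:
            out.add(tuple(sorted((a, b))))
    return out


class TestReciprocalBestHits:
    GENOME_OF = {"g1|a": "g1", "g2|b": "g2"}

    def test_mutual_perfect_hit_single_pair(self):
        hits = [_hit("g1|a", "g2|b"), _hit("g2|b", "g1|a")]
        (pair,) = orthology.reciprocal_best_hits(hits, self.GENOME_OF)
        assert (pair.a, pair.b) == ("g1|a", "g2|b")
        assert pair.support == "rbh"

    def test_identity_cutoff_is_inclusive_80(self):
        below = [_hit("g1|a", "g2|b", pid=79.0), _hit("g2|b", "g1|a", pid=79.0)]
        at = [_hit("g1|a", "g2|b", pid=80.0), _hit("g2|b", "g1|a", pid=80.0)]
        assert orthology.reciprocal_best_hits(below, self.GENOME_OF) == []
        assert len(orthology.reciprocal_best_hits(at, self.GENOME_OF)) == 1

    def test_coverage_enforced_on_both_sequences(self):
        # alignment covers 80% of query but only 50% of subject
        hits = [_hit("g1|a", "g2|b", alen=80, qlen=100, slen=160),
                _hit("g2|b", "g1|a", alen=80, qlen=160, slen=100)]
        assert orthology.reciprocal_best_hits(hits, self.GENOME_OF) == []

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError, match="unknown feature"):
            orthology.reciprocal_best_hits([_hit("g1|a", "g9|zz")], self.GENOME_OF)

    def test_matches_brute_force_on_random_instances(self):
        """3 genomes x 5 families with paralogs: equals exhaustive RBH."""
        rng = np.random.default_rng(42)
        genome_of = {}
        feats = []
        for g in range(3):
            for fam in range(5):
                fid = f"g{g}|f{fam}"
                genome_of[fid] = f"g{g}"
                feats.append((fid, fam))
            # one paralog pair in each genome
            fid = f"g{g}|f0p"
            genome_of[fid] = f"g{g}"
            feats.append((fid, 0))
        hits = []
        for (a, fa), (b, fb) in itertools.permutations(feats, 2):
            if genome_of[a] == genome_of[b]:
                continue
            if fa == fb:
                pid = float(rng.uniform(75, 100))
                bits = float(rng.uniform(150, 300))
            else:
                pid = float(rng.uniform(20, 50))
                bits = float(rng.uniform(30, 60))
            hits.append(_hit(a, b, pid=pid, bits=bits))
        got = {(p.a, p.b) for p in orthology.reciprocal_best_hits(hits, genome_of)}
        assert got == _brute_force_rbh(hits, genome_of)

    def test_invariant_to_hit_order(self):
        rng = np.random.default_rng(3)
        genome_of = {f"g{g}|f{i}": f"g{g}" for g in range(3) for i in range(4)}
        hits = [_hit(a, b, pid=float(rng.uniform(70, 100)),
                     bits=float(rng.uniform(50, 300)))
                for a in genome_of for b in genome_of
                if genome_of[a] != genome_of[b]]
        ref = orthology.reciprocal_best_hits(hits, genome_of)
        shuffled = list(hits)
        rng.shuffle(shuffled)
        assert orthology.reciprocal_best_hits(shuffled, genome_of) == ref


def _collinear_genomes(n_genes=10, pid_override=None):
    """Two genomes with identical gene order; per-family hits at 100%
    identity except families listed in pid_override: {fam: pct}."""
    genomes, hits, genome_of = [], [], {}
    for g in ("gA", "gB"):
        feats = []
        for i in range(n_genes):
            fid = f"{g}|f{i}"
            genome_of[fid] = g
            feats.append(GeneFeature(fid, g, "c", 100 * i, 100 * i + 90,
                                     "+", "M" * 30))
        genomes.append(Genome(genome_id=g, features={"c": feats}))
    for i in range(n_genes):
        pid = (pid_override or {}).get(i, 100.0)
        a, b = f"gA|f{i}", f"gB|f{i}"
        hits.append(_hit(a, b, pid=pid, bits=2 * pid))
        hits.append(_hit(b, a, pid=pid, bits=2 * pid))
    return genomes, hits, genome_of


class TestSyntenyRefine:
    def test_collinear_all_confirmed_none_added(self):
        genomes, hits, genome_of = _collinear_genomes()
        pairs = orthology.reciprocal_best_hits(hits, genome_of)
        refined = orthology.synteny_refine(pairs, genomes, hits)
        assert len(refined) == 10
        assert all(p.confirmed and p.support == "rbh" for p in refined)

    def test_subcutoff_family_rescued_in_conserved_block(self):
        genomes, hits, genome_of = _collinear_genomes(pid_override={5: 70.0})
        pairs = orthology.reciprocal_best_hits(hits, genome_of)
        assert not any("f5" in p.a for p in pairs)
        refined = orthology.synteny_refine(pairs, genomes, hits)
        rescued = [p for p in refined if p.support == "synteny_rescue"]
        assert [(p.a, p.b) for p in rescued] == [("gA|f5", "gB|f5")]

    def test_scrambled_context_not_rescued(self):
        genomes, hits, genome_of = _collinear_genomes(pid_override={5: 70.0})
        # isolate gB|f5 on its own contig: no conserved neighborhood
        gb = genomes[1]
        moved = [f for f in gb.features["c"] if f.feature_id == "gB|f5"]
        gb.features["c"] = [f for f in gb.features["c"] if f.feature_id != "gB|f5"]
        gb.features["c2"] = [
            GeneFeature("gB|f5", "gB", "c2", 0, 90, "+", "M" * 30)
        ]
        pairs = orthology.reciprocal_best_hits(hits, genome_of)
        refined = orthology.synteny_refine(pairs, genomes, hits)
        assert not any(p.support == "synteny_rescue" for p in refined)

    def test_window_validation(self):
        genomes, hits, genome_of = _collinear_genomes()
        with pytest.raises(ValueError, match="window"):
            orthology.synteny_refine([], genomes, hits, window=0)


class TestMclCluster:
    def _clique_hits(self, members, ev=1e-60):
        return [_hit(a, b, ev=ev) for a in members for b in members if a != b]

    def test_two_disconnected_cliques(self):
        c1 = [f"g{i}|a" for i in range(3)]
        c2 = [f"g{i}|b" for i in range(3)]
        hits = self._clique_hits(c1) + self._clique_hits(c2)
        cs = orthology.mcl_cluster(c1 + c2, hits)
        assert sorted(map(sorted, cs.clusters.values())) == sorted(
            [sorted(c1), sorted(c2)])
        assert cs.orphans == set()

    @pytest.mark.parametrize("inflation", [1.2, 1.5, 2.0, 4.0])
    def test_block_diagonal_recovered_for_any_inflation(self, inflation):
        blocks = [[f"b{k}|m{i}" for i in range(4)] for k in range(3)]
        hits = [h for blk in blocks for h in self._clique_hits(blk)]
        feats = [m for blk in blocks for m in blk]
        cs = orthology.mcl_cluster(feats, hits, inflation=inflation)
        assert sorted(map(sorted, cs.clusters.values())) == sorted(
            map(sorted, blocks))

    def test_partition_invariant(self, synthetic_pipeline):
        sp = synthetic_pipeline
        cs = orthology.mcl_cluster(sorted(sp["proteins"]), sp["hits"])
        cs.validate()
        assert cs.n_features == len(sp["proteins"])

    def test_synthetic_families_recovered_exactly(self, synthetic_pipeline):
        """End-to-end: MCL on 2%-diverged synthetic proteins matches the
        generating families (adjusted Rand index 1.0)."""
        sklearn = pytest.importorskip("sklearn.metrics")
        sp = synthetic_pipeline
        cs = orthology.mcl_cluster(sorted(sp["proteins"]), sp["hits"])
        memb = cs.membership()
        feats = sorted(sp["proteins"])
        truth = [sp["fam_of"][f] for f in feats]
        pred = [memb.get(f, f"orph::{f}") for f in feats]
        assert sklearn.adjusted_rand_score(truth, pred) == 1.0


def _union_find_components(pairs, universe):
    parent = {f: f for f in universe}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p in pairs:
        ra, rb = find(p.a), find(p.b)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for f in universe:
        comps.setdefault(find(f), set()).add(f)
    return sorted(map(sorted, comps.values()))


class TestPairsToClusters:
    def _pair(self, a, b, pid=99.0):
        return orthology.OrthologPair(a=a, b=b, support="rbh",
                                      pct_identity=pid, coverage=1.0)

    def test_transitive_chain(self):
        pairs = [self._pair("g1|a", "g2|b"), self._pair("g2|b", "g3|c")]
        cs = orthology.pairs_to_clusters(pairs)
        assert sorted(map(sorted, cs.clusters.values())) == [
            ["g1|a", "g2|b", "g3|c"]]

    def test_empty_pairs_yield_singletons(self):
        cs = orthology.pairs_to_clusters([], features=["g1|a", "g2|b"])
        assert sorted(map(sorted, cs.clusters.values())) == [["g1|a"], ["g2|b"]]

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(11)
        universe = [f"g{g}|x{i}" for g in range(5) for i in range(6)]
        for _ in range(10):
            cand = [(a, b) for a in universe for b in universe
                    if a < b and a.split("|")[0] != b.split("|")[0]]
            take = rng.choice(len(cand), size=12, replace=False)
            pairs = [self._pair(*cand[i]) for i in take]
            cs = orthology.pairs_to_clusters(pairs, features=universe)
            # per-genome uniqueness may split components; only compare when
            # the union-find result is already genome-unique
            uf = _union_find_components(pairs, universe)
            genomes_ok = all(
                len({f.split("|")[0] for f in comp}) == len(comp) for comp in uf)
            if genomes_ok:
                assert sorted(map(sorted, cs.clusters.values())) == uf

    def test_paralog_component_split_by_weakest_edge(self):
        pairs = [self._pair("g1|a", "g2|b", pid=99.0),
                 self._pair("g2|b", "g3|c", pid=95.0),
                 self._pair("g3|c", "g1|a2", pid=60.0)]
        cs = orthology.pairs_to_clusters(pairs)
        groups = sorted(map(sorted, cs.clusters.values()))
        assert ["g1|a", "g2|b", "g3|c"] in groups
        assert ["g1|a2"] in groups
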
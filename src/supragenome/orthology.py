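"""Ortholog prediction: reciprocal best hits, synteny confirmation/rescue,
and Markov clustering of the protein similarity graph.

The RBH criterion follows the classic recipe: two features in different
genomes are called orthologs when each is the other's best hit and the
alignment passes 80% identity over 80% of the length of *both* sequences.
Ambiguous cases (paralogs, sub-cutoff families) can be rescued by conserved
gene neighborhood.  Families are then grouped either by Markov clustering
(MCL) of the -log10(evalue) similarity graph or by transitive closure of
the one-to-one pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .io import GeneFeature, Genome, PairHit

__all__ = [
    "OrthologPair",
    "ClusterSet",
    "reciprocal_best_hits",
    "synteny_refine",
    "mcl_cluster",
    "pairs_to_clusters",
]


@dataclass(frozen=True)
class OrthologPair:
    """An unordered one-to-one ortholog call between two genomes."""

    a: str
    b: str
    support: str  # "rbh" or "synteny_rescue"
    pct_identity: float
    coverage: float
    confirmed: bool = False

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("self-pair")
        if self.a > self.b:  # canonical order
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)

    def key(self) -> tuple[str, str]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)


@dataclass
class ClusterSet:
    """A partition of clustered features plus the unclustered orphans."""

    clusters: dict[str, set[str]] = field(default_factory=dict)
    orphans: set[str] = field(default_factory=set)

    def validate(self) -> None:
        seen: set[str] = set()
        for cid, members in self.clusters.items():
            if not members:
                raise ValueError(f"empty cluster {cid}")
            overlap = seen & members
            if overlap:
                raise ValueError(f"clusters overlap on {sorted(overlap)[:3]}")
            seen |= members
        if seen & self.orphans:
            raise ValueError("orphans overlap clusters")

    @property
    def n_features(self) -> int:
        return sum(len(m) for m in self.clusters.values()) + len(self.orphans)

    def membership(self) -> dict[str, str]:
        out = {}
        for cid, members in self.clusters.items():
            for f in members:
                out[f] = cid
        return out


def _hit_rank_key(h: PairHit) -> tuple:
    # better first: bitscore desc, identity desc, subject id asc
    return (-h.bitscore, -h.pct_identity, h.subject_id)


def _passes(h: PairHit, id_min: float, cov_min: float) -> bool:
    return (
        h.pct_identity >= id_min
        and h.aln_len >= cov_min * h.q_len
        and h.aln_len >= cov_min * h.s_len
    )


def reciprocal_best_hits(
    hits: Sequence[PairHit],
    genome_of: Mapping[str, str],
    id_min: float = 80.0,
    cov_min: float = 0.80,
) -> list[OrthologPair]:
    """Reciprocal-best-hit ortholog pairs at >= ``id_min`` % identity over
    >= ``cov_min`` of the length of both sequences.

    ``genome_of`` maps every feature id to its genome.  For each ordered
    (feature, partner genome) the best hit is chosen by bitscore, then
    identity, then subject id; a pair is emitted only when the choice is
    mutual and both cutoffs hold.  Output is independent of hit order.
    """
    best: dict[tuple[str, str], PairHit] = {}
    for h in hits:
        if h.query_id not in genome_of or h.subject_id not in genome_of:
            unknown = h.query_id if h.query_id not in genome_of else h.subject_id
            raise ValueError(f"hit references unknown feature {unknown!r}")
        gq, gs = genome_of[h.query_id], genome_of[h.subject_id]
        if gq == gs:
            continue
        slot = (h.query_id, gs)
        cur = best.get(slot)
        if cur is None or _hit_rank_key(h) < _hit_rank_key(cur):
            best[slot] = h

    pairs: dict[tuple[str, str], OrthologPair] = {}
    for (q, _gs), h in best.items():
        s = h.subject_id
        back = best.get((s, genome_of[q]))
        if back is None or back.subject_id != q:
            continue
        if not (_passes(h, id_min, cov_min) and _passes(back, id_min, cov_min)):
            continue
        key = tuple(sorted((q, s)))
        if key in pairs:
            continue
        # record values from the better-ranked direction: independent of
        # hit-file row order
        rec = min(h, back, key=_hit_rank_key)
        cov = min(rec.aln_len / rec.q_len, rec.aln_len / rec.s_len)
        pairs[key] = OrthologPair(
            a=key[0], b=key[1], support="rbh",
            pct_identity=rec.pct_identity, coverage=cov,
        )
    return [pairs[k] for k in sorted(pairs)]


# ---------------------------------------------------------------------------
# Synteny confirmation and rescue


def _neighbor_index(genomes: Iterable[Genome]) -> dict[str, tuple[str, str, int]]:
    """feature id -> (genome, contig, ordinal position on contig)."""
    idx = {}
    for g in genomes:
        for contig_id, feats in g.features.items():
            for pos, f in enumerate(feats):
                idx[f.feature_id] = (g.genome_id, contig_id, pos)
    return idx


def _window(genome: Genome, contig: str, pos: int, window: int) -> list[str]:
    feats = genome.features[contig]
    lo, hi = max(0, pos - window), min(len(feats), pos + window + 1)
    return [feats[i].feature_id for i in range(lo, hi) if i != pos]


def _neighbor_support(a: str, b: str, pair_of: Mapping[str, dict[str, str]],
                      genomes: Mapping[str, Genome],
                      idx: Mapping[str, tuple[str, str, int]],
                      window: int) -> int:
    ga, ca, pa = idx[a]
    gb, cb, pb = idx[b]
    near_a = _window(genomes[ga], ca, pa, window)
    near_b = set(_window(genomes[gb], cb, pb, window))
    support = 0
    for n in near_a:
        partner = pair_of.get(n, {}).get(gb)
        if partner is not None and partner in near_b:
            support += 1
    return support


def synteny_refine(
    pairs: Sequence[OrthologPair],
    genomes: Sequence[Genome],
    hits: Sequence[PairHit],
    window: int = 5,
    min_support: int = 2,
    relaxed_id: float = 50.0,
) -> list[OrthologPair]:
    """Confirm RBH pairs by conserved neighborhood and rescue sub-cutoff
    orthologs embedded in a conserved gene-order context.

    A pair is *confirmed* when at least ``min_support`` of the ``window``
    genes flanking one member are themselves paired with genes inside the
    other member's window.  A feature left unpaired against some genome is
    *rescued* via its best sub-cutoff hit when that hit reaches
    ``relaxed_id`` % identity, the partner is also unpaired, and the same
    neighborhood-support test passes.  The result stays one-to-one per
    genome pair.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    genome_map = {g.genome_id: g for g in genomes}
    idx = _neighbor_index(genomes)
    genome_of = {fid: t[0] for fid, t in idx.items()}

    # feature -> partner genome -> partner feature
    pair_of: dict[str, dict[str, str]] = {}
    for p in pairs:
        ga, gb = genome_of[p.a], genome_of[p.b]
        pair_of.setdefault(p.a, {})[gb] = p.b
        pair_of.setdefault(p.b, {})[ga] = p.a

    out: list[OrthologPair] = []
    for p in pairs:
        sup = _neighbor_support(p.a, p.b, pair_of, genome_map, idx, window)
        out.append(
            OrthologPair(a=p.a, b=p.b, support=p.support,
                         pct_identity=p.pct_identity, coverage=p.coverage,
                         confirmed=sup >= min_support)
        )

    # rescue: best sub-cutoff hit per (feature, partner genome) slot
    candidates: dict[tuple[str, str], PairHit] = {}
    for h in hits:
        gq = genome_of.get(h.query_id)
        gs = genome_of.get(h.subject_id)
        if gq is None or gs is None or gq == gs:
            continue
        if gs in pair_of.get(h.query_id, {}):
            continue  # already paired toward that genome
        slot = (h.query_id, gs)
        cur = candidates.get(slot)
        if cur is None or _hit_rank_key(h) < _hit_rank_key(cur):
            candidates[slot] = h

    taken = {(p.a, genome_of[p.b]) for p in out} | {(p.b, genome_of[p.a]) for p in out}
    for (q, gs), h in sorted(candidates.items()):
        s = h.subject_id
        if h.pct_identity < relaxed_id:
            continue
        if (q, gs) in taken or (s, genome_of[q]) in taken:
            continue
        sup = _neighbor_support(q, s, pair_of, genome_map, idx, window)
        if sup < min_support:
            continue
        cov = min(h.aln_len / h.q_len, h.aln_len / h.s_len)
        rescued = OrthologPair(a=q, b=s, support="synteny_rescue",
                               pct_identity=h.pct_identity, coverage=cov,
                               confirmed=True)
        out.append(rescued)
        taken.add((q, gs))
        taken.add((s, genome_of[q]))
        pair_of.setdefault(q, {})[gs] = s
        pair_of.setdefault(s, {})[genome_of[q]] = q
    return out


# ---------------------------------------------------------------------------
# Markov clustering


class MclConvergenceWarning(UserWarning):
    pass


def mcl_cluster(
    features: Sequence[str],
    hits: Sequence[PairHit],
    inflation: float = 1.5,
    expansion: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
    evalue_floor: float = 1e-5,
    prune: float = 1e-8,
) -> ClusterSet:
    """Markov clustering of the protein similarity graph.

    Edges are hits with evalue <= ``evalue_floor`` weighted by
    -log10(evalue) capped at 300; per-node self-loops at the node's max
    incident weight stabilize the iteration.  The process alternates
    column normalization, expansion (matrix power) and inflation
    (entrywise power + renormalize), pruning entries below ``prune``,
    until the matrix changes by less than ``tol``.  Clusters are the
    attractor sets of the limit matrix; features with no qualifying edges
    never enter the walk and are reported as orphans.
    """
    order = list(features)
    pos = {f: i for i, f in enumerate(order)}
    n = len(order)
    W = np.zeros((n, n))
    for h in hits:
        if h.query_id not in pos or h.subject_id not in pos:
            continue
        if h.query_id == h.subject_id or h.evalue > evalue_floor:
            continue
        w = min(300.0, -math.log10(h.evalue) if h.evalue > 0 else 300.0)
        i, j = pos[h.query_id], pos[h.subject_id]
        W[i, j] = max(W[i, j], w)
        W[j, i] = max(W[j, i], w)

    connected = W.sum(axis=0) > 0
    loop = np.where(connected, W.max(axis=0), 0.0)
    W[np.diag_indices(n)] = loop

    M = W.copy()
    colsum = M.sum(axis=0)
    nz = colsum > 0
    M[:, nz] /= colsum[nz]

    converged = False
    for _ in range(max_iter):
        M2 = np.linalg.matrix_power(M, expansion)
        M2 = np.power(M2, inflation)
        M2[M2 < prune] = 0.0
        colsum = M2.sum(axis=0)
        nzc = colsum > 0
        M2[:, nzc] /= colsum[nzc]
        if np.abs(M2 - M).max() < tol:
            M = M2
            converged = True
            break
        M = M2
    if not converged:
        warnings.warn("MCL did not converge within max_iter; returning "
                      "current clustering", MclConvergenceWarning)

    # attractors: rows with positive diagonal mass; cluster = attractor row support
    g = nx.Graph()
    attractors = [i for i in range(n) if M[i, i] > prune]
    for i in attractors:
        g.add_node(i)
        for j in np.nonzero(M[i] > prune)[0]:
            g.add_edge(i, int(j))
    clusters: dict[str, set[str]] = {}
    assigned: set[int] = set()
    comps = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    for k, comp in enumerate(comps):
        members = {order[i] for i in comp}
        if len(members) >= 2:
            clusters[f"C{k:05d}"] = members
            assigned |= comp
        else:
            assigned |= comp  # isolated attractor -> orphan-equivalent singleton
            clusters[f"C{k:05d}"] = members
    orphans = {order[i] for i in range(n) if i not in assigned}
    cs = ClusterSet(clusters=clusters, orphans=orphans)
    cs.validate()
    return cs


def pairs_to_clusters(pairs: Sequence[OrthologPair],
                      features: Sequence[str] | None = None,
                      genome_of: Mapping[str, str] | None = None) -> ClusterSet:
    """Group one-to-one pairs into clusters by connected components.

    If a component ends up holding two features of one genome (possible
    when closure chains paralogs across genome pairs), the weakest-identity
    edge is removed repeatedly until per-genome uniqueness holds.
    ``features`` lists the full universe; unpaired members become
    singleton clusters.
    """
    g = nx.Graph()
    for p in pairs:
        g.add_edge(p.a, p.b, weight=p.pct_identity)
    universe = list(features) if features is not None else sorted(g.nodes)
    for f in universe:
        g.add_node(f)

    clusters: dict[str, set[str]] = {}
    k = 0
    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0]):
        sub = g.subgraph(comp).copy()
        stack = [sub]
        while stack:
            piece = stack.pop()
            if genome_of is not None:
                genomes = [genome_of.get(f, f.split("|")[0]) for f in piece.nodes]
            else:
                genomes = [f.split("|")[0] for f in piece.nodes]
            if len(genomes) != len(set(genomes)) and piece.number_of_edges() > 0:
                weakest = min(piece.edges(data=True),
                              key=lambda e: (e[2].get("weight", 0.0),
                                             tuple(sorted((e[0], e[1])))))
                piece.remove_edge(weakest[0], weakest[1])
                for c in nx.connected_components(piece):
                    stack.append(piece.subgraph(c).copy())
            else:
                clusters[f"P{k:05d}"] = set(piece.nodes)
                k += 1
    cs = ClusterSet(clusters=clusters)
    cs.validate()
    return cs
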
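"""MLST phylogeny: concatenation with complete deletion, Nei-Gojobori
synonymous distances, minimum-evolution trees with bootstrap, strict-clock
linearization and divergence-time scaling.

Distances are synonymous substitutions per synonymous site (dS), computed
by the (modified) Nei-Gojobori method: synonymous site counts weight each
possible single-base change by the transition/transversion ratio R (R = 1
recovers the original method); codons differing at several positions are
averaged over all minimal substitution pathways that avoid stop codons;
the raw proportion p_S is Jukes-Cantor corrected,
dS = -(3/4) ln(1 - 4 p_S / 3).

The tree is built by neighbor joining, given ordinary-least-squares branch
lengths, and refined by nearest-neighbor interchanges accepted whenever
the total tree length decreases (the minimum-evolution criterion).
Bootstrap resamples codon columns of the concatenated alignment.
"""

from __future__ import annotations

import io as _io
import itertools
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import dendropy
import networkx as nx
import numpy as np

from .genecontent import DistanceMatrix

__all__ = [
    "MLST_LOCI",
    "MlstProfile",
    "concat_and_mask",
    "ng_syn_distance",
    "syn_distance_matrix",
    "me_tree",
    "linearize",
    "divergence_time",
    "node_ages_myr",
    "tree_from_newick",
    "PhyloTree",
]

MLST_LOCI = ("ftsZ", "metRS", "mutL", "pgm", "nrdD", "polA")

_BASES = "TCAG"
_CODE = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
_CODONS = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
_CODON_IDX = {c: i for i, c in enumerate(_CODONS)}
_AA = {c: _CODE[i] for i, c in enumerate(_CODONS)}
_STOPS = {c for c, a in _AA.items() if a == "*"}
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class MlstProfile:
    """Codon-aligned, complete-deletion-masked MLST concatenation."""

    strains: list[str]
    sequences: dict[str, str]  # strain -> concatenated coding sequence
    locus_order: tuple[str, ...] = MLST_LOCI
    n_codons_removed: int = 0

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))


def concat_and_mask(loci: Mapping[str, Mapping[str, str]],
                    locus_order: Sequence[str] = MLST_LOCI) -> MlstProfile:
    """Concatenate per-locus alignments and apply complete deletion.

    ``loci`` maps locus name -> {strain -> aligned sequence}.  Loci are
    concatenated in ``locus_order``; any codon column holding a gap or
    ambiguous base in *any* strain is removed in every strain (complete
    deletion at codon granularity, preserving frame).
    """
    missing = [l for l in locus_order if l not in loci]
    if missing:
        raise ValueError(f"missing loci: {missing}")
    strains = sorted(loci[locus_order[0]])
    for locus in locus_order:
        if sorted(loci[locus]) != strains:
            raise ValueError(f"locus {locus}: strain set differs")
        lengths = {len(s) for s in loci[locus].values()}
        if len(lengths) != 1:
            raise ValueError(f"locus {locus}: unequal sequence lengths")
        (L,) = lengths
        if L % 3:
            raise ValueError(f"locus {locus}: length {L} not divisible by 3")

    concat = {s: "".join(loci[l][s].upper() for l in locus_order) for s in strains}
    L = len(concat[strains[0]])
    kept: list[str] = []
    removed = 0
    clean = set("ACGT")
    for c0 in range(0, L, 3):
        ok = all(set(concat[s][c0 : c0 + 3]) <= clean for s in strains)
        if ok:
            kept.append(slice(c0, c0 + 3))
        else:
            removed += 1
    masked = {
        s: "".join(concat[s][sl] for sl in kept) for s in strains
    }
    return MlstProfile(strains=strains, sequences=masked,
                       locus_order=tuple(locus_order), n_codons_removed=removed)


# ---------------------------------------------------------------------------
# Nei-Gojobori machinery


def _syn_sites_per_codon(R: float) -> np.ndarray:
    """Synonymous site count for each codon; each position contributes a
    weighted fraction of one site (transition weight R, transversion 1);
    changes creating stop codons are excluded."""
    out = np.zeros(64)
    for idx, codon in enumerate(_CODONS):
        if codon in _STOPS:
            out[idx] = np.nan
            continue
        s = 0.0
        for pos in range(3):
            w_syn = w_tot = 0.0
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                mutant = codon[:pos] + b + codon[pos + 1 :]
                if mutant in _STOPS:
                    continue
                w = R if (codon[pos], b) in _TRANSITIONS else 1.0
                w_tot += w
                if _AA[mutant] == _AA[codon]:
                    w_syn += w
            if w_tot > 0:
                s += w_syn / w_tot
        out[idx] = s
    return out


@lru_cache(maxsize=8)
def _syn_sites_table(R: float) -> tuple:
    return tuple(_syn_sites_per_codon(R))


@lru_cache(maxsize=1)
def _pair_diff_tables() -> tuple[np.ndarray, np.ndarray]:
    """(syn, nonsyn) substitution counts per ordered codon pair, averaged
    over all minimal pathways; pathways through stop codons are excluded
    (all-blocked pairs fall back to unrestricted averaging)."""
    syn = np.zeros((64, 64))
    non = np.zeros((64, 64))
    for i, a in enumerate(_CODONS):
        for j, b in enumerate(_CODONS):
            if a in _STOPS or b in _STOPS or a == b:
                continue
            positions = [p for p in range(3) if a[p] != b[p]]
            paths = []
            for order in itertools.permutations(positions):
                cur = a
                sd = nd = 0.0
                blocked = False
                for p in order:
                    nxt = cur[:p] + b[p] + cur[p + 1 :]
                    if nxt in _STOPS:
                        blocked = True
                        break
                    if _AA[nxt] == _AA[cur]:
                        sd += 1.0
                    else:
                        nd += 1.0
                    cur = nxt
                if not blocked:
                    paths.append((sd, nd))
            if not paths:  # every pathway crosses a stop; average ignoring stops
                for order in itertools.permutations(positions):
                    cur = a
                    sd = nd = 0.0
                    for p in order:
                        nxt = cur[:p] + b[p] + cur[p + 1 :]
                        if _AA[nxt] == _AA[cur]:
                            sd += 1.0
                        else:
                            nd += 1.0
                        cur = nxt
                    paths.append((sd, nd))
            syn[i, j] = float(np.mean([p[0] for p in paths]))
            non[i, j] = float(np.mean([p[1] for p in paths]))
    return syn, non


def _codon_indices(seq: str, name: str) -> np.ndarray:
    seq = seq.upper()
    if len(seq) % 3:
        raise ValueError(f"{name}: length {len(seq)} not divisible by 3")
    if set(seq) - set("ACGT"):
        raise ValueError(f"{name}: sequence must be gap-free ACGT "
                         "(mask with concat_and_mask first)")
    idx = np.array([_CODON_IDX[seq[i : i + 3]] for i in range(0, len(seq), 3)])
    stops = [i for i, c in enumerate(idx) if _CODONS[c] in _STOPS]
    internal = [i for i in stops if i < len(idx) - 1]
    if internal:
        raise ValueError(f"{name}: internal stop codon at codon {internal[0]}")
    if stops:  # terminal stop: drop it from the comparison
        idx = idx[:-1]
    return idx


def ng_syn_distance(seq_a: str, seq_b: str, R: float = 1.0) -> float:
    """Synonymous distance dS between two in-frame coding sequences.

    Raises on saturation (p_S >= 3/4) and on internal stop codons.
    """
    ia = _codon_indices(seq_a, "seq_a")
    ib = _codon_indices(seq_b, "seq_b")
    if len(ia) != len(ib):
        raise ValueError("sequences differ in length")
    sites = np.asarray(_syn_sites_table(R))
    syn_tab, _ = _pair_diff_tables()
    S = 0.5 * (sites[ia].sum() + sites[ib].sum())
    if S <= 0:
        raise ValueError("no synonymous sites")
    sd = syn_tab[ia, ib].sum()
    p_s = sd / S
    if p_s >= 0.75:
        raise ValueError(f"synonymous saturation: p_S = {p_s:.3f} >= 3/4")
    return -0.75 * math.log(1.0 - 4.0 * p_s / 3.0)


def syn_distance_matrix(profile: MlstProfile, R: float = 1.0) -> DistanceMatrix:
    n = len(profile.strains)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = ng_syn_distance(
                profile.sequences[profile.strains[i]],
                profile.sequences[profile.strains[j]], R=R,
            )
    return DistanceMatrix(labels=list(profile.strains), d=d)


# ---------------------------------------------------------------------------
# Minimum-evolution tree


def _nj_topology(dist: DistanceMatrix) -> nx.Graph:
    """Neighbor-joining starting topology (dendropy) as an undirected graph
    with leaves labeled and internal nodes numbered."""
    buf = _io.StringIO()
    buf.write("," + ",".join(dist.labels) + "\n")
    for i, lab in enumerate(dist.labels):
        buf.write(lab + "," + ",".join(f"{x:.12g}" for x in dist.d[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    tree = pdm.nj_tree()
    g = nx.Graph()
    counter = itertools.count()
    node_of: dict = {}

    def name_for(nd) -> str:
        if nd not in node_of:
            if nd.taxon is not None:
                node_of[nd] = nd.taxon.label
            else:
                node_of[nd] = f"__internal_{next(counter)}"
        return node_of[nd]

    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        g.add_edge(name_for(edge.tail_node), name_for(edge.head_node))
    # suppress degree-2 nodes (rooting artifacts)
    for nd in [n for n in g.nodes if g.degree[n] == 2 and str(n).startswith("__")]:
        a, b = list(g.neighbors(nd))
        g.remove_node(nd)
        g.add_edge(a, b)
    return g


def _ols_lengths(g: nx.Graph, dist: DistanceMatrix) -> tuple[dict, float]:
    """Ordinary-least-squares edge lengths for topology ``g``; returns
    (edge -> length, total tree length with negatives clamped at 0)."""
    labels = dist.labels
    edges = sorted((tuple(sorted(e)) for e in g.edges))
    eidx = {e: k for k, e in enumerate(edges)}
    pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    paths = dict(nx.all_pairs_shortest_path(g))
    for r, (i, j) in enumerate(pairs):
        path = paths[labels[i]][labels[j]]
        for u, v in zip(path, path[1:]):
            A[r, eidx[tuple(sorted((u, v)))]] = 1.0
        y[r] = dist.d[i, j]
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    lengths = {e: float(b) for e, b in zip(edges, sol)}
    total = float(np.sum(np.maximum(sol, 0.0)))
    return lengths, total


def _nni_neighbors(g: nx.Graph):
    """Yield topologies one NNI away (around every internal edge)."""
    for u, v in list(g.edges):
        if g.degree[u] != 3 or g.degree[v] != 3:
            continue
        a_nbrs = [x for x in g.neighbors(u) if x != v]
        b_nbrs = [x for x in g.neighbors(v) if x != u]
        for b in b_nbrs:
            # swap a_nbrs[1] with b
            h = g.copy()
            h.remove_edge(u, a_nbrs[1])
            h.remove_edge(v, b)
            h.add_edge(u, b)
            h.add_edge(v, a_nbrs[1])
            yield h


def _canonical_split(side: set, leaves: set) -> frozenset:
    """A leaf bipartition keyed by its smaller side (ties lexicographic)."""
    other = leaves - side
    return frozenset(min(side, other, key=lambda s: (len(s), sorted(s))))


@dataclass
class PhyloTree:
    """Unrooted tree with OLS branch lengths and optional bootstrap support.

    ``graph`` is undirected with string nodes (leaf labels and
    ``__internal_*`` placeholders); ``lengths`` maps sorted edge tuples to
    branch lengths; ``supports`` maps leaf bipartitions (frozenset of the
    smaller side) to support fractions.
    """

    graph: nx.Graph
    lengths: dict[tuple[str, str], float]
    labels: list[str]
    supports: dict[frozenset, float] = field(default_factory=dict)
    total_length: float = 0.0

    def splits(self) -> set[frozenset]:
        out = set()
        leaves = set(self.labels)
        for u, v in self.graph.edges:
            h = self.graph.copy()
            h.remove_edge(u, v)
            side = set(nx.node_connected_component(h, u)) & leaves
            if 1 < len(side) < len(leaves) - 1:
                out.add(_canonical_split(side, leaves))
        return out

    def to_newick(self) -> str:
        """Newick string (supports, when present, as internal labels)."""
        leaves = set(self.labels)
        root = next(n for n in self.graph.nodes if n not in leaves) \
            if len(self.labels) > 2 else self.labels[0]

        def fmt(node: str, parent: str | None) -> str:
            kids = [n for n in self.graph.neighbors(node) if n != parent]
            if not kids:
                return node
            inner = ",".join(
                f"{fmt(k, node)}:{max(0.0, self.lengths[tuple(sorted((node, k)))]):.10g}"
                for k in kids
            )
            label = ""
            if self.supports and parent is not None:
                side = self._leafset_below(node, parent)
                key = _canonical_split(side, set(self.labels))
                if key in self.supports:
                    label = f"{100 * self.supports[key]:.0f}"
            return f"({inner}){label}"

        return fmt(root, None) + ";"

    def _leafset_below(self, node: str, parent: str) -> set:
        h = self.graph.copy()
        h.remove_edge(node, parent)
        return set(nx.node_connected_component(h, node)) & set(self.labels)

    def to_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.to_newick(), schema="newick",
                                 preserve_underscores=True)

    def leaf_distance(self, a: str, b: str) -> float:
        path = nx.shortest_path(self.graph, a, b)
        return sum(max(0.0, self.lengths[tuple(sorted((u, v)))])
                   for u, v in zip(path, path[1:]))


def _me_from_distance(dist: DistanceMatrix) -> PhyloTree:
    g = _nj_topology(dist)
    lengths, total = _ols_lengths(g, dist)
    improved = True
    while improved:
        improved = False
        for h in _nni_neighbors(g):
            l2, t2 = _ols_lengths(h, dist)
            if t2 < total - 1e-12:
                g, lengths, total = h, l2, t2
                improved = True
                break
    if any(v < -1e-9 for v in lengths.values()):
        warnings.warn("negative OLS branch length(s) clamped to 0")
    return PhyloTree(graph=g, lengths=lengths, labels=list(dist.labels),
                     total_length=total)


def me_tree(dist: DistanceMatrix, bootstrap_n: int = 0,
            seed: int | None = None,
            alignment: Mapping[str, str] | None = None,
            R: float = 1.0) -> PhyloTree:
    """Minimum-evolution tree: NJ start, OLS lengths, NNI refinement.

    Bootstrapping (``bootstrap_n`` > 0) requires the codon ``alignment``
    the distances came from; replicates resample codon columns, rebuild
    distances and trees, and supports are the fraction of replicates
    containing each leaf bipartition.
    """
    if len(dist.labels) < 3:
        raise ValueError("need >= 3 taxa")
    tree = _me_from_distance(dist)
    if bootstrap_n > 0:
        if alignment is None:
            raise ValueError("bootstrap requires the codon alignment")
        rng = np.random.default_rng(seed)
        strains = list(dist.labels)
        n_codons = len(alignment[strains[0]]) // 3
        counts: dict[frozenset, int] = {s: 0 for s in tree.splits()}
        for _ in range(bootstrap_n):
            cols = rng.integers(0, n_codons, size=n_codons)
            boot_aln = {
                s: "".join(alignment[s][3 * c : 3 * c + 3] for c in cols)
                for s in strains
            }
            prof = MlstProfile(strains=strains, sequences=boot_aln)
            try:
                bd = syn_distance_matrix(prof, R=R)
            except ValueError:  # saturated replicate
                continue
            rep = _me_from_distance(bd)
            rep_splits = rep.splits()
            for s in counts:
                if s in rep_splits:
                    counts[s] += 1
        tree.supports = {s: c / bootstrap_n for s, c in counts.items()}
    return tree


def tree_from_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)


# ---------------------------------------------------------------------------
# Clock linearization and dating


def linearize(tree: dendropy.Tree | PhyloTree) -> dendropy.Tree:
    """Impose a strict clock: midpoint-root (if needed), then set every
    node's height to the mean node-to-descendant-leaf path length,
    clipping children at their parent's height.  Leaves sit at height 0;
    the result is ultrametric.
    """
    if isinstance(tree, PhyloTree):
        tree = tree.to_dendropy()
    tree = tree.clone(depth=1)
    tree.encode_bipartitions()
    if len(tree.seed_node.child_nodes()) > 2:
        tree.reroot_at_midpoint(update_bipartitions=True)

    heights: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            heights[nd] = 0.0
        else:
            vals = []
            for child in nd.child_nodes():
                bl = child.edge.length or 0.0
                for leaf in child.leaf_iter():
                    # path child-subtree leaf -> nd
                    d = bl
                    cur = leaf
                    while cur is not child:
                        d += cur.edge.length or 0.0
                        cur = cur.parent_node
                    vals.append(d)
            heights[nd] = float(np.mean(vals))
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None and heights[nd] > heights[nd.parent_node]:
            heights[nd] = heights[nd.parent_node]
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = heights[nd.parent_node] - heights[nd]
        nd.age = heights[nd]
    return tree


def divergence_time(node_height_d: float, rate: float = 4.7e-9) -> float:
    """Convert a per-lineage node height (substitutions/site) to years.

    With an ultrametric height d and per-site per-year rate r, t = d / r:
    the height is already per lineage, so no extra factor of two.
    """
    if node_height_d < 0:
        raise ValueError("negative height")
    if rate <= 0:
        raise ValueError("rate must be positive")
    return node_height_d / rate


def node_ages_myr(tree: dendropy.Tree, rate: float = 4.7e-9) -> dict[str, float]:
    """Ages (Myr) of internal nodes of a linearized tree, keyed by the
    sorted tuple of descendant leaf labels."""
    out = {}
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        leaves = ",".join(sorted(l.taxon.label for l in nd.leaf_iter()))
        out[leaves] = divergence_time(getattr(nd, "age", 0.0), rate) / 1e6
    return out
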
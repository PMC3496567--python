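"""Synthetic data with known ground truth for every pipeline stage.

The pan-genome generator draws gene families from a K-component binomial
mixture (the model the extrapolation assumes), the genome generator turns
a presence/absence matrix into diverged protein sequences laid out in
conserved synteny blocks, the CRISPR generator plants repeat-spacer arrays
with designated shared spacer blocks, and the MLST generator evolves codon
sequences on a known clock tree.  Defaults mirror the scale of a
17-strain lactic-acid-bacterium study (G = 17, pan-genome scale ~9,000
families); mixture weights/detection probabilities are illustrative.
Every generator is bit-reproducible per seed and returns a machine-
readable truth record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .crispr import CrisprArray, RepeatModel, LSAL1
from .io import GeneFeature, Genome
from .panmatrix import PanMatrix

__all__ = [
    "SynthPanConfig",
    "SynthSeqConfig",
    "simulate_pangenome",
    "simulate_genomes",
    "simulate_crispr",
    "simulate_mlst",
]

_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_NT = np.array(list("ACGT"))


@dataclass
class SynthPanConfig:
    G: int = 17
    pan_size: int = 9072
    K: int = 3
    pi: tuple[float, ...] = (0.45, 0.35, 0.20)
    rho: tuple[float, ...] = (0.08, 0.55, 0.99)
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.pi) != self.K or len(self.rho) != self.K:
            raise ValueError("pi/rho length must equal K")
        if abs(sum(self.pi) - 1.0) > 1e-9:
            raise ValueError("pi must sum to 1")
        if any(not (0 < r <= 1) for r in self.rho):
            raise ValueError("rho must lie in (0, 1]")


@dataclass
class SynthSeqConfig:
    mean_gene_len: int = 300  # amino acids
    divergence: float = 0.02  # per-residue substitution probability
    paralog_prob: float = 0.02
    synteny_block_len: int = 20
    seed: int | None = None


def simulate_pangenome(config: SynthPanConfig) -> tuple[PanMatrix, dict]:
    """Draw a presence/absence matrix from the binomial mixture.

    Each of ``pan_size`` families gets a component k ~ pi, then per-genome
    presence ~ Bernoulli(rho_k); all-zero families are dropped from the
    matrix but counted in the truth record.
    """
    rng = np.random.default_rng(config.seed)
    comp = rng.choice(config.K, size=config.pan_size, p=config.pi)
    rho = np.asarray(config.rho)[comp]
    X = (rng.random((config.pan_size, config.G)) < rho[:, None]).astype(int)
    observed = X.sum(axis=1) > 0
    genome_ids = [f"g{i + 1:02d}" for i in range(config.G)]
    fam_ids = [f"fam{i:05d}" for i in range(config.pan_size)]
    df = pd.DataFrame(X[observed],
                      index=[f for f, o in zip(fam_ids, observed) if o],
                      columns=genome_ids)
    truth = {
        "component": {f: int(k) for f, k in zip(fam_ids, comp)},
        "n_unobserved": int((~observed).sum()),
        "pan_size": config.pan_size,
        "pi": list(config.pi),
        "rho": list(config.rho),
    }
    return PanMatrix(df=df), truth


def _mutate_protein(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    if hit.any():
        repl = _AA20[rng.integers(0, 20, size=int(hit.sum()))]
        # force a change where the draw equals the original residue
        same = repl == out[hit]
        while same.any():
            repl[same] = _AA20[rng.integers(0, 20, size=int(same.sum()))]
            same = repl == out[hit]
        out[hit] = repl
    return out


def simulate_genomes(
    pan_matrix: PanMatrix,
    seq_config: SynthSeqConfig,
) -> tuple[list[Genome], dict[str, str], dict[str, str], dict]:
    """Materialize a pan-matrix as diverged protein sequences with synteny.

    One ancestral protein per family; each genome's copy is mutated at the
    configured per-residue divergence.  Genes are laid out on one contig
    per genome in a global family order (shared families therefore sit in
    conserved blocks); paralogs are extra, further-diverged copies.

    Returns (genomes, proteins id->seq, feature id->family truth, meta).
    """
    rng = np.random.default_rng(seq_config.seed)
    fams = list(pan_matrix.cluster_ids)
    lens = np.maximum(
        50, rng.poisson(seq_config.mean_gene_len, size=len(fams))
    )
    ancestors = {
        f: _AA20[rng.integers(0, 20, size=int(L))] for f, L in zip(fams, lens)
    }
    genomes: list[Genome] = []
    proteins: dict[str, str] = {}
    fam_of: dict[str, str] = {}
    for gid in pan_matrix.genome_ids:
        present = [f for f in fams if pan_matrix.df.loc[f, gid] == 1]
        feats: list[GeneFeature] = []
        pos = 0
        contig_id = f"{gid}_c1"
        copy_counter: dict[str, int] = {}
        for f in present:
            n_copies = 1 + int(rng.random() < seq_config.paralog_prob)
            for c in range(n_copies):
                rate = seq_config.divergence * (1 + c)  # paralogs drift more
                seq = "".join(_mutate_protein(ancestors[f], rate, rng))
                copy_counter[f] = copy_counter.get(f, 0) + 1
                fid = f"{gid}|{f}_{copy_counter[f]}"
                start = pos
                end = start + 3 * len(seq) + 3
                pos = end + int(rng.integers(50, 200))
                feats.append(GeneFeature(
                    feature_id=fid, genome_id=gid, contig_id=contig_id,
                    start=start, end=end, strand="+", protein_seq=seq,
                ))
                proteins[fid] = seq
                fam_of[fid] = f
        contig_len = (feats[-1].end + 100) if feats else 100
        contig = "".join(_NT[rng.integers(0, 4, size=contig_len)])
        genomes.append(Genome(genome_id=gid, contigs={contig_id: contig},
                              features={contig_id: feats}))
    meta = {"n_features": len(proteins),
            "n_families_observed": len(fams)}
    return genomes, proteins, fam_of, meta


def simulate_crispr(
    n_strains: int = 3,
    n_spacers: int = 8,
    shared_block: tuple[int, int] | None = None,
    shared_strains: tuple[int, ...] | None = None,
    repeat_model: RepeatModel = LSAL1,
    spacer_len: int = 30,
    contig_len: int = 5000,
    n_arrays_per_strain: int = 1,
    seed: int | None = None,
) -> tuple[dict[str, str], dict[str, list[CrisprArray]], dict]:
    """Plant CRISPR arrays in random contigs.

    Without ``shared_block`` every strain gets its own random spacers.
    With ``shared_block = (start, length)`` (0-based position from the
    leader), the strains in ``shared_strains`` (default: all) carry the
    same spacer sequences over that stretch.  Truth arrays list planted
    spacers leader-proximal first.
    """
    rng = np.random.default_rng(seed)
    shared_strains = tuple(range(n_strains)) if shared_strains is None else shared_strains
    shared_seqs: dict[int, str] = {}
    if shared_block is not None:
        b0, blen = shared_block
        for k in range(b0, b0 + blen):
            shared_seqs[k] = "".join(_NT[rng.integers(0, 4, size=spacer_len)])

    contigs: dict[str, str] = {}
    truth_arrays: dict[str, list[CrisprArray]] = {}
    rep = repeat_model.consensus
    for si in range(n_strains):
        strain = f"s{si + 1:02d}"
        truth_arrays[strain] = []
        pieces = []
        pos = 0
        for _ in range(n_arrays_per_strain):
            lead = "".join(_NT[rng.integers(0, 4, size=int(rng.integers(200, 400)))])
            pieces.append(lead)
            pos += len(lead)
            spacers = []
            for k in range(n_spacers):
                if si in shared_strains and k in shared_seqs:
                    spacers.append(shared_seqs[k])
                else:
                    spacers.append("".join(_NT[rng.integers(0, 4, size=spacer_len)]))
            start = pos
            array_seq = rep + "".join(s + rep for s in spacers)
            pieces.append(array_seq)
            pos += len(array_seq)
            truth_arrays[strain].append(CrisprArray(
                genome_id=strain, contig_id=f"{strain}_c1",
                start=start, end=pos, strand="+",
                repeat_starts=[],  # filled by detection, not needed as truth
                repeat_mismatches=[0] * (n_spacers + 1),
                spacers=spacers,
            ))
        tail = "".join(_NT[rng.integers(0, 4, size=max(0, contig_len - pos))])
        contigs[f"{strain}_c1"] = "".join(pieces) + tail
    truth = {"n_spacers": n_spacers, "shared_block": shared_block,
             "shared_strains": list(shared_strains)}
    return contigs, truth_arrays, truth


# ---------------------------------------------------------------------------
# MLST simulation

_STOP_CODONS = {"TAA", "TAG", "TGA"}


def _random_coding_seq(n_codons: int, rng: np.random.Generator) -> str:
    out = []
    while len(out) < n_codons:
        c = "".join(_NT[rng.integers(0, 4, size=3)])
        if c not in _STOP_CODONS:
            out.append(c)
    return "".join(out)


def _evolve(seq: str, exp_subs_per_site: float, rng: np.random.Generator) -> str:
    """Evolve a coding sequence; substitutions are Poisson per site and
    uniform over the three alternative bases, rejecting stop-creating hits."""
    arr = list(seq)
    n_events = rng.poisson(exp_subs_per_site * len(arr))
    sites = rng.integers(0, len(arr), size=n_events)
    for s in sites:
        old = arr[s]
        choices = [b for b in "ACGT" if b != old]
        new = choices[int(rng.integers(0, 3))]
        codon_start = 3 * (s // 3)
        codon = arr[codon_start : codon_start + 3]
        codon[s - codon_start] = new
        if "".join(codon) in _STOP_CODONS:
            continue
        arr[s] = new
    return "".join(arr)


def simulate_mlst(
    tree: dendropy.Tree,
    locus_lengths: dict[str, int] | None = None,
    clock_rate: float = 4.7e-9,
    seed: int | None = None,
) -> tuple[dict[str, dict[str, str]], dict]:
    """Evolve codon-aligned MLST loci along an ultrametric tree.

    Branch lengths are interpreted in years; the expected number of
    substitutions per site on a branch is ``clock_rate * years``.  Returns
    ({locus: {strain: sequence}}, truth with node ages in years).
    """
    from .mlst import MLST_LOCI

    if locus_lengths is None:
        locus_lengths = {l: 450 for l in MLST_LOCI}
    for l, L in locus_lengths.items():
        if L % 3:
            raise ValueError(f"locus {l}: length must be divisible by 3")
    rng = np.random.default_rng(seed)
    tree = tree.clone(depth=1)

    loci: dict[str, dict[str, str]] = {l: {} for l in locus_lengths}
    for locus, L in locus_lengths.items():
        root_seq = _random_coding_seq(L // 3, rng)
        seqs: dict = {tree.seed_node: root_seq}
        for nd in tree.preorder_node_iter():
            if nd is tree.seed_node:
                continue
            t_years = nd.edge.length or 0.0
            seqs[nd] = _evolve(seqs[nd.parent_node], clock_rate * t_years, rng)
        for leaf in tree.leaf_node_iter():
            loci[locus][leaf.taxon.label] = seqs[leaf]

    # truth node ages (years): max root-to-tip distance below each node
    ages = {}
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        dists = []
        for leaf in nd.leaf_iter():
            d = 0.0
            cur = leaf
            while cur is not nd:
                d += cur.edge.length or 0.0
                cur = cur.parent_node
            dists.append(d)
        key = ",".join(sorted(l.taxon.label for l in nd.leaf_iter()))
        ages[key] = float(np.mean(dists))
    truth = {"node_ages_years": ages, "clock_rate": clock_rate,
             "locus_lengths": dict(locus_lengths)}
    return loci, truth
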
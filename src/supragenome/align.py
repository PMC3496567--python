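"""Built-in protein local alignment for toy-scale inputs.

Production runs are expected to supply precomputed all-vs-all hits in BLAST
tabular form; this Smith-Waterman path (BLOSUM62, affine gaps) exists so
that synthetic fixtures exercise the whole pipeline without an external
search tool.  Scores are converted to bits and pseudo-evalues with gapped
Karlin-Altschul parameters so downstream weighting (-log10 evalue) is
uniform across both hit sources.
"""

from __future__ import annotations

import math
import re
from typing import Iterable, Mapping

from Bio.Align import PairwiseAligner, substitution_matrices

from .io import PairHit

__all__ = ["align_pair", "all_vs_all_hits", "NO_HIT"]

# gapped BLOSUM62 (open 11, extend 1) Karlin-Altschul parameters
_LAMBDA = 0.267
_K = 0.041

_AA = set("ACDEFGHIKLMNPQRSTVWYBZX*")

#: sentinel returned when no positive-scoring local window exists
NO_HIT = None


def _aligner() -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln.open_gap_score = -11.0
    aln.extend_gap_score = -1.0
    return aln


def _check_protein(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    bad = set(seq.upper()) - _AA
    if bad:
        raise ValueError(f"{name}: non-amino-acid symbols {sorted(bad)}")


def align_pair(seq_a: str, seq_b: str, *, query_id: str = "a",
               subject_id: str = "b") -> PairHit | None:
    """Locally align two protein sequences; return a PairHit or ``NO_HIT``.

    Percent identity is computed over aligned columns (gap columns count
    against identity); ``aln_len`` is the number of alignment columns.
    """
    _check_protein(seq_a, query_id)
    _check_protein(seq_b, subject_id)
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    aln = _aligner()
    try:
        best = next(iter(aln.align(seq_a, seq_b)))
    except (StopIteration, ValueError):
        return NO_HIT
    score = best.score
    if score <= 0:
        return NO_HIT
    ta, tb = best[0], best[1]  # aligned rows with gap dashes
    ncols = len(ta)
    ident = sum(1 for x, y in zip(ta, tb) if x == y and x != "-")
    bits = (_LAMBDA * score - math.log(_K)) / math.log(2.0)
    evalue = len(seq_a) * len(seq_b) * 2.0 ** (-bits)
    return PairHit(
        query_id=query_id,
        subject_id=subject_id,
        pct_identity=100.0 * ident / ncols if ncols else 0.0,
        aln_len=ncols,
        q_len=len(seq_a),
        s_len=len(seq_b),
        bitscore=bits,
        evalue=evalue,
    )


def all_vs_all_hits(proteins: Mapping[str, str],
                    genome_of: Mapping[str, str] | None = None,
                    *, include_self: bool = False) -> list[PairHit]:
    """All-vs-all local alignment over a protein set (toy scale only).

    Emits both hit directions for every unordered pair, mirroring what an
    external search produces.  ``genome_of`` restricts pairs to features of
    different genomes when given (self-genome paralog hits are still kept —
    clustering needs them — only identical-feature self hits are dropped
    unless ``include_self``).
    """
    ids = list(proteins)
    hits: list[PairHit] = []
    for i, a in enumerate(ids):
        for b in ids[i:]:
            if a == b and not include_self:
                continue
            h = align_pair(proteins[a], proteins[b], query_id=a, subject_id=b)
            if h is NO_HIT:
                continue
            hits.append(h)
            if a != b:
                hits.append(
                    PairHit(query_id=b, subject_id=a,
                            pct_identity=h.pct_identity, aln_len=h.aln_len,
                            q_len=h.s_len, s_len=h.q_len,
                            bitscore=h.bitscore, evalue=h.evalue)
                )
    return hits
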
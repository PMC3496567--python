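"""CRISPR repeat-spacer arrays: detection, cross-strain spacer comparison,
and protospacer-flank (PAM) consensus.

Arrays are found by scanning both strands for near-exact (Hamming, no
indels) occurrences of a known repeat consensus and chaining occurrences
whose gaps fall in the allowed spacer-length range.  Spacers are reported
leader-proximal first; the leader end is taken to be the array end
opposite the most degenerate (most mismatched) terminal repeat, a common
property of the repeat adjoining the trailer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RepeatModel",
    "LSAL1",
    "LDBU1",
    "CrisprArray",
    "SpacerMatch",
    "find_arrays",
    "spacer_sharing",
    "find_protospacers",
    "protospacer_flanks",
    "reverse_complement",
]

_COMP = str.maketrans("ACGTNRYSWKMacgtnryswkm", "TGCANYRSWMKtgcanyrswmk")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class RepeatModel:
    """A CRISPR repeat family: consensus plus mismatch tolerance."""

    name: str
    consensus: str
    max_mismatch: int = 2

    def __post_init__(self) -> None:
        if len(self.consensus) < 20:
            raise ValueError("repeat consensus must be >= 20 nt")
        if set(self.consensus.upper()) - set("ACGT"):
            raise ValueError("consensus must be over ACGT")


#: Type II-A repeat family (found in L. salivarius / L. casei / L. rhamnosus)
LSAL1 = RepeatModel("Lsal1", "GTCTCAGGTAGATGTCGAATCAATCAGTTCAAGAGC")
#: Type I-E repeat family (found in L. casei / L. delbrueckii / others)
LDBU1 = RepeatModel("Ldbu1", "GTTTTCCCCGCACATGCGGGGGTGATCCC")


@dataclass
class CrisprArray:
    genome_id: str
    contig_id: str
    start: int  # 0-based half-open on the forward strand
    end: int
    strand: str
    repeat_starts: list[int]  # forward-strand coordinates, ascending
    repeat_mismatches: list[int]  # ordered leader-proximal first
    spacers: list[str]  # ordered leader-proximal first
    leader_flagged_ambiguous: bool = False

    def __post_init__(self) -> None:
        if len(self.spacers) != len(self.repeat_mismatches) - 1:
            raise ValueError("spacer count must be repeat count - 1")

    @property
    def n_repeats(self) -> int:
        return len(self.repeat_mismatches)


@dataclass(frozen=True)
class SpacerMatch:
    """A spacer's match (protospacer) in a target sequence with its
    7-nt flanks; flanks shorter than 7 (contig edge) are flagged."""

    spacer_id: str  # "<genome>:<contig>:<array-start>:<pos-from-leader>"
    target_id: str
    start: int
    end: int
    strand: str
    identity: float
    up7: str
    down7: str

    @property
    def truncated(self) -> bool:
        return len(self.up7) < 7 or len(self.down7) < 7


def _occurrences(contig: str, consensus: str, max_mismatch: int) -> list[tuple[int, int]]:
    """(start, mismatches) of all near-matches of consensus in contig."""
    L = len(consensus)
    n = len(contig)
    if n < L:
        return []
    arr = np.frombuffer(contig.upper().encode(), dtype=np.uint8)
    cons = np.frombuffer(consensus.upper().encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, L)
    mism = (windows != cons).sum(axis=1)
    hits = np.nonzero(mism <= max_mismatch)[0]
    return [(int(s), int(mism[s])) for s in hits]


def _chain(occ: list[tuple[int, int]], rep_len: int,
           spacer_len: range) -> list[list[tuple[int, int]]]:
    chains: list[list[tuple[int, int]]] = []
    cur: list[tuple[int, int]] = []
    for s, m in occ:
        if cur:
            gap = s - (cur[-1][0] + rep_len)
            if spacer_len.start <= gap <= spacer_len[-1]:
                cur.append((s, m))
                continue
            chains.append(cur)
        cur = [(s, m)]
    if cur:
        chains.append(cur)
    return chains


def find_arrays(
    contig: str,
    repeat_model: RepeatModel,
    *,
    genome_id: str = "genome",
    contig_id: str = "contig",
    spacer_len: range = range(20, 59),
    min_repeats: int = 3,
) -> list[CrisprArray]:
    """Detect repeat-anchored CRISPR arrays on both strands of a contig.

    Occurrences of the repeat consensus with at most ``max_mismatch``
    Hamming mismatches are chained into arrays whenever consecutive
    repeats are separated by a spacer-length gap; arrays need at least
    ``min_repeats`` repeats.  Spacers come out leader-proximal first: the
    leader is placed at the end opposite the most-mismatched terminal
    repeat, falling back (flagged) to the forward-strand left end when
    both terminal repeats are equally degenerate.
    """
    contig = contig.upper()
    results: list[CrisprArray] = []
    for strand in ("+", "-"):
        cons = (repeat_model.consensus if strand == "+"
                else reverse_complement(repeat_model.consensus))
        occ = _occurrences(contig, cons, repeat_model.max_mismatch)
        for chain in _chain(occ, len(cons), spacer_len):
            if len(chain) < min_repeats:
                continue
            starts = [s for s, _ in chain]
            mism = [m for _, m in chain]
            spacers = [
                contig[starts[i] + len(cons) : starts[i + 1]]
                for i in range(len(starts) - 1)
            ]
            a_start, a_end = starts[0], starts[-1] + len(cons)
            # canonical reading: along the strand the consensus matched
            arr_strand = strand
            if arr_strand == "-":
                spacers = [reverse_complement(s) for s in spacers][::-1]
                mism_o = mism[::-1]
            else:
                mism_o = list(mism)
            # leader sits opposite the degenerate (most mismatched) terminal
            # repeat; flipping the reading direction flips the strand
            ambiguous = False
            if mism_o[0] > mism_o[-1]:
                spacers = [reverse_complement(s) for s in spacers][::-1]
                mism_o = mism_o[::-1]
                arr_strand = "-" if arr_strand == "+" else "+"
            elif mism_o[0] == mism_o[-1] and len(set(mism_o)) > 1:
                ambiguous = True  # equally degenerate ends; keep reading order
            results.append(
                CrisprArray(
                    genome_id=genome_id,
                    contig_id=contig_id,
                    start=a_start,
                    end=a_end,
                    strand=arr_strand,
                    repeat_starts=starts,
                    repeat_mismatches=mism_o,
                    spacers=spacers,
                    leader_flagged_ambiguous=ambiguous,
                )
            )
    # deduplicate arrays found identically on both strands (palindromic edge)
    results.sort(key=lambda a: (a.start, a.end, a.strand))
    dedup: list[CrisprArray] = []
    for a in results:
        if dedup and dedup[-1].start == a.start and dedup[-1].end == a.end:
            continue
        dedup.append(a)
    return dedup


# ---------------------------------------------------------------------------
# Spacer comparison


def _canonical(seq: str) -> str:
    rc = reverse_complement(seq)
    return min(seq, rc)


def _spacers_equal(a: str, b: str, max_mismatch: int) -> bool:
    if len(a) != len(b):
        return False
    for cand in (b, reverse_complement(b)):
        if sum(x != y for x, y in zip(a, cand)) <= max_mismatch:
            return True
    return False


def spacer_sharing(
    arrays_by_strain: Mapping[str, Sequence[CrisprArray]],
    max_mismatch: int = 1,
) -> tuple["pd.DataFrame", list[dict]]:
    """Cross-strain spacer comparison.

    Unique spacers are equivalence classes under <= ``max_mismatch``
    mismatches (reverse-complement aware, equal length).  Returns
    (i) a strain x unique-spacer incidence DataFrame and (ii) maximal runs
    of contiguous shared spacers between strain pairs, with positions
    counted from the leader end (position 1 = leader-proximal).
    """
    import networkx as nx
    import pandas as pd

    # collect (strain, array index, position, sequence)
    entries: list[tuple[str, int, int, str]] = []
    for strain, arrays in arrays_by_strain.items():
        for ai, arr in enumerate(arrays):
            for pos, sp in enumerate(arr.spacers, start=1):
                entries.append((strain, ai, pos, sp.upper()))

    uniq = sorted({e[3] for e in entries}, key=lambda s: (_canonical(s), s))
    g = nx.Graph()
    g.add_nodes_from(uniq)
    for i, a in enumerate(uniq):
        for b in uniq[i + 1 :]:
            if _spacers_equal(a, b, max_mismatch):
                g.add_edge(a, b)
    rep: dict[str, str] = {}
    cls_id: dict[str, str] = {}
    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0]):
        label = f"S{len(cls_id):04d}"
        canon = sorted(comp)[0]
        for s in comp:
            rep[s] = canon
        cls_id[canon] = label

    strains = sorted(arrays_by_strain)
    classes = sorted(cls_id.values())
    inc = pd.DataFrame(0, index=strains, columns=classes, dtype=int)
    label_of = {seq: cls_id[rep[seq]] for seq in uniq}
    per_strain_seq: dict[str, dict[tuple[int, int], str]] = {s: {} for s in strains}
    for strain, ai, pos, sp in entries:
        inc.loc[strain, label_of[sp]] = 1
        per_strain_seq[strain][(ai, pos)] = label_of[sp]

    # maximal shared contiguous runs per strain pair and array pair
    runs: list[dict] = []
    for i, sa in enumerate(strains):
        for sb in strains[i + 1 :]:
            for ai, arr_a in enumerate(arrays_by_strain[sa]):
                la = [label_of[s.upper()] for s in arr_a.spacers]
                for bi, arr_b in enumerate(arrays_by_strain[sb]):
                    lb = [label_of[s.upper()] for s in arr_b.spacers]
                    runs.extend(
                        {
                            "strain_a": sa, "array_a": ai, "pos_a": pa + 1,
                            "strain_b": sb, "array_b": bi, "pos_b": pb + 1,
                            "length": ln,
                            "spacers": la[pa : pa + ln],
                        }
                        for pa, pb, ln in _maximal_runs(la, lb)
                    )
    return inc, runs


def _maximal_runs(a: list[str], b: list[str]) -> list[tuple[int, int, int]]:
    """Maximal common contiguous runs (start_a, start_b, length), length >= 1."""
    out = []
    for i in range(len(a)):
        for j in range(len(b)):
            if a[i] != b[j]:
                continue
            if i > 0 and j > 0 and a[i - 1] == b[j - 1]:
                continue  # not maximal: extendable left
            ln = 0
            while i + ln < len(a) and j + ln < len(b) and a[i + ln] == b[j + ln]:
                ln += 1
            out.append((i, j, ln))
    return out


# ---------------------------------------------------------------------------
# Protospacers and PAM


def find_protospacers(
    arrays: Iterable[CrisprArray],
    targets: Mapping[str, str],
    max_mismatch: int = 1,
) -> list[SpacerMatch]:
    """Locate spacer matches (protospacers) in target sequences and record
    the 7 nt immediately upstream/downstream of each match."""
    matches: list[SpacerMatch] = []
    for arr in arrays:
        for pos, spacer in enumerate(arr.spacers, start=1):
            sid = f"{arr.genome_id}:{arr.contig_id}:{arr.start}:{pos}"
            for tid, tseq in targets.items():
                tseq_u = tseq.upper()
                for strand in ("+", "-"):
                    probe = spacer if strand == "+" else reverse_complement(spacer)
                    for s, m in _occurrences(tseq_u, probe, max_mismatch):
                        e = s + len(probe)
                        up = tseq_u[max(0, s - 7) : s]
                        down = tseq_u[e : e + 7]
                        if strand == "-":
                            up, down = reverse_complement(down), reverse_complement(up)
                        matches.append(
                            SpacerMatch(
                                spacer_id=sid, target_id=tid, start=s, end=e,
                                strand=strand,
                                identity=100.0 * (len(probe) - m) / len(probe),
                                up7=up, down7=down,
                            )
                        )
    return matches


_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T", frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("CG"): "S", frozenset("AT"): "W", frozenset("GT"): "K",
    frozenset("AC"): "M", frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


def _consensus_base(counts: Counter, threshold: float) -> str:
    total = sum(counts.values())
    if total == 0:
        return "N"
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    chosen: set[str] = set()
    covered = 0
    for base, c in ranked:
        chosen.add(base)
        covered += c
        if covered / total >= threshold:
            break
    return _IUPAC[frozenset(chosen)]


def protospacer_flanks(
    matches: Sequence[SpacerMatch], threshold: float = 0.9
) -> dict:
    """Position-wise base counts and degenerate IUPAC consensus for the
    7-nt upstream and downstream protospacer flanks.

    Matches with truncated flanks are excluded (their count is reported);
    at least one full-flank match is required.  Consensus per position is
    the IUPAC code of the smallest base set covering ``threshold`` of the
    observations.
    """
    full = [m for m in matches if not m.truncated]
    if not full:
        raise ValueError("no matches with full 7-nt flanks")
    up_counts = [Counter() for _ in range(7)]
    down_counts = [Counter() for _ in range(7)]
    for m in full:
        for i, b in enumerate(m.up7):
            up_counts[i][b] += 1
        for i, b in enumerate(m.down7):
            down_counts[i][b] += 1
    return {
        "n_matches": len(full),
        "n_truncated_excluded": len(matches) - len(full),
        "up_counts": [dict(c) for c in up_counts],
        "down_counts": [dict(c) for c in down_counts],
        "up_consensus": "".join(_consensus_base(c, threshold) for c in up_counts),
        "down_consensus": "".join(_consensus_base(c, threshold) for c in down_counts),
    }
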
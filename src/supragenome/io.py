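"""Readers and writers for the plain-text formats the pipeline exchanges.

All coordinates are 0-based half-open internally; GFF-like feature tables
(1-based inclusive) are converted on read.  Every reader rejects malformed
records with an error naming the offending line — nothing is silently
skipped.
"""

from __future__ import annotations

import io as _io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd

__all__ = [
    "GeneFeature",
    "Genome",
    "PairHit",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_feature_table",
    "write_feature_table",
    "read_hits_tabular",
    "write_hits_tabular",
    "read_newick",
    "write_newick",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_json_report",
]


class ParseError(ValueError):
    """Malformed input; the message carries the file line number."""


@dataclass(frozen=True)
class GeneFeature:
    """A protein-coding feature on a contig.

    Coordinates are 0-based half-open.  ``feature_id`` is globally unique
    ("genomeid|locus" by convention).  Strand only flags orientation;
    ``start < end`` always.
    """

    feature_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein_seq: str = ""
    is_pseudo: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.feature_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id}: strand must be + or -")
        if not self.protein_seq and not self.is_pseudo:
            raise ValueError(
                f"feature {self.feature_id}: empty protein_seq on a non-pseudo feature"
            )


@dataclass
class Genome:
    """A genome: contig sequences plus per-contig, start-ordered features."""

    genome_id: str
    contigs: dict[str, str] = field(default_factory=dict)
    features: dict[str, list[GeneFeature]] = field(default_factory=dict)

    def validate(self) -> None:
        for contig_id, feats in self.features.items():
            seq = self.contigs.get(contig_id)
            prev_start = -1
            for f in feats:
                if f.contig_id != contig_id:
                    raise ValueError(
                        f"{self.genome_id}: feature {f.feature_id} filed under "
                        f"contig {contig_id} but claims {f.contig_id}"
                    )
                if seq is not None and f.end > len(seq):
                    raise ValueError(
                        f"{self.genome_id}: feature {f.feature_id} end {f.end} "
                        f"exceeds contig length {len(seq)}"
                    )
                if f.start <= prev_start:
                    raise ValueError(
                        f"{self.genome_id}: features on {contig_id} not strictly "
                        f"increasing by start at {f.feature_id}"
                    )
                prev_start = f.start

    def all_features(self) -> list[GeneFeature]:
        return [f for feats in self.features.values() for f in feats]


@dataclass(frozen=True)
class PairHit:
    """One row of an all-vs-all similarity search (BLAST outfmt-6 dialect)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    q_len: int
    s_len: int
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError("negative evalue")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an order-preserving id -> sequence map.

    Sequences are uppercased; duplicate ids and headerless sequence lines
    are rejected with the offending line number.
    """
    path = Path(path)
    records: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if current is not None:
                    records[current] = "".join(chunks).upper()
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                seq_id = header.split()[0]
                if seq_id in records:
                    raise ParseError(f"{path}:{lineno}: duplicate FASTA id {seq_id!r}")
                current = seq_id
                chunks = []
            else:
                if current is None:
                    raise ParseError(f"{path}:{lineno}: sequence before first header")
                if not re.fullmatch(r"[A-Za-z*.\-]+", line.strip()):
                    raise ParseError(f"{path}:{lineno}: non-sequence characters")
                chunks.append(line.strip())
        if current is not None:
            records[current] = "".join(chunks).upper()
        if not records:
            raise ParseError(f"{path}:{lineno or 0}: empty FASTA file")
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in records.items():
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF-like feature tables

_GFF_COLS = 9


def read_feature_table(path: str | Path, genome_id: str,
                       proteins: Mapping[str, str] | None = None) -> list[GeneFeature]:
    """Read a GFF3-like TSV of gene features.

    Columns: seqid, source, type, start, end, score, strand, frame,
    attributes (must carry ``ID=``; ``pseudo=true`` flags pseudogenes).
    Input coordinates are 1-based inclusive and converted to 0-based
    half-open.  ``proteins`` supplies translations keyed by feature id.
    """
    path = Path(path)
    feats: list[GeneFeature] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLS:
                raise ParseError(
                    f"{path}:{lineno}: expected {_GFF_COLS} columns, got {len(cols)}"
                )
            seqid, _src, _type, start_s, end_s, _score, strand, _frame, attrs = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if "ID" not in attr_map:
                raise ParseError(f"{path}:{lineno}: attributes lack ID=")
            fid = attr_map["ID"]
            if fid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate feature ID {fid!r}")
            seen.add(fid)
            is_pseudo = attr_map.get("pseudo", "false").lower() == "true"
            seq = (proteins or {}).get(fid, "")
            feats.append(
                GeneFeature(
                    feature_id=fid,
                    genome_id=genome_id,
                    contig_id=seqid,
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    protein_seq=seq,
                    is_pseudo=is_pseudo or not seq,
                )
            )
    return feats


def write_feature_table(features: Iterable[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            attrs = f"ID={f.feature_id}"
            if f.is_pseudo:
                attrs += ";pseudo=true"
            fh.write(
                "\t".join(
                    [f.contig_id, "supragenome", "CDS", str(f.start + 1), str(f.end),
                     ".", f.strand, "0", attrs]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)

_HITS_COLS = 12


def read_hits_tabular(path: str | Path,
                      seq_lengths: Mapping[str, int] | None = None) -> list[PairHit]:
    """Read 12-column BLAST tabular hits.

    ``seq_lengths`` (id -> residues) fills ``q_len``/``s_len``; when absent
    the alignment span on each sequence is used as a lower bound.
    """
    path = Path(path)
    hits: list[PairHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _HITS_COLS:
                raise ParseError(
                    f"{path}:{lineno}: expected {_HITS_COLS} columns, got {len(cols)}"
                )
            (q, s, pid, alen, _mm, _go, qs, qe, ss, se, ev, bits) = cols
            try:
                q_span = abs(int(qe) - int(qs)) + 1
                s_span = abs(int(se) - int(ss)) + 1
                hit = PairHit(
                    query_id=q,
                    subject_id=s,
                    pct_identity=float(pid),
                    aln_len=int(alen),
                    q_len=(seq_lengths or {}).get(q, q_span),
                    s_len=(seq_lengths or {}).get(s, s_span),
                    bitscore=float(bits),
                    evalue=float(ev),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_hits_tabular(hits: Iterable[PairHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [h.query_id, h.subject_id, f"{h.pct_identity:.1f}",
                     str(h.aln_len), "0", "0", "1", str(h.aln_len),
                     "1", str(h.aln_len), f"{h.evalue:.2g}", f"{h.bitscore:.1f}"]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)


def read_newick(source: str | Path) -> dendropy.Tree:
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    return dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialize a tree as Newick with branch lengths; every leaf must be labeled."""
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("unlabeled leaf in tree")
    text = tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()
    if not text.endswith(";"):
        text += ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# TSV matrices and JSON reports


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ParseError(f"{path}: matrix has no data columns")
    return df


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-dimensional")
    matrix.to_csv(path, sep="\t")


def write_json_report(report: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
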
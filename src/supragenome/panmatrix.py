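"""Presence/absence matrix of ortholog clusters across strains, per-strain
accounting (total / core / distributed / unique) and the gene-frequency
spectrum that feeds the mixture model.

"Distributed" counts every non-core cluster a strain carries, unique
clusters included, so that total = core + distributed row by row.
Percentages are rounded half-away-from-zero to the nearest integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .orthology import ClusterSet

__all__ = [
    "PanMatrix",
    "StrainAccounting",
    "SpectrumCounts",
    "build_matrix",
    "strain_accounting",
    "accounting_table",
    "spectrum",
    "summary_stats",
]


@dataclass
class PanMatrix:
    """Binary cluster-by-genome presence matrix (pandas-backed)."""

    df: pd.DataFrame  # index: cluster ids, columns: genome ids, values 0/1
    copy_counts: pd.DataFrame | None = None  # same shape, member multiplicity

    def __post_init__(self) -> None:
        vals = self.df.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("pan-matrix cells must be 0/1")
        if (vals.sum(axis=1) == 0).any():
            raise ValueError("pan-matrix contains an all-zero row")
        if self.df.shape[1] < 1:
            raise ValueError("need at least one genome")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def n_genomes(self) -> int:
        return self.df.shape[1]


@dataclass(frozen=True)
class StrainAccounting:
    genome_id: str
    total: int
    core: int
    distributed: int
    unique: int
    pct_noncore: int
    pct_unique: int


@dataclass(frozen=True)
class SpectrumCounts:
    """y[j-1] = number of clusters present in exactly j of G genomes."""

    G: int
    y: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.y) != self.G:
            raise ValueError("spectrum length must equal genome count")
        if any(v < 0 for v in self.y):
            raise ValueError("negative spectrum count")

    @property
    def n_obs(self) -> int:
        return int(sum(self.y))

    @property
    def core(self) -> int:
        return int(self.y[-1])


def build_matrix(clusters: ClusterSet, genome_ids: Sequence[str],
                 genome_of: Mapping[str, str] | None = None,
                 include_orphans: bool = True) -> PanMatrix:
    """One row per cluster; cell 1 iff the cluster holds >= 1 feature of
    that genome.  Orphan features become singleton rows when
    ``include_orphans``.  Row order: cluster id; column order: input order.
    """
    genome_ids = list(genome_ids)
    known = set(genome_ids)

    def gid(fid: str) -> str:
        g = genome_of[fid] if genome_of is not None else fid.split("|")[0]
        if g not in known:
            raise ValueError(f"feature {fid!r} maps to unknown genome {g!r}")
        return g

    entries = dict(clusters.clusters)
    if include_orphans:
        for i, f in enumerate(sorted(clusters.orphans)):
            entries[f"orphan{i:05d}"] = {f}

    rows = sorted(entries)
    counts = pd.DataFrame(0, index=rows, columns=genome_ids, dtype=int)
    for cid in rows:
        for fid in entries[cid]:
            counts.loc[cid, gid(fid)] += 1
    return PanMatrix(df=(counts > 0).astype(int), copy_counts=counts)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def strain_accounting(matrix: PanMatrix, genome_id: str) -> StrainAccounting:
    if genome_id not in matrix.df.columns:
        raise ValueError(f"unknown genome {genome_id!r}")
    present = matrix.df[genome_id].to_numpy() == 1
    row_sums = matrix.df.to_numpy().sum(axis=1)
    G = matrix.n_genomes
    total = int(present.sum())
    core = int((present & (row_sums == G)).sum())
    unique = int((present & (row_sums == 1)).sum())
    distributed = total - core
    return StrainAccounting(
        genome_id=genome_id,
        total=total,
        core=core,
        distributed=distributed,
        unique=unique,
        pct_noncore=_round_half_away(100.0 * distributed / total) if total else 0,
        pct_unique=_round_half_away(100.0 * unique / total) if total else 0,
    )


def accounting_table(matrix: PanMatrix) -> pd.DataFrame:
    """Per-strain accounting for every genome, one row per strain."""
    recs = [strain_accounting(matrix, g) for g in matrix.genome_ids]
    df = pd.DataFrame([r.__dict__ for r in recs]).set_index("genome_id")
    return df


def spectrum(matrix: PanMatrix) -> SpectrumCounts:
    G = matrix.n_genomes
    row_sums = matrix.df.to_numpy().sum(axis=1)
    y = np.bincount(row_sums, minlength=G + 1)[1 : G + 1]
    return SpectrumCounts(G=G, y=tuple(int(v) for v in y))


def summary_stats(matrix: PanMatrix | None = None,
                  totals: Sequence[int] | None = None,
                  uniques: Sequence[int] | None = None,
                  spec: SpectrumCounts | None = None) -> dict:
    """Summary of per-strain totals and unique counts plus observed core/pan.

    Either pass a ``PanMatrix`` or supply printed per-strain ``totals`` /
    ``uniques`` columns directly (core/pan then require ``spec`` or are
    omitted).  Standard deviation uses the n-1 denominator.
    """
    if matrix is not None:
        table = accounting_table(matrix)
        totals = table["total"].tolist()
        uniques = table["unique"].tolist()
        spec = spectrum(matrix)
    if totals is None or uniques is None:
        raise ValueError("need a matrix or explicit totals/uniques")
    totals_a = np.asarray(totals, dtype=float)
    uniques_a = np.asarray(uniques, dtype=float)
    out = {
        "mean_total": float(totals_a.mean()),
        "sd_total": float(totals_a.std(ddof=1)) if len(totals_a) > 1 else 0.0,
        "mean_unique": float(uniques_a.mean()),
        "unique_min": int(uniques_a.min()),
        "unique_max": int(uniques_a.max()),
    }
    if spec is not None:
        out["core"] = spec.core
        out["pan"] = spec.n_obs
    return out
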
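"""Core- and pan-genome accumulation (collector's) curves.

For each random ordering of the genomes and each prefix length g, pan(g)
counts clusters present in at least one of the first g genomes and core(g)
those present in all of them.  Means and sample standard deviations are
taken over orderings; when the number of genomes is small enough that all
G! orderings fit within the requested number of permutations, they are
enumerated exactly instead of sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .panmatrix import PanMatrix

__all__ = ["RarefactionResult", "rarefy"]


@dataclass
class RarefactionResult:
    G: int
    n_perm: int
    exhaustive: bool
    seed: int | None
    pan_mean: np.ndarray
    pan_sd: np.ndarray
    core_mean: np.ndarray
    core_sd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "g": np.arange(1, self.G + 1),
                "pan_mean": self.pan_mean,
                "pan_sd": self.pan_sd,
                "core_mean": self.core_mean,
                "core_sd": self.core_sd,
            }
        ).set_index("g")


def _curves_for_order(X: np.ndarray, order: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pan/core counts along one genome ordering (clusters x genomes 0/1)."""
    sub = X[:, order]
    any_cum = np.maximum.accumulate(sub, axis=1)
    all_cum = np.minimum.accumulate(sub, axis=1)
    return any_cum.sum(axis=0), all_cum.sum(axis=0)


def rarefy(matrix: PanMatrix, n_perm: int = 500,
           seed: int | None = None) -> RarefactionResult:
    """Accumulation curves over ``n_perm`` random genome orderings.

    Exhaustive enumeration replaces sampling when G! <= n_perm.  Endpoint
    values (g = G) are ordering-free: pan(G) is the observed pan size and
    core(G) the observed core size, with zero spread.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = matrix.df.to_numpy()
    if X.size == 0:
        raise ValueError("empty matrix")
    G = X.shape[1]

    if math.factorial(G) <= n_perm:
        orders = [np.array(p) for p in permutations(range(G))]
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(G) for _ in range(n_perm)]
        exhaustive = False

    pans = np.empty((len(orders), G))
    cores = np.empty((len(orders), G))
    for i, order in enumerate(orders):
        pans[i], cores[i] = _curves_for_order(X, order)

    ddof = 1 if len(orders) > 1 else 0
    return RarefactionResult(
        G=G,
        n_perm=len(orders),
        exhaustive=exhaustive,
        seed=seed,
        pan_mean=pans.mean(axis=0),
        pan_sd=pans.std(axis=0, ddof=ddof),
        core_mean=cores.mean(axis=0),
        core_sd=cores.std(axis=0, ddof=ddof),
    )
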
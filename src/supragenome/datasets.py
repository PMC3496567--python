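"""Published per-strain cluster counts for the 17-strain L. casei panel.

These printed values are inputs for desk-scale accounting checks: the
observed core (1,715) and pan (5,935) sizes, and the per-strain Total /
Distributed / Unique columns.  The mixture-model extrapolation of the
same study (pan 9,072, core 1,600) is reproducible only from the genome
sequences themselves; here it serves as a scale reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panmatrix import PanMatrix

__all__ = [
    "CORE_CLUSTERS",
    "PAN_CLUSTERS",
    "ACCESSORY_CLUSTERS",
    "EXTRAPOLATED_PAN",
    "EXTRAPOLATED_CORE",
    "SUBSTITUTION_RATE",
    "strain_cluster_table",
    "matrix_from_counts",
]

CORE_CLUSTERS = 1715
PAN_CLUSTERS = 5935
ACCESSORY_CLUSTERS = 4220
EXTRAPOLATED_PAN = 9072
EXTRAPOLATED_CORE = 1600
SUBSTITUTION_RATE = 4.7e-9  # substitutions / site / year (E. coli vs S. enterica)

# strain: (total clusters, distributed, unique, % non-core, % unique)
_STRAIN_COUNTS = {
    "ATCC 334": (2511, 796, 54, 32, 2),
    "M36": (2918, 1203, 91, 41, 3),
    "UW1": (2700, 985, 203, 36, 8),
    "UW4": (2593, 878, 187, 34, 7),
    "Zhang": (2649, 934, 49, 35, 2),
    "BD-II": (2936, 1221, 19, 42, 1),
    "BL23": (2866, 1151, 54, 40, 2),
    "LC2W": (2893, 1178, 29, 41, 1),
    "Lc-10": (2715, 1000, 104, 37, 4),
    "Lpc-37": (2799, 1084, 37, 39, 1),
    "12A": (2651, 936, 47, 35, 2),
    "21/1": (2958, 1243, 183, 42, 6),
    "32G": (2821, 1106, 174, 39, 6),
    "A2-362": (3108, 1393, 326, 45, 10),
    "UCD174": (2879, 1164, 240, 40, 8),
    "T71499": (2745, 1030, 85, 38, 3),
    "CRF28": (2851, 1136, 148, 40, 5),
}


def strain_cluster_table() -> pd.DataFrame:
    """Per-strain published cluster counts (17 strains)."""
    df = pd.DataFrame.from_dict(
        _STRAIN_COUNTS, orient="index",
        columns=["total", "distributed", "unique", "pct_noncore", "pct_unique"],
    )
    df.index.name = "strain"
    df["core"] = CORE_CLUSTERS
    return df


def matrix_from_counts(total: int, core: int, unique: int, G: int = 17,
                       focal: str = "focal") -> PanMatrix:
    """Construct a minimal presence/absence matrix whose focal-strain
    accounting realizes the given (total, core, unique) counts.

    Core rows are present everywhere; unique rows only in the focal
    strain; the remaining focal rows in the focal strain plus one other.
    Useful for checking row arithmetic against published per-strain counts.
    """
    if not (core + unique <= total):
        raise ValueError("core + unique may not exceed total")
    if G < 2:
        raise ValueError("need G >= 2")
    other = total - core - unique
    genome_ids = [focal] + [f"other{i:02d}" for i in range(1, G)]
    rows = []
    idx = []
    for i in range(core):
        rows.append([1] * G)
        idx.append(f"core{i:05d}")
    for i in range(unique):
        rows.append([1] + [0] * (G - 1))
        idx.append(f"uniq{i:05d}")
    for i in range(other):
        r = [1] + [0] * (G - 1)
        r[1 + (i % (G - 1))] = 1
        rows.append(r)
        idx.append(f"dist{i:05d}")
    df = pd.DataFrame(np.array(rows, dtype=int), index=idx, columns=genome_ids)
    return PanMatrix(df=df)
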
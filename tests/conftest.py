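import numpy as np
import pandas as pd
import pytest

import supragenome as sg
from supragenome.panmatrix import PanMatrix


@pytest.fixture
def toy_matrix():
    """3 clusters x 2 genomes: one shared, one private each."""
    df = pd.DataFrame(
        [[1, 1], [1, 0], [0, 1]],
        index=["c0", "c1", "c2"], columns=["gA", "gB"],
    )
    return PanMatrix(df=df)


@pytest.fixture(scope="session")
def synthetic_pipeline():
    """4 genomes x 50 families at 2% divergence, aligned all-vs-all.

    Session-scoped: the built-in aligner pass is the expensive step and
    several orthology/panmatrix tests share it.
    """
    cfg = sg.simulate.SynthPanConfig(
        G=4, pan_size=50, K=1, pi=(1.0,), rho=(0.8,), seed=1
    )
    matrix, pan_truth = sg.simulate.simulate_pangenome(cfg)
    seq_cfg = sg.simulate.SynthSeqConfig(mean_gene_len=80, divergence=0.02, seed=1)
    genomes, proteins, fam_of, meta = sg.simulate.simulate_genomes(matrix, seq_cfg)
    hits = sg.align.all_vs_all_hits(proteins)
    return {
        "matrix": matrix,
        "pan_truth": pan_truth,
        "genomes": genomes,
        "proteins": proteins,
        "fam_of": fam_of,
        "hits": hits,
        "genome_of": {fid: fid.split("|")[0] for fid in proteins},
    }
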
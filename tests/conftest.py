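import numpy as np
import pandas as pd
import pytest

from mecp2core import core, io, simulate


def make_contrast(contrast_id, rows):
    """rows: list of (gene, log2fc, fdr); pvalue mirrors fdr."""
    df = pd.DataFrame(rows, columns=["gene", "log2fc", "fdr"])
    df["pvalue"] = df["fdr"]
    return io.ContrastTable(contrast_id=contrast_id, data=df)


@pytest.fixture(scope="session")
def six_gene_fixture():
    """6 genes x 10 contrasts with hand-enumerable support counts.

    gA: up (lfc +0.8) and significant in contrasts 1-8  -> support 8
    gB: down (lfc -0.7) and significant in contrasts 1-8 -> support 8
    gC: significant in contrasts 1-3 -> support 3
    gD: significant in contrasts 1-2 -> support 2
    gE: significant in contrast 1 -> support 1
    gF: significant in contrast 2 -> support 1
    """
    support_plan = {
        "gA": (0.8, range(1, 9)),
        "gB": (-0.7, range(1, 9)),
        "gC": (0.5, range(1, 4)),
        "gD": (-0.4, range(1, 3)),
        "gE": (0.3, [1]),
        "gF": (0.6, [2]),
    }
    tables = []
    for c in range(1, 11):
        rows = []
        for gene, (lfc, sig_in) in support_plan.items():
            sig = c in set(sig_in)
            rows.append((gene, lfc if sig else 0.01, 0.005 if sig else 0.5))
        tables.append(make_contrast(f"C{c:02d}", rows))
    return tables


@pytest.fixture(scope="session")
def default_multi_contrast():
    tables, meta, truth = simulate.generate_multi_contrast(seed=20240901)
    return tables, meta, truth


@pytest.fixture(scope="session")
def default_counts():
    cm, truth = simulate.generate_counts(seed=20240902)
    return cm, truth


@pytest.fixture
def consensus_cfg():
    return core.ConsensusConfig(alpha=0.01, min_contrasts=4)
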
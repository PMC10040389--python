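import warnings

import numpy as np
import pandas as pd
import pytest

from mcdmkit import synthetic as syn

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def pathway_db_truth():
    return syn.generate_pathway_db(seed=11)


@pytest.fixture(scope="session")
def scenario():
    return syn.inflammation_scenario(seed=42)


@pytest.fixture(scope="session")
def expression():
    return syn.generate_expression(
        ["A", "B", "C", "D"], n_cells_per_type=60, n_genes=150, separation=2.0, seed=5
    )


def deg_table(genes_signs, dataset="d1", fdr=0.01):
    """Hand-built DEG table: {gene: logFC}."""
    genes = sorted(genes_signs)
    return pd.DataFrame(
        {
            "gene": genes,
            "logFC": [float(genes_signs[g]) for g in genes],
            "pvalue": fdr / 2,
            "fdr": fdr,
            "dataset": dataset,
        }
    )


def hypergeom_tail_oracle(k, n_bg, n_target, n_query):
    """Right tail P(X >= k) by explicit summation of hypergeometric terms."""
    from math import comb

    denom = comb(n_bg, n_query)
    total = 0
    for x in range(k, min(n_query, n_target) + 1):
        if n_query - x > n_bg - n_target:
            continue
        total += comb(n_target, x) * comb(n_bg - n_target, n_query - x)
    return total / denom


def pav_oracle(y):
    """Pool-adjacent-violators for a non-decreasing least-squares fit."""
    y = [float(v) for v in y]
    blocks = [[v, 1.0] for v in y]  # (mean, weight)
    out = []
    for mean, w in blocks:
        out.append([mean, w])
        while len(out) > 1 and out[-2][0] > out[-1][0] - 1e-15:
            m2, w2 = out.pop()
            m1, w1 = out.pop()
            out.append([(m1 * w1 + m2 * w2) / (w1 + w2), w1 + w2])
    fitted = []
    for mean, w in out:
        fitted.extend([mean] * int(round(w)))
    return np.array(fitted)
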
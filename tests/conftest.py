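import numpy as np
import pandas as pd
import pytest

import trmex


@pytest.fixture(scope="session")
def cells_and_truth():
    """Moderate synthetic single-cell dataset with planted subset DE."""
    return trmex.simulate_cells(
        n_donors=3,
        n_cells_per_donor=240,
        subsets=("TRM", "TEX", "TEM", "TN"),
        n_genes=500,
        effect_log2fc=1.0,
        dispersion=0.3,
        seed=42,
        n_tissues=2,
        n_de_per_subset=15,
        n_control_genes=60,
    )


@pytest.fixture(scope="session")
def pseudobulk_set(cells_and_truth):
    cells, _ = cells_and_truth
    pb = trmex.aggregate_pseudobulk(cells, group_by=("donor", "tissue", "subset"))
    return trmex.filter_genes(pb)


@pytest.fixture(scope="session")
def repertoire():
    """Repertoire with 10% planted viral clones (half exact, half 1-mutant)."""
    return trmex.simulate_repertoire(
        {"TRM": 300, "TEX": 300, "TEM": 150},
        viral_fraction=0.1,
        seed=7,
    )


def brute_levenshtein(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance (test oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@pytest.fixture(scope="session")
def levenshtein_oracle():
    return brute_levenshtein
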
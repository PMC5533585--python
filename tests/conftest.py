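import numpy as np
import pandas as pd
import pytest

from bioidpipe.quant import CountMatrix, empty_shared


@pytest.fixture
def simple_counts():
    """Two proteins, one shared peptide, one replicate: A uSpC 6 / B uSpC 2,
    shared peptide with 4 spectra."""
    return CountMatrix(
        unique=pd.DataFrame({"rep1": [6, 2]}, index=["A", "B"]),
        shared=pd.DataFrame({"parents": [("A", "B")], "rep1": [4]}, index=["sp1"]),
        lengths=pd.Series([100, 100], index=["A", "B"]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20257)


def random_count_matrix(rng, n_proteins=20, n_shared=50, n_replicates=2):
    """A randomized CountMatrix with shared-peptide structure for oracle
    comparisons: uniform counts, random 2-4 parent sets, random lengths."""
    ids = [f"P{i:03d}" for i in range(n_proteins)]
    reps = [f"rep{i+1}" for i in range(n_replicates)]
    unique = pd.DataFrame(
        rng.integers(0, 30, size=(n_proteins, n_replicates)), index=ids, columns=reps
    )
    rows = {"parents": []}
    for rep in reps:
        rows[rep] = []
    for j in range(n_shared):
        k = int(rng.integers(2, 5))
        parents = tuple(rng.choice(ids, size=k, replace=False))
        rows["parents"].append(parents)
        for rep in reps:
            rows[rep].append(int(rng.integers(0, 12)))
    shared = pd.DataFrame(rows, index=[f"sh{j:03d}" for j in range(n_shared)])
    lengths = pd.Series(rng.integers(50, 2000, size=n_proteins), index=ids)
    return CountMatrix(unique=unique, shared=shared, lengths=lengths)
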
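import numpy as np
import pandas as pd
import pytest

from divscan import genio


def make_table(dosages, chrom=None, bp=None, lines=None, sexes=None):
    """Small GenotypeTable from a plain dosage array (NaN = missing)."""
    dosages = np.asarray(dosages, dtype=float)
    n, L = dosages.shape
    chrom = ["1"] * L if chrom is None else list(map(str, chrom))
    bp = list(range(10_000, 10_000 * (L + 1), 10_000)) if bp is None else bp
    snp_map = pd.DataFrame({
        "snp": [f"snp{j + 1}" for j in range(L)],
        "chrom": chrom, "bp": bp, "a1": "A", "a2": "B",
    })
    individuals = pd.DataFrame({
        "id": [f"ind{i + 1}" for i in range(n)],
        "line": lines if lines is not None else ["L"] * n,
        "generation": 0,
        "sex": sexes if sexes is not None else [1] * n,
        "hatch": "h1",
    })
    return genio.GenotypeTable(dosages, snp_map, individuals)


@pytest.fixture
def toy_table():
    return make_table([[0, 1], [1, 2], [2, 0]])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
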
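import numpy as np
import pandas as pd
import pytest

from gsel.simdata import simulate_dataset
from gsel.types import GenotypeMatrix


def make_snp_map(m, chrom="chr1", start=100, step=100):
    return pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": np.arange(start, start + m * step, step),
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )


def make_genotypes(dosages, chrom="chr1"):
    dosages = np.asarray(dosages, dtype=float)
    return GenotypeMatrix(dosages=dosages, snp_map=make_snp_map(dosages.shape[1], chrom))


@pytest.fixture(scope="session")
def small_population():
    """Shared small simulated dataset (no missingness) for model tests."""
    return simulate_dataset(
        n_founders=80,
        n_offspring=250,
        m=400,
        n_chrom=4,
        n_qtl=40,
        h2_target=0.4,
        missing_rate=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
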
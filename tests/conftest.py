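import numpy as np
import pandas as pd
import pytest

from nucleostates import SyntheticConfig


@pytest.fixture(scope="session")
def config() -> SyntheticConfig:
    return SyntheticConfig()


@pytest.fixture(scope="session")
def small_map(config):
    """A small default-priors map with reads and marks, shared across tests."""
    from nucleostates import generate_nucleosome_map

    return generate_nucleosome_map(config, "Veh", n_regions=80, seed=101)


def make_genes(rows) -> pd.DataFrame:
    """rows: (gene, chrom, strand, tss, tes)"""
    return pd.DataFrame(rows, columns=["gene", "chrom", "strand",
                                       "tss", "tes"])


def midpoint_frame(positions, chrom="chr1") -> pd.DataFrame:
    pos = np.sort(np.asarray(positions, dtype=np.int64))
    return pd.DataFrame({"chrom": chrom, "pos": pos})
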
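import numpy as np
import pandas as pd
import pytest

from chromlink import simulate


@pytest.fixture(scope="session")
def dataset():
    """Default-condition synthetic dataset shared across tests."""
    return simulate.generate_dataset(simulate.SimulationSpec(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A 50-gene instance for brute-force oracle comparisons."""
    return simulate.generate_dataset(
        simulate.SimulationSpec(
            seed=3,
            n_genes=50,
            n_chrom=2,
            chrom_length=8_000_000,
            n_background_windows=200,
            n_background_meth=100,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def expr_from_linear(rows: dict[str, tuple]) -> pd.DataFrame:
    """Expression table from linear-scale triples (stored as log2)."""
    recs = []
    for gid, (a, b, c) in rows.items():
        recs.append(
            {
                "gene_id": gid,
                "GE_ect": np.log2(a) if a > 0 else -np.inf,
                "GE_end": np.log2(b) if b > 0 else -np.inf,
                "GE_mes": np.log2(c) if c > 0 else -np.inf,
            }
        )
    return pd.DataFrame(recs)
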
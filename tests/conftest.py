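import numpy as np
import pandas as pd
import pytest

from hetblup import (
    DosageMatrix,
    SampleMetadata,
    SimConfig,
    compute_G,
    compute_pcs,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small mixture-effect dataset shared across read-only tests."""
    return simulate_dataset(
        SimConfig(n=120, m=400, seed=11, effect_model="mixture", rho_true=0.5)
    )


@pytest.fixture(scope="session")
def small_structure(small_sim):
    """G, allele frequencies and PCs for the shared dataset."""
    G, freqs = compute_G(small_sim.X)
    P = compute_pcs(G, d=4)
    return G, freqs, P


@pytest.fixture()
def toy_dosages():
    """Hand-sized dosage matrix with one missing entry and positions."""
    values = np.array(
        [
            [0.0, 1.0, 2.0, 0.0],
            [0.0, 1.0, 0.0, 1.0],
            [2.0, 1.0, 0.0, np.nan],
            [0.0, 1.0, 2.0, 1.0],
        ]
    )
    marker_ids = [f"m{j}" for j in range(4)]
    return DosageMatrix(
        values=values,
        individual_ids=[f"i{k}" for k in range(4)],
        marker_ids=marker_ids,
        positions={m: ("chr1", j + 1) for j, m in enumerate(marker_ids)},
    )


@pytest.fixture()
def toy_metadata():
    ids = [f"i{k}" for k in range(4)]
    return SampleMetadata(
        population=pd.Series(["A", "A", "B", "B"], index=ids),
        panel=pd.Series(["AP", "AP", "BP", "BP"], index=ids),
    )
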
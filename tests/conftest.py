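import numpy as np
import pandas as pd
import pytest

from landgen import GenotypeMatrix, SimConfig, simulate_landscape, simulate_populations


@pytest.fixture
def toy_gm() -> GenotypeMatrix:
    """3 populations x 4 individuals x 6 loci with scattered missing calls."""
    M = -1
    calls = np.array(
        [
            # popA
            [0, 0, 1, 0, M, 0],
            [0, 1, 1, 0, 0, 0],
            [0, 0, 0, M, 0, 0],
            [0, 1, 0, 0, 0, 0],
            # popB
            [1, 1, 1, 1, 1, 0],
            [1, 1, 0, 1, M, 0],
            [1, 0, 1, 1, 1, 0],
            [M, 1, 1, 1, 1, 0],
            # popC
            [0, 0, 0, 1, 1, 0],
            [1, 0, 0, 1, 1, 0],
            [0, 0, M, 1, 1, 0],
            [0, 0, 0, M, 1, 0],
        ],
        dtype=np.int16,
    )
    inds = [f"i{k}" for k in range(12)]
    pops = np.array(["popA"] * 4 + ["popB"] * 4 + ["popC"] * 4, dtype=object)
    loci = [f"L{k}" for k in range(6)]
    return GenotypeMatrix(inds, pops, loci, calls)


@pytest.fixture(scope="session")
def small_sim():
    """Shared 60-population synthetic landscape + population table."""
    cfg = SimConfig(seed=42, n_populations=60, ncols=20, nrows=18)
    land = simulate_landscape(cfg)
    pops, truth = simulate_populations(land, cfg)
    return cfg, land, pops, truth


@pytest.fixture
def pair_table(small_sim):
    """Pairwise MLPE table from the shared simulation (ibd predictor only)."""
    from scipy.spatial.distance import cdist

    from landgen import simulate_pairwise

    cfg, _, pops, _ = small_sim
    coords = pops[["x", "y"]].to_numpy(float)
    geo = pd.DataFrame(cdist(coords, coords), index=pops["id"], columns=pops["id"])
    table, truth = simulate_pairwise(pops, {"ibd": geo}, cfg)
    return table, truth
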
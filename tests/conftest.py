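import numpy as np
import pandas as pd
import pytest

import settleflow as sf


@pytest.fixture
def toy_settlements() -> sf.SettlementTable:
    """Three settlements on a 3-4-5-friendly planar layout with two waves."""
    df = pd.DataFrame(
        {
            "id": ["A", "B", "C"],
            "name": ["A", "B", "C"],
            "x": [0.0, 10.0, 10.0],
            "y": [0.0, 0.0, 20.0],
            "region": ["R1", "R1", "R2"],
            "pop_t0": [100, 200, 400],
            "pop_t1": [90, 220, 425],
        }
    )
    return sf.SettlementTable(df, crs="planar_km")


@pytest.fixture(scope="session")
def noiseless_world() -> sf.SyntheticWorld:
    """Small noise-free gravity world with on-grid truth (power, beta=1, gamma=1.5)."""
    cfg = sf.SyntheticConfig(n_settlements=60, seed=11, poisson=False)
    return sf.generate_world(cfg)


@pytest.fixture(scope="session")
def poisson_world() -> sf.SyntheticWorld:
    """Default-condition world with Poisson flow noise."""
    cfg = sf.SyntheticConfig(seed=5, poisson=True)
    return sf.generate_world(cfg)


def naive_gravity(pops: np.ndarray, dist: np.ndarray, family: str, beta: float,
                  gamma: float, k: float) -> np.ndarray:
    """Double-loop gravity evaluation used as an independent oracle."""
    n = len(pops)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if family == "power":
                f = dist[i, j] ** -beta
            else:
                f = np.exp(-beta * dist[i, j])
            out[i, j] = k * pops[i] * pops[j] ** gamma * f
    return out
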
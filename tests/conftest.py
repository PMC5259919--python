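from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from shoremeth import simulate as sim


@pytest.fixture(scope="session")
def default_dataset() -> sim.SimulatedDataset:
    """The default synthetic study (10/10/10 samples, planted shore effect)."""
    return sim.generate(sim.SimConfig(seed=42))


@pytest.fixture(scope="session")
def small_config() -> sim.SimConfig:
    """A reduced study for fast end-to-end runs."""
    return sim.SimConfig(
        seed=7,
        n_chroms=2,
        chrom_len=60_000,
        n_islands=10,
        n_genes=6,
        n_coupled_genes=4,
        n_affected_shore_bins=40,
        n_cpg_sites=600,
        n_specific_per_subtype=5,
        n_bs_regions=5,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> sim.SimulatedDataset:
    return sim.generate(small_config)


@pytest.fixture()
def sheet_30() -> pd.DataFrame:
    return sim.sample_sheet(sim.SimConfig())


def make_sheet(n_per: int = 10) -> pd.DataFrame:
    rows = []
    for st, pre in (("luminal", "Lu"), ("basalA", "BaA"), ("basalB", "BaB")):
        for i in range(n_per):
            rows.append({"sample": f"{pre}{i + 1:02d}", "subtype": st})
    return pd.DataFrame(rows)


def clamp01(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)
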
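import numpy as np
import pytest

from csfnet.model import AbundanceMatrix, SampleInfo
from csfnet.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def two_block_matrix():
    """Noise-free-ish 2-block matrix: blocks of 20 proteins, within r ~0.8,
    cross-block r ~0, 50 samples, no missing values."""
    rng = np.random.default_rng(7)
    S = 50
    f = rng.normal(size=(2, S))
    lam = np.sqrt(0.8)
    rows = []
    for m in range(2):
        for _ in range(20):
            rows.append(lam * f[m] + np.sqrt(1 - 0.8) * rng.normal(size=S))
    ids = [f"B{m}_{i}" for m in range(2) for i in range(20)]
    values = np.asarray(rows)
    truth = np.repeat([1, 2], 20)
    return AbundanceMatrix(ids, [f"s{j}" for j in range(S)], values, scale="log"), truth


@pytest.fixture(scope="session")
def noiseless_two_block_matrix():
    """Exactly rank-2 data: every protein a scaled copy of its block factor."""
    rng = np.random.default_rng(11)
    S = 30
    f = rng.normal(size=(2, S))
    rows = []
    ids = []
    for m in range(2):
        for i in range(10):
            rows.append((1.0 + 0.1 * i) * f[m] + 0.05 * i)
            ids.append(f"N{m}_{i}")
    return AbundanceMatrix(ids, [f"s{j}" for j in range(S)], np.asarray(rows), scale="log"), np.repeat([1, 2], 10)


@pytest.fixture
def small_generated():
    """A small generated dataset with two groups and planted structure."""
    cfg = SyntheticConfig(
        n_proteins=60,
        module_sizes=[15, 15],
        within_module_cor=0.7,
        group_sizes={"HC": 25, "DIS": 25},
        eigenprotein_shift={("DIS", 1): 1.5},
        missing_rate={"HC": 0.02, "DIS": 0.02},
        seed=3,
    )
    return generate(cfg)


def make_metadata(groups: dict[str, int], prefix_visit: int = 1) -> list[SampleInfo]:
    records = []
    for g, n in groups.items():
        for i in range(n):
            sid = f"{g}{i:03d}"
            records.append(SampleInfo(f"{sid}_v1", sid, g, 1, 0.0))
    return records
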
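import numpy as np
import pandas as pd
import pytest

from dockfp.fingerprint import FingerprintSet
from dockfp.ingest import ScoreMatrix
from dockfp.synthetic import SyntheticConfig, generate


def make_fingerprints(rng: np.random.Generator, n_ligands: int,
                      n_targets: int) -> FingerprintSet:
    """Random standardised fingerprints with the package's invariants."""
    raw = rng.normal(size=(n_ligands, n_targets))
    mu = raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, ddof=1, keepdims=True)
    Z = pd.DataFrame((raw - mu) / sd,
                     index=[f"L{i:02d}" for i in range(n_ligands)],
                     columns=[f"Q{j + 1:05d}" for j in range(n_targets)])
    return FingerprintSet(Z=Z, mu=pd.Series(mu[:, 0], index=Z.index),
                          sigma=pd.Series(sd[:, 0], index=Z.index))


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_matrix():
    """4 ligands x 5 targets, complete, hand-readable values."""
    rows = ["THC", "CBD", "CBG", "CBC"]
    cols = ["P00001", "P00002", "P00003", "P00004", "P00005"]
    rng = np.random.default_rng(7)
    values = rng.normal(-50, 5, size=(4, 5))
    return ScoreMatrix(scores=pd.DataFrame(values, index=rows, columns=cols))


@pytest.fixture(scope="session")
def default_fixture():
    """One default-config synthetic campaign shared across tests."""
    cfg = SyntheticConfig(seed=42)
    records, cmap, truth = generate(cfg)
    return records, cmap, truth
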
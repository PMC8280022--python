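import numpy as np
import pandas as pd
import pytest

import polyfacet as pf


@pytest.fixture(scope="session")
def small_study():
    """A small but complete simulated study shared by read-only tests."""
    cfg = pf.SimulationConfig(
        n_samples=300, n_variants=600, seed=11, missing_rate=0.01, ld_block_size=30
    )
    return pf.simulate_study(cfg, discovery_ns={"IQ": 250_000, "EA": 750_000})


@pytest.fixture()
def tiny_dataset():
    """Hand-built 4-sample x 5-variant dataset with one missing call."""
    dosages = np.array(
        [
            [0.0, 1.0, 2.0, 0.0, 1.0],
            [1.0, 1.0, 2.0, 0.0, 0.0],
            [2.0, 0.0, 2.0, np.nan, 1.0],
            [1.0, 0.0, 2.0, 0.0, 2.0],
        ]
    )
    variants = pd.DataFrame(
        {
            "id": [f"v{i}" for i in range(1, 6)],
            "chrom": [1, 1, 1, 2, 2],
            "pos": [1000, 2000, 3000, 1000, 2000],
            "a1": ["A", "C", "G", "A", "T"],
            "a2": ["G", "T", "A", "C", "C"],
        }
    )
    samples = pd.DataFrame(
        {"fid": ["F1", "F2", "F3", "F4"], "iid": ["s1", "s2", "s3", "s4"], "sex": [1, 2, 1, 2]}
    )
    return pf.GenotypeDataset(dosages, variants, samples)


def make_dataset(dosages, chrom=None, pos=None, a1=None, a2=None):
    """Build a GenotypeDataset from a raw dosage matrix with defaults."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
            "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
            "a1": a1 if a1 is not None else ["A"] * m,
            "a2": a2 if a2 is not None else ["G"] * m,
        }
    )
    samples = pd.DataFrame(
        {
            "fid": [f"F{i}" for i in range(n)],
            "iid": [f"s{i}" for i in range(n)],
            "sex": [1 + i % 2 for i in range(n)],
        }
    )
    return pf.GenotypeDataset(dosages, variants, samples)
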
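import numpy as np
import pandas as pd
import pytest

from triomed import CiteSeqDataset, SimConfig, make_fixture, simulate_citeseq


@pytest.fixture(scope="session")
def tiny_null():
    return make_fixture("tiny-null", seed=7)


@pytest.fixture(scope="session")
def strong_trio():
    return make_fixture("one-strong-trio", seed=11)


@pytest.fixture(scope="session")
def sparse20():
    return make_fixture("sparse-mediation-20", seed=3)


@pytest.fixture
def counts_dataset():
    """Hand-built raw-count dataset with known QC edge cases."""
    rng = np.random.default_rng(0)
    cells = [f"c{i}" for i in range(6)]
    genes = [f"G{i}" for i in range(8)] + ["MT-1", "MT-2"]
    counts = rng.integers(1, 20, size=(6, 10)).astype(float)
    rna = pd.DataFrame(counts, index=cells, columns=genes)
    adt = pd.DataFrame(rng.integers(0, 50, size=(6, 3)).astype(float),
                       index=cells, columns=["P1", "P2", "P3"])
    obs = pd.DataFrame({
        "sample_id": ["s1", "s1", "s1", "s2", "s2", "s2"],
        "phenotype": ["a", "a", "a", "b", "b", "b"],
    }, index=pd.Index(cells, name="cell_id"))
    return CiteSeqDataset(rna=rna, adt=adt, obs=obs)


def two_group_dataset(seed=0, n_samples=3, cells=80, **kw):
    """Binary-phenotype simulation used across mediation tests."""
    cfg = SimConfig(
        n_samples={"healthy": n_samples, "severe": n_samples},
        cells_per_sample=cells, seed=seed, **kw,
    )
    return simulate_citeseq(cfg)
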
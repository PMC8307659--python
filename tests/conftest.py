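import numpy as np
import pandas as pd
import pytest

from dmrkit import simulate as sim
from dmrkit.io import Methylome


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def small_config():
    """A ~2000-CpG genome, quick enough for per-test simulation."""
    return sim.SimConfig(
        chrom_length=200_000,
        n_islands=4,
        n_hyper_dmr=3,
        n_hypo_dmr=3,
        global_shift=0.0,
        coverage_mean=20,
        seed=7,
    )


@pytest.fixture
def small_sim(small_config):
    ref = sim.simulate_reference(small_config)
    meth_a, meth_b, truth = sim.simulate_methylomes(ref, small_config)
    return ref, meth_a, meth_b, truth


def make_methylome(rows, sample_id="s", condition="WT", replicate=1):
    """rows: iterable of (chrom, pos, n_meth, n_unmeth)."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "n_meth", "n_unmeth"])
    return Methylome(sample_id=sample_id, condition=condition, replicate=replicate, sites=df)
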
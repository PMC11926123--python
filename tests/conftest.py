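import numpy as np
import pytest

from sparsepaint.panel import GeneticMap, HaplotypePanel
from sparsepaint.simulate import SimConfig, simulate


def make_panel(alleles, positions=None, pops=None, chrom="1"):
    alleles = np.asarray(alleles, dtype=np.uint8)
    if positions is None:
        positions = np.arange(alleles.shape[1]) * 100 + 1
    n_ind = alleles.shape[0] // 2
    panel = HaplotypePanel(chrom=chrom, positions=np.asarray(positions),
                           alleles=alleles,
                           sample_ids=[f"ind{i}" for i in range(n_ind)])
    if pops is not None:
        panel.pop_label = {i: pops[i] for i in range(n_ind)}
    return panel


def uniform_map(K, total_cm=10.0):
    return GeneticMap(cm=np.linspace(0.0, total_cm, K))


@pytest.fixture(scope="session")
def sim_small():
    """Small 3-way admixture world shared across tests."""
    cfg = SimConfig(n_pop=3, n_ref_per_pop=40, n_target=15, n_snp=1500,
                    seed=11)
    return cfg, simulate(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260918)
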
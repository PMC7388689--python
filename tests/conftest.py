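import numpy as np
import pytest

import pleiokit as pk


@pytest.fixture(scope="session")
def panel20k():
    """Default-scale reference panel shared by the heavier statistical tests."""
    cfg = pk.SimulationConfig(seed=7)
    return pk.simulate_panel(cfg)


@pytest.fixture(scope="session")
def ell20k(panel20k):
    return pk.ld_scores(panel20k)


@pytest.fixture(scope="session")
def small_sim():
    """A small but well-powered paired-GWAS simulation with its truth."""
    cfg = pk.SimulationConfig(m_snps=2000, block_sizes=[20] * 100,
                              n1=100_000, n2=100_000, n_outcome=100_000,
                              h2_1=0.5, h2_2=0.5, seed=11)
    panel = pk.simulate_panel(cfg)
    truth = pk.simulate_effects(cfg, panel)
    s1, s2 = pk.simulate_sumstats(truth, panel, cfg)
    return cfg, panel, truth, s1, s2


def toy_panel(dosages, chrom=None, pos=None, mafs_hint=None):
    """Build a GenotypePanel from a raw (individuals x SNPs) dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    chrom = np.array(["1"] * m if chrom is None else chrom, dtype=object)
    pos = np.arange(1, m + 1) * 100 if pos is None else np.asarray(pos)
    ids = np.array([f"snp{j}" for j in range(m)], dtype=object)
    return pk.GenotypePanel(ids, chrom, pos,
                            np.full(m, "A", dtype=object),
                            np.full(m, "G", dtype=object), dosages)
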
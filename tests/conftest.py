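import numpy as np
import pytest

from sweepscan import GenotypePanel, PopulationMap, SimConfig, SweepTruth, simulate_panel


def make_panel(genotypes, haplotypes=None, pos=None, chrom="1", samples=None):
    """Small hand-built panel helper; genotypes is (n_samples, n_sites)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sam, n_sites = g.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    samples = samples or [f"s{i + 1}" for i in range(n_sam)]
    return GenotypePanel(
        samples=samples,
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "G", dtype=object),
        genotypes=g,
        haplotypes=None if haplotypes is None else np.asarray(haplotypes, dtype=np.int8),
    )


def hap_panel(haps, pos=None, chrom="1", samples=None):
    """Panel from a (n_samples, 2, n_sites) haplotype tensor."""
    h = np.asarray(haps, dtype=np.int8)
    g = np.where((h == -1).any(axis=1), -1, h.sum(axis=1)).astype(np.int8)
    return make_panel(g, haplotypes=h, pos=pos, chrom=chrom, samples=samples)


@pytest.fixture(scope="session")
def sweep_sim():
    """Two breeds, one planted 40 kb sweep fixed in breed_1."""
    cfg = SimConfig(
        n_breeds=2, samples_per_breed=[10, 10], chrom_length=2_000_000,
        snp_density=1 / 1000, drift_F=0.05,
        sweep_spec=SweepTruth("1", 900_000, 940_000, ("breed_1",)),
        seed=7,
    )
    panel, sweep, roh = simulate_panel(cfg)
    return cfg, panel, sweep, cfg.population_map()


@pytest.fixture(scope="session")
def neutral_sim():
    """Three breeds without planted features, mild drift and missingness."""
    cfg = SimConfig(
        n_breeds=3, samples_per_breed=[8, 8, 8], chrom_length=1_000_000,
        snp_density=1 / 1000, drift_F=0.05, missing_rate=0.03, seed=13,
    )
    panel, _, _ = simulate_panel(cfg)
    return cfg, panel, cfg.population_map()


@pytest.fixture()
def two_breed_map():
    return PopulationMap(
        {"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
        {"A": "TEB", "B": "wild"},
    )
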
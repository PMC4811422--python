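import numpy as np
import pytest

from rsbscan import (
    GenotypeMatrix, HaplotypePanel, SnpMap,
    SweepSimConfig, simulate_sweep_haplotypes,
)


def make_map(n, chrom="1", spacing=1000, start=1):
    pos = start + spacing * np.arange(n)
    return SnpMap(np.repeat(chrom, n), pos,
                  np.array([f"snp{i}" for i in range(n)], dtype=object),
                  np.repeat("A", n), np.repeat("G", n))


def make_panel(alleles, chrom="1", spacing=1000, positions=None):
    alleles = np.asarray(alleles, dtype=np.uint8)
    n_hap, n_snp = alleles.shape
    if positions is not None:
        smap = SnpMap(np.repeat(chrom, n_snp), positions,
                      np.array([f"snp{i}" for i in range(n_snp)], dtype=object),
                      np.repeat("A", n_snp), np.repeat("G", n_snp))
    else:
        smap = make_map(n_snp, chrom, spacing)
    samples = [f"ind{i}" for i in range(n_hap // 2)]
    return HaplotypePanel(alleles, smap, samples, {s: "0" for s in samples})


def make_genotypes(dosage, pops=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n_ind, n_snp = dosage.shape
    samples = [f"ind{i}" for i in range(n_ind)]
    if pops is None:
        pops = ["A"] * n_ind
    return GenotypeMatrix(dosage, make_map(n_snp), samples,
                          dict(zip(samples, pops)))


@pytest.fixture(scope="session")
def neutral_replicates():
    """Neutral two-population panels shared across calibration tests."""
    out = []
    for seed in range(20):
        out.append(simulate_sweep_haplotypes(
            SweepSimConfig(s=0.0, seed=1000 + seed)))
    return out


@pytest.fixture(scope="session")
def sweep_replicates():
    """Strong-sweep (s = 0.1) panels shared across recovery tests."""
    out = []
    for seed in range(20):
        out.append(simulate_sweep_haplotypes(
            SweepSimConfig(s=0.1, seed=2000 + seed)))
    return out
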
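import numpy as np
import pytest

from pollenmap import Haplotype, align_haplotypes, build_panmolecule
from pollenmap import synthetic_data as sd


@pytest.fixture(scope="session")
def toy_panmolecule():
    """9 bp panmolecule from ACGTACGT vs ACGTTACGT: one B-only base at pan 5."""
    a = Haplotype("A", "ACGTACGT", "parentA")
    b = Haplotype("B", "ACGTTACGT", "parentB")
    return build_panmolecule(align_haplotypes(a, b))


@pytest.fixture(scope="session")
def small_truth():
    """Random divergent pair (~4 kb, truth panmolecule and markers known)."""
    cfg = sd.SimConfig(seed=11, length_bp=4000)
    _, _, truth = sd.make_haplotypes(cfg)
    return cfg, truth


@pytest.fixture(scope="session")
def snp_only_panmolecule():
    """2 kb indel-free pair with SNPs at known positions, so pan == parental
    coordinates and liftover can be done by hand in tests."""
    rng = np.random.default_rng(5)
    bases = "ACGT"
    seq = "".join(bases[i] for i in rng.integers(0, 4, size=2000))
    snp_positions = [150, 450, 750, 950, 1200, 1500, 1850]  # 1-based
    alt = list(seq)
    for p in snp_positions:
        alt[p - 1] = {"A": "C", "C": "G", "G": "T", "T": "A"}[alt[p - 1]]
    a = Haplotype("A", seq, "parentA")
    b = Haplotype("B", "".join(alt), "parentB")
    pm = build_panmolecule(align_haplotypes(a, b))
    assert pm.length_bp == 2000 and pm.n_snps == len(snp_positions)
    return pm, snp_positions
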
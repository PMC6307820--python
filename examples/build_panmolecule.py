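"""Build a panmolecule union coordinate system from two diverged alleles.

Generates a ~5.4 kb haplotype pair at Col/Ler-like divergence, aligns the two
alleles globally and builds the panmolecule, which assigns a coordinate to
every base present in either parent."""

import numpy as np

from pollenmap import align_haplotypes, build_panmolecule, polymorphism_track, write_key_table
from pollenmap import synthetic_data as sd

rng = np.random.default_rng(0)
hap_a, hap_b, _ = sd.make_haplotypes_exact(
    rng, length_a=5431, n_snps=160, insertions_b=[15] * 13, insertions_a=[10] * 10
)

pm = build_panmolecule(align_haplotypes(hap_a, hap_b))
track = polymorphism_track(pm)
write_key_table(pm, "panmolecule_key.csv")

print(f"parent A: {len(hap_a)} bp, parent B: {len(hap_b)} bp")
print(f"panmolecule: {pm.length_bp} bp "
      f"({pm.insertion_bases(1)} B-only bases, {pm.insertion_bases(2)} A-only bases)")
print(f"SNPs: {pm.n_snps}, total polymorphism weight: {track.total_weight()} bp-equivalents")
print("key table written to panmolecule_key.csv")
# The panmolecule length equals each parent's length plus the other parent's
# insertions, so crossovers from either parent can share one coordinate axis.
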
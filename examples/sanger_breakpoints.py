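"""Call crossover breakpoints from Sanger-genotyped single molecules.

Simulates single-breakpoint recombinant molecules, genotypes each at every SNP
marker, calls the breakpoint interval per molecule and builds the
per-interval recombination-rate table."""

import numpy as np

from pollenmap import call_breakpoint, interval_rates
from pollenmap import synthetic_data as sd

cfg = sd.SimConfig(seed=2, length_bp=6000)
_, _, truth = sd.make_haplotypes(cfg)
molecules = sd.sample_crossover_molecules(cfg, truth, n_molecules=44)

calls = [call_breakpoint(sd.molecule_genotype(m, truth)) for m in molecules]
statuses = [c.status for c in calls]
print(f"molecules: {len(calls)}  simple: {statuses.count('simple')}  "
      f"parental: {statuses.count('parental')}  complex: {statuses.count('complex')}")

table = interval_rates(calls, total_cm=0.074, pm=truth.panmolecule)
hot = max(table.rows, key=lambda r: r.cM_per_Mb if r.length_bp > 0 else 0)
print(f"intervals: {len(table.rows)}  total cM conserved: "
      f"{sum(r.cM for r in table.rows):.4f}")
print(f"hottest interval: pan {hot.pan_start}-{hot.pan_end} "
      f"({hot.length_bp} bp, {hot.n_crossovers} crossovers, {hot.cM_per_Mb} cM/Mb)")
# Each simple molecule's breakpoint is bracketed by the last parent-A marker
# and the first parent-B marker; interval cM values sum to the amplicon total.
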
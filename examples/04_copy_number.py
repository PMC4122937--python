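"""Estimate chromosome copy number from read depth.

Macronuclear chromosomes are amplified to chromosome-specific levels;
mapped reads per base of contig is the depth proxy.  The example also
shows the cross-library normalization by ratio of total mapped reads.
"""

import numpy as np
from scipy import stats

from nanoterm import (Contig, MapperParams, SimParams, estimate_copy_number,
                      normalize_libraries, simulate_genome, simulate_reads)

params = SimParams(n_chromosomes=40, seed=9)
truth = simulate_genome(params)
pairs, _ = simulate_reads(truth)

contigs = [Contig(id=c.id, seq=c.seq) for c in truth.chromosomes]
table = estimate_copy_number(contigs, pairs, MapperParams())

by = table.by_id()
est = np.array([by[c.id].reads_per_base for c in truth.chromosomes])
planted = np.array([c.copy_number for c in truth.chromosomes])
r = stats.pearsonr(est, planted).statistic
print(f"total mapped reads: {table.total_mapped_reads:,}")
print(f"Pearson r (reads/bp vs planted copy number): {r:.3f}")
# r close to 1 means depth faithfully tracks the planted amplification.

half = len(pairs) // 3
small = estimate_copy_number(contigs, pairs[:half], MapperParams())
big, small_scaled = normalize_libraries(table, small)
print(f"library sizes {table.total_mapped_reads:,} vs "
      f"{small.total_mapped_reads:,}: scale factor "
      f"{small_scaled.scale_factor:.3f} applied to the smaller library")
# After scaling, reads/bp values from libraries of different depth are
# directly comparable (the construction behind cross-species factors).
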
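"""Simulate a small macronuclear genome with planted ground truth.

Builds 40 telomere-capped, gene-sized chromosomes with lognormal copy
number, ~10% alternative fragmentation, two haplotypes, and paired-end
reads from a small-insert library (outer distance 163 +/- 20 bp).
"""

from nanoterm import SimParams, make_draft, simulate_genome, simulate_reads

params = SimParams(n_chromosomes=40, seed=7)
truth = simulate_genome(params)
pairs, provenance = simulate_reads(truth)
draft, draft_table = make_draft(truth)

lengths = [len(c.seq) for c in truth.chromosomes]
print(f"chromosomes:        {len(truth.chromosomes)}")
print(f"genome size:        {sum(lengths):,} bp "
      f"(median chromosome {sorted(lengths)[len(lengths) // 2]:,} bp)")
print(f"alt-fragmented:     {len({i.parent_id for i in truth.isoforms})} "
      f"chromosomes ({len(truth.isoforms)} isoforms)")
print(f"read pairs:         {len(pairs):,} "
      f"(~{2 * 90 * len(pairs) / sum(lengths):.0f}x mean coverage)")
print(f"draft contigs:      {len(draft)} (ends trimmed up to "
      f"{params.draft_trim_max} bp, some chromosomes split)")

# Every chromosome is capped by the C4A4-type repeat on both ends;
# the draft has lost many of those caps, which is what finishing repairs.
from nanoterm import Contig, TelomereSpec, classify_all

spec = TelomereSpec()
n2_truth = sum(c.n_telomeres == 2 for c in classify_all(
    [Contig(id=c.id, seq=c.seq) for c in truth.chromosomes], spec))
n2_draft = sum(c.n_telomeres == 2 for c in classify_all(draft, spec))
print(f"2-telomere contigs: truth {n2_truth}/{len(truth.chromosomes)}, "
      f"draft {n2_draft}/{len(draft)}")
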
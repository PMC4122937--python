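# Methods

This note documents the models, parameter choices and numerical
behaviour of `nanoterm`: what each stage assumes, which knobs matter,
what the simulator does and does not emulate, and where the design was
genuinely open.

## The genome model

The toolkit targets genomes organised as *nanochromosomes*: gene-sized
DNA molecules, each capped on both ends by a short tandem telomeric
repeat and amplified to a chromosome-specific copy number. On the
forward strand a molecule reads

```
CCCCAAAACCCCAAAACCCC · core · GGGGTTTTGGGGTTTTGGGG
```

i.e. a C-rich 5' telomere (2.5 units of `CCCCAAAA`) and the reverse
complement at the 3' end. A minority of genomic regions is processed
into several *isoforms*: shorter molecules sharing one telomere with
the full-length form and acquiring a fresh telomere at an internal
*telomere-addition site*. The precise junction coordinate varies by a
few bp between molecule copies; the repeat itself is always added in
canonical phase (telomerase synthesises it de novo from the junction),
which is why literal selector matching on read prefixes works.

## Telomere detection (`telomere`)

Two tolerance regimes, on purpose:

* **Read selection is exact.** A mate is telomeric iff it (or its
  reverse complement) begins with the 20-bp selector
  `CCCCAAAACCCCAAAACCCC`. Every selected read becomes evidence for a
  site, so precision wins over recall; at 0.1% sequencing error the
  exactness costs ~2% of true telomeric reads.
* **Contig-end classification is tolerant.** Assembled consensus may
  carry allelic or erroneous bases, so a contig end counts as capped
  when a repeat run of ≥ `min_contig_run` (16 bp) begins within
  `end_window` (30 bp) of the terminus, allowing
  `max_mismatch_per_20bp` (1) mismatches per *completed* 20 bp of run.
  A run must end on a matching base, so a trailing mismatch never
  inflates the measured telomere length. Both repeat senses are
  scanned at both ends, so contigs on either strand classify
  correctly, and classification of the reverse complement provably
  swaps the flags.

Stripping removes the maximal leading run (whole and partial units,
phase anchored at the read start). It is gated on the selector, which
makes it idempotent: a stripped residual can never begin with the
selector again. Residuals shorter than 20 nt are discarded (logged):
they are too short to place reliably.

## The simulator (`simulate`)

The generator's defaults are the study conditions; every downstream
recovery figure is measured against its planted truth.

| parameter | default | meaning |
|---|---|---|
| `n_chromosomes` | 200 | chromosomes in the genome |
| `length_median`, `length_sigma` | 2,500 bp, 0.55 | lognormal lengths, truncated to [500, 20,000] bp |
| `gc_content` | 0.35 | AT-rich cores, as in ciliate MAC DNA |
| `telomere_len` | 20 bp | per end, canonical phase |
| `copy_sigma` | 0.6 | lognormal copy number, rescaled to mean 1 — most mass within one order of magnitude |
| `alt_frag_fraction` | 0.10 | chromosomes with one internal telomere-addition site |
| `alt_frag_isoform_weight` | 0.3 | isoform abundance relative to the parent |
| `tas_jitter_sd` | 3 bp | junction jitter at molecule ends |
| `heterozygosity` | 0.002/bp | two haplotypes, i.i.d. substitutions (noise stress; nothing phases them) |
| `read_len`, `frag_mean`, `frag_sd` | 90, 163, 20 bp | small-insert paired-end library; mates overlap mid-fragment |
| `terminal_frag_fraction` | 0.15 | fragments anchored at a molecule end |
| `error_rate` | 0.001/base | i.i.d. substitutions; no indels |
| `coverage` | 60× | mean depth of a copy-number-1 chromosome |
| `draft_trim_max` | 80 bp | uniform per-end trim emulating assembler telomere loss |
| `draft_split_fraction` | 0.1 | chromosomes emitted as two pieces overlapping 60 bp |

**Terminal fragments.** Libraries made from intact gene-sized molecules
over-represent molecule termini: every molecule contributes two
terminal fragments no matter how long it is (two of roughly fifteen
fragments for a median chromosome at the default insert size). The
simulator therefore anchors a configurable fraction of fragments at a
molecule end. This is not a convenience: without terminal fragments no
read starts exactly at the telomere, junction support vanishes, and no
finisher could cap an end — the same physics that makes small-insert
libraries the right choice for telomere recovery in real data.

**Jitter is one-sided at the genomic junction.** Terminal fragments
trim `max(0, round(N(0, 3)))` bases off the genomic side of the
junction and keep the full-length repeat in canonical phase. Jitter
modelled as trimming/extending the *repeat* instead would shift its
phase and make selector-based selection blind to ~7/8 of junction
reads, which contradicts how telomere addition works; the one-sided
clamp exists because a true molecule end has no genomic sequence
beyond the canonical junction to extend into.

**Sampling.** Fragments are drawn across molecules (chromosomes ×
haplotypes plus isoforms) with probability proportional to copy-number
weight × molecule length; outer distance is Normal(163, 20) truncated
to [read length, molecule length]; mates are inward; errors i.i.d.
All randomness flows from `numpy.random.default_rng([seed, stream])`
with separate streams for genome (0), reads (1) and draft (2), so each
stage is independently reproducible and byte-identical under a fixed
seed.

What the simulator does **not** emulate: indel errors, quality-score
structure (constant Phred), coverage bias (GC or fragmentation-motif),
micronuclear precursors (IESs, scrambling), chimeric reads, and any
isoform abundance model beyond a single relative weight. Passing
recovery tests therefore demonstrates the pipeline's logic under
substitution-dominated noise, not robustness to indel-rich or biased
real libraries.

## The mapper (`mapper`)

Gapless, deterministic, best-only; built for an exact oracle rather
than for generality.

* Seeds are non-overlapping 21-mers of the read plus the final 21-mer,
  so any placement with fewer mismatches than seeds is guaranteed to
  be found; with default read length that is ≥ 4 mismatches detected
  with certainty, far beyond the strict budget (1) and beyond what the
  0.1% error rate produces. Very divergent placements near the lenient
  boundary (≥ 5 mismatches, all landing in distinct seeds) can in
  principle be missed; the thresholds, not the seeding, are the
  contract there.
* Candidates are verified by vectorised Hamming counting against a
  padded genome array; separator runs longer than any read make
  cross-contig windows impossible, and clipping at contig ends falls
  out of counting separator positions (used by the lenient mode's
  aligned-fraction rule). `N` counts as a mismatch everywhere and
  never seeds.
* Best placement: fewest mismatches, ties by (lexicographically
  smallest contig id, smallest coordinate, `+` before `-`). The
  exhaustive Hamming oracle in the tests implements the same order, so
  equality is exact, including unmapped reads.
* Proper pair: both mates on one contig, opposite strands, inward,
  outer distance within [83, 243] (library mean ± 4 SD).
* Multi-mapping reads count once, at the tie-broken location — depth
  estimation does not de-duplicate or down-weight them.

## Finishing (`terminator`)

One round = classify → extend → merge → chaff; the loop accepts a
round only if the objective (2-telomere fraction) does not decrease,
and stops when a round neither gains ≥ `min_gain` (0.001) objective
nor changes the assembly at all (no bases appended, no merges, no
drops). That second clause quantifies "no significant improvement"
while letting multi-round extensions (a 100-bp gap takes two rounds at
~75 bp/round) run to completion; `max_rounds` (20) guarantees
termination.

Extension details that matter:

* The anchored mate must be strict-mapped (full length, ≤ 1
  substitution) pointing off the end; the partner must have *failed*
  full-length mapping (it may overhang). The partner is then placed on
  the terminal region by trying every offset consistent with the
  proper-pair insert range, requiring ≤ 1 substitution over the
  overlap and at least 12 bp of anchor; fewest mismatches wins, then
  the largest overlap.
* Columns beyond the end are appended while ≥ `min_support` (3) reads
  vote and a strict majority agrees; an exact tie stops the column.
  At heterozygous positions the consensus collapses to the majority
  allele — haplotypes are deliberately not resolved.
* `min_support = 3` guards against a single errored read chimerically
  extending an end at 60× coverage; 1 would be credulous, 5 would
  stall low-copy chromosomes.
* An end is frozen only when its telomere run is *complete*
  (≥ the 20-bp selector length, configurable), not merely detectable
  (16 bp): a partially rebuilt cap may still gain its outermost bases
  in the next round. Votes end naturally at the molecule terminus, so
  telomeres do not overrun.
* Left ends are extended by mirroring: the contig is
  reverse-complemented, extended on the right, and flipped back — one
  code path, strand symmetry for free.

Merging uses shared 15-mers for candidate discovery (a 40-bp overlap
with one mismatch still guarantees a clean 15-mer; 21 would not fit),
verifies each candidate diagonal by gapless alignment, and applies
candidates greedily by overlap × identity with id-based tie-breaking,
re-scanning until no merge applies (so split chains converge within a
round). Overlap consensus between two sequences is majority with ties
to the longer contig — with two voters every disagreement is a tie, so
the longer contig's bases win, which empirically favours the
error-free extended contig. Containments are absorbed by the longer
contig. A capped telomere end is never a junction; chaff removal uses
the best single gapless diagonal (sufficient for substitution-only
divergence; a heavily indel-divergent containment would be missed).

Chimera detection is deliberately absent: extension is anchored,
merging is identity-verified, and the simulator plants no chimeras;
stalled ends are reported, never forced.

## Site calling (`fragmentation`)

Stripped residuals are strict-mapped with a pair-consistency check
(a partner that maps to a *different* contig vetoes the read). A
residual mapping `+` puts a left-sense (C-rich) junction at its start;
`-` puts a right-sense junction at its end. Raw sites of one sense
cluster by single linkage with a 100-bp gap; the reported position is
the support-weighted mode (smallest coordinate on ties), so every
cluster position is witnessed by an actual read and, with one-sided
junction jitter, sits at the canonical junction. Sites within
`terminal_margin` (50 bp — larger than any plausible jitter, smaller
than gene scale) of a contig end are normal chromosome ends; the rest
are alternative fragmentation. The default `min_support = 1` flags a contig on a single internally
mapping telomeric read; raising it to 2 suppresses singleton
artefacts when a conservative call set is wanted.

## Quantification (`quantify`)

Reads per base from lenient mapping; each mapped read increments
exactly one contig. Cross-library normalization multiplies the smaller
library's reads/bp by (larger total mapped)/(smaller total mapped) —
a positive scalar, so rank order is preserved by construction.
Ortholog correlation is plain Pearson on normalized reads/bp over
reciprocal-best, by default single-gene, pairs; a `log10` option is
provided because depth ratios are multiplicative, and both variants
are reported by the CLI. Two-gene synteny: a two-gene contig is
syntenic iff its genes match two *distinct* genes on a single partner
contig below the e-value threshold (1e-10); gene-order agreement is
reported separately and does not gate the call.

## Problem sizes and run times

The test suite and the acceptance script run the full default
simulation: 200 chromosomes (~0.6 Mb of genome), ~190,000 read pairs,
finishing to convergence in 3–5 rounds (≈ 40 s on one CPU); the mapper
oracle check uses 1,000+ reads against 40 kb (exhaustive scan);
the stripping oracle uses 10,000 reads; determinism is checked by
running a 30-chromosome pipeline twice and comparing bytes. These
sizes were chosen so a complete validation runs in about two minutes
while still exercising every code path at realistic coverage.

## Known limitations

* Gapless alignment throughout: indel-containing reads fail thresholds
  rather than being placed; real indel-rich data would need an
  affine-gap mapper behind the same interface.
* Telomere tallies at contig ends depend on the configurable mismatch
  tolerance; the run manifest records the resolved thresholds so any
  tally can be tied to its settings.
* Isoform abundance is a single free weight, not an estimate; no claim
  is made about recovering per-site read counts, only positions and
  presence.
* Haplotypes are collapsed by majority vote; allele-aware finishing is
  out of scope.
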
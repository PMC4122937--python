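"""Finishing-loop contracts: exact thresholds, interior immutability,
fixpoints, and truth recovery on constructed cases."""

import numpy as np

from conftest import random_dna
from nanoterm.mapper import MapperParams
from nanoterm.simulate import SimParams, make_draft, simulate_genome, simulate_reads
from nanoterm.telomere import TelomereSpec, classify_all
from nanoterm.terminator import (ExtensionParams, MergeParams, _extend_right,
                                 assembly_objective, extend_ends,
                                 merge_overlaps, remove_chaff, run_terminator)
from nanoterm.types import Contig, ReadPair, revcomp

MP = MapperParams()
MG = MergeParams()
SPEC = TelomereSpec()


def _classified(seqs):
    return classify_all([Contig(id=f"c{i:02d}", seq=s)
                         for i, s in enumerate(seqs)], SPEC)


def _mutate_at(seq, positions):
    arr = list(seq)
    for p in positions:
        arr[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[arr[p]]
    return "".join(arr)


class TestMergeThresholds:
    def _pair_with_overlap(self, rng, len_a, len_b, overlap, n_mismatch):
        left = random_dna(rng, len_a - overlap)
        ov = random_dna(rng, overlap)
        right = random_dna(rng, len_b - overlap)
        ov_b = _mutate_at(ov, rng.choice(overlap, n_mismatch, replace=False)) \
            if n_mismatch else ov
        return _classified([left + ov, ov_b + right])

    def test_exact_40bp_overlap_merges_to_sum_minus_overlap(self, rng):
        contigs = self._pair_with_overlap(rng, 300, 260, 40, 0)
        merged = merge_overlaps(contigs, MG, SPEC)
        assert len(merged) == 1
        assert len(merged[0].seq) == 300 + 260 - 40

    def test_40bp_overlap_at_97_5_percent_identity_merges(self, rng):
        contigs = self._pair_with_overlap(rng, 300, 260, 40, 1)  # 39/40 = 0.975
        assert len(merge_overlaps(contigs, MG, SPEC)) == 1

    def test_39bp_perfect_overlap_rejected(self, rng):
        contigs = self._pair_with_overlap(rng, 300, 260, 39, 0)
        assert len(merge_overlaps(contigs, MG, SPEC)) == 2

    def test_40bp_overlap_at_95_percent_identity_rejected(self, rng):
        contigs = self._pair_with_overlap(rng, 300, 260, 40, 2)  # 38/40 = 0.95
        assert len(merge_overlaps(contigs, MG, SPEC)) == 2

    def test_100bp_overlap_with_3_mismatches_merges_to_truth(self, rng):
        """97% overlap merges; consensus equals truth when the longer
        contig is error-free."""
        truth = random_dna(rng, 700)
        a = truth[:450]                        # error-free, longer
        b = _mutate_at(truth[350:], [10, 40, 80])  # 100-bp overlap, 3 errors
        merged = merge_overlaps(_classified([a, b]), MG, SPEC)
        assert len(merged) == 1
        assert merged[0].seq[:450] == truth[:450]
        assert len(merged[0].seq) == 700

    def test_never_merges_through_a_capped_telomere_end(self, rng):
        g_tel = revcomp(SPEC.read_selector)
        ov = random_dna(rng, 60)
        # perfect 80-bp dovetail, but the junction would run through a's
        # capped right telomere: such a merge must be refused
        a = random_dna(rng, 200) + ov + g_tel
        b = ov + g_tel + random_dna(rng, 200)
        contigs = _classified([a, b])
        assert contigs[0].right_telomere and not contigs[1].left_telomere
        merged = merge_overlaps(contigs, MG, SPEC)
        assert len(merged) == 2

    def test_reverse_complement_overlap_is_found(self, rng):
        truth = random_dna(rng, 600)
        a, b = truth[:350], revcomp(truth[300:])
        merged = merge_overlaps(_classified([a, b]), MG, SPEC)
        assert len(merged) == 1
        assert merged[0].seq in (truth, revcomp(truth))


class TestChaff:
    def test_contained_small_contig_dropped(self, rng):
        big = random_dna(rng, 5000)
        contigs = [Contig(id="big", seq=big),
                   Contig(id="small", seq=big[1000:1400])]
        kept = remove_chaff(contigs, MG)
        assert [c.id for c in kept] == ["big"]

    def test_unmatched_small_contig_kept(self, rng):
        contigs = [Contig(id="big", seq=random_dna(rng, 5000)),
                   Contig(id="small", seq=random_dna(rng, 400))]
        assert len(remove_chaff(contigs, MG)) == 2

    def test_75_percent_coverage_keeps_contig(self, rng):
        big = random_dna(rng, 5000)
        # 300 of 400 bases match the big contig (75% coverage), rest random
        small = big[2000:2300] + random_dna(rng, 100)
        contigs = [Contig(id="big", seq=big), Contig(id="small", seq=small)]
        kept = remove_chaff(contigs, MG)
        assert {c.id for c in kept} == {"big", "small"}

    def test_long_contigs_never_dropped(self, rng):
        big = random_dna(rng, 5000)
        contigs = [Contig(id="big", seq=big),
                   Contig(id="alsobig", seq=big[:900])]
        assert len(remove_chaff(contigs, MG)) == 2


class TestExtension:
    def _make_candidates(self, contig_seq, truth, n_reads, rng, n_sub=0):
        """Partner reads overlapping the right end of contig by 40,
        overhanging 50 into truth."""
        Lc = len(contig_seq)
        cands = []
        for i in range(n_reads):
            p = truth[Lc - 40: Lc + 50]
            if n_sub:
                p = _mutate_at(p, rng.choice(40, n_sub, replace=False))
            cands.append((Lc - 40 - 63, p))  # anchored mate start upstream
        return cands

    def test_overhang_read_with_two_substitutions_excluded(self, rng):
        truth = random_dna(rng, 400)
        contig = truth[:300]
        ext = ExtensionParams(min_support=1)
        good = self._make_candidates(contig, truth, 1, rng, n_sub=0)
        bad = self._make_candidates(contig, truth, 1, rng, n_sub=2)
        assert _extend_right(contig, bad, ext, MP) == contig
        assert _extend_right(contig, good, ext, MP) == truth[:350]

    def test_one_substitution_overhang_still_votes(self, rng):
        truth = random_dna(rng, 400)
        contig = truth[:300]
        ext = ExtensionParams(min_support=1)
        cand = self._make_candidates(contig, truth, 1, rng, n_sub=1)
        assert _extend_right(contig, cand, ext, MP) == truth[:350]

    def test_zero_mapped_pairs_is_a_fixpoint(self, rng):
        contigs = _classified([random_dna(rng, 500)])
        out, report = extend_ends(contigs, [], ExtensionParams(), MP, SPEC)
        assert out[0].seq == contigs[0].seq
        assert report.bases_added == 0

    def test_trimmed_end_extended_to_truth_terminus(self):
        """A chromosome trimmed by 30 bp at one end is reconstructed
        exactly, including its telomere, from error-free 60x reads."""
        params = SimParams(n_chromosomes=1, error_rate=0.0, heterozygosity=0.0,
                           alt_frag_fraction=0.0, tas_jitter_sd=0.0,
                           length_median=1000, seed=33)
        truth = simulate_genome(params)
        pairs, _ = simulate_reads(truth)
        chrom = truth.chromosomes[0]
        draft = classify_all([Contig(id="d", seq=chrom.seq[:-30])], SPEC)
        final, reports = run_terminator(draft, pairs, telomere_spec=SPEC)
        assert len(final) == 1
        assert final[0].seq == chrom.seq

    def test_interior_bases_never_modified(self, small_sim):
        draft = classify_all(
            [Contig(id=c.id, seq=c.seq) for c in small_sim["draft"]], SPEC)
        out, _ = extend_ends(draft, small_sim["pairs"][:20000],
                             ExtensionParams(), MP, SPEC)
        for before, after in zip(draft, out):
            assert before.seq in after.seq


class TestRunTerminator:
    def test_complete_draft_converges_without_change(self):
        params = SimParams(n_chromosomes=5, draft_trim_max=0,
                           draft_split_fraction=0.0, seed=44)
        truth = simulate_genome(params)
        pairs, _ = simulate_reads(truth)
        draft, _ = make_draft(truth)
        final, reports = run_terminator(draft, pairs)
        assert [c.seq for c in final] == [c.seq for c in draft]
        assert len(reports) <= 2
        assert reports[-1].objective == 1.0

    def test_split_draft_pairs_merge_in_round_one(self):
        params = SimParams(n_chromosomes=12, draft_split_fraction=0.5,
                           draft_split_overlap=60, seed=45)
        truth = simulate_genome(params)
        pairs, _ = simulate_reads(truth)
        draft, _ = make_draft(truth)
        assert len(draft) > 12
        final, reports = run_terminator(draft, pairs)
        assert len(final) == 12
        assert reports[0].n_merges == len(draft) - 12

    def test_objective_monotone_across_rounds(self, small_sim):
        final, reports = run_terminator(small_sim["draft"], small_sim["pairs"])
        objectives = [r.objective for r in reports]
        assert objectives == sorted(objectives)
        assert assembly_objective(final) == objectives[-1]
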
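"""Copy number, normalization, metrics and synteny statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import random_dna
from nanoterm.mapper import MapperParams
from nanoterm.quantify import (CopyNumberEstimate, CopyNumberTable,
                               HomologyTable, compute_metrics,
                               correlate_orthologs, estimate_copy_number,
                               normalize_libraries, two_gene_synteny)
from nanoterm.simulate import SimParams, simulate_genome, simulate_reads
from nanoterm.telomere import TelomereSpec, classify_all
from nanoterm.types import Contig, ReadPair, revcomp

MP = MapperParams()
SPEC = TelomereSpec()


def _table(rows):
    return CopyNumberTable(
        estimates=[CopyNumberEstimate(cid, n, rpb, rpb)
                   for cid, n, rpb in rows],
        total_mapped_reads=sum(r[1] for r in rows))


class TestCopyNumber:
    def test_reads_per_base_arithmetic(self, rng):
        contig = Contig(id="c", seq=random_dna(rng, 1000))
        pairs = []
        for i in range(250):   # 500 mapped reads over 1000 bp -> 0.5 rpb
            s = int(rng.integers(0, 1000 - 163))
            frag = contig.seq[s:s + 163]
            pairs.append(ReadPair(id=f"p{i}", seq1=frag[:90],
                                  seq2=revcomp(frag[-90:]),
                                  qual1="I" * 90, qual2="I" * 90))
        table = estimate_copy_number([contig], pairs, MP)
        est = table.estimates[0]
        assert est.mapped_reads == 500
        assert est.reads_per_base == pytest.approx(0.5)

    def test_zero_mapped_contig_retained(self, rng):
        contigs = [Contig(id="a", seq=random_dna(rng, 500)),
                   Contig(id="b", seq=random_dna(rng, 500))]
        frag = contigs[0].seq[100:263]
        pairs = [ReadPair(id="p", seq1=frag[:90], seq2=revcomp(frag[-90:]),
                          qual1="I" * 90, qual2="I" * 90)]
        table = estimate_copy_number(contigs, pairs, MP)
        by = table.by_id()
        assert by["b"].mapped_reads == 0
        assert by["b"].reads_per_base == 0.0

    def test_estimates_invariant_under_reverse_complement(self, small_sim):
        truth = small_sim["truth"]
        pairs = small_sim["pairs"][:15000]
        fwd = estimate_copy_number(
            [Contig(id=c.id, seq=c.seq) for c in truth.chromosomes], pairs, MP)
        rev = estimate_copy_number(
            [Contig(id=c.id, seq=revcomp(c.seq)) for c in truth.chromosomes],
            pairs, MP)
        f = {e.contig_id: e.mapped_reads for e in fwd.estimates}
        r = {e.contig_id: e.mapped_reads for e in rev.estimates}
        shared = sum(f[k] == r[k] for k in f)
        # tie-broken multi-mappers may flip; the estimates must agree overall
        assert shared >= 0.9 * len(f)
        total_f = sum(f.values())
        total_r = sum(r.values())
        assert abs(total_f - total_r) <= 0.001 * total_f


class TestNormalization:
    def test_ratio_of_totals_factor_applied_to_smaller(self):
        a = _table([("x", 1_242_000, 0.9)])
        b = _table([("x", 1_000_000, 0.9)])
        na, nb = normalize_libraries(a, b)
        assert nb.scale_factor == pytest.approx(1.242)
        assert nb.estimates[0].normalized_rpb == pytest.approx(0.9 * 1.242)
        assert na.estimates[0].normalized_rpb == pytest.approx(0.9)

    def test_equal_totals_identity(self):
        a = _table([("x", 500, 0.4)])
        b = _table([("y", 500, 0.8)])
        na, nb = normalize_libraries(a, b)
        assert na.scale_factor == nb.scale_factor == 1.0
        assert nb.estimates[0].normalized_rpb == 0.8

    def test_rank_order_preserved(self, rng):
        rows = [(f"c{i}", int(r), float(r) / 1000)
                for i, r in enumerate(rng.integers(10, 5000, size=30))]
        a, b = _table(rows), _table([("z", 99_999, 1.0)])
        na, _ = normalize_libraries(a, b)
        before = np.argsort([e.reads_per_base for e in a.estimates])
        after = np.argsort([e.normalized_rpb for e in na.estimates])
        assert (before == after).all()

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalize_libraries(_table([("x", 0, 0.0)]), _table([("y", 5, 1.0)]))


def _homology(rows):
    return HomologyTable(pd.DataFrame(
        rows, columns=["contig_a", "gene_a", "contig_b", "gene_b",
                       "evalue", "reciprocal_best"]))


class TestOrthologCorrelation:
    def _tables(self, values, factor=2.0):
        a = _table([(f"a{i}", 100, v) for i, v in enumerate(values)])
        b = _table([(f"b{i}", 100, v * factor) for i, v in enumerate(values)])
        t = _homology([(f"a{i}", f"ga{i}", f"b{i}", f"gb{i}", 1e-30, True)
                       for i in range(len(values))])
        return a, b, t

    def test_perfect_linearity_gives_r_one(self):
        a, b, t = self._tables([0.2, 0.5, 1.1, 2.0, 3.3])
        r, n, _ = correlate_orthologs(a, b, t)
        assert r == pytest.approx(1.0)
        assert n == 5

    def test_self_correlation_is_exactly_one(self):
        a, _, _ = self._tables([0.2, 0.5, 1.1, 2.0])
        t = _homology([(f"a{i}", f"g{i}", f"a{i}", f"g{i}", 1e-30, True)
                       for i in range(4)])
        r, _, _ = correlate_orthologs(a, a, t)
        assert r == 1.0

    def test_shuffled_pairing_sits_in_permutation_null_band(self, rng):
        values = rng.lognormal(0, 0.6, size=60)
        a = _table([(f"a{i}", 100, v) for i, v in enumerate(values)])
        perm = rng.permutation(60)
        b = _table([(f"b{i}", 100, values[perm[i]] * 1.01)
                    for i in range(60)])
        t = _homology([(f"a{i}", f"ga{i}", f"b{i}", f"gb{i}", 1e-30, True)
                       for i in range(60)])
        r, _, _ = correlate_orthologs(a, b, t)
        # permutation oracle: null distribution of r under random pairing
        null = []
        x = values
        for _ in range(1000):
            y = rng.permutation(values)
            null.append(stats.pearsonr(x, y).statistic)
        assert abs(r) <= np.quantile(np.abs(null), 0.999) + 0.05

    def test_twin_simulations_with_shared_copy_numbers(self, rng):
        copies = rng.lognormal(0, 0.6, size=50)
        noisy_a = copies * rng.lognormal(0, 0.1, size=50)
        noisy_b = copies * rng.lognormal(0, 0.1, size=50)
        a = _table([(f"a{i}", 100, v) for i, v in enumerate(noisy_a)])
        b = _table([(f"b{i}", 100, v) for i, v in enumerate(noisy_b)])
        t = _homology([(f"a{i}", f"ga{i}", f"b{i}", f"gb{i}", 1e-30, True)
                       for i in range(50)])
        r, _, _ = correlate_orthologs(a, b, t)
        assert r >= 0.9

    def test_single_gene_restriction_drops_two_gene_contigs(self):
        a, b, t = self._tables([0.2, 0.5, 1.1, 2.4])
        extra = _homology([("a0", "ga0x", "bX", "gbX", 1e-30, False)])
        t = HomologyTable(pd.concat([t.frame, extra.frame],
                                    ignore_index=True))
        _, n, _ = correlate_orthologs(a, b, t, single_gene_only=True)
        assert n == 3   # a0 now carries two genes and is excluded

    def test_too_few_pairs_rejected(self):
        a, b, t = self._tables([0.2, 0.5])
        with pytest.raises(ValueError, match=">= 3"):
            correlate_orthologs(a, b, t)


class TestMetrics:
    def test_hand_built_assembly_arithmetic(self, rng):
        c_tel = SPEC.read_selector
        g_tel = revcomp(c_tel)
        seqs = [c_tel + "GG" + random_dna(rng, 56) + "CC" + g_tel,   # 100, 2-tel
                "GG" + random_dna(rng, 178) + g_tel,                 # 200, 1-tel
                random_dna(rng, 300)]                                # 300, 0-tel
        contigs = classify_all([Contig(id=f"c{i}", seq=s)
                                for i, s in enumerate(seqs)], SPEC)
        m = compute_metrics(contigs)
        assert m.assembly_size == 600
        assert m.n_telomeres == 3
        assert (m.n_2tel, m.n_1tel, m.n_0tel) == (1, 1, 1)
        assert m.mean_contig_len == pytest.approx(200)
        assert m.max_contig_len == 300
        m.check_invariants()

    def test_error_free_simulation_fully_covered(self):
        params = SimParams(n_chromosomes=10, error_rate=0.0, seed=71)
        truth = simulate_genome(params)
        pairs, _ = simulate_reads(truth)
        contigs = classify_all([Contig(id=c.id, seq=c.seq)
                                for c in truth.chromosomes], SPEC)
        m = compute_metrics(contigs, pairs, SPEC, MP)
        assert m.total_read_coverage_pct >= 99.9
        assert m.telomeric_read_coverage_pct >= 99.0
        assert m.proper_pair_pct >= 99.0

    def test_empty_read_set_keeps_counts_valid(self, rng):
        contigs = classify_all([Contig(id="c", seq=random_dna(rng, 400))],
                               SPEC)
        m = compute_metrics(contigs, [], SPEC, MP)
        assert m.n_contigs == 1
        assert np.isnan(m.total_read_coverage_pct)


class TestSynteny:
    def _gene_maps(self, n, syntenic_n):
        gm_a = {f"a{i}": [f"ga{i}.1", f"ga{i}.2"] for i in range(n)}
        gm_b = {f"b{i}": [f"gb{i}.1", f"gb{i}.2"] for i in range(n)}
        rows = []
        for i in range(n):
            if i < syntenic_n:
                rows.append((f"a{i}", f"ga{i}.1", f"b{i}", f"gb{i}.1",
                             1e-20, True))
                rows.append((f"a{i}", f"ga{i}.2", f"b{i}", f"gb{i}.2",
                             1e-20, False))
            else:   # genes match different contigs
                rows.append((f"a{i}", f"ga{i}.1", f"b{i}", f"gb{i}.1",
                             1e-20, True))
                rows.append((f"a{i}", f"ga{i}.2", f"b{(i + 1) % n}",
                             f"gb{(i + 1) % n}.2", 1e-20, False))
        return _homology(rows), gm_a, gm_b

    def test_two_gene_contig_with_shared_target_is_syntenic(self):
        t, gm_a, gm_b = self._gene_maps(1, 1)
        s = two_gene_synteny(t, gm_a, gm_b)
        assert s.n_syntenic == 1
        assert s.order_agreement == 1

    def test_genes_on_different_targets_not_syntenic(self):
        t, gm_a, gm_b = self._gene_maps(2, 0)
        s = two_gene_synteny(t, gm_a, gm_b)
        assert s.n_syntenic == 0

    def test_constructed_43_of_100_fraction(self):
        t, gm_a, gm_b = self._gene_maps(100, 43)
        s = two_gene_synteny(t, gm_a, gm_b)
        assert s.n_two_gene_contigs == 100
        assert s.fraction_syntenic == pytest.approx(0.43)

    def test_evalue_threshold_applies(self):
        rows = [("a0", "g1", "b0", "h1", 1e-20, True),
                ("a0", "g2", "b0", "h2", 1e-5, False)]  # too weak
        t = _homology(rows)
        s = two_gene_synteny(t, {"a0": ["g1", "g2"]}, {"b0": ["h1", "h2"]})
        assert s.n_syntenic == 0

    def test_unknown_gene_map_contig_raises(self):
        t, gm_a, gm_b = self._gene_maps(1, 1)
        with pytest.raises(ValueError, match="absent"):
            two_gene_synteny(t, gm_a, gm_b, contig_ids_a=["somethingelse"])
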
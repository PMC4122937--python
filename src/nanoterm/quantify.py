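"""Copy-number estimation, assembly metrics, and synteny statistics.

Macronuclear chromosomes are amplified to chromosome-specific copy
numbers, so read depth carries biology: mapped reads per base of contig
(lenient mapping — >=90% identity over >=70% of the read) is the
copy-number proxy used throughout.  Cross-library comparison first
rescales the smaller library by the ratio of total mapped reads, then
correlates orthologous single-gene chromosomes (Pearson).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mapper import MapperParams, build_index, map_batch, pair_flags
from .telomere import TelomereSpec, strip_telomeric_prefix
from .types import Contig, ReadPair, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "CopyNumberEstimate",
    "CopyNumberTable",
    "AssemblyMetrics",
    "HomologyTable",
    "estimate_copy_number",
    "normalize_libraries",
    "correlate_orthologs",
    "compute_metrics",
    "two_gene_synteny",
    "SyntenySummary",
]


@dataclass
class CopyNumberEstimate:
    contig_id: str
    mapped_reads: int
    reads_per_base: float
    normalized_rpb: float


@dataclass
class CopyNumberTable:
    """Per-contig estimates plus the library total needed for scaling."""

    estimates: list[CopyNumberEstimate]
    total_mapped_reads: int
    scale_factor: float = 1.0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.estimates])

    def by_id(self) -> dict[str, CopyNumberEstimate]:
        return {e.contig_id: e for e in self.estimates}


def estimate_copy_number(contigs: Sequence[Contig],
                         pairs: Iterable[ReadPair],
                         mp: MapperParams | None = None) -> CopyNumberTable:
    """Reads per base of contig from lenient best-only mapping.

    Every mapped read increments exactly one contig (multi-mapping
    reads count once, at the deterministically tie-broken placement).
    Output is sorted by contig id; contigs with zero mapped reads are
    retained with 0.0 reads/bp.
    """
    mp = mp or MapperParams()
    contigs = sorted(contigs, key=lambda c: c.id)
    index = build_index(contigs, k=mp.k)
    pairs = list(pairs)
    counts = np.zeros(len(contigs), dtype=np.int64)
    for seqs in ([p.seq1 for p in pairs], [p.seq2 for p in pairs]):
        b = map_batch(seqs, index, mp, mode="lenient")
        np.add.at(counts, b.contig_idx[b.mapped], 1)
    total = int(counts.sum())
    estimates = [
        CopyNumberEstimate(
            contig_id=c.id, mapped_reads=int(counts[i]),
            reads_per_base=counts[i] / len(c.seq),
            normalized_rpb=counts[i] / len(c.seq))
        for i, c in enumerate(contigs)
    ]
    logger.info("copy number: %d reads mapped over %d contigs",
                total, len(contigs))
    return CopyNumberTable(estimates=estimates, total_mapped_reads=total)


def normalize_libraries(est_a: CopyNumberTable, est_b: CopyNumberTable
                        ) -> tuple[CopyNumberTable, CopyNumberTable]:
    """Scale the smaller library's reads/bp by the ratio of totals.

    The factor is (larger total mapped reads)/(smaller total), applied
    to the smaller library only, making reads/bp directly comparable
    across libraries of different depth.  Rank order is preserved (positive
    scalar).  Returns new tables; inputs are unchanged.
    """
    ta, tb = est_a.total_mapped_reads, est_b.total_mapped_reads
    if ta == 0 or tb == 0:
        raise ValueError("cannot normalize a library with zero mapped reads")

    def scaled(table: CopyNumberTable, factor: float) -> CopyNumberTable:
        ests = [CopyNumberEstimate(e.contig_id, e.mapped_reads,
                                   e.reads_per_base,
                                   e.reads_per_base * factor)
                for e in table.estimates]
        return CopyNumberTable(estimates=ests,
                               total_mapped_reads=table.total_mapped_reads,
                               scale_factor=factor)

    if ta >= tb:
        factor = ta / tb
        out = scaled(est_a, 1.0), scaled(est_b, factor)
    else:
        factor = tb / ta
        out = scaled(est_a, factor), scaled(est_b, 1.0)
    logger.info("library normalization factor: %.3f", factor)
    return out


@dataclass
class HomologyTable:
    """Cross-assembly gene homology, one row per match.

    Columns: contig_a, gene_a, contig_b, gene_b, evalue,
    reciprocal_best (bool).  The computation that produces it (protein
    prediction, clustering, reciprocal BLAST) is upstream of this
    toolkit; the table is an input.
    """

    frame: pd.DataFrame

    REQUIRED = ("contig_a", "gene_a", "contig_b", "gene_b", "evalue",
                "reciprocal_best")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"homology table missing columns: {missing}")
        rb = self.frame[self.frame["reciprocal_best"]]
        if rb["gene_a"].duplicated().any() or rb["gene_b"].duplicated().any():
            raise ValueError("reciprocal-best pairs must be one-to-one")

    @classmethod
    def from_tsv(cls, path) -> "HomologyTable":
        df = pd.read_csv(path, sep="\t")
        if df["reciprocal_best"].dtype != bool:
            df["reciprocal_best"] = df["reciprocal_best"].astype(bool)
        return cls(df)

    def genes_per_contig(self, side: str) -> pd.Series:
        return self.frame.groupby(f"contig_{side}")[f"gene_{side}"].nunique()


def correlate_orthologs(est_a: CopyNumberTable, est_b: CopyNumberTable,
                        table: HomologyTable,
                        single_gene_only: bool = True,
                        log10: bool = False
                        ) -> tuple[float, int, pd.DataFrame]:
    """Pearson correlation of normalized reads/bp over ortholog pairs.

    Restricted to reciprocal-best pairs (optionally only those on
    single-gene contigs, the cleanest copy-number comparison); requires
    at least 3 usable pairs.  Returns (r, n, paired table).
    """
    rb = table.frame[table.frame["reciprocal_best"]].copy()
    if single_gene_only:
        ga = table.genes_per_contig("a")
        gb = table.genes_per_contig("b")
        rb = rb[rb["contig_a"].map(ga).eq(1) & rb["contig_b"].map(gb).eq(1)]
    a_by, b_by = est_a.by_id(), est_b.by_id()
    rows = []
    for t in rb.itertuples(index=False):
        ea, eb = a_by.get(t.contig_a), b_by.get(t.contig_b)
        if ea is None or eb is None:
            continue
        rows.append((t.contig_a, t.contig_b,
                     ea.normalized_rpb, eb.normalized_rpb))
    if len(rows) < 3:
        raise ValueError(f"need >= 3 ortholog pairs with estimates, "
                         f"got {len(rows)}")
    paired = pd.DataFrame(rows, columns=["contig_a", "contig_b",
                                         "rpb_a", "rpb_b"])
    x, y = paired["rpb_a"].to_numpy(), paired["rpb_b"].to_numpy()
    if log10:
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("log10 correlation requires positive estimates")
        x, y = np.log10(x), np.log10(y)
    r = float(stats.pearsonr(x, y).statistic)
    return r, len(paired), paired


@dataclass
class AssemblyMetrics:
    """The standard per-assembly summary table."""

    assembly_size: int
    n_contigs: int
    n_telomeres: int
    mean_contig_len: float
    max_contig_len: int
    n_2tel: int
    n_1tel: int
    n_0tel: int
    total_read_coverage_pct: float = math.nan
    telomeric_read_coverage_pct: float = math.nan
    proper_pair_pct: float = math.nan

    def check_invariants(self) -> None:
        assert self.n_contigs == self.n_2tel + self.n_1tel + self.n_0tel
        assert self.n_telomeres == 2 * self.n_2tel + self.n_1tel
        assert self.mean_contig_len <= self.max_contig_len

    def as_row(self) -> dict:
        return {
            "Assembly size (bp)": self.assembly_size,
            "Contigs (n)": self.n_contigs,
            "Telomeres (n)": self.n_telomeres,
            "Mean contig length (bp)": round(self.mean_contig_len, 1),
            "Max contig length (bp)": self.max_contig_len,
            "2-Telomere contigs": self.n_2tel,
            "1-Telomere contigs": self.n_1tel,
            "0-Telomere contigs": self.n_0tel,
            "Total PE read coverage (%)": round(self.total_read_coverage_pct, 1),
            "Telomeric PE read coverage (%)":
                round(self.telomeric_read_coverage_pct, 1),
            "Properly paired (%)": round(self.proper_pair_pct, 1),
        }


def compute_metrics(contigs: Sequence[Contig],
                    pairs: Sequence[ReadPair] | None = None,
                    spec: TelomereSpec | None = None,
                    mp: MapperParams | None = None) -> AssemblyMetrics:
    """Assembly metrics; read-based fields need *pairs*.

    ``total_read_coverage_pct`` is the percentage of non-telomeric
    reads that lenient-map; ``telomeric_read_coverage_pct`` is the same
    for telomere-selector reads after stripping their repeat; the
    proper-pair percentage is over pairs with both mates mapped.
    Contigs must be classified.
    """
    spec = spec or TelomereSpec()
    mp = mp or MapperParams()
    contigs = list(contigs)
    if any(not c.classified for c in contigs):
        raise ValueError("contigs must be classified before computing metrics")
    lengths = [len(c.seq) for c in contigs]
    n2 = sum(c.n_telomeres == 2 for c in contigs)
    n1 = sum(c.n_telomeres == 1 for c in contigs)
    n0 = sum(c.n_telomeres == 0 for c in contigs)
    metrics = AssemblyMetrics(
        assembly_size=sum(lengths),
        n_contigs=len(contigs),
        n_telomeres=2 * n2 + n1,
        mean_contig_len=sum(lengths) / len(lengths) if lengths else 0.0,
        max_contig_len=max(lengths) if lengths else 0,
        n_2tel=n2, n_1tel=n1, n_0tel=n0,
    )
    if pairs is None:
        return metrics
    pairs = list(pairs)
    index = build_index(contigs, k=mp.k)

    telomeric: list[str] = []
    normal: list[str] = []
    for p in pairs:
        for mate in (p.seq1, p.seq2):
            for seq in (mate, revcomp(mate)):
                n = strip_telomeric_prefix(seq, spec)
                if n and len(seq) - n >= spec.min_residual:
                    telomeric.append(seq[n:])
                    break
            else:
                normal.append(mate)
    if normal:
        b = map_batch(normal, index, mp, mode="lenient")
        metrics.total_read_coverage_pct = 100.0 * b.mapped.sum() / len(normal)
    if telomeric:
        bt = map_batch(telomeric, index, mp, mode="lenient")
        metrics.telomeric_read_coverage_pct = \
            100.0 * bt.mapped.sum() / len(telomeric)

    b1 = map_batch([p.seq1 for p in pairs], index, mp, mode="lenient")
    b2 = map_batch([p.seq2 for p in pairs], index, mp, mode="lenient")
    proper, _ = pair_flags(index, b1, b2, mp)
    both = b1.mapped & b2.mapped
    if both.any():
        metrics.proper_pair_pct = 100.0 * proper.sum() / both.sum()
    metrics.check_invariants()
    return metrics


@dataclass
class SyntenySummary:
    n_two_gene_contigs: int
    n_syntenic: int
    order_agreement: int
    per_contig: pd.DataFrame = field(repr=False)

    @property
    def fraction_syntenic(self) -> float | None:
        if self.n_two_gene_contigs == 0:
            return None
        return self.n_syntenic / self.n_two_gene_contigs


def two_gene_synteny(table: HomologyTable,
                     gene_map_a: dict[str, list[str]],
                     gene_map_b: dict[str, list[str]],
                     evalue_threshold: float = 1e-10,
                     contig_ids_a: Iterable[str] | None = None
                     ) -> SyntenySummary:
    """Two-gene-contig synteny between assemblies A and B.

    A two-gene contig of A is syntenic iff its two genes separately
    match (e-value below threshold) two distinct genes on a single
    contig of B.  *gene_map_a*/*gene_map_b* give the ordered genes per
    contig.  Gene-order agreement (matched genes in the same or exactly
    reversed order on a two-gene B contig) is reported separately.
    """
    if contig_ids_a is not None:
        known = set(contig_ids_a)
        for cid in gene_map_a:
            if cid not in known:
                raise ValueError(f"gene map contig {cid!r} absent from assembly")
    sig = table.frame[table.frame["evalue"] < evalue_threshold]
    matches: dict[str, set[tuple[str, str]]] = {}
    for t in sig.itertuples(index=False):
        matches.setdefault(t.gene_a, set()).add((t.contig_b, t.gene_b))

    rows = []
    n_syntenic = 0
    n_order = 0
    for cid, genes in sorted(gene_map_a.items()):
        if len(genes) != 2:
            continue
        g1, g2 = genes
        m1 = matches.get(g1, set())
        m2 = matches.get(g2, set())
        hit_contig = None
        order_ok = False
        for cb in sorted({c for c, _ in m1} & {c for c, _ in m2}):
            genes1 = {g for c, g in m1 if c == cb}
            genes2 = {g for c, g in m2 if c == cb}
            # distinct target proteins required
            if genes1 == genes2 and len(genes1) == 1:
                continue
            hit_contig = cb
            gb = gene_map_b.get(cb, [])
            if len(gb) == 2:
                order_ok = (gb[0] in genes1 and gb[1] in genes2) or \
                           (gb[1] in genes1 and gb[0] in genes2)
            break
        syntenic = hit_contig is not None
        n_syntenic += syntenic
        n_order += order_ok
        rows.append({"contig_a": cid, "gene_1": g1, "gene_2": g2,
                     "syntenic": syntenic, "contig_b": hit_contig or "",
                     "order_agreement": order_ok})
    per_contig = pd.DataFrame(
        rows, columns=["contig_a", "gene_1", "gene_2", "syntenic",
                       "contig_b", "order_agreement"])
    return SyntenySummary(n_two_gene_contigs=len(rows), n_syntenic=n_syntenic,
                          order_agreement=n_order, per_contig=per_contig)
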
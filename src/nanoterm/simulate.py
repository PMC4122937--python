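"""Synthetic macronuclear genome, read-pair, and draft-assembly simulator.

The generator emulates the architecture of a stichotrich macronuclear
genome: a few hundred gene-sized chromosomes, each capped by a 20-bp
C4A4-type telomere at both ends, with lognormal per-chromosome copy
number, a ~10% minority of alternatively fragmented chromosomes that
give rise to shorter telomere-capped isoforms, two haplotypes, and
small-insert paired-end reads (mean outer distance 163 bp).

Two features deserve a note because they drive everything downstream:

* **Terminal fragments.**  Shotgun libraries made from intact
  gene-sized molecules over-represent molecule termini: every molecule
  contributes two terminal fragments regardless of its length.  A
  configurable fraction of fragments (``terminal_frag_fraction``) is
  therefore anchored at a molecule end; these are the fragments whose
  outer read begins with the telomeric repeat and they are what lets an
  assembly be finished out to the telomere.

* **Telomere-addition jitter.**  The precise site of telomere addition
  varies by a few bp between molecule copies.  Terminal fragments trim
  ``max(0, round(N(0, tas_jitter_sd)))`` bases off the genomic side of
  the junction and keep the full-length repeat, so the repeat itself
  always starts in canonical phase (a phase-shifted repeat would never
  be recognised by literal selector matching, and is not what telomere
  addition produces).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import Contig, ReadPair, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "Chromosome",
    "Isoform",
    "TruthSet",
    "simulate_genome",
    "simulate_reads",
    "make_draft",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimParams:
    """All tunables of the simulator; defaults are the study conditions.

    Lengths are lognormal around a 2,500-bp median truncated to
    [500, 20,000] bp; copy numbers are lognormal (sigma 0.6) rescaled to
    mean 1; ~10% of chromosomes carry one internal telomere-addition
    site whose isoforms have 0.3 relative abundance; reads are 90-bp
    mates from ~Normal(163, 20) fragments at 60x mean coverage with
    0.001 substitutions/base.
    """

    n_chromosomes: int = 200
    length_median: float = 2500.0
    length_sigma: float = 0.55
    length_min: int = 500
    length_max: int = 20000
    gc_content: float = 0.35
    telomere_len: int = 20
    telomere_unit: str = "CCCCAAAA"
    copy_sigma: float = 0.6
    alt_frag_fraction: float = 0.10
    alt_frag_isoform_weight: float = 0.3
    tas_jitter_sd: float = 3.0
    heterozygosity: float = 0.002
    read_len: int = 90
    frag_mean: float = 163.0
    frag_sd: float = 20.0
    terminal_frag_fraction: float = 0.15
    error_rate: float = 0.001
    coverage: float = 60.0
    draft_trim_max: int = 80
    draft_split_fraction: float = 0.1
    draft_split_overlap: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_content", "alt_frag_fraction", "terminal_frag_fraction",
                     "error_rate", "draft_split_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frag_mean < self.read_len:
            raise ValueError("frag_mean must be >= read_len")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.length_min < 2 * self.telomere_len + 100:
            raise ValueError(
                "length_min must be >= 2*telomere_len + 100 "
                "(chromosomes need a genomic core)")


@dataclass
class Chromosome:
    id: str
    seq: str                 # haplotype-A sequence including both telomeres
    copy_number: float       # relative amplification (mean 1 over the genome)
    het_positions: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    het_bases: np.ndarray = field(default_factory=lambda: np.empty(0, "U1"))

    def hap_seq(self, hap: int) -> str:
        if hap == 0 or len(self.het_positions) == 0:
            return self.seq
        arr = np.frombuffer(self.seq.encode(), dtype="S1").copy()
        arr[self.het_positions] = self.het_bases.astype("S1")
        return arr.tobytes().decode()


@dataclass
class Isoform:
    """A shorter telomere-capped product of alternative fragmentation.

    ``breakpoint`` is the internal telomere-addition coordinate on the
    parent (0-based, first base of the right-hand part).  The ``left``
    isoform shares the parent's left telomere and gains a G-rich
    telomere at the breakpoint; the ``right`` isoform is the
    complementary product with a fresh C-rich telomere.
    """

    parent_id: str
    breakpoint: int
    side: str                # 'left' or 'right'
    weight: float            # abundance relative to the parent (parent = 1)


@dataclass
class TruthSet:
    """Planted ground truth against which all recovery tests run."""

    params: SimParams
    chromosomes: list[Chromosome]
    isoforms: list[Isoform]

    def chromosome(self, cid: str) -> Chromosome:
        return self._index[cid]

    def __post_init__(self) -> None:
        self._index = {c.id: c for c in self.chromosomes}

    def isoform_seq(self, iso: Isoform, hap: int = 0) -> str:
        parent = self.chromosome(iso.parent_id).hap_seq(hap)
        tel = _telomere(self.params)
        if iso.side == "left":
            return parent[: iso.breakpoint] + revcomp(tel)
        return tel + parent[iso.breakpoint:]

    def truth_table(self) -> pd.DataFrame:
        rows = [
            {"id": c.id, "length": len(c.seq), "copy_number": c.copy_number,
             "n_het": len(c.het_positions)}
            for c in self.chromosomes
        ]
        return pd.DataFrame(rows)

    def isoform_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"parent_id": i.parent_id, "breakpoint": i.breakpoint,
              "side": i.side, "weight": i.weight} for i in self.isoforms],
            columns=["parent_id", "breakpoint", "side", "weight"])


def _telomere(params: SimParams) -> str:
    u = params.telomere_unit
    return (u * (params.telomere_len // len(u) + 1))[: params.telomere_len]


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def simulate_genome(params: SimParams) -> TruthSet:
    """Generate the planted chromosome set (deterministic under the seed).

    Every chromosome is ``telomere + core + revcomp(telomere)``;
    alternatively fragmented chromosomes additionally get a left and a
    right isoform around one strictly internal breakpoint (>= 100 bp
    from either telomere).
    """
    rng = np.random.default_rng([int(params.seed), 0])
    tel = _telomere(params)
    n = params.n_chromosomes

    lengths = np.exp(rng.normal(math.log(params.length_median),
                                params.length_sigma, size=n))
    lengths = np.clip(np.round(lengths).astype(int),
                      params.length_min, params.length_max)

    copies = np.exp(rng.normal(0.0, params.copy_sigma, size=n))
    copies = copies / copies.mean()

    alt = rng.random(n) < params.alt_frag_fraction

    chromosomes: list[Chromosome] = []
    isoforms: list[Isoform] = []
    width = max(4, len(str(n)))
    for i in range(n):
        core_len = int(lengths[i]) - 2 * params.telomere_len
        core = _random_seq(rng, core_len, params.gc_content)
        seq = tel + core + revcomp(tel)
        cid = f"chr{i:0{width}d}"

        n_het = int(rng.binomial(core_len, params.heterozygosity))
        if n_het:
            het_pos = (np.sort(rng.choice(core_len, size=n_het, replace=False))
                       + params.telomere_len).astype(int)
        else:
            het_pos = np.empty(0, int)
        ref = np.frombuffer(seq.encode(), dtype="S1")
        het_base = np.empty(n_het, dtype="U1")
        for j, p in enumerate(het_pos):
            choices = [b for b in "ACGT" if b.encode() != ref[p]]
            het_base[j] = choices[rng.integers(3)]

        chrom = Chromosome(id=cid, seq=seq, copy_number=float(copies[i]),
                           het_positions=het_pos, het_bases=het_base)
        chromosomes.append(chrom)

        if alt[i]:
            lo = params.telomere_len + 100
            hi = len(seq) - params.telomere_len - 100
            bp = int(rng.integers(lo, hi))
            w = params.alt_frag_isoform_weight
            isoforms.append(Isoform(cid, bp, "left", w))
            isoforms.append(Isoform(cid, bp, "right", w))

    logger.info("simulated %d chromosomes (%d alternatively fragmented)",
                n, int(alt.sum()))
    return TruthSet(params=params, chromosomes=chromosomes, isoforms=isoforms)


class _Molecule:
    """One sequencable species: (chromosome | isoform) x haplotype."""

    __slots__ = ("name", "seq", "weight", "parent_id", "offset", "is_isoform",
                 "side", "tel_len")

    def __init__(self, name, seq, weight, parent_id, offset, is_isoform, side,
                 tel_len):
        self.name = name
        self.seq = seq
        self.weight = weight
        self.parent_id = parent_id
        self.offset = offset          # molecule position 0 in parent coords
        self.is_isoform = is_isoform
        self.side = side
        self.tel_len = tel_len


def _molecules(truth: TruthSet) -> list[_Molecule]:
    params = truth.params
    mols: list[_Molecule] = []
    for chrom in truth.chromosomes:
        for hap in (0, 1):
            mols.append(_Molecule(
                name=f"{chrom.id}.h{hap}", seq=chrom.hap_seq(hap),
                weight=chrom.copy_number / 2.0, parent_id=chrom.id, offset=0,
                is_isoform=False, side="", tel_len=params.telomere_len))
    for iso in truth.isoforms:
        chrom = truth.chromosome(iso.parent_id)
        for hap in (0, 1):
            seq = truth.isoform_seq(iso, hap)
            offset = 0 if iso.side == "left" else iso.breakpoint - params.telomere_len
            mols.append(_Molecule(
                name=f"{iso.parent_id}.{iso.side}.h{hap}", seq=seq,
                weight=iso.weight * chrom.copy_number / 2.0,
                parent_id=iso.parent_id, offset=offset, is_isoform=True,
                side=iso.side, tel_len=params.telomere_len))
    return mols


def simulate_reads(truth: TruthSet,
                   params: SimParams | None = None
                   ) -> tuple[list[ReadPair], pd.DataFrame]:
    """Draw paired-end reads from the truth set.

    Fragments are sampled across molecules with probability proportional
    to copy-number weight x molecule length, so expected per-chromosome
    depth is proportional to planted copy number.  Outer distance is
    Normal(frag_mean, frag_sd) truncated to [read_len, molecule length];
    a ``terminal_frag_fraction`` of fragments is anchored at a molecule
    end (with telomere-addition jitter, see module docstring); mates are
    inward-oriented; substitution errors are i.i.d. at ``error_rate``.

    Returns the pairs and a provenance table (one row per pair) with the
    molecule, fragment coordinates and planted error offsets.
    """
    params = params or truth.params
    rng = np.random.default_rng([int(params.seed), 1])
    mols = _molecules(truth)
    weights = np.array([m.weight * len(m.seq) for m in mols])
    probs = weights / weights.sum()

    # Pair count chosen so that a copy-number-1 chromosome gets `coverage`
    # mean depth; isoform molecules add their share on top.
    n_pairs = int(round(params.coverage * weights.sum() / (2 * params.read_len)))
    smallest = min(len(m.seq) for m in mols)
    if params.coverage * smallest / (2 * params.read_len) < 1:
        logger.warning("coverage yields < 1 expected pair for the smallest molecule")

    mol_idx = rng.choice(len(mols), size=n_pairs, p=probs)
    frag_lens = np.round(rng.normal(params.frag_mean, params.frag_sd,
                                    size=n_pairs)).astype(int)
    is_terminal = rng.random(n_pairs) < params.terminal_frag_fraction
    term_side = rng.integers(2, size=n_pairs)  # 0 = 5' end, 1 = 3' end
    jitters = np.maximum(0, np.round(rng.normal(
        0.0, params.tas_jitter_sd, size=n_pairs))).astype(int)
    u_start = rng.random(n_pairs)

    L = params.read_len
    qual = "I" * L
    pairs: list[ReadPair] = []
    prov_rows = []
    for i in range(n_pairs):
        m = mols[mol_idx[i]]
        mlen = len(m.seq)
        F = int(min(max(frag_lens[i], L), mlen))
        if is_terminal[i]:
            t = int(min(jitters[i], mlen - F))  # keep the fragment inside
            tel = m.tel_len
            if term_side[i] == 0:
                # 5'-terminal: full left telomere, genomic side trimmed by t
                frag = m.seq[:tel] + m.seq[tel + t: t + F]
                start = 0
            else:
                # 3'-terminal: genomic side trimmed by t, full right telomere
                frag = m.seq[mlen - F - t: mlen - tel - t] + m.seq[mlen - tel:]
                start = mlen - F - t
            jit = t
        else:
            start = int(u_start[i] * (mlen - F + 1))
            frag = m.seq[start: start + F]
            jit = 0

        mate1 = frag[:L]
        mate2 = revcomp(frag[-L:])
        e1 = _plant_errors(rng, mate1, params.error_rate)
        e2 = _plant_errors(rng, mate2, params.error_rate)
        mate1, err1 = e1
        mate2, err2 = e2
        rid = f"read{i:07d}"
        pairs.append(ReadPair(id=rid, seq1=mate1, seq2=mate2,
                              qual1=qual, qual2=qual))
        prov_rows.append({
            "read_id": rid, "molecule": m.name, "parent_id": m.parent_id,
            "frag_start": start, "frag_len": F,
            "terminal": "53"[term_side[i]] if is_terminal[i] else ".",
            "jitter": jit,
            "errors1": ",".join(map(str, err1)), "errors2": ",".join(map(str, err2)),
        })
    logger.info("simulated %d read pairs from %d molecules", n_pairs, len(mols))
    return pairs, pd.DataFrame(prov_rows)


def _plant_errors(rng: np.random.Generator, seq: str,
                  rate: float) -> tuple[str, list[int]]:
    if rate <= 0:
        return seq, []
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq, []
    pos = sorted(rng.choice(len(seq), size=n_err, replace=False).tolist())
    arr = list(seq)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(3)]
    return "".join(arr), pos


def make_draft(truth: TruthSet,
               params: SimParams | None = None
               ) -> tuple[list[Contig], pd.DataFrame]:
    """Degrade the truth into a draft: trim contig ends, optionally split.

    Each chromosome yields one contig with an independent uniform
    [0, draft_trim_max] trim at each end (emulating assembler telomere
    loss); a ``draft_split_fraction`` of chromosomes is instead emitted
    as two pieces overlapping by ``draft_split_overlap`` bp to exercise
    overlap merging.  Returns the contigs and a table mapping each
    contig back to its truth interval.
    """
    params = params or truth.params
    rng = np.random.default_rng([int(params.seed), 2])
    contigs: list[Contig] = []
    rows = []
    for chrom in truth.chromosomes:
        L = len(chrom.seq)
        tl = int(rng.integers(0, params.draft_trim_max + 1))
        tr = int(rng.integers(0, params.draft_trim_max + 1))
        if tl + tr >= L:
            raise ValueError(f"trim exceeds chromosome length for {chrom.id}")
        piece = chrom.seq[tl: L - tr]
        split = (rng.random() < params.draft_split_fraction
                 and len(piece) >= 2 * params.draft_split_overlap + 400)
        if split:
            ov = params.draft_split_overlap
            cut = int(rng.integers(200, len(piece) - 200 - ov))
            a, b = piece[: cut + ov], piece[cut:]
            contigs.append(Contig(id=f"{chrom.id}_ctgA", seq=a))
            contigs.append(Contig(id=f"{chrom.id}_ctgB", seq=b))
            rows.append({"contig_id": f"{chrom.id}_ctgA", "chrom": chrom.id,
                         "truth_start": tl, "truth_end": tl + len(a)})
            rows.append({"contig_id": f"{chrom.id}_ctgB", "chrom": chrom.id,
                         "truth_start": tl + cut, "truth_end": L - tr})
        else:
            contigs.append(Contig(id=f"{chrom.id}_ctg", seq=piece))
            rows.append({"contig_id": f"{chrom.id}_ctg", "chrom": chrom.id,
                         "truth_start": tl, "truth_end": L - tr})
    logger.info("draft: %d contigs from %d chromosomes",
                len(contigs), len(truth.chromosomes))
    return contigs, pd.DataFrame(rows)
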
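"""Deterministic, self-contained paired-end read mapper.

Gapless seed-and-extend alignment against a k-mer index of the contigs,
with an explicit mismatch budget and two modes:

``strict``
    The extension contract: the read must align full-length inside a
    contig with at most ``strict_max_mismatch`` substitutions (default
    1, i.e. "zero or one substitution").

``lenient``
    The coverage/depth contract: >= ``lenient_min_identity`` identical
    matches over the aligned region (default 0.90) covering at least
    ``lenient_min_aligned_fraction`` of the read length (default 0.70);
    placements may be clipped at contig ends.

Only substitutions are modelled (Illumina substitution errors dominate
and the strict rule is substitution-phrased); reads containing indels
simply fail the thresholds.  The best placement is the one with fewest
mismatches, ties broken by (lowest contig id, lowest coordinate, then
``+`` before ``-``), which makes the mapper's output reproducible and
directly comparable to an exhaustive Hamming-distance oracle.

Alignment is vectorised over reads: seeds are non-overlapping k-mers of
the read (plus the final k-mer), so any placement with fewer mismatches
than seeds is guaranteed to be found.  N bases count as mismatches and
never seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .types import AlignmentRecord, Contig, ReadPair

logger = logging.getLogger(__name__)

__all__ = [
    "MapperParams",
    "KmerIndex",
    "build_index",
    "BatchAlignments",
    "map_batch",
    "map_read",
    "PairAlignment",
    "map_pairs",
]

_SEP = np.int8(4)          # inter-contig separator code
_CONTIG_N = np.int8(5)
_READ_N = np.int8(6)
_PAD = 256                 # separator/pad run length; must exceed read length

_ENC_CONTIG = np.full(256, _CONTIG_N, dtype=np.int8)
_ENC_READ = np.full(256, _READ_N, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENC_CONTIG[_b] = _i
    _ENC_READ[_b] = _i


def encode_contig(seq: str) -> np.ndarray:
    return _ENC_CONTIG[np.frombuffer(seq.encode(), dtype=np.uint8)]


def encode_reads(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length reads into an (n, L) int8 matrix."""
    joined = "".join(seqs).encode()
    return _ENC_READ[np.frombuffer(joined, dtype=np.uint8)].reshape(len(seqs), -1)


def revcomp_codes(mat: np.ndarray) -> np.ndarray:
    rc = np.where(mat < 4, 3 - mat, mat)
    return rc[..., ::-1]


@dataclass
class MapperParams:
    """Mapping thresholds; see the module docstring for the two modes."""

    k: int = 21
    mode: str = "lenient"
    strict_max_mismatch: int = 1
    lenient_min_identity: float = 0.90
    lenient_min_aligned_fraction: float = 0.70
    proper_pair_min: int = 83     # library mean - 4 SD (163 - 80)
    proper_pair_max: int = 243    # library mean + 4 SD

    def __post_init__(self) -> None:
        if not (0 < self.lenient_min_identity <= 1):
            raise ValueError("lenient_min_identity must be in (0, 1]")
        if not (0 < self.lenient_min_aligned_fraction <= 1):
            raise ValueError("lenient_min_aligned_fraction must be in (0, 1]")
        if self.mode not in ("strict", "lenient"):
            raise ValueError("mode must be 'strict' or 'lenient'")


class KmerIndex:
    """Every-position k-mer index over a contig set.

    Contigs are laid out (sorted by id) in one padded array with
    separator runs longer than any read, so a candidate window can
    overlap at most one contig.  Desk-scale genomes (tens of Mb) make a
    full every-position index affordable; no minimizers.
    """

    def __init__(self, contigs: Sequence[Contig], k: int = 21):
        if not contigs:
            raise ValueError("cannot index an empty contig list")
        self.k = int(k)
        self.contigs = sorted(contigs, key=lambda c: c.id)
        self.ids = [c.id for c in self.contigs]
        lengths = np.array([len(c.seq) for c in self.contigs], dtype=np.int64)
        self.lengths = lengths

        starts = np.empty(len(self.contigs), dtype=np.int64)
        chunks = []
        pos = 0
        pad = np.full(_PAD, _SEP, dtype=np.int8)
        chunks.append(pad)
        pos += _PAD
        n_short = 0
        for i, c in enumerate(self.contigs):
            starts[i] = pos
            chunks.append(encode_contig(c.seq))
            pos += lengths[i]
            chunks.append(pad)
            pos += _PAD
            if lengths[i] < self.k:
                n_short += 1
        if n_short:
            logger.info("%d contig(s) shorter than k=%d are unmappable",
                        n_short, self.k)
        self.genome = np.concatenate(chunks)
        self.starts = starts
        self.ends = starts + lengths

        g = self.genome.astype(np.int64)
        pows = 4 ** np.arange(self.k - 1, -1, -1, dtype=np.int64)
        n_win = len(g) - self.k + 1
        codes = np.empty(n_win, dtype=np.int64)
        chunk = 1 << 20
        for ofs in range(0, n_win, chunk):
            end = min(ofs + chunk, n_win)
            win = np.lib.stride_tricks.sliding_window_view(
                g[ofs: end + self.k - 1], self.k)
            codes[ofs:end] = win @ pows
        bad = np.concatenate([[0], np.cumsum(g >= 4)])
        valid = (bad[self.k:] - bad[:-self.k]) == 0
        vpos = np.nonzero(valid)[0].astype(np.int64)
        vcodes = codes[vpos]
        order = np.argsort(vcodes, kind="stable")
        self.sorted_codes = vcodes[order]
        self.sorted_pos = vpos[order]

    def contig_of(self, gpos: np.ndarray) -> np.ndarray:
        """Contig index of the (single) contig a window at *gpos* overlaps."""
        return np.searchsorted(self.ends, gpos, side="right")


def build_index(contigs: Sequence[Contig], k: int = 21) -> KmerIndex:
    return KmerIndex(contigs, k=k)


@dataclass
class BatchAlignments:
    """Column-oriented best alignments for a batch of reads.

    ``mapped`` masks reads with an accepted placement; coordinate
    fields are only meaningful where ``mapped`` is true.
    """

    index: KmerIndex
    mapped: np.ndarray          # bool (n,)
    contig_idx: np.ndarray      # int32
    start: np.ndarray           # int64, clipped contig-local
    end: np.ndarray             # int64
    strand: np.ndarray          # int8: 0 = '+', 1 = '-'
    n_mismatch: np.ndarray      # int32, within aligned region
    aligned: np.ndarray         # int32 aligned bases

    def record(self, i: int, read_id: str, mate: int,
               read_len: int) -> AlignmentRecord | None:
        if not self.mapped[i]:
            return None
        return AlignmentRecord(
            read_id=read_id, mate=mate,
            contig_id=self.index.ids[self.contig_idx[i]],
            start=int(self.start[i]), end=int(self.end[i]),
            strand="+-"[self.strand[i]],
            n_mismatch=int(self.n_mismatch[i]),
            aligned_fraction=float(self.aligned[i]) / read_len,
        )


def _seed_offsets(L: int, k: int) -> list[int]:
    offs = list(range(0, L - k + 1, k))
    if offs[-1] != L - k:
        offs.append(L - k)
    return offs


def _candidates(index: KmerIndex, mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All candidate (read_idx, genome window start) pairs for one strand."""
    n, L = mat.shape
    k = index.k
    pows = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    sc, sp = index.sorted_codes, index.sorted_pos
    r_parts, p_parts = [], []
    for off in _seed_offsets(L, k):
        codes = mat[:, off:off + k].astype(np.int64) @ pows
        lo = np.searchsorted(sc, codes, side="left")
        hi = np.searchsorted(sc, codes, side="right")
        cnt = hi - lo
        tot = int(cnt.sum())
        if tot == 0:
            continue
        read_idx = np.repeat(np.arange(n, dtype=np.int64), cnt)
        cum = np.concatenate([[0], np.cumsum(cnt)[:-1]])
        flat = np.repeat(lo - cum, cnt) + np.arange(tot)
        r_parts.append(read_idx)
        p_parts.append(sp[flat] - off)
    if not r_parts:
        return (np.empty(0, np.int64), np.empty(0, np.int64))
    read_idx = np.concatenate(r_parts)
    gpos = np.concatenate(p_parts)
    key = read_idx * np.int64(len(index.genome) + _PAD) + gpos
    _, keep = np.unique(key, return_index=True)
    return read_idx[keep], gpos[keep]


def _verify(index: KmerIndex, mat: np.ndarray, read_idx: np.ndarray,
            gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mismatches-within-alignment and aligned length for each candidate."""
    L = mat.shape[1]
    m = len(read_idx)
    mism_in = np.empty(m, dtype=np.int32)
    aligned = np.empty(m, dtype=np.int32)
    chunk = 1 << 16
    offsets = np.arange(L, dtype=np.int64)
    genome = index.genome
    for ofs in range(0, m, chunk):
        end = min(ofs + chunk, m)
        win = genome[gpos[ofs:end, None] + offsets]
        reads = mat[read_idx[ofs:end]]
        mism = np.count_nonzero(win != reads, axis=1).astype(np.int32)
        outside = np.count_nonzero(win == _SEP, axis=1).astype(np.int32)
        aligned[ofs:end] = L - outside
        mism_in[ofs:end] = mism - outside
    return mism_in, aligned


def map_batch(seqs: Sequence[str], index: KmerIndex,
              params: MapperParams, mode: str | None = None) -> BatchAlignments:
    """Best-only placements for a batch of (possibly mixed-length) reads."""
    mode = mode or params.mode
    n = len(seqs)
    out = BatchAlignments(
        index=index,
        mapped=np.zeros(n, bool),
        contig_idx=np.zeros(n, np.int32),
        start=np.zeros(n, np.int64),
        end=np.zeros(n, np.int64),
        strand=np.zeros(n, np.int8),
        n_mismatch=np.zeros(n, np.int32),
        aligned=np.zeros(n, np.int32),
    )
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    for L, idxs in sorted(by_len.items()):
        if L < index.k or L > _PAD:
            continue
        _map_uniform([seqs[i] for i in idxs], np.array(idxs), index, params,
                     mode, out)
    return out


def _map_uniform(seqs: list[str], orig_idx: np.ndarray, index: KmerIndex,
                 params: MapperParams, mode: str, out: BatchAlignments) -> None:
    mat = encode_reads(seqs)
    n, L = mat.shape
    rc = np.ascontiguousarray(revcomp_codes(mat))

    all_read, all_gpos, all_strand, all_mism, all_aligned = [], [], [], [], []
    for strand, m in ((0, mat), (1, rc)):
        read_idx, gpos = _candidates(index, m)
        if len(read_idx) == 0:
            continue
        mism_in, aligned = _verify(index, m, read_idx, gpos)
        if mode == "strict":
            ok = (aligned == L) & (mism_in <= params.strict_max_mismatch)
        else:
            min_aligned = int(math.ceil(params.lenient_min_aligned_fraction * L - 1e-9))
            ok = (aligned >= min_aligned) & \
                 ((aligned - mism_in).astype(np.float64)
                  >= params.lenient_min_identity * aligned - 1e-9)
        if not ok.any():
            continue
        all_read.append(read_idx[ok])
        all_gpos.append(gpos[ok])
        all_strand.append(np.full(int(ok.sum()), strand, np.int8))
        all_mism.append(mism_in[ok])
        all_aligned.append(aligned[ok])
    if not all_read:
        return

    read_idx = np.concatenate(all_read)
    gpos = np.concatenate(all_gpos)
    strand = np.concatenate(all_strand)
    mism = np.concatenate(all_mism)
    aligned = np.concatenate(all_aligned)

    ci = index.contig_of(gpos)
    local = gpos - index.starts[ci]
    start = np.maximum(local, 0)
    end = np.minimum(local + L, index.lengths[ci])

    order = np.lexsort((strand, start, ci, mism, read_idx))
    first = np.unique(read_idx[order], return_index=True)[1]
    sel = order[first]

    oi = orig_idx[read_idx[sel]]
    out.mapped[oi] = True
    out.contig_idx[oi] = ci[sel]
    out.start[oi] = start[sel]
    out.end[oi] = end[sel]
    out.strand[oi] = strand[sel]
    out.n_mismatch[oi] = mism[sel]
    out.aligned[oi] = aligned[sel]


def map_read(read: str, index: KmerIndex, params: MapperParams,
             mode: str | None = None, read_id: str = "read",
             mate: int = 1) -> AlignmentRecord | None:
    """Best placement of a single read, or None if it fails the mode."""
    batch = map_batch([read], index, params, mode=mode)
    return batch.record(0, read_id, mate, len(read))


@dataclass
class PairAlignment:
    pair_id: str
    rec1: AlignmentRecord | None
    rec2: AlignmentRecord | None
    properly_paired: bool
    outer_distance: int | None


def pair_flags(index: KmerIndex, b1: BatchAlignments, b2: BatchAlignments,
               params: MapperParams) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised proper-pair test for two mate batches.

    Proper = both mapped, same contig, opposite strands, inward
    orientation, outer distance within [proper_pair_min, proper_pair_max].
    Returns (proper mask, outer distance; -1 where not proper).
    """
    both = b1.mapped & b2.mapped
    same = both & (b1.contig_idx == b2.contig_idx)
    opp = same & (b1.strand != b2.strand)
    plus_start = np.where(b1.strand == 0, b1.start, b2.start)
    minus_start = np.where(b1.strand == 1, b1.start, b2.start)
    minus_end = np.where(b1.strand == 1, b1.end, b2.end)
    inward = opp & (plus_start <= minus_start)
    outer = minus_end - plus_start
    proper = inward & (outer >= params.proper_pair_min) & \
        (outer <= params.proper_pair_max)
    return proper, np.where(proper, outer, -1)


def map_pairs(pairs: Iterable[ReadPair], index: KmerIndex,
              params: MapperParams, mode: str | None = None
              ) -> Iterator[PairAlignment]:
    """Map both mates of each pair (best-only) and set pairing flags."""
    pairs = list(pairs)
    b1 = map_batch([p.seq1 for p in pairs], index, params, mode=mode)
    b2 = map_batch([p.seq2 for p in pairs], index, params, mode=mode)
    proper, outer = pair_flags(index, b1, b2, params)
    n_proper = int(proper.sum())
    n_both = int((b1.mapped & b2.mapped).sum())
    logger.info("mapped pairs: %d/%d both-mapped, %d properly paired",
                n_both, len(pairs), n_proper)
    for i, p in enumerate(pairs):
        r1 = b1.record(i, p.id, 1, len(p.seq1))
        r2 = b2.record(i, p.id, 2, len(p.seq2))
        if proper[i]:
            r1.properly_paired = True
            r2.properly_paired = True
        yield PairAlignment(pair_id=p.id, rec1=r1, rec2=r2,
                            properly_paired=bool(proper[i]),
                            outer_distance=int(outer[i]) if proper[i] else None)
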
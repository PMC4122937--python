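"""Core domain types shared by every pipeline stage.

The unit of assembly is the :class:`Contig`, a DNA sequence with a
per-end telomere state.  Reads enter the pipeline as :class:`ReadPair`
objects (inward-oriented Illumina mates) and read placements are
expressed as :class:`AlignmentRecord` objects.  All coordinates in the
toolkit are 0-based half-open on the contig forward strand; 1-based
coordinates appear only in human-readable reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "DNA_ALPHABET",
    "revcomp",
    "validate_dna",
    "Contig",
    "ReadPair",
    "AlignmentRecord",
]

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, name: str = "sequence") -> None:
    """Raise ``ValueError`` naming the offending record if *seq* contains
    characters outside {A,C,G,T,N}.  RNA input (U) is rejected."""
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(
            f"{name}: illegal character(s) {sorted(bad)!r}; "
            "sequences must be uppercase DNA over A,C,G,T,N"
        )


@dataclass
class Contig:
    """A contig (or finished nanochromosome) with per-end telomere state.

    ``left_telomere``/``right_telomere`` report whether a C-rich
    (respectively G-rich) telomeric repeat caps the corresponding end;
    the ``*_telomere_len`` fields hold the measured repeat run in bp.
    Flags are meaningful only after classification (``classified`` is
    set by :func:`nanoterm.telomere.classify_contig`).
    """

    id: str
    seq: str
    left_telomere: bool = False
    right_telomere: bool = False
    left_telomere_len: int = 0
    right_telomere_len: int = 0
    classified: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"contig {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def n_telomeres(self) -> int:
        return int(self.left_telomere) + int(self.right_telomere)

    def check_invariants(self) -> None:
        if (self.left_telomere_len == 0) != (not self.left_telomere):
            raise ValueError(f"contig {self.id!r}: left telomere flag/length disagree")
        if (self.right_telomere_len == 0) != (not self.right_telomere):
            raise ValueError(f"contig {self.id!r}: right telomere flag/length disagree")
        if self.left_telomere_len + self.right_telomere_len > len(self.seq):
            raise ValueError(f"contig {self.id!r}: telomere lengths exceed contig length")


@dataclass
class ReadPair:
    """Two inward-oriented mates with Phred+33 quality strings."""

    id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str

    def __post_init__(self) -> None:
        if not self.seq1 or not self.seq2:
            raise ValueError(f"read pair {self.id!r}: empty mate sequence")
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(
                f"read pair {self.id!r}: sequence/quality length mismatch"
            )

    def mate(self, which: int) -> str:
        if which == 1:
            return self.seq1
        if which == 2:
            return self.seq2
        raise ValueError("mate index must be 1 or 2")


@dataclass
class AlignmentRecord:
    """Gapless placement of one read (or stripped read) on one contig.

    ``start``/``end`` are 0-based half-open on the contig forward
    strand and are clipped to the contig, so ``end - start`` is the
    aligned length; ``aligned_fraction`` is that length over the full
    read length.  ``n_mismatch`` counts mismatches inside the aligned
    region only (N counts as a mismatch).
    """

    read_id: str
    mate: int
    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    n_mismatch: int
    aligned_fraction: float
    properly_paired: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"alignment {self.read_id!r}: bad interval")
        if self.strand not in "+-":
            raise ValueError(f"alignment {self.read_id!r}: bad strand")
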
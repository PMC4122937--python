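"""Detection, measurement and stripping of the C4A4-type telomeric repeat.

Nanochromosomes of stichotrichous ciliates are capped by short tandem
``CCCCAAAA`` repeats: the C-rich strand 5' end reads
``CCCCAAAACCCCAAAA...`` and the complementary G-rich repeat
(``GGGGTTTT...``) terminates the 3' end of the same strand.  This module
classifies contigs as 0/1/2-telomere, and selects and strips telomeric
reads for telomere-addition-site analysis.

Two different tolerance regimes are used on purpose: *read* selection is
an exact prefix match on a 2.5-unit selector (precision matters — every
selected read becomes site evidence), while *contig end* classification
tolerates a configurable mismatch rate (recall matters — assembled
consensus may carry allelic or erroneous bases).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

from .types import Contig, ReadPair, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "TelomereSpec",
    "classify_contig",
    "count_telomeres",
    "strip_telomeric_prefix",
    "select_and_strip_telomeric_reads",
    "StrippedRead",
]


@dataclass
class TelomereSpec:
    """Parameters of the telomeric repeat and its detection.

    ``unit``
        The repeat unit on the C-rich strand (default ``CCCCAAAA``).
    ``read_selector``
        Literal prefix a read must start with to count as telomeric
        (default 2.5 units, ``CCCCAAAACCCCAAAACCCC``); selection is
        exact-match.
    ``min_contig_run``
        Minimum repeat run (bp) for a contig end to count as capped.
    ``end_window``
        A capping telomere must begin within this many bp of the contig
        terminus; tolerates small adapter/junk overhangs without
        mistaking internal repeats for caps.
    ``max_mismatch_per_20bp``
        Mismatch allowance for contig-end runs (1 mismatch per started
        20 bp by default); read selection ignores this.
    """

    unit: str = "CCCCAAAA"
    read_selector: str = "CCCCAAAACCCCAAAACCCC"
    min_contig_run: int = 16
    end_window: int = 30
    max_mismatch_per_20bp: int = 1
    min_residual: int = 20  # stripped reads shorter than this are discarded

    def __post_init__(self) -> None:
        n = len(self.read_selector)
        tiled = (self.unit * (n // len(self.unit) + 1))[:n]
        if self.read_selector != tiled:
            raise ValueError("read_selector must be a prefix-repetition of unit")
        if self.min_contig_run < len(self.unit):
            raise ValueError("min_contig_run must be >= len(unit)")


_SCAN_CAP = 512  # longest repeat run we ever try to measure at a contig end


def _repeat_run(seq: str, start: int, unit: str, phase: int,
                budget_per_20: int) -> tuple[int, int] | None:
    """Longest mismatch-tolerant repeat run at *start* for one unit phase.

    A run of length r may contain at most ``budget_per_20 * floor(r/20)``
    mismatches (i.e. one mismatch per completed 20 bp by default) and
    must end on a matching base, so a trailing mismatch never inflates
    the measured run.  Returns (run_length, n_mismatch) of the longest
    admissible run, or None.
    """
    u = len(unit)
    limit = min(_SCAN_CAP, len(seq) - start)
    hard_budget = budget_per_20 * (limit // 20 + 1)
    mism = 0
    good_run: tuple[int, int] | None = None
    for i in range(limit):
        if seq[start + i] != unit[(phase + i) % u]:
            mism += 1
            if mism > hard_budget:
                break
            continue
        if mism <= budget_per_20 * ((i + 1) // 20):
            good_run = (i + 1, mism)
    return good_run


def _exact_run(seq: str, unit: str, phase: int) -> int:
    u = len(unit)
    i = 0
    n = len(seq)
    while i < n and seq[i] == unit[(phase + i) % u]:
        i += 1
    return i


def _scan_left(seq: str, spec: TelomereSpec) -> int:
    """Telomere run length at the left (low-coordinate) end, 0 if none.

    Scans for either repeat sense so that contigs supplied on an
    arbitrary strand are still recognised.  The common case (an exact
    run at position 0) is checked first; the mismatch-tolerant sliding
    scan over ``end_window`` start positions is the fallback.
    """
    units = (spec.unit, revcomp(spec.unit))
    best = 0
    for unit in units:
        for phase in range(len(unit)):
            run = _exact_run(seq, unit, phase)
            if run >= spec.min_contig_run:
                best = max(best, run)
    if best and spec.max_mismatch_per_20bp == 0:
        return best
    for unit in units:
        for start in range(0, min(spec.end_window, max(len(seq) - 1, 0)) + 1):
            ch = seq[start]
            for phase in range(len(unit)):
                if unit[phase] != ch:
                    continue  # a run opening on a mismatch adds nothing new
                hit = _repeat_run(seq, start, unit, phase,
                                  spec.max_mismatch_per_20bp)
                if hit and hit[0] >= spec.min_contig_run:
                    best = max(best, hit[0])
    return best


def classify_contig(contig: Contig, spec: TelomereSpec | None = None) -> Contig:
    """Set telomere flags and run lengths on *contig* (in place; returned).

    The left end is scanned for a repeat run beginning within
    ``end_window`` bp of position 0, the right end for a run ending
    within ``end_window`` bp of the terminus (by scanning the reverse
    complement).  Contigs shorter than ``min_contig_run`` get both
    flags false.
    """
    spec = spec or TelomereSpec()
    left = _scan_left(contig.seq, spec) if len(contig.seq) >= spec.min_contig_run else 0
    right = _scan_left(revcomp(contig.seq), spec) if len(contig.seq) >= spec.min_contig_run else 0
    # Cap the recorded lengths so both ends together never exceed the contig.
    if left + right > len(contig.seq):
        overshoot = left + right - len(contig.seq)
        right = max(0, right - overshoot)
    contig.left_telomere = left > 0
    contig.left_telomere_len = left
    contig.right_telomere = right > 0
    contig.right_telomere_len = right
    contig.classified = True
    return contig


def classify_all(contigs: Iterable[Contig], spec: TelomereSpec | None = None) -> list[Contig]:
    spec = spec or TelomereSpec()
    return [classify_contig(c, spec) for c in contigs]


def count_telomeres(assembly: Iterable[Contig]) -> int:
    """Total telomere tally: 2 x (2-telomere contigs) + (1-telomere contigs)."""
    total = 0
    for c in assembly:
        if not c.classified:
            raise ValueError(f"contig {c.id!r} has not been classified")
        total += c.n_telomeres
    return total


def strip_telomeric_prefix(seq: str, spec: TelomereSpec | None = None) -> int:
    """Length of the maximal leading telomeric run of *seq*.

    Returns 0 unless *seq* begins exactly with ``read_selector``;
    otherwise the run is extended greedily through whole and partial
    units (exact match, phase anchored at position 0).  Because the
    residual after stripping can no longer begin with the selector, the
    operation is idempotent.
    """
    spec = spec or TelomereSpec()
    if not seq.startswith(spec.read_selector):
        return 0
    u = spec.unit
    i = len(spec.read_selector)
    while i < len(seq) and seq[i] == u[i % len(u)]:
        i += 1
    return i


@dataclass
class StrippedRead:
    """A selected telomeric read after removal of its leading repeat."""

    pair: ReadPair
    mate: int               # 1 or 2
    oriented_rc: bool       # True if the mate was reverse-complemented first
    residual: str           # read sequence after stripping
    strip_len: int


def select_and_strip_telomeric_reads(
    pairs: Iterable[ReadPair], spec: TelomereSpec | None = None
) -> Iterator[StrippedRead]:
    """Select read pairs with a telomere-selector mate and strip the repeat.

    A mate qualifies if it (or its reverse complement, covering reads
    that run into the G-rich repeat at their 3' end) begins exactly with
    ``read_selector``.  The maximal leading run is stripped; reads left
    shorter than ``min_residual`` are excluded and counted in the log.
    The junction sense (left/C-rich vs right/G-rich) is decided later
    from the mapped strand of the residual.
    """
    spec = spec or TelomereSpec()
    n_selected = 0
    n_too_short = 0
    for pair in pairs:
        for mate in (1, 2):
            raw = pair.mate(mate)
            for oriented_rc, seq in ((False, raw), (True, revcomp(raw))):
                strip_len = strip_telomeric_prefix(seq, spec)
                if strip_len == 0:
                    continue
                residual = seq[strip_len:]
                if len(residual) < spec.min_residual:
                    n_too_short += 1
                    break
                n_selected += 1
                yield StrippedRead(pair=pair, mate=mate, oriented_rc=oriented_rc,
                                   residual=residual, strip_len=strip_len)
                break  # a mate is counted once even if both orientations match
    logger.info("selected %d telomeric reads (%d discarded: residual < %d nt)",
                n_selected, n_too_short, spec.min_residual)
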
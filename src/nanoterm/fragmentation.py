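"""Telomere-addition-site calling and alternative-fragmentation analysis.

A chromosome end (normal or alternative) leaves a precise signature in
shotgun data: reads that begin with the telomeric repeat.  Stripping the
repeat and mapping the residual pins the junction to a single
coordinate — the first non-telomeric base.  Raw junction coordinates
from individual reads scatter over a few bp (telomere addition is
position-discrete with jitter), so nearby raw sites of the same sense
are clustered and each cluster is reported at its support-weighted mode.
Clusters away from contig ends are alternative fragmentation sites.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mapper import MapperParams, build_index, map_batch
from .telomere import TelomereSpec, select_and_strip_telomeric_reads
from .types import Contig, ReadPair

logger = logging.getLogger(__name__)

__all__ = [
    "FragsiteParams",
    "FragmentationSite",
    "call_sites",
    "alt_frag_flag",
    "compare_site_sets",
]


@dataclass
class FragsiteParams:
    """Clustering parameters for telomere-addition sites.

    Raw sites of one sense within ``cluster_window`` bp (~100 bp, the
    inspection window used for per-site read counting) form one cluster;
    sites within ``terminal_margin`` bp of a contig end are normal
    chromosome ends, everything else is internal; clusters need
    ``min_support`` reads ("at least one internally mapping telomeric
    read" suffices to flag alternative fragmentation, so the default
    is 1).
    """

    cluster_window: int = 100
    terminal_margin: int = 50
    min_support: int = 1

    def __post_init__(self) -> None:
        if self.cluster_window <= 0:
            raise ValueError("cluster_window must be positive")


@dataclass
class FragmentationSite:
    """A clustered telomere-addition position on a contig.

    ``position`` is the 0-based coordinate of the first non-telomeric
    base: for a left-sense (C-rich) junction the residual read maps
    forward and the site is its start; for a right-sense (G-rich)
    junction the residual maps reverse and the site is its end.
    """

    contig_id: str
    position: int
    end_sense: str           # 'left' or 'right'
    support: int
    is_terminal: bool

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("site support must be >= 1")
        if self.end_sense not in ("left", "right"):
            raise ValueError("end_sense must be 'left' or 'right'")


def _cluster_positions(positions: list[int], window: int
                       ) -> list[tuple[int, int]]:
    """Single-linkage clustering of sorted raw positions.

    Consecutive positions closer than *window* join one cluster; the
    reported position is the support-weighted mode (most frequent raw
    coordinate, smallest on ties) so every cluster position is
    witnessed by at least one raw site.  Returns (position, support).
    """
    out = []
    positions = sorted(positions)
    block: list[int] = []
    for p in positions + [None]:  # type: ignore[list-item]
        if block and (p is None or p - block[-1] > window):
            counts = defaultdict(int)
            for q in block:
                counts[q] += 1
            mode = min(counts, key=lambda q: (-counts[q], q))
            out.append((mode, len(block)))
            block = []
        if p is not None:
            block.append(p)
    return out


def call_sites(contigs: Sequence[Contig], pairs: Iterable[ReadPair],
               spec: TelomereSpec | None = None,
               fp: FragsiteParams | None = None,
               mp: MapperParams | None = None) -> list[FragmentationSite]:
    """Call telomere-addition sites on *contigs* from telomere-stripped reads.

    Telomeric reads are selected and stripped, the residuals are
    strict-mapped, and each mapped residual contributes one raw site.
    When the residual's partner mate also maps, it must map to the same
    contig (a cheap pair-consistency check); residuals shorter than the
    seed length are discarded and logged.
    """
    spec = spec or TelomereSpec()
    fp = fp or FragsiteParams()
    mp = mp or MapperParams()
    contigs = list(contigs)
    index = build_index(contigs, k=mp.k)
    lengths = dict(zip(index.ids, index.lengths.tolist()))

    stripped = list(select_and_strip_telomeric_reads(pairs, spec))
    n_short = sum(1 for s in stripped if len(s.residual) < mp.k)
    if n_short:
        logger.info("%d stripped reads shorter than k=%d discarded",
                    n_short, mp.k)
    stripped = [s for s in stripped if len(s.residual) >= mp.k]

    res = map_batch([s.residual for s in stripped], index, mp, mode="strict")
    partners = [s.pair.mate(2 if s.mate == 1 else 1) for s in stripped]
    pb = map_batch(partners, index, mp, mode="strict")

    raw: dict[tuple[str, str], list[int]] = defaultdict(list)
    n_used = 0
    for i in range(len(stripped)):
        if not res.mapped[i]:
            continue
        if pb.mapped[i] and pb.contig_idx[i] != res.contig_idx[i]:
            continue  # pair maps elsewhere: likely a mismapped residual
        cid = index.ids[res.contig_idx[i]]
        if res.strand[i] == 0:
            raw[(cid, "left")].append(int(res.start[i]))
        else:
            raw[(cid, "right")].append(int(res.end[i]))
        n_used += 1
    logger.info("%d stripped reads mapped into raw sites", n_used)

    sites: list[FragmentationSite] = []
    for (cid, sense), positions in sorted(raw.items()):
        L = lengths[cid]
        for pos, support in _cluster_positions(positions, fp.cluster_window):
            if support < fp.min_support:
                continue
            is_term = pos <= fp.terminal_margin or pos >= L - fp.terminal_margin
            sites.append(FragmentationSite(
                contig_id=cid, position=pos, end_sense=sense,
                support=support, is_terminal=is_term))
    sites.sort(key=lambda s: (s.contig_id, s.position, s.end_sense))
    return sites


def alt_frag_flag(sites: Iterable[FragmentationSite], contig: Contig,
                  min_support: int = 1) -> bool:
    """True iff *contig* has >= 1 internal (non-terminal) site with
    sufficient support — i.e. shows alternative fragmentation."""
    return any(s.contig_id == contig.id and not s.is_terminal
               and s.support >= min_support for s in sites)


@dataclass
class ConservationSummary:
    """Fragmentation-conservation counts over paired contigs.

    ``fraction_conserved`` is both/either: of the contig pairs where at
    least one member shows alternative fragmentation, the fraction
    where both do.
    """

    n_pairs: int
    n_both: int
    n_either: int
    n_neither: int
    site_matches: int
    site_total_a: int

    @property
    def fraction_conserved(self) -> float | None:
        return self.n_both / self.n_either if self.n_either else None


def compare_site_sets(sites_a: Sequence[FragmentationSite],
                      sites_b: Sequence[FragmentationSite],
                      pairing: Sequence[tuple[str, str]] | pd.DataFrame,
                      tolerance: int = 10,
                      min_support: int = 1,
                      contig_ids_a: Iterable[str] | None = None,
                      contig_ids_b: Iterable[str] | None = None
                      ) -> ConservationSummary:
    """Compare alternative-fragmentation calls across two assemblies.

    *pairing* maps contig ids of assembly A to their counterparts in B
    (e.g. orthologous contigs).  When the assemblies' contig id sets
    are supplied, a pairing row referencing an unknown contig raises
    ``ValueError``.  Reports both/either/neither
    alternative-fragmentation counts and, for internal sites on shared
    coordinates, per-site matches within *tolerance* bp (same sense).
    """
    if isinstance(pairing, pd.DataFrame):
        pairing = list(pairing.itertuples(index=False, name=None))
    by_contig_a = defaultdict(list)
    by_contig_b = defaultdict(list)
    for s in sites_a:
        by_contig_a[s.contig_id].append(s)
    for s in sites_b:
        by_contig_b[s.contig_id].append(s)
    known_a = set(contig_ids_a) if contig_ids_a is not None else None
    known_b = set(contig_ids_b) if contig_ids_b is not None else None

    n_both = n_either = n_neither = 0
    site_matches = 0
    site_total_a = 0
    for ida, idb in pairing:
        if known_a is not None and ida not in known_a:
            raise ValueError(f"pairing references unknown contig {ida!r}")
        if known_b is not None and idb not in known_b:
            raise ValueError(f"pairing references unknown contig {idb!r}")
        a_sites = by_contig_a.get(ida, [])
        b_sites = by_contig_b.get(idb, [])
        a_flag = any(not s.is_terminal and s.support >= min_support
                     for s in a_sites)
        b_flag = any(not s.is_terminal and s.support >= min_support
                     for s in b_sites)
        if a_flag and b_flag:
            n_both += 1
        if a_flag or b_flag:
            n_either += 1
        else:
            n_neither += 1
        internal_b = [s for s in b_sites if not s.is_terminal]
        for s in (x for x in a_sites if not x.is_terminal):
            site_total_a += 1
            if any(t.end_sense == s.end_sense
                   and abs(t.position - s.position) <= tolerance
                   for t in internal_b):
                site_matches += 1
    return ConservationSummary(
        n_pairs=len(pairing), n_both=n_both, n_either=n_either,
        n_neither=n_neither, site_matches=site_matches,
        site_total_a=site_total_a)
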
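"""Readers/writers for the standard formats the toolkit speaks.

FASTA for contigs (via Biopython), paired FASTQ (Phred+33, optionally
gzipped) for reads, TSV for tables, and BED (0-based half-open) for
telomere-addition sites.  Every writer orders records deterministically
(contig id, then coordinate) so identical runs produce byte-identical
files.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
import logging
import platform
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .types import Contig, ReadPair, validate_dna

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "read_fastq_pairs",
    "write_outputs",
    "read_bed_sites",
    "write_manifest",
]


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[Contig]:
    """Read a FASTA file into :class:`Contig` objects (telomere flags unset).

    Order is preserved and sequences are uppercased.  Non-DNA characters
    (including U) raise ``ValueError`` naming the record.
    """
    contigs: list[Contig] = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            validate_dna(seq, name=f"record {rec.id!r}")
            contigs.append(Contig(id=rec.id, seq=seq))
    logger.info("read %d contigs from %s", len(contigs), path)
    return contigs


def _strip_mate_suffix(read_id: str) -> str:
    if read_id.endswith("/1") or read_id.endswith("/2"):
        return read_id[:-2]
    return read_id


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Stream mate files as :class:`ReadPair` objects, lazily.

    Mate ids must pair up record-by-record (ignoring ``/1``/``/2``
    suffixes); a count or id mismatch raises ``ValueError`` with the
    failing record index.
    """
    with _open_text(path1) as fh1, _open_text(path2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        index = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                raise ValueError(
                    f"mate files have unequal record counts: record {index} "
                    f"missing from {'mate-1' if rec1 is None else 'mate-2'} file"
                )
            (id1, seq1, q1), (id2, seq2, q2) = rec1, rec2
            id1, id2 = id1.split()[0], id2.split()[0]
            base1, base2 = _strip_mate_suffix(id1), _strip_mate_suffix(id2)
            if base1 != base2:
                raise ValueError(
                    f"read id mismatch at record {index}: {id1!r} vs {id2!r}"
                )
            yield ReadPair(id=base1, seq1=seq1.upper(), seq2=seq2.upper(),
                           qual1=q1, qual2=q2)
            index += 1


def _wrap(seq: str, width: int = 80) -> str:
    return "\n".join(seq[i:i + width] for i in range(0, len(seq), width))


def write_fasta(contigs: Iterable[Contig], path: str | Path) -> None:
    contigs = sorted(contigs, key=lambda c: c.id)
    with _open_text(path, "wt") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n{_wrap(c.seq)}\n")


def write_fastq_pairs(pairs: Iterable[ReadPair], path1: str | Path,
                      path2: str | Path) -> None:
    with _open_text(path1, "wt") as fh1, _open_text(path2, "wt") as fh2:
        for p in pairs:
            fh1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            fh2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def _looks_like_site(obj) -> bool:
    return all(hasattr(obj, a) for a in ("contig_id", "position", "end_sense", "support"))


def write_outputs(objects, path: str | Path, format: str) -> None:
    """Write *objects* to *path* in ``FASTA``, ``TSV`` or ``BED`` format.

    Contigs go to FASTA; telomere-addition sites go to BED as 1-bp
    features (``name`` = end sense, ``score`` = supporting reads,
    ``strand`` ``+`` for left/C-rich and ``-`` for right/G-rich) or to a
    TSV with the same columns; any other sequence of dataclass rows (or
    a single one) becomes a TSV with the field names as header.
    """
    fmt = format.upper()
    if dataclasses.is_dataclass(objects) and not isinstance(objects, type):
        objects = [objects]
    else:
        objects = list(objects)
    if fmt == "FASTA":
        write_fasta(objects, path)
        return
    if fmt == "BED":
        sites = sorted(objects, key=lambda s: (s.contig_id, s.position, s.end_sense))
        with _open_text(path, "wt") as fh:
            for s in sites:
                strand = "+" if s.end_sense == "left" else "-"
                fh.write(f"{s.contig_id}\t{s.position}\t{s.position + 1}\t"
                         f"{s.end_sense}\t{s.support}\t{strand}\n")
        return
    if fmt == "TSV":
        if objects and dataclasses.is_dataclass(objects[0]):
            rows = [dataclasses.asdict(o) for o in objects]
        else:
            rows = list(objects)
        df = pd.DataFrame(rows)
        if "contig_id" in df.columns:
            by = ["contig_id"] + [c for c in ("position", "start") if c in df.columns]
            df = df.sort_values(by, kind="stable")
        df.to_csv(path, sep="\t", index=False)
        return
    raise ValueError(f"unsupported output format {format!r}")


def read_bed_sites(path: str | Path):
    """Round-trip reader for the BED emitted by :func:`write_outputs`."""
    from .fragmentation import FragmentationSite

    sites = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, _end, name, score, _strand = line.rstrip("\n").split("\t")
            sites.append(FragmentationSite(
                contig_id=chrom, position=int(start), end_sense=name,
                support=int(score), is_terminal=False))
    return sites


def write_manifest(path: str | Path, config, seed: int | None = None) -> None:
    """Write a run manifest (resolved config + seed + versions) as JSON."""
    import numpy
    from . import __version__

    payload = {
        "nanoterm_version": __version__,
        "python": platform.python_version(),
        "numpy": numpy.__version__,
        "seed": seed,
        "config": dataclasses.asdict(config) if dataclasses.is_dataclass(config) else config,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
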
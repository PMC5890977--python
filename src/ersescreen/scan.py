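"""Genome scanning: stream FASTA records and report every motif occurrence.

The production matcher compiles each spaced consensus to a regular
expression (IUPAC codes become character classes, spacers become ``.{k}``)
wrapped in a lookahead so that overlapping and nested occurrences are all
reported.  FASTA line wrapping is irrelevant: each record's sequence is
logically unwrapped before scanning, so matches straddling line breaks are
found.

Coordinates are 0-based half-open on the forward strand of the source
record.  With reverse-strand scanning enabled, the reverse complement is
scanned too and its hits are mapped back to forward coordinates with
strand ``'-'``; ``matched_text`` is always the window as read 5'->3' on
the reported strand.
"""

from __future__ import annotations

import gzip
import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .motifs import ConsensusMotif, FixedBlock, IUPAC_TABLE, reverse_complement

__all__ = [
    "MotifHit",
    "ScanOptions",
    "RecordLog",
    "motif_to_regex",
    "scan_sequence",
    "scan_fasta",
    "hits_to_bed",
    "hits_to_tsv",
]


@dataclass(frozen=True, order=True)
class MotifHit:
    """One genomic occurrence of a motif."""

    sequence_id: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    motif_name: str
    strand: str  # '+' or '-'
    matched_text: str  # window read 5'->3' on the reported strand


@dataclass(frozen=True)
class ScanOptions:
    """Scanner behaviour switches.

    The defaults — forward strand only, all overlapping occurrences
    reported — are the plain-text-search convention used for reference
    genome screens with these elements.
    """

    scan_reverse_strand: bool = False
    report_overlaps: bool = True


@dataclass
class RecordLog:
    """Per-record scan accounting: id, length, hits per motif."""

    sequence_id: str
    length: int
    hits_per_motif: dict[str, int] = field(default_factory=dict)


def motif_to_regex(motif: ConsensusMotif) -> re.Pattern[str]:
    """Compile a spaced consensus to an overlapping-occurrence regex.

    Fixed IUPAC codes become character classes over their concrete bases
    (upper and lower case), so assembly ambiguity characters can never
    satisfy a fixed position; spacers become ``.{k}`` and accept anything.
    """
    parts: list[str] = []
    for blk in motif.blocks:
        if isinstance(blk, FixedBlock):
            for code in blk.bases:
                bases = sorted(IUPAC_TABLE[code])
                cls = "".join(bases) + "".join(b.lower() for b in bases)
                parts.append(f"[{cls}]")
        else:
            parts.append(f".{{{blk.length}}}")
    return re.compile("(?=(" + "".join(parts) + "))")


def _drop_overlaps(hits: list[MotifHit]) -> list[MotifHit]:
    out: list[MotifHit] = []
    last_end: dict[tuple[str, str], int] = {}
    for h in hits:
        key = (h.motif_name, h.strand)
        if h.start >= last_end.get(key, 0):
            out.append(h)
            last_end[key] = h.end
    return out


def scan_sequence(
    sequence_id: str,
    sequence: str,
    motifs: list[ConsensusMotif],
    options: ScanOptions = ScanOptions(),
) -> list[MotifHit]:
    """All motif occurrences in one sequence, sorted by (start, motif, strand).

    Reverse-strand hits (when enabled) are reported in forward coordinates
    with strand ``'-'``.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if not motifs:
        raise ValueError("motif list must be non-empty")
    seen = set()
    for m in motifs:
        if m.name in seen:
            raise ValueError(f"duplicate motif name {m.name!r}")
        seen.add(m.name)

    hits: list[MotifHit] = []
    length = len(sequence)
    for motif in motifs:
        if motif.total_length > length:
            continue
        rx = motif_to_regex(motif)
        for m in rx.finditer(sequence):
            s = m.start()
            hits.append(
                MotifHit(
                    sequence_id=sequence_id,
                    start=s,
                    end=s + motif.total_length,
                    motif_name=motif.name,
                    strand="+",
                    matched_text=m.group(1),
                )
            )
        if options.scan_reverse_strand:
            rc = reverse_complement(sequence)
            for m in rx.finditer(rc):
                s_rc = m.start()
                # forward coordinates of the reverse-complement window
                start = length - (s_rc + motif.total_length)
                hits.append(
                    MotifHit(
                        sequence_id=sequence_id,
                        start=start,
                        end=start + motif.total_length,
                        motif_name=motif.name,
                        strand="-",
                        matched_text=m.group(1),
                    )
                )
    hits.sort(key=lambda h: (h.start, h.motif_name, h.strand))
    if not options.report_overlaps:
        hits = _drop_overlaps(hits)
    return hits


FastaSource = Union[str, Path, IO[str]]


def _open_fasta(source: FastaSource) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def scan_fasta(
    fasta_source: FastaSource,
    motifs: list[ConsensusMotif],
    options: ScanOptions = ScanOptions(),
    logs: list[RecordLog] | None = None,
) -> Iterator[MotifHit]:
    """Scan every record of a FASTA file (plain or gzip), in file order.

    Record ids are truncated at the first whitespace.  Duplicate ids and
    empty records are rejected with record context.  If ``logs`` is given,
    a :class:`RecordLog` is appended per record as it is scanned.
    """
    handle = _open_fasta(fasta_source)
    seen_ids: set[str] = set()
    opened = not hasattr(fasta_source, "read")
    try:
        first = handle.readline()
        while first and not first.strip():
            first = handle.readline()
        if first and not first.startswith(">"):
            raise ValueError(
                "malformed FASTA: records must start with a '>' header"
            )
        lines = itertools.chain([first], handle) if first else iter(())
        n_records = 0
        for title, seq in SimpleFastaParser(lines):
            n_records += 1
            rec_id = title.split()[0] if title.split() else ""
            if not rec_id:
                raise ValueError(f"FASTA record {n_records} has an empty header")
            if rec_id in seen_ids:
                raise ValueError(f"duplicate FASTA record id {rec_id!r}")
            seen_ids.add(rec_id)
            if not seq:
                raise ValueError(f"FASTA record {rec_id!r} has no sequence")
            rec_hits = scan_sequence(rec_id, seq, motifs, options)
            if logs is not None:
                log = RecordLog(rec_id, len(seq))
                for m in motifs:
                    log.hits_per_motif[m.name] = 0
                for h in rec_hits:
                    log.hits_per_motif[h.motif_name] += 1
                logs.append(log)
            yield from rec_hits
        if n_records == 0:
            raise ValueError("no FASTA records found (missing '>' header?)")
    finally:
        if opened:
            handle.close()


def hits_to_bed(hits: Iterable[MotifHit]) -> str:
    """6-column BED (0-based half-open), name = motif, score = 0."""
    lines = [
        f"{h.sequence_id}\t{h.start}\t{h.end}\t{h.motif_name}\t0\t{h.strand}"
        for h in hits
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def hits_to_tsv(hits: Iterable[MotifHit]) -> str:
    """Hit table with 1-based inclusive coordinates plus matched text."""
    lines = ["motif\tchrom\tstart_1based\tend_1based\tstrand\tmatched_text"]
    for h in hits:
        lines.append(
            f"{h.motif_name}\t{h.sequence_id}\t{h.start + 1}\t{h.end}\t"
            f"{h.strand}\t{h.matched_text}"
        )
    return "\n".join(lines) + "\n"
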
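"""Promoter analysis: IUPAC TF-site scanning and conservation scoring.

Two independent pieces:

* :func:`scan_promoter` scans a TSS-anchored promoter window (written
  5'->3' on the gene's strand, ending at the TSS) for exact IUPAC
  consensus transcription-factor sites.  Presets cover the stress-relevant
  factors ATF/CREB (``TGASTCA``), NF-kB (``GGGRNNYYCC``) and ATF4/CHOP
  (``GCATCAK``).  Matches are reported as positive "bp upstream of the
  TSS" offsets, the convention of promoter schematics.
* :func:`count_mismatches` scores cross-species conservation of an
  element instance by Hamming distance over the motif's fixed-block
  positions only — spacer positions are free to diverge and are ignored.
  :func:`is_conserved` applies a mismatch threshold (default 2: one or
  two substitutions across species still count as a conserved element).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .motifs import ConsensusMotif, FixedBlock
from .scan import motif_to_regex

__all__ = [
    "TFConsensus",
    "TFBSHit",
    "ConservationResult",
    "TF_PRESETS",
    "builtin_tf_consensus",
    "load_tf_file",
    "scan_promoter",
    "count_mismatches",
    "is_conserved",
    "conservation_table",
    "tfbs_to_tsv",
    "conservation_to_tsv",
]

#: Transcription-factor consensus presets (IUPAC, no spacers).
TF_PRESETS: dict[str, str] = {
    "ATF/CREB": "TGASTCA",
    "NF-kB": "GGGRNNYYCC",
    "ATF4/CHOP": "GCATCAK",
}


@dataclass(frozen=True)
class TFConsensus:
    """A transcription factor's IUPAC consensus binding sequence."""

    tf_name: str
    pattern: str

    def __post_init__(self) -> None:
        FixedBlock(self.pattern)  # validates: non-empty, IUPAC only
        object.__setattr__(self, "pattern", self.pattern.upper())


@dataclass(frozen=True)
class TFBSHit:
    """One consensus match in a promoter window.

    ``upstream_offset`` is the distance in bp from the TSS back to the
    5'-most base of the match (positive = upstream), mirroring the
    "site at -3530 bp" style of promoter maps.
    """

    tf_name: str
    upstream_offset: int
    matched_text: str
    strand: str = "+"


@dataclass(frozen=True)
class ConservationResult:
    """Fixed-position mismatch count of one ortholog element."""

    species: str
    mismatches: int
    conserved: bool


def builtin_tf_consensus() -> list[TFConsensus]:
    """The ATF/CREB, NF-kB and ATF4/CHOP presets."""
    return [TFConsensus(name, pat) for name, pat in TF_PRESETS.items()]


def load_tf_file(lines: Iterable[str]) -> list[TFConsensus]:
    """Read ``tf_name<TAB>iupac_pattern`` lines; '#' comments skipped."""
    out: list[TFConsensus] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(
                f"TF file line {lineno}: expected 'name<TAB>pattern', got {line!r}"
            )
        out.append(TFConsensus(fields[0], fields[1]))
    return out


def _tf_regex(tf: TFConsensus):
    motif = ConsensusMotif(name=tf.tf_name, blocks=(FixedBlock(tf.pattern),))
    return motif_to_regex(motif)


def scan_promoter(
    promoter_seq: str,
    tf_list: Sequence[TFConsensus],
    window: int = 5000,
) -> list[TFBSHit]:
    """All IUPAC consensus matches in a TSS-anchored promoter window.

    ``promoter_seq`` is genomic sequence written 5'->3' on the gene's
    strand with its last base immediately upstream of the TSS; it may be
    shorter than ``window`` when the contig starts inside the window.
    Hits are sorted by decreasing upstream offset (farthest first).
    Scanning is single-strand: the gene's strand.
    """
    if not tf_list:
        raise ValueError("TF consensus list must be non-empty")
    if len(promoter_seq) > window:
        raise ValueError(
            f"promoter sequence ({len(promoter_seq)} bp) exceeds window ({window} bp)"
        )
    hits: list[TFBSHit] = []
    n = len(promoter_seq)
    for tf in tf_list:
        rx = _tf_regex(tf)
        for m in rx.finditer(promoter_seq):
            hits.append(
                TFBSHit(
                    tf_name=tf.tf_name,
                    upstream_offset=n - m.start(),
                    matched_text=m.group(1),
                )
            )
    hits.sort(key=lambda h: (-h.upstream_offset, h.tf_name))
    return hits


def count_mismatches(
    motif: ConsensusMotif, reference_elem: str, ortholog_elem: str
) -> int:
    """Hamming distance over the motif's fixed-block positions.

    Spacer positions are ignored; comparison is case-insensitive.  Both
    sequences must span the full motif window.
    """
    if len(reference_elem) != motif.total_length:
        raise ValueError(
            f"reference length {len(reference_elem)} != motif length {motif.total_length}"
        )
    if len(ortholog_elem) != motif.total_length:
        raise ValueError(
            f"ortholog length {len(ortholog_elem)} != motif length {motif.total_length}"
        )
    ref = reference_elem.upper()
    oth = ortholog_elem.upper()
    return sum(ref[i] != oth[i] for i in motif.fixed_positions)


def is_conserved(result_mismatches: int, threshold: int = 2) -> bool:
    """Conserved iff the mismatch count does not exceed the threshold."""
    if result_mismatches < 0 or threshold < 0:
        raise ValueError("mismatch counts must be non-negative")
    return result_mismatches <= threshold


def conservation_table(
    motif: ConsensusMotif,
    reference_elem: str,
    ortholog_fasta,
    threshold: int = 2,
) -> list[ConservationResult]:
    """Score each ortholog record (record id = species label) in a FASTA.

    Ortholog sequences are assumed pre-aligned to the motif window (same
    length as the motif); no alignment is performed here.
    """
    results: list[ConservationResult] = []
    close = isinstance(ortholog_fasta, str)
    handle = open(ortholog_fasta) if close else ortholog_fasta
    try:
        for title, seq in SimpleFastaParser(handle):
            species = title.split()[0]
            mm = count_mismatches(motif, reference_elem, seq)
            results.append(
                ConservationResult(species, mm, is_conserved(mm, threshold))
            )
    finally:
        if close:
            handle.close()
    return results


def tfbs_to_tsv(hits: Sequence[TFBSHit]) -> str:
    lines = ["tf\tupstream_offset_bp\tmatched_text"]
    for h in hits:
        lines.append(f"{h.tf_name}\t{h.upstream_offset}\t{h.matched_text}")
    return "\n".join(lines) + "\n"


def conservation_to_tsv(results: Sequence[ConservationResult]) -> str:
    lines = ["species\tmismatches\tconserved"]
    for r in results:
        lines.append(f"{r.species}\t{r.mismatches}\t{str(r.conserved).lower()}")
    return "\n".join(lines) + "\n"
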
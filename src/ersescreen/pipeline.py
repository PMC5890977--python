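"""Full-screen orchestration: scan -> associate -> summarize, with manifests.

`run_screen` composes the stages deterministically and writes the
publication-style outputs: hits as BED and TSV, an association table, a
per-class summary and a JSON run manifest (tool version, config echo,
input digests, per-stage record counts and wall times).  Re-running on
identical inputs reproduces byte-identical data files; only the
manifest's timing fields may differ.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

from . import __version__
from .annotate import (
    Association,
    Category,
    GeneRecord,
    ScreenConfig,
    ScreenSummary,
    associate_hits,
    associations_to_tsv,
    parse_genes,
    summarize,
    summary_to_tsv,
    tss_of,
)
from .motifs import ConsensusMotif, reverse_complement
from .promoter import TFBSHit, TFConsensus, scan_promoter, tfbs_to_tsv
from .scan import (
    MotifHit,
    RecordLog,
    ScanOptions,
    hits_to_bed,
    hits_to_tsv,
    scan_fasta,
)

__all__ = ["run_screen", "run_promoter_report", "extract_promoter", "read_hits_tsv"]

log = logging.getLogger("ersescreen")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def read_hits_tsv(source) -> list[MotifHit]:
    """Parse a hit TSV (1-based inclusive coordinates) back into hits."""
    lines = Path(source).read_text().splitlines() if isinstance(source, (str, Path)) else list(source)
    if not lines or not lines[0].startswith("motif\t"):
        raise ValueError("hit TSV missing header")
    hits = []
    for line in lines[1:]:
        if not line.strip():
            continue
        motif, chrom, start1, end1, strand, text = line.split("\t")
        hits.append(MotifHit(chrom, int(start1) - 1, int(end1), motif, strand, text))
    return hits


def run_screen(
    genome_fasta: str | Path,
    annotation: str | Path | None,
    motif_set: Sequence[ConsensusMotif],
    config: ScreenConfig,
    output_dir: str | Path,
    annotation_format: str = "GFF3",
    options: ScanOptions = ScanOptions(),
) -> dict:
    """Run the complete element screen and write all report files.

    Returns the manifest dict.  On any stage failure, files already
    written into ``output_dir`` by this run are removed before the error
    propagates, so no partial result set is left behind.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {
        "tool": "ersescreen",
        "version": __version__,
        "config": {
            "upstream_window": config.upstream_window,
            "downstream_window": config.downstream_window,
            "no_gene_scan": config.no_gene_scan,
            "strict_upstream_no_gene": config.strict_upstream_no_gene,
            "scan_reverse_strand": options.scan_reverse_strand,
            "report_overlaps": options.report_overlaps,
            "motifs": {m.name: m.pattern() for m in motif_set},
        },
        "inputs": {},
        "stages": {},
        "outputs": {},
    }

    def emit(name: str, text: str, n_rows: int) -> None:
        path = out / name
        path.write_text(text)
        written.append(path)
        manifest["outputs"][name] = {"rows": n_rows}

    try:
        manifest["inputs"]["genome_fasta"] = {
            "path": str(genome_fasta), "sha256": _sha256(genome_fasta)
        }
        if annotation is not None:
            manifest["inputs"]["annotation"] = {
                "path": str(annotation), "sha256": _sha256(annotation)
            }

        t0 = time.perf_counter()
        logs: list[RecordLog] = []
        hits = list(scan_fasta(genome_fasta, list(motif_set), options, logs=logs))
        manifest["stages"]["scan"] = {
            "records": len(logs),
            "hits": len(hits),
            "seconds": round(time.perf_counter() - t0, 3),
            "per_record": [asdict(l) for l in logs],
        }
        log.info("scan: %d hits over %d records", len(hits), len(logs))

        t0 = time.perf_counter()
        genes: list[GeneRecord] = (
            parse_genes(annotation, annotation_format) if annotation is not None else []
        )
        associations = associate_hits(hits, genes, config)
        manifest["stages"]["annotate"] = {
            "genes": len(genes),
            "associations": len(associations),
            "seconds": round(time.perf_counter() - t0, 3),
        }
        log.info("annotate: %d genes, %d associations", len(genes), len(associations))

        t0 = time.perf_counter()
        summary = summarize(associations, hits, genes)
        manifest["stages"]["summarize"] = {
            "candidate_genes": summary.n_candidate_genes,
            "seconds": round(time.perf_counter() - t0, 3),
        }

        emit("hits.bed", hits_to_bed(hits), len(hits))
        emit("hits.tsv", hits_to_tsv(hits), len(hits))
        emit("associations.tsv", associations_to_tsv(associations, genes), len(associations))
        emit("summary.tsv", summary_to_tsv(summary), len(summary.per_motif) + 1)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return manifest


def extract_promoter(
    genome_fasta: str | Path, gene: GeneRecord, window: int = 5000
) -> str:
    """TSS-anchored promoter, 5'->3' on the gene's strand, ending at the TSS.

    Clipped at the contig boundary when the window extends past it.
    """
    seq = None
    with open(genome_fasta) as fh:
        for title, s in SimpleFastaParser(fh):
            if title.split()[0] == gene.sequence_id:
                seq = s
                break
    if seq is None:
        raise ValueError(
            f"sequence {gene.sequence_id!r} for gene {gene.gene_id!r} "
            f"not found in {genome_fasta}"
        )
    tss = tss_of(gene)
    if gene.strand == "+":
        return seq[max(0, tss - window) : tss]
    region = seq[tss + 1 : tss + 1 + window]
    return reverse_complement(region)


def run_promoter_report(
    genome_fasta: str | Path,
    gene: GeneRecord,
    tf_set: Sequence[TFConsensus],
    window: int = 5000,
) -> list[TFBSHit]:
    """Scan a gene's promoter window for TF consensus sites."""
    promoter = extract_promoter(genome_fasta, gene, window)
    return scan_promoter(promoter, list(tf_set), window)
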
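"""Assign motif hits to genes and classify them by TSS-relative distance.

Each element occurrence is associated with its closest gene (smallest
absolute signed distance to the transcription start site) and binned:

``UPSTREAM_PROXIMAL``
    within ``upstream_window`` bp upstream of the TSS (default 10 kb;
    boundary inclusive),
``INSIDE_GENE``
    at or downstream of the TSS by at most ``downstream_window`` bp
    (default 20 kb, inclusive) *and* overlapping the gene interval,
``DISTAL``
    a gene exists within ``no_gene_scan`` bp (default 100 kb) but the hit
    falls outside both windows,
``NO_GENE``
    no gene TSS within ``no_gene_scan`` bp of the hit and no gene overlaps
    it.

Distances are signed in the gene's orientation: negative = upstream.  The
distance of a hit is measured from the TSS to the hit edge nearest the
TSS; a hit spanning the TSS has distance 0.  Genes in the first two
categories are the screen's candidate genes.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

from intervaltree import IntervalTree

from .scan import MotifHit

__all__ = [
    "Category",
    "GeneRecord",
    "ScreenConfig",
    "Association",
    "MotifClassSummary",
    "ScreenSummary",
    "GeneIndex",
    "parse_genes",
    "tss_of",
    "signed_distance",
    "associate_hit",
    "associate_hits",
    "summarize",
    "associations_to_tsv",
    "summary_to_tsv",
]


class Category(str, Enum):
    """TSS-relative bin of one element-to-gene association."""

    UPSTREAM_PROXIMAL = "UPSTREAM_PROXIMAL"
    INSIDE_GENE = "INSIDE_GENE"
    DISTAL = "DISTAL"
    NO_GENE = "NO_GENE"


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: id, name, location, strand (0-based half-open)."""

    gene_id: str
    gene_name: str
    sequence_id: str
    strand: str
    start: int  # 0-based inclusive
    end: int  # exclusive

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start {self.start} must be < end {self.end}"
            )


@dataclass(frozen=True)
class ScreenConfig:
    """Windows (bp) of the candidate-gene filters.

    ``strict_upstream_no_gene`` restricts the no-gene scan to genes the
    hit lies upstream of, the literal reading of a one-sided 100 kb
    upstream search; the default is the symmetric (more robust) scan.
    """

    upstream_window: int = 10_000
    downstream_window: int = 20_000
    no_gene_scan: int = 100_000
    strict_upstream_no_gene: bool = False

    def __post_init__(self) -> None:
        if min(self.upstream_window, self.downstream_window, self.no_gene_scan) <= 0:
            raise ValueError("all windows must be positive")
        if self.upstream_window > self.no_gene_scan:
            raise ValueError("upstream_window must not exceed no_gene_scan")


@dataclass(frozen=True)
class Association:
    """One hit's assignment to its closest gene (or to none)."""

    hit: MotifHit
    gene_id: str | None
    signed_distance: int | None  # bp; negative = upstream of the TSS
    category: Category

    def __post_init__(self) -> None:
        none_like = (self.gene_id is None, self.signed_distance is None,
                     self.category is Category.NO_GENE)
        if any(none_like) and not all(none_like):
            raise ValueError("NO_GENE requires gene_id and distance to be None")


def tss_of(gene: GeneRecord) -> int:
    """0-based transcription start site: 5' end of the gene on its strand."""
    return gene.start if gene.strand == "+" else gene.end - 1


def signed_distance(hit: MotifHit, gene: GeneRecord) -> int:
    """Signed bp from the gene's TSS to the hit edge nearest the TSS.

    0 if the hit interval contains the TSS.  Negative values are upstream
    in the gene's orientation (for '-'-strand genes, genomic coordinates
    greater than the TSS are upstream).
    """
    if hit.sequence_id != gene.sequence_id:
        raise ValueError(
            f"hit on {hit.sequence_id!r} but gene {gene.gene_id!r} on "
            f"{gene.sequence_id!r}"
        )
    tss = tss_of(gene)
    if hit.start <= tss < hit.end:
        return 0
    edge = hit.end - 1 if hit.end - 1 < tss else hit.start
    genomic = edge - tss
    return genomic if gene.strand == "+" else -genomic


def _feature_from_gff_line(line: str):
    # gffutils does the attribute/coordinate parsing; we keep line numbers.
    from gffutils.feature import feature_from_line

    return feature_from_line(line)


GeneSource = Union[str, Path, IO[str], Iterable[str]]


def _iter_lines(source: GeneSource) -> Iterable[str]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from fh
    else:
        yield from source


def parse_genes(annotation_source: GeneSource, format: str = "GFF3") -> list[GeneRecord]:
    """Read gene records from GFF3 (feature type ``gene``) or 6-column BED.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention; BED is already 0-based half-open.
    Malformed lines are rejected with their line number.
    """
    fmt = format.upper()
    if fmt not in ("GFF3", "BED"):
        raise ValueError(f"unknown annotation format {format!r}")
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(_iter_lines(annotation_source), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        try:
            if fmt == "GFF3":
                feat = _feature_from_gff_line(line)
                if feat.featuretype != "gene":
                    continue
                if feat.strand not in ("+", "-"):
                    raise ValueError("missing strand")
                gene_id = (feat.attributes.get("ID") or [feat.id or ""])[0]
                if not gene_id:
                    raise ValueError("missing ID attribute")
                name = (feat.attributes.get("Name") or [gene_id])[0]
                rec = GeneRecord(
                    gene_id=gene_id,
                    gene_name=name,
                    sequence_id=feat.seqid,
                    strand=feat.strand,
                    start=feat.start - 1,
                    end=feat.end,
                )
            else:
                cols = line.split("\t")
                if len(cols) < 6:
                    raise ValueError(f"BED needs >= 6 columns, got {len(cols)}")
                chrom, start, end, name, _score, strand = cols[:6]
                if strand not in ("+", "-"):
                    raise ValueError("missing strand")
                rec = GeneRecord(
                    gene_id=name,
                    gene_name=name,
                    sequence_id=chrom,
                    strand=strand,
                    start=int(start),
                    end=int(end),
                )
        except ValueError as exc:
            raise ValueError(f"annotation line {lineno}: {exc}") from None
        if rec.gene_id in seen:
            raise ValueError(f"annotation line {lineno}: duplicate gene id {rec.gene_id!r}")
        seen.add(rec.gene_id)
        genes.append(rec)
    return genes


class GeneIndex:
    """Per-sequence query structure over gene records.

    ``candidates(hit, radius)`` returns every gene whose TSS lies within
    ``radius`` bp of the hit interval, plus every gene overlapping the
    hit — the contract :func:`associate_hit` relies on.
    """

    def __init__(self, genes: Sequence[GeneRecord]):
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._tss: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for i, g in enumerate(self.genes):
            self._trees[g.sequence_id].addi(g.start, g.end, i)
            self._tss[g.sequence_id].append((tss_of(g), i))
        for seq_id in self._tss:
            self._tss[seq_id].sort()

    def candidates(self, hit: MotifHit, radius: int) -> list[GeneRecord]:
        found: set[int] = set()
        tss_list = self._tss.get(hit.sequence_id, [])
        lo = bisect.bisect_left(tss_list, (hit.start - radius, -1))
        hi = bisect.bisect_right(tss_list, (hit.end - 1 + radius, len(self.genes)))
        for pos in range(lo, hi):
            found.add(tss_list[pos][1])
        tree = self._trees.get(hit.sequence_id)
        if tree is not None:
            for iv in tree.overlap(hit.start, hit.end):
                found.add(iv.data)
        return [self.genes[i] for i in sorted(found)]


def _overlaps(hit: MotifHit, gene: GeneRecord) -> bool:
    return hit.start < gene.end and gene.start < hit.end


def associate_hit(
    hit: MotifHit,
    genes: Union[GeneIndex, Sequence[GeneRecord]],
    config: ScreenConfig = ScreenConfig(),
) -> Association:
    """Assign one hit to its closest gene and classify the distance.

    The closest gene minimises the absolute signed distance; ties prefer
    the upstream (negative) gene, then the lexicographically smallest
    gene id.  ``genes`` may be a prebuilt :class:`GeneIndex` or a plain
    sequence (then every gene on the hit's sequence is examined).
    """
    if isinstance(genes, GeneIndex):
        pool = genes.candidates(hit, config.no_gene_scan)
    else:
        pool = [g for g in genes if g.sequence_id == hit.sequence_id]

    best: tuple[int, int, str] | None = None
    best_gene: GeneRecord | None = None
    best_d: int | None = None
    for g in pool:
        d = signed_distance(hit, g)
        within_scan = abs(d) <= config.no_gene_scan or _overlaps(hit, g)
        if not within_scan:
            continue
        if config.strict_upstream_no_gene and d > 0 and not _overlaps(hit, g):
            continue
        key = (abs(d), 0 if d < 0 else 1, g.gene_id)
        if best is None or key < best:
            best, best_gene, best_d = key, g, d
    if best_gene is None or best_d is None:
        return Association(hit=hit, gene_id=None, signed_distance=None,
                           category=Category.NO_GENE)
    if -config.upstream_window <= best_d < 0:
        cat = Category.UPSTREAM_PROXIMAL
    elif 0 <= best_d <= config.downstream_window and _overlaps(hit, best_gene):
        cat = Category.INSIDE_GENE
    else:
        cat = Category.DISTAL
    return Association(hit=hit, gene_id=best_gene.gene_id,
                       signed_distance=best_d, category=cat)


def associate_hits(
    hits: Iterable[MotifHit],
    genes: Union[GeneIndex, Sequence[GeneRecord]],
    config: ScreenConfig = ScreenConfig(),
) -> list[Association]:
    """Vector form of :func:`associate_hit`, building the index once."""
    if not isinstance(genes, GeneIndex):
        genes = GeneIndex(list(genes))
    return [associate_hit(h, genes, config) for h in hits]


@dataclass
class MotifClassSummary:
    """Counts for one motif class (one row of the screen summary)."""

    n_hits: int = 0
    n_upstream_proximal: int = 0
    n_inside_gene: int = 0
    n_distal: int = 0
    n_no_gene: int = 0
    candidate_genes: list[str] = field(default_factory=list)

    @property
    def n_candidate_genes(self) -> int:
        return len(self.candidate_genes)


@dataclass
class ScreenSummary:
    """Per-motif-class category counts plus grand totals.

    ``n_candidate_genes`` in the totals counts each distinct gene once per
    motif class (a gene hit by two element classes contributes twice);
    ``n_distinct_candidate_genes`` deduplicates across classes.
    """

    per_motif: dict[str, MotifClassSummary]
    total_hits: int
    n_candidate_genes: int
    n_distinct_candidate_genes: int
    n_upstream_proximal_genes: int
    n_inside_gene_genes: int


_CANDIDATE = (Category.UPSTREAM_PROXIMAL, Category.INSIDE_GENE)


def summarize(
    associations: Sequence[Association],
    hits: Sequence[MotifHit],
    genes: Sequence[GeneRecord] | None = None,
) -> ScreenSummary:
    """Tabulate associations into the screen summary.

    Every hit must carry exactly one association.  Candidate-gene lists
    are ordered by (sequence id, TSS, gene id) when gene records are
    supplied, else by gene id.
    """
    if len(associations) != len(hits) or {a.hit for a in associations} != set(hits):
        raise ValueError("each hit must have exactly one association")

    order: dict[str, tuple] = {}
    if genes is not None:
        order = {g.gene_id: (g.sequence_id, tss_of(g), g.gene_id) for g in genes}

    per: dict[str, MotifClassSummary] = {}
    cand: dict[str, set[str]] = defaultdict(set)
    up_genes: set[str] = set()
    in_genes: set[str] = set()
    for a in associations:
        row = per.setdefault(a.hit.motif_name, MotifClassSummary())
        row.n_hits += 1
        if a.category is Category.UPSTREAM_PROXIMAL:
            row.n_upstream_proximal += 1
            up_genes.add(a.gene_id)  # type: ignore[arg-type]
        elif a.category is Category.INSIDE_GENE:
            row.n_inside_gene += 1
            in_genes.add(a.gene_id)  # type: ignore[arg-type]
        elif a.category is Category.DISTAL:
            row.n_distal += 1
        else:
            row.n_no_gene += 1
        if a.category in _CANDIDATE and a.gene_id is not None:
            cand[a.hit.motif_name].add(a.gene_id)

    for motif_name, row in per.items():
        ids = cand.get(motif_name, set())
        row.candidate_genes = sorted(ids, key=lambda g: order.get(g, ((), (), g)))

    all_cand = set().union(*cand.values()) if cand else set()
    return ScreenSummary(
        per_motif=per,
        total_hits=sum(r.n_hits for r in per.values()),
        n_candidate_genes=sum(r.n_candidate_genes for r in per.values()),
        n_distinct_candidate_genes=len(all_cand),
        n_upstream_proximal_genes=len(up_genes),
        n_inside_gene_genes=len(in_genes),
    )


def associations_to_tsv(
    associations: Sequence[Association],
    genes: Sequence[GeneRecord] | None = None,
) -> str:
    """Association table, element coordinates 1-based inclusive."""
    names = {g.gene_id: g.gene_name for g in genes} if genes else {}
    lines = [
        "motif\tchrom\telement_start_1based\telement_end_1based\tstrand\t"
        "gene_id\tgene_name\tsigned_distance_bp\tcategory"
    ]
    for a in associations:
        h = a.hit
        gid = a.gene_id if a.gene_id is not None else "."
        gname = names.get(a.gene_id, gid) if a.gene_id is not None else "."
        dist = str(a.signed_distance) if a.signed_distance is not None else "."
        lines.append(
            f"{h.motif_name}\t{h.sequence_id}\t{h.start + 1}\t{h.end}\t{h.strand}\t"
            f"{gid}\t{gname}\t{dist}\t{a.category.value}"
        )
    return "\n".join(lines) + "\n"


def summary_to_tsv(summary: ScreenSummary) -> str:
    """Per-class counts and candidate gene lists, one motif class per row."""
    lines = [
        "motif\tn_hits\tn_upstream_proximal\tn_inside_gene\tn_distal\t"
        "n_no_gene\tn_candidate_genes\tcandidate_genes"
    ]
    for motif_name in sorted(summary.per_motif):
        r = summary.per_motif[motif_name]
        lines.append(
            f"{motif_name}\t{r.n_hits}\t{r.n_upstream_proximal}\t{r.n_inside_gene}\t"
            f"{r.n_distal}\t{r.n_no_gene}\t{r.n_candidate_genes}\t"
            + ",".join(r.candidate_genes)
        )
    lines.append(
        f"TOTAL\t{summary.total_hits}\t-\t-\t-\t-\t{summary.n_candidate_genes}\t"
        f"distinct={summary.n_distinct_candidate_genes}"
    )
    return "\n".join(lines) + "\n"
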
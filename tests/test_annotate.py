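"""Gene parsing, signed TSS distances, closest-gene classification, summaries."""

import numpy as np
import pytest

from ersescreen.annotate import (
    Association,
    Category,
    GeneIndex,
    GeneRecord,
    ScreenConfig,
    associate_hit,
    associate_hits,
    parse_genes,
    signed_distance,
    summarize,
    tss_of,
)
from ersescreen.scan import MotifHit


def hit(start, end, seq_id="chr1"):
    return MotifHit(seq_id, start, end, "ERSE-I", "+", "x" * (end - start))


# --- parsing ---------------------------------------------------------------

def test_parse_gff3_gene_line():
    lines = [
        "##gff-version 3",
        "chr1\t.\tgene\t1001\t5000\t.\t+\t.\tID=g1;Name=ASB7",
        "chr1\t.\tmRNA\t1001\t5000\t.\t+\t.\tID=t1;Parent=g1",  # skipped
    ]
    genes = parse_genes(lines, "GFF3")
    assert genes == [GeneRecord("g1", "ASB7", "chr1", "+", 1000, 5000)]


def test_parse_bed6():
    genes = parse_genes(["chr1\t1000\t5000\tg1\t0\t-"], "BED")
    assert genes == [GeneRecord("g1", "g1", "chr1", "-", 1000, 5000)]


@pytest.mark.parametrize(
    "line,fmt",
    [
        ("chr1\t.\tgene\t1001\t5000\t.\t.\t.\tID=g1", "GFF3"),  # no strand
        ("chr1\t5000\t1000\tg1\t0\t+", "BED"),  # start >= end
        ("chr1\t1000\t5000\tg1", "BED"),  # too few columns
    ],
)
def test_parse_rejects_with_line_number(line, fmt):
    with pytest.raises(ValueError, match="line 1"):
        parse_genes([line], fmt)


def test_parse_unknown_format():
    with pytest.raises(ValueError):
        parse_genes([], "GTF")


def test_empty_annotation_gives_no_gene():
    genes = parse_genes([], "GFF3")
    assert genes == []
    a = associate_hit(hit(100, 119), genes)
    assert a.category is Category.NO_GENE


# --- TSS and distances -----------------------------------------------------

@pytest.mark.parametrize(
    "strand,start,end,expected",
    [("+", 1000, 5000, 1000), ("-", 1000, 5000, 4999), ("+", 7, 8, 7), ("-", 7, 8, 7)],
)
def test_tss_of(strand, start, end, expected):
    assert tss_of(GeneRecord("g", "g", "c", strand, start, end)) == expected


def test_signed_distance_examples():
    plus = GeneRecord("g", "g", "chr1", "+", 10_000, 30_000)
    assert signed_distance(hit(9000, 9019), plus) == -982
    assert signed_distance(hit(9990, 10_009), plus) == 0  # spans the TSS
    minus = GeneRecord("g", "g", "chr1", "-", 1000, 5000)
    assert signed_distance(hit(5200, 5211), minus) == -201
    assert signed_distance(hit(4000, 4011), minus) == 989  # downstream on '-'


def test_signed_distance_requires_same_sequence():
    g = GeneRecord("g", "g", "chr2", "+", 0, 10)
    with pytest.raises(ValueError):
        signed_distance(hit(0, 19, "chr1"), g)


# --- association ------------------------------------------------------------

CFG = ScreenConfig()


def test_boundary_exactness():
    """-10,000 and +20,000 are candidate; one bp beyond is distal."""
    g = GeneRecord("g", "g", "chr1", "+", 50_000, 80_000)
    # nearest hit edge at tss - 10_000 => d = -10_000
    a = associate_hit(hit(39_982, 40_001), [g], CFG)
    assert (a.signed_distance, a.category) == (-10_000, Category.UPSTREAM_PROXIMAL)
    a = associate_hit(hit(39_981, 40_000), [g], CFG)
    assert (a.signed_distance, a.category) == (-10_001, Category.DISTAL)
    a = associate_hit(hit(70_000, 70_019), [g], CFG)
    assert (a.signed_distance, a.category) == (20_000, Category.INSIDE_GENE)
    a = associate_hit(hit(70_001, 70_020), [g], CFG)
    assert (a.signed_distance, a.category) == (20_001, Category.DISTAL)


def test_inside_gene_requires_overlap():
    """Downstream of a short gene's TSS but past its end is distal."""
    short = GeneRecord("g", "g", "chr1", "+", 10_000, 14_000)
    a = associate_hit(hit(15_000, 15_019), [short], CFG)
    assert a.signed_distance == 5000
    assert a.category is Category.DISTAL


def test_no_gene_beyond_100kb():
    g = GeneRecord("g", "g", "chr1", "+", 300_000, 320_000)
    a = associate_hit(hit(100_000, 100_019), [g], CFG)
    assert a == Association(hit(100_000, 100_019), None, None, Category.NO_GENE)
    # exactly at the 100 kb scan radius: still associated (distal)
    a = associate_hit(hit(199_982, 200_001), [g], CFG)
    assert (a.signed_distance, a.category) == (-100_000, Category.DISTAL)


def test_overlapping_gene_without_tss_in_radius_is_found():
    huge = GeneRecord("g", "g", "chr1", "+", 0, 500_000)
    a = associate_hit(hit(400_000, 400_019), [huge], CFG)
    assert a.gene_id == "g"
    assert a.category is Category.DISTAL  # d = 400,000 > downstream window


def test_tie_break_prefers_upstream_then_gene_id():
    # equidistant genes differing only in id -> smallest id wins
    g1 = GeneRecord("a", "a", "chr1", "+", 5000, 5100)
    g2 = GeneRecord("zz", "zz", "chr1", "+", 5000, 5100)
    a = associate_hit(hit(4000, 4019), [g2, g1], CFG)
    assert a.gene_id == "a"
    # upstream (negative) preferred over downstream at equal |d|
    gup = GeneRecord("z_up", "z", "chr1", "+", 4119, 6000)  # d = -101
    gdn = GeneRecord("a_dn", "a", "chr1", "+", 3899, 3999)  # tss 3899, d = +101
    a = associate_hit(hit(4000, 4019), [gdn, gup], CFG)
    assert (a.gene_id, a.signed_distance) == ("z_up", -101)


def test_strict_upstream_no_gene_mode():
    cfg = ScreenConfig(strict_upstream_no_gene=True)
    g = GeneRecord("g", "g", "chr1", "+", 1000, 2000)
    h = hit(50_000, 50_019)  # hit downstream of the gene
    assert associate_hit(h, [g], cfg).category is Category.NO_GENE
    assert associate_hit(h, [g], CFG).category is Category.DISTAL


def test_index_agrees_with_brute_force():
    """GeneIndex-backed association equals the all-genes scan."""
    rng = np.random.default_rng(5)
    genes = []
    for i in range(100):
        chrom = f"chr{rng.integers(1, 4)}"
        start = int(rng.integers(0, 900_000))
        genes.append(
            GeneRecord(f"g{i:03d}", f"g{i:03d}", chrom,
                       "+-"[rng.integers(2)], start, start + int(rng.integers(100, 60_000)))
        )
    index = GeneIndex(genes)
    for _ in range(300):
        h = hit(int(rng.integers(0, 950_000)), 0, f"chr{rng.integers(1, 4)}")
        h = MotifHit(h.sequence_id, h.start, h.start + 19, "ERSE-I", "+", "")
        assert associate_hit(h, index, CFG) == associate_hit(h, genes, CFG)


def test_monotonicity_in_windows(fixture_genome):
    """Wider windows never lose candidate genes."""
    cfg, _, _, truth = fixture_genome
    hits = truth.planted_hits
    genes = truth.genes
    prev = -1
    for up, down in [(2000, 4000), (5000, 10_000), (10_000, 20_000), (20_000, 40_000)]:
        sc = ScreenConfig(upstream_window=up, downstream_window=down)
        s = summarize(associate_hits(hits, genes, sc), hits, genes)
        assert s.n_candidate_genes >= prev
        prev = s.n_candidate_genes


# --- summaries --------------------------------------------------------------

def make_assoc(h, gid, d, cat):
    return Association(h, gid, d, cat)


def test_summarize_counts_distinct_genes():
    hits = [hit(i * 100, i * 100 + 19) for i in range(5)]
    assocs = [
        make_assoc(hits[0], "g1", -500, Category.UPSTREAM_PROXIMAL),
        make_assoc(hits[1], "g2", -900, Category.UPSTREAM_PROXIMAL),
        make_assoc(hits[2], "g3", -100, Category.UPSTREAM_PROXIMAL),
        make_assoc(hits[3], "g4", 50, Category.INSIDE_GENE),
        make_assoc(hits[4], "g5", 70, Category.INSIDE_GENE),
    ]
    s = summarize(assocs, hits)
    row = s.per_motif["ERSE-I"]
    assert row.n_candidate_genes == 5
    assert (row.n_upstream_proximal, row.n_inside_gene) == (3, 2)


def test_summarize_gene_with_two_elements_counted_once():
    hits = [hit(0, 19), hit(100, 119)]
    assocs = [
        make_assoc(hits[0], "g1", -500, Category.UPSTREAM_PROXIMAL),
        make_assoc(hits[1], "g1", 50, Category.INSIDE_GENE),
    ]
    s = summarize(assocs, hits)
    assert s.per_motif["ERSE-I"].n_candidate_genes == 1
    assert s.n_distinct_candidate_genes == 1


def test_summarize_empty():
    s = summarize([], [])
    assert s.total_hits == 0
    assert s.n_candidate_genes == 0
    assert s.per_motif == {}


def test_summarize_rejects_mismatched_inputs():
    h1, h2 = hit(0, 19), hit(50, 69)
    a1 = make_assoc(h1, None, None, Category.NO_GENE)
    with pytest.raises(ValueError):
        summarize([a1], [h2])


def test_category_counts_sum_to_hits(fixture_genome):
    """Conservation of hits: the four category counts partition each class."""
    cfg, _, _, truth = fixture_genome
    s = truth.expected_summary
    for row in s.per_motif.values():
        assert (
            row.n_upstream_proximal + row.n_inside_gene + row.n_distal + row.n_no_gene
            == row.n_hits
        )
    assert s.total_hits == len(truth.plants)
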
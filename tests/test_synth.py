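"""Synthetic genome generation: determinism, truth tables, planted recovery."""

import io

import numpy as np
import pytest

from ersescreen.annotate import GeneRecord
from ersescreen.motifs import builtin_erse_motifs, matches_at
from ersescreen.scan import ScanOptions, scan_fasta
from ersescreen.synth import (
    GenomeConfig,
    PlantSpec,
    default_fixture,
    generate_genome,
    instantiate_motif,
    load_config,
    naive_scan_sequence,
    truth_to_tsv,
)


def hit_key(h):
    return (h.sequence_id, h.start, h.motif_name, h.strand)


def test_instantiate_motif_always_matches(erse_motifs):
    rng = np.random.default_rng(0)
    for _ in range(2000):
        for m in erse_motifs:
            s = instantiate_motif(m, rng)
            assert len(s) == m.total_length
            assert matches_at(m, s, 0)


def test_instantiate_motif_fixed_blocks_and_determinism(erse2):
    s1 = instantiate_motif(erse2, np.random.default_rng(1))
    s2 = instantiate_motif(erse2, np.random.default_rng(1))
    assert s1 == s2
    assert s1.startswith("ATTGG") and s1.endswith("CCACG")


def small_config(seed=7, **kw):
    genes = [
        GeneRecord("g1", "g1", "s1", "+", 20_000, 40_000),
        GeneRecord("g2", "g2", "s1", "-", 44_000, 48_000),
    ]
    plants = [
        PlantSpec("ERSE-I", "s1", 15_000),
        PlantSpec("ERSE-I", "s1", 25_000),
        PlantSpec("ERSE-I", "s1", 5_000),
        PlantSpec("ERSE-I", "s1", 49_000, strand="-"),
        PlantSpec("ERSE-I", "s1", 30_000),
    ]
    return GenomeConfig(seed=seed, lengths={"s1": 50_000}, plants=plants,
                        genes=genes, **kw)


def test_generated_genome_recovers_all_plants():
    cfg = small_config()
    fasta, gff3, truth = generate_genome(cfg)
    hits = list(scan_fasta(io.StringIO(fasta), cfg.motifs, cfg.scan_options()))
    got = {hit_key(h) for h in hits}
    assert {hit_key(h) for h in truth.planted_hits} <= got
    assert "##gff-version 3" in gff3
    assert "ID=g1" in gff3


def test_generation_is_byte_deterministic():
    f1, g1, _ = generate_genome(small_config())
    f2, g2, _ = generate_genome(small_config())
    assert f1 == f2 and g1 == g2
    f3, _, _ = generate_genome(small_config(seed=8))
    assert f3 != f1


def test_fasta_wrapped_at_60_columns():
    fasta, _, _ = generate_genome(small_config())
    body = [l for l in fasta.splitlines() if not l.startswith(">")]
    assert all(len(l) == 60 for l in body[:-1])


@pytest.mark.parametrize(
    "plants,err",
    [
        ([PlantSpec("ERSE-I", "s1", 49_990)], "out of bounds"),
        ([PlantSpec("ERSE-I", "s1", 100), PlantSpec("ERSE-II", "s1", 110)], "overlap"),
        ([PlantSpec("ERSE-I", "nope", 100)], "unknown sequence"),
        ([PlantSpec("NOPE", "s1", 100)], "unknown motif"),
    ],
)
def test_invalid_plants_rejected(plants, err):
    cfg = GenomeConfig(seed=1, lengths={"s1": 50_000}, plants=plants)
    with pytest.raises(ValueError, match=err):
        generate_genome(cfg)


def test_out_of_bounds_gene_rejected():
    cfg = GenomeConfig(seed=1, lengths={"s1": 1000},
                       genes=[GeneRecord("g", "g", "s1", "+", 0, 2000)])
    with pytest.raises(ValueError, match="out of bounds"):
        generate_genome(cfg)


def test_default_fixture_layout(fixture_genome):
    cfg, fasta, gff3, truth = fixture_genome
    assert len(cfg.plants) == 100
    assert len(cfg.genes) == 30
    assert len(cfg.lengths) == 10
    assert set(cfg.lengths.values()) == {100_000}
    strands = {g.strand for g in cfg.genes}
    assert strands == {"+", "-"}
    # every association category is exercised
    cats = {p.association.category.value for p in truth.plants}
    assert cats == {"UPSTREAM_PROXIMAL", "INSIDE_GENE", "DISTAL", "NO_GENE"}


def test_default_fixture_intents_match_computed_categories(fixture_genome):
    cfg, _, _, truth = fixture_genome
    checked = 0
    for p in truth.plants:
        if p.spec.category_intent is not None:
            assert p.association.category.value == p.spec.category_intent
            checked += 1
    assert checked >= 80


def test_background_hits_are_oracle_confirmed(fixture_genome):
    """Every non-planted scanner hit appears in the truth's background list."""
    cfg, fasta, _, truth = fixture_genome
    hits = list(scan_fasta(io.StringIO(fasta), cfg.motifs, cfg.scan_options()))
    planted = {hit_key(h) for h in truth.planted_hits}
    background = {hit_key(h) for h in truth.background_hits}
    extras = {hit_key(h) for h in hits} - planted
    assert extras == background


def test_expected_summary_recomputable(fixture_genome):
    from ersescreen.annotate import associate_hits, summarize

    cfg, _, _, truth = fixture_genome
    hits = truth.planted_hits
    s = summarize(associate_hits(hits, truth.genes, cfg.screen_config), hits, truth.genes)
    assert s == truth.expected_summary


def test_truth_tsv_roundtrip_rows(fixture_genome):
    _, _, _, truth = fixture_genome
    lines = truth_to_tsv(truth).splitlines()
    assert len(lines) == 1 + len(truth.plants) + len(truth.background_hits)
    assert lines[1].startswith("planted\t")


def test_load_config_toml(tmp_path):
    cfg_text = """
seed = 5

[sequences]
s1 = 2000
s2 = 1000

[base_composition]
a = 0.3
c = 0.2
g = 0.2
t = 0.3

[motifs]
"ERSE-II" = "ATTGG-N-CCACG"

[[plants]]
motif = "ERSE-II"
sequence = "s1"
position = 100

[[genes]]
id = "g1"
sequence = "s1"
strand = "+"
start = 500
end = 1500
"""
    path = tmp_path / "build.toml"
    path.write_text(cfg_text)
    cfg = load_config(str(path))
    assert cfg.seed == 5
    assert cfg.lengths == {"s1": 2000, "s2": 1000}
    assert [m.name for m in cfg.motifs] == ["ERSE-II"]
    assert cfg.base_composition["A"] == 0.3
    fasta, _, truth = generate_genome(cfg)
    assert truth.plants[0].hit.start == 100


def test_load_config_requires_seed(tmp_path):
    path = tmp_path / "bad.toml"
    path.write_text("[sequences]\ns1 = 100\n")
    with pytest.raises(ValueError, match="seed"):
        load_config(str(path))


def test_naive_scan_reverse_strand_consistency(erse_motifs):
    from conftest import random_sequence
    from ersescreen.scan import scan_sequence

    rng = np.random.default_rng(17)
    seq = random_sequence(20_000, rng)
    opts = ScanOptions(scan_reverse_strand=True)
    assert naive_scan_sequence("c", seq, erse_motifs, opts) == scan_sequence(
        "c", seq, erse_motifs, opts
    )
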
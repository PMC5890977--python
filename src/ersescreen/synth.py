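"""Seeded synthetic genomes with planted elements and ground truth.

The generator draws i.i.d. background sequence, overwrites it with
concrete instances of the configured motifs at specified positions
(reverse-strand plants are written as the reverse complement), lays down
gene annotations, and emits FASTA (wrapped at 60 columns, deliberately
exercising the scanner's line-spanning contract), GFF3 and a truth table.

Background sequence can spawn spurious motif occurrences by chance; the
generator does not reject them — rejection would bias the background —
but enumerates them with an exhaustive per-offset matcher and records
them in the truth table, so tests can account for every hit the scanner
reports.  Expected screen summaries are computed from the planted hits
with the annotation module's own rules, keeping the truth table and the
pipeline definitionally consistent.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotate import (
    Association,
    GeneIndex,
    GeneRecord,
    ScreenConfig,
    ScreenSummary,
    associate_hit,
    summarize,
)
from .motifs import (
    ConsensusMotif,
    ERSE_PRESETS,
    IUPAC_TABLE,
    builtin_erse_motifs,
    compile_consensus,
    reverse_complement,
)
from .scan import MotifHit, ScanOptions

__all__ = [
    "PlantSpec",
    "PlantedElement",
    "SyntheticTruth",
    "GenomeConfig",
    "instantiate_motif",
    "naive_scan_sequence",
    "generate_genome",
    "default_fixture",
    "load_config",
    "truth_to_tsv",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class PlantSpec:
    """Where to plant one motif instance.

    ``category_intent`` optionally records the association category the
    layout was designed to produce; the truth table always carries the
    category actually computed by the annotation rules.
    """

    motif_name: str
    sequence_id: str
    position: int  # 0-based start
    strand: str = "+"
    category_intent: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"plant strand must be '+' or '-', got {self.strand!r}")
        if self.position < 0:
            raise ValueError("plant position must be >= 0")


@dataclass(frozen=True)
class PlantedElement:
    """A plant after instantiation: its hit record and truth category."""

    spec: PlantSpec
    hit: MotifHit
    association: Association


@dataclass
class SyntheticTruth:
    """Ground truth of one generated genome."""

    plants: list[PlantedElement]
    genes: list[GeneRecord]
    expected_summary: ScreenSummary
    background_hits: list[MotifHit]

    @property
    def planted_hits(self) -> list[MotifHit]:
        return [p.hit for p in self.plants]


@dataclass
class GenomeConfig:
    """Full description of one synthetic genome build."""

    seed: int
    lengths: dict[str, int]  # sequence_id -> length
    plants: list[PlantSpec] = field(default_factory=list)
    genes: list[GeneRecord] = field(default_factory=list)
    base_composition: dict[str, float] = field(
        default_factory=lambda: {b: 0.25 for b in _BASES}
    )
    motifs: list[ConsensusMotif] = field(default_factory=builtin_erse_motifs)
    screen_config: ScreenConfig = field(default_factory=ScreenConfig)
    scan_reverse_strand: bool | None = None  # None: infer from plant strands

    def scan_options(self) -> ScanOptions:
        rev = self.scan_reverse_strand
        if rev is None:
            rev = any(p.strand == "-" for p in self.plants)
        return ScanOptions(scan_reverse_strand=rev)


def instantiate_motif(motif: ConsensusMotif, rng: np.random.Generator) -> str:
    """Draw one concrete DNA string satisfying the motif.

    Degenerate fixed codes resolve uniformly over their base sets; spacer
    positions draw uniformly from ACGT.
    """
    out = []
    for code in motif.position_codes:
        choices = sorted(IUPAC_TABLE[code]) if code else list(_BASES)
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def naive_scan_sequence(
    sequence_id: str,
    sequence: str,
    motifs: Sequence[ConsensusMotif],
    options: ScanOptions = ScanOptions(),
) -> list[MotifHit]:
    """Exhaustive per-offset matcher — the reference the scanner is held to.

    Checks every (offset, motif) pair position-by-position with no
    preprocessing beyond upper-casing, so its correctness is transparent.
    """

    def one_strand(seq: str) -> dict[str, list[int]]:
        found: dict[str, list[int]] = {}
        upper = seq.upper()
        for motif in motifs:
            checks = [
                (i, IUPAC_TABLE[c])
                for i, c in enumerate(motif.position_codes)
                if c is not None
            ]
            starts: list[int] = []
            for off in range(len(seq) - motif.total_length + 1):
                for i, allowed in checks:
                    if upper[off + i] not in allowed:
                        break
                else:
                    starts.append(off)
            found[motif.name] = starts
        return found

    by_len = {m.name: m.total_length for m in motifs}
    hits: list[MotifHit] = []
    for name, starts in one_strand(sequence).items():
        for s in starts:
            hits.append(
                MotifHit(sequence_id, s, s + by_len[name], name, "+",
                         sequence[s : s + by_len[name]])
            )
    if options.scan_reverse_strand:
        rc = reverse_complement(sequence)
        n = len(sequence)
        for name, starts in one_strand(rc).items():
            tl = by_len[name]
            for s in starts:
                hits.append(
                    MotifHit(sequence_id, n - s - tl, n - s, name, "-",
                             rc[s : s + tl])
                )
    hits.sort(key=lambda h: (h.start, h.motif_name, h.strand))
    return hits


def _wrap_fasta(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def generate_genome(config: GenomeConfig) -> tuple[str, str, SyntheticTruth]:
    """Build (FASTA text, GFF3 text, truth) from a genome config.

    Byte-identical across runs with the same config and seed.  Rejects
    out-of-bounds or mutually overlapping plants and out-of-bounds genes
    at generation time.
    """
    motif_by_name = {m.name: m for m in config.motifs}
    # validate plants and genes against sequence bounds
    occupied: dict[str, list[tuple[int, int]]] = {}
    for p in sorted(config.plants, key=lambda p: (p.sequence_id, p.position, p.motif_name)):
        if p.sequence_id not in config.lengths:
            raise ValueError(f"plant on unknown sequence {p.sequence_id!r}")
        if p.motif_name not in motif_by_name:
            raise ValueError(f"plant references unknown motif {p.motif_name!r}")
        tl = motif_by_name[p.motif_name].total_length
        if p.position + tl > config.lengths[p.sequence_id]:
            raise ValueError(
                f"plant at {p.sequence_id}:{p.position} ({p.motif_name}) out of bounds"
            )
        for s, e in occupied.get(p.sequence_id, []):
            if p.position < e and s < p.position + tl:
                raise ValueError(
                    f"overlapping plants on {p.sequence_id} at {p.position}"
                )
        occupied.setdefault(p.sequence_id, []).append((p.position, p.position + tl))
    for g in config.genes:
        if g.sequence_id not in config.lengths:
            raise ValueError(f"gene {g.gene_id!r} on unknown sequence {g.sequence_id!r}")
        if g.end > config.lengths[g.sequence_id]:
            raise ValueError(f"gene {g.gene_id!r} out of bounds")

    rng = np.random.default_rng(config.seed)
    comp_bases = sorted(config.base_composition)
    probs = np.array([config.base_composition[b] for b in comp_bases])
    probs = probs / probs.sum()

    sequences: dict[str, str] = {}
    for seq_id in config.lengths:  # insertion order = file order
        length = config.lengths[seq_id]
        draw = rng.choice(np.frombuffer("".join(comp_bases).encode(), dtype="S1"),
                          size=length, p=probs)
        sequences[seq_id] = draw.tobytes().decode()

    plants_sorted = sorted(
        config.plants, key=lambda p: (p.sequence_id, p.position, p.motif_name)
    )
    planted: list[PlantedElement] = []
    gene_index = GeneIndex(config.genes)
    buffers = {sid: list(s) for sid, s in sequences.items()}
    for p in plants_sorted:
        motif = motif_by_name[p.motif_name]
        instance = instantiate_motif(motif, rng)
        written = instance if p.strand == "+" else reverse_complement(instance)
        buf = buffers[p.sequence_id]
        buf[p.position : p.position + motif.total_length] = written
        hit = MotifHit(
            sequence_id=p.sequence_id,
            start=p.position,
            end=p.position + motif.total_length,
            motif_name=p.motif_name,
            strand=p.strand,
            matched_text=instance,
        )
        planted.append(
            PlantedElement(
                spec=p,
                hit=hit,
                association=associate_hit(hit, gene_index, config.screen_config),
            )
        )
    sequences = {sid: "".join(buf) for sid, buf in buffers.items()}

    options = config.scan_options()
    planted_keys = {
        (e.hit.sequence_id, e.hit.start, e.hit.motif_name, e.hit.strand)
        for e in planted
    }
    background: list[MotifHit] = []
    for seq_id, seq in sequences.items():
        for h in naive_scan_sequence(seq_id, seq, config.motifs, options):
            if (h.sequence_id, h.start, h.motif_name, h.strand) not in planted_keys:
                background.append(h)

    expected = summarize(
        [e.association for e in planted],
        [e.hit for e in planted],
        config.genes,
    )
    truth = SyntheticTruth(
        plants=planted,
        genes=config.genes,
        expected_summary=expected,
        background_hits=background,
    )

    fasta = "".join(
        f">{sid}\n{_wrap_fasta(seq)}\n" for sid, seq in sequences.items()
    )
    gff_lines = ["##gff-version 3"]
    for sid, length in config.lengths.items():
        gff_lines.append(f"##sequence-region {sid} 1 {length}")
    for g in config.genes:
        gff_lines.append(
            f"{g.sequence_id}\t.\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id};Name={g.gene_name}"
        )
    gff3 = "\n".join(gff_lines) + "\n"
    return fasta, gff3, truth


# ---------------------------------------------------------------------------
# the standard desk-scale fixture

#: Per-chromosome gene slots (start, end, strand) for gene-bearing sequences.
_GENE_SLOTS = [
    (20_000, 45_000, "+"),
    (60_000, 64_000, "-"),  # short gene: body < downstream window
    (80_000, 95_000, "-"),
    (5_000, 9_000, "+"),
]

#: Plant sites within each gene-bearing sequence, with hand-checked intent
#: where the closest-gene outcome is unambiguous by construction.
_PLANT_SITES: list[tuple[int, str | None]] = [
    (2_000, "UPSTREAM_PROXIMAL"),  # upstream of the gene at 5 kb (where present)
    (6_000, None),
    (15_000, "UPSTREAM_PROXIMAL"),  # within 10 kb of the TSS at 20 kb
    (25_000, "INSIDE_GENE"),
    (35_000, "INSIDE_GENE"),
    (50_000, "DISTAL"),  # 4 kb past the long gene's end, > 20 kb past its TSS
    (65_000, "UPSTREAM_PROXIMAL"),  # '-' gene: upstream is rightward
    (85_000, "INSIDE_GENE"),
    (96_000, "UPSTREAM_PROXIMAL"),
    (98_500, "UPSTREAM_PROXIMAL"),
]


def default_fixture(
    seed: int,
    n_sequences: int = 10,
    seq_length: int = 100_000,
    screen_config: ScreenConfig | None = None,
) -> GenomeConfig:
    """The standard test genome: 10 x 100 kb, 100 plants, 30 genes.

    Eight sequences carry genes on both strands (including one gene much
    shorter than the downstream window); the last two are gene-free so
    plants there fall in no-gene territory.  Plant sites exercise every
    association category; motif classes cycle through the three element
    presets and every seventh plant goes on the reverse strand.
    """
    if n_sequences < 3:
        raise ValueError("fixture needs at least 3 sequences")
    seq_ids = [f"chr{i + 1:02d}" for i in range(n_sequences)]
    lengths = {sid: seq_length for sid in seq_ids}
    gene_seqs = seq_ids[:-2]

    genes: list[GeneRecord] = []
    for si, sid in enumerate(gene_seqs):
        n_slots = 4 if si < 6 else 3
        for slot, (start, end, strand) in enumerate(_GENE_SLOTS[:n_slots]):
            if len(genes) >= 30:
                break
            gid = f"G{len(genes) + 1:03d}"
            genes.append(GeneRecord(gid, gid, sid, strand, start, end))

    motif_names = list(ERSE_PRESETS)
    plants: list[PlantSpec] = []
    for si, sid in enumerate(gene_seqs):
        has_short_slot = si >= 6  # chr07/chr08 lack the gene at 5 kb
        for pos, intent in _PLANT_SITES:
            if intent == "UPSTREAM_PROXIMAL" and pos == 2_000 and has_short_slot:
                intent = None  # no gene at 5 kb on these sequences
            i = len(plants)
            plants.append(
                PlantSpec(
                    motif_name=motif_names[i % 3],
                    sequence_id=sid,
                    position=pos,
                    strand="-" if i % 7 == 6 else "+",
                    category_intent=intent,
                )
            )
    for sid in seq_ids[-2:]:
        for k in range(10):
            i = len(plants)
            plants.append(
                PlantSpec(
                    motif_name=motif_names[i % 3],
                    sequence_id=sid,
                    position=5_000 + 10_000 * k,
                    strand="-" if i % 7 == 6 else "+",
                    category_intent="NO_GENE",
                )
            )

    return GenomeConfig(
        seed=seed,
        lengths=lengths,
        plants=plants,
        genes=genes,
        screen_config=screen_config or ScreenConfig(),
    )


# ---------------------------------------------------------------------------
# flat config files

def load_config(path: str) -> GenomeConfig:
    """Read a genome build config from a flat TOML file.

    Top level: ``seed`` (mandatory), ``sequences`` (table id -> length),
    optional ``base_composition`` table, optional ``motifs`` table
    (name -> spaced-consensus pattern; defaults to the ERSE presets),
    plus ``[[plants]]`` and ``[[genes]]`` arrays.
    """
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    if "seed" not in doc:
        raise ValueError("config must set 'seed'")
    if "sequences" not in doc:
        raise ValueError("config must set a [sequences] table (id -> length)")
    motifs = (
        [compile_consensus(pat, name) for name, pat in doc["motifs"].items()]
        if "motifs" in doc
        else builtin_erse_motifs()
    )
    plants = [
        PlantSpec(
            motif_name=p["motif"],
            sequence_id=p["sequence"],
            position=int(p["position"]),
            strand=p.get("strand", "+"),
        )
        for p in doc.get("plants", [])
    ]
    genes = [
        GeneRecord(
            gene_id=g["id"],
            gene_name=g.get("name", g["id"]),
            sequence_id=g["sequence"],
            strand=g["strand"],
            start=int(g["start"]),
            end=int(g["end"]),
        )
        for g in doc.get("genes", [])
    ]
    kwargs = {}
    if "base_composition" in doc:
        kwargs["base_composition"] = {
            k.upper(): float(v) for k, v in doc["base_composition"].items()
        }
    return GenomeConfig(
        seed=int(doc["seed"]),
        lengths={k: int(v) for k, v in doc["sequences"].items()},
        plants=plants,
        genes=genes,
        motifs=motifs,
        **kwargs,
    )


def truth_to_tsv(truth: SyntheticTruth) -> str:
    """Truth table: planted and background hits with truth categories."""
    lines = [
        "kind\tmotif\tchrom\tstart_0based\tend\tstrand\tmatched_text\t"
        "gene_id\tsigned_distance_bp\tcategory"
    ]
    for e in truth.plants:
        a = e.association
        lines.append(
            f"planted\t{e.hit.motif_name}\t{e.hit.sequence_id}\t{e.hit.start}\t"
            f"{e.hit.end}\t{e.hit.strand}\t{e.hit.matched_text}\t"
            f"{a.gene_id or '.'}\t"
            f"{a.signed_distance if a.signed_distance is not None else '.'}\t"
            f"{a.category.value}"
        )
    for h in truth.background_hits:
        lines.append(
            f"background\t{h.motif_name}\t{h.sequence_id}\t{h.start}\t{h.end}\t"
            f"{h.strand}\t{h.matched_text}\t.\t.\t."
        )
    return "\n".join(lines) + "\n"
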
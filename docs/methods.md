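# Methods

## Element model and matching semantics

A spaced consensus is an ordered list of fixed IUPAC blocks and
fixed-length spacers; its length is the sum of block and spacer lengths.
Matching is position-wise with three deliberate conventions:

1. **Case-insensitive scanning.** Soft-masked (lowercase) regions are
   searched; repeat masking is a property of the FASTA distribution, not
   of the element definition, and the screen should not depend on it.
2. **Assembly ambiguity characters never satisfy a fixed position.** A
   genome `N` (or any non-ACGT letter) fails every fixed-block code,
   including a pattern `N` inside a fixed block: fixed positions assert
   base identity, and an undetermined base cannot do that. Long `N` runs
   in assemblies therefore produce no hits, rather than a flood of them.
3. **Spacer positions accept anything**, including genome `N`: spacers
   are explicit wildcards by definition.

Patterns are stored 5'→3' as written. A bare `N` spacer token means
length 1 (the conventional `ATTGG-N-CCACG` notation); adjacent spacers
merge at compile time so the block list is canonical and serialization
round-trips.

The production scanner compiles each motif to a regular expression of
character classes and `.{k}` gaps wrapped in a lookahead, so overlapping
and nested occurrences are all reported — occurrences are independent
candidate elements and non-overlapping consumption would silently drop
some. Each FASTA record is held in memory and scanned as one unwrapped
string, so matches spanning line breaks are found by construction; at
human-chromosome scale this peaks around a quarter of a gigabyte of
text, well within ordinary memory. The exhaustive per-offset matcher
(`naive_scan_sequence`) shares only the single-position semantics with
the regex path and serves as its reference in tests.

**Strand convention.** Forward-strand-only scanning is the default; the
`--reverse-strand` flag also scans the reverse complement and reports
hits in forward coordinates with strand `-` and `matched_text` as read
on the reported strand. Note ERSE-I's reverse complement
(`CGTGG-N9-ATTGG`) is not ERSE-II, so two-strand scanning cannot
double-count across classes.

## Gene assignment

The TSS is the gene's 5' end in its orientation: interval start for `+`
genes, end − 1 for `-` genes (0-based, half-open). The signed distance
of a hit is 0 if its interval contains the TSS, otherwise the distance
from the TSS to the nearest hit edge, negative on the upstream side.
Edge distance (not midpoint) matches how gap distances are read off a
genome browser.

Each hit is assigned to the gene minimising |d| among all genes whose
TSS lies within the 100 kb scan radius or which overlap the hit. Ties
break deterministically: upstream preferred over downstream, then
smallest gene id. Window boundaries are inclusive (−10,000 and +20,000
are candidate; one bp beyond is distal) — "within 10 kb" reads naturally
as inclusive and the tests pin it. The inside-gene category additionally
requires overlap with the gene interval, so an element past the end of a
short gene is distal even when d ≤ +20 kb. The no-gene scan is symmetric
(any TSS within 100 kb) by default because a one-sided scan discards
informative downstream neighbours; `strict_upstream_no_gene` restores
the literal one-sided upstream reading.

Tunable windows (`ScreenConfig`): upstream 10,000 bp, downstream
20,000 bp from the TSS, no-gene radius 100,000 bp — the standard
promoter-proximal / gene-body / vicinity scales for this screen.
Candidate genes are counted once per element class; the grand total sums
classes (a gene hit by two classes counts twice there), with a
cross-class distinct count reported alongside. Transcript-isoform-aware
TSS selection is out of scope: one TSS per gene record.

## Promoter scan and conservation

The promoter window (default 5,000 bp) is extracted 5'→3' on the gene's
strand ending at the TSS, clipped at contig boundaries; offsets are
reported as positive "bp upstream" from the TSS to the 5'-most base of
the match. Matching is exact IUPAC consensus on the gene's strand only —
no position-weight-matrix scoring or match p-values; the consensus
presets are short and nearly information-saturated, so threshold choice
would dominate any PWM refinement.

Conservation of an element instance across species is the Hamming count
over fixed-block positions only, case-insensitive, with spacers ignored
(they are unconstrained in the model, so their divergence is not
evidence against conservation). The default call threshold is 2
mismatches: one to two substitutions across a ~10-position consensus
still leaves the element recognisable by its factors. Ortholog sequences
are user-supplied and assumed pre-aligned to the motif window; ortholog
retrieval and alignment are out of scope.

## Synthetic genomes

The generator draws i.i.d. background (uniform ACGT by default,
composition configurable), overwrites it with concrete motif instances
(degenerate codes resolved uniformly, spacers uniform ACGT;
reverse-strand plants written as reverse complements), and emits
60-column-wrapped FASTA — deliberately exercising the line-spanning
contract — plus GFF3 and a truth table. Generation is byte-deterministic
given config and seed (single `numpy` generator, fixed draw order).

Background can spawn spurious element occurrences (expected
(L−18)·4⁻¹⁰ per strand for the 19-mer element on uniform sequence);
rejecting them would bias the background, so they are instead
enumerated with the exhaustive matcher and recorded as
oracle-confirmed background hits. Expected screen summaries are computed
from the planted hits by the annotation module's own rules, so the truth
table cannot drift from the pipeline's definitions; the standard
fixture's hand-checked placements are additionally asserted against
their intended categories in tests.

The standard fixture (10 × 100 kb, 100 plants, 30 genes) covers genes on
both strands, a gene body much shorter than the downstream window, and
two gene-free 100 kb sequences, so every association category occurs.
What it does **not** emulate: real base composition, isochores, repeats,
alternative TSSs, or any regulatory signal beyond the planted elements —
passing tests demonstrate the machinery is exact, not that candidate
genes from a real genome are biologically validated.

## Scales used in verification

Scanner-vs-oracle equivalence runs on 50 seeded 100 kb sequences; the
background-rate check aggregates 100 × 10 Mb (1 Gb) in the test suite
and 20 × 10 Mb in the acceptance script, comparing the aggregate count
to the analytic expectation within three binomial standard deviations.
The acceptance script's promoter offsets (3530 / 2422 / 1468 bp) and
ortholog mismatch counts (1 / 2 / 2) are computed on synthetic inputs
constructed to that layout — they verify the measurement machinery, not
any external genome.

A full reference-genome run is supported through the same CLI but needs
the assembly FASTA and annotation locally; published element counts for
such screens depend on unstated choices (strand handling, scanned record
subset, line-buffering of the original implementation, annotation
release), so the manifest's per-record counts are the basis for
reconciling any replication attempt.

## Known limitations

- One association per hit (its closest gene); polycistronic or
  bidirectional-promoter ambiguity is resolved by the tie-break, not
  modelled.
- Consensus matching is binary; degenerate-position information content
  is ignored.
- The GFF3 reader uses `gene` features only and requires explicit
  strands.
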
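"""Spaced degenerate consensus motifs.

An ER stress-response element (ERSE) is a tripartite promoter motif: two
short fixed blocks separated by a fixed-length stretch of unconstrained
nucleotides (a *spacer*), e.g. ``CCAAT-N9-CCACG``.  This module defines the
:class:`ConsensusMotif` container for such patterns, the IUPAC degenerate
nucleotide alphabet, and position-wise matching semantics.

Matching rules
--------------
* Fixed-block positions assert base identity through the IUPAC code sets;
  they are case-insensitive (soft-masked lowercase genome regions are
  searched) but an assembly ambiguity character (``N`` or any other
  non-ACGT letter) in the *genome* never satisfies a fixed position — not
  even a fixed-block ``N`` code.
* Spacer positions are explicit wildcards and accept any character,
  including assembly ``N``.

Patterns are stored 5'->3' as written; reverse-complement handling is the
scanner's job, not the motif's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

__all__ = [
    "IUPAC_TABLE",
    "FixedBlock",
    "Spacer",
    "ConsensusMotif",
    "compile_consensus",
    "base_matches",
    "matches_at",
    "reverse_complement",
    "iupac_matches",
    "ERSE_PRESETS",
    "builtin_erse_motifs",
    "load_motif_file",
]

#: IUPAC degenerate nucleotide codes mapped to their concrete base sets.
IUPAC_TABLE: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware, case kept)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FixedBlock:
    """A contiguous run of IUPAC-constrained positions."""

    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("fixed block must be non-empty")
        for i, b in enumerate(self.bases):
            if b.upper() not in IUPAC_TABLE:
                raise ValueError(
                    f"invalid IUPAC code {b!r} at position {i} of block {self.bases!r}"
                )
        object.__setattr__(self, "bases", self.bases.upper())

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class Spacer:
    """``k`` unconstrained nucleotide positions between fixed blocks."""

    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"spacer length must be >= 1, got {self.length}")

    def __len__(self) -> int:
        return self.length


Block = Union[FixedBlock, Spacer]


@dataclass(frozen=True)
class ConsensusMotif:
    """A spaced degenerate consensus pattern.

    Parameters
    ----------
    name
        Short label, e.g. ``"ERSE-I"``.
    blocks
        Ordered fixed blocks and spacers.  Adjacent spacers are merged at
        construction so the block list is canonical.
    """

    name: str
    blocks: tuple[Block, ...]
    total_length: int = field(init=False)

    def __post_init__(self) -> None:
        merged: list[Block] = []
        for blk in self.blocks:
            if (
                isinstance(blk, Spacer)
                and merged
                and isinstance(merged[-1], Spacer)
            ):
                merged[-1] = Spacer(merged[-1].length + blk.length)
            else:
                merged.append(blk)
        if not any(isinstance(b, FixedBlock) for b in merged):
            raise ValueError(f"motif {self.name!r} has no fixed block")
        object.__setattr__(self, "blocks", tuple(merged))
        object.__setattr__(self, "total_length", sum(len(b) for b in merged))

    @property
    def fixed_positions(self) -> tuple[int, ...]:
        """0-based offsets within the motif window that are constrained."""
        out: list[int] = []
        pos = 0
        for blk in self.blocks:
            if isinstance(blk, FixedBlock):
                out.extend(range(pos, pos + len(blk)))
            pos += len(blk)
        return tuple(out)

    @property
    def position_codes(self) -> tuple[str | None, ...]:
        """Per-position IUPAC code, ``None`` at spacer positions."""
        out: list[str | None] = []
        for blk in self.blocks:
            if isinstance(blk, FixedBlock):
                out.extend(blk.bases)
            else:
                out.extend([None] * blk.length)
        return tuple(out)

    def pattern(self) -> str:
        """Serialize back to dash-delimited spaced-consensus notation."""
        parts = []
        for blk in self.blocks:
            if isinstance(blk, FixedBlock):
                parts.append(blk.bases)
            else:
                parts.append("N" if blk.length == 1 else f"N{blk.length}")
        return "-".join(parts)


def compile_consensus(pattern: str, name: str = "") -> ConsensusMotif:
    """Parse a dash-delimited spaced-consensus string into a motif.

    Tokens are either IUPAC strings (fixed blocks) or spacer tokens ``N`` /
    ``N<k>`` with ``k >= 1``.  A bare ``N`` token is a spacer of length 1,
    matching the conventional ``ATTGG-N-CCACG`` notation for ERSE-II.

    >>> compile_consensus("CCAAT-N9-CCACG", "ERSE-I").total_length
    19
    """
    if not name:
        name = pattern
    tokens = pattern.split("-")
    blocks: list[Block] = []
    for tok in tokens:
        if not tok:
            raise ValueError(f"zero-length token in pattern {pattern!r}")
        upper = tok.upper()
        if upper == "N":
            blocks.append(Spacer(1))
        elif upper[0] == "N" and upper[1:].isdigit():
            k = int(upper[1:])
            if k < 1:
                raise ValueError(f"spacer length must be >= 1 in token {tok!r}")
            blocks.append(Spacer(k))
        else:
            blocks.append(FixedBlock(upper))
    return ConsensusMotif(name=name, blocks=tuple(blocks))


def base_matches(code: str, base: str) -> bool:
    """Does a genome character satisfy one IUPAC code at a fixed position?

    True iff the upper-cased ``base`` is one of the code's concrete bases.
    Assembly ambiguity characters never satisfy a fixed position: genome
    ``N`` fails even against pattern code ``N``.
    """
    try:
        allowed = IUPAC_TABLE[code.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {code!r}") from None
    return base.upper() in allowed


def iupac_matches(pattern: str, text: str) -> bool:
    """Does ``text`` satisfy the plain (unspaced) IUPAC ``pattern``?

    Lengths must agree; every position is a fixed position.
    """
    if len(pattern) != len(text):
        raise ValueError(
            f"length mismatch: pattern {len(pattern)} vs text {len(text)}"
        )
    return all(base_matches(c, b) for c, b in zip(pattern, text))


def matches_at(motif: ConsensusMotif, sequence: str, offset: int) -> bool:
    """Does ``motif`` match ``sequence`` at 0-based ``offset``?

    The window must fit entirely inside the sequence; an out-of-range
    offset is an error, not a non-match.
    """
    if offset < 0 or offset > len(sequence) - motif.total_length:
        raise ValueError(
            f"offset {offset} out of range for sequence of length "
            f"{len(sequence)} and motif length {motif.total_length}"
        )
    pos = offset
    for blk in motif.blocks:
        if isinstance(blk, FixedBlock):
            for code in blk.bases:
                if not base_matches(code, sequence[pos]):
                    return False
                pos += 1
        else:
            pos += blk.length
    return True


#: The three ERSE consensus patterns used as genome-screen probes.
ERSE_PRESETS: dict[str, str] = {
    "ERSE-I": "CCAAT-N9-CCACG",
    "ERSE-II": "ATTGG-N-CCACG",
    "ERSE-III": "CCAAT-N26-CCACG",
}


def builtin_erse_motifs() -> list[ConsensusMotif]:
    """The ERSE I/II/III presets, compiled."""
    return [compile_consensus(pat, name) for name, pat in ERSE_PRESETS.items()]


def load_motif_file(lines: Iterable[str]) -> list[ConsensusMotif]:
    """Read a motif definition file: ``name<TAB>pattern`` per line.

    Blank lines and ``#`` comment lines are skipped.
    """
    motifs: list[ConsensusMotif] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(
                f"motif file line {lineno}: expected 'name<TAB>pattern', got {line!r}"
            )
        motifs.append(compile_consensus(fields[1], fields[0]))
    return motifs
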
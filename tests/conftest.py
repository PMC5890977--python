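import io

import numpy as np
import pytest

from ersescreen import builtin_erse_motifs, default_fixture, generate_genome

BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Fast i.i.d. uniform ACGT sequence."""
    return BASES[rng.integers(0, 4, size=length)].tobytes().decode()


@pytest.fixture(scope="session")
def erse_motifs():
    return builtin_erse_motifs()


@pytest.fixture(scope="session")
def erse1(erse_motifs):
    return erse_motifs[0]


@pytest.fixture(scope="session")
def erse2(erse_motifs):
    return erse_motifs[1]


@pytest.fixture(scope="session")
def erse3(erse_motifs):
    return erse_motifs[2]


@pytest.fixture(scope="session")
def fixture_genome():
    """The standard 10 x 100 kb fixture at seed 11, generated once."""
    cfg = default_fixture(11)
    fasta, gff3, truth = generate_genome(cfg)
    return cfg, fasta, gff3, truth


@pytest.fixture()
def fixture_files(fixture_genome, tmp_path):
    cfg, fasta, gff3, truth = fixture_genome
    fa = tmp_path / "genome.fa"
    gff = tmp_path / "genes.gff3"
    fa.write_text(fasta)
    gff.write_text(gff3)
    return cfg, fa, gff, truth


def fasta_handle(text: str) -> io.StringIO:
    return io.StringIO(text)
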
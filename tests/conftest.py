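import numpy as np
import pytest

from kmermask.genome_io import GenomeSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def make_fasta(tmp_path):
    """Write a FASTA file from (name, residues) pairs and return its path."""

    def _write(records, filename="input.fa"):
        path = tmp_path / filename
        with open(path, "w") as handle:
            for name, residues in records:
                handle.write(f">{name}\n{residues}\n")
        return path

    return _write


def random_dna(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture
def genome_factory(rng):
    def _make(length, name="g"):
        return GenomeSequence(name, random_dna(rng, length))

    return _make
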
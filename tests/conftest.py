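import numpy as np
import pytest

import cubkit as ck
from cubkit.io import CodingSequence, CodonCountTable


@pytest.fixture(scope="session")
def code():
    return ck.STANDARD_CODE


@pytest.fixture(scope="session")
def table1():
    return ck.load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return ck.load_fixture("table2")


@pytest.fixture(scope="session")
def at_rich_90():
    """The seeded 90-sequence AT-rich panel used by dataset-level checks."""
    return ck.at_rich_panel(90, seed=42)


@pytest.fixture
def toy_fasta(tmp_path):
    p = tmp_path / "toy.fasta"
    p.write_text(">a\nATGAAATAA\n>b\nATGTTTTGA\n")
    return p


def make_counts(mapping):
    """Count table from a sparse codon→count mapping (DNA or RNA keys)."""
    counts = {}
    for codon, n in mapping.items():
        counts[codon.upper().replace("U", "T")] = n
    return CodonCountTable(counts=counts, n_codons=sum(mapping.values()))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
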
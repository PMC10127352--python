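import pytest

from mthap.alignment import write_fasta, write_popmap
from mthap.simulate import make_fixture


@pytest.fixture(scope="session")
def table4_like():
    """One locality, two species; planted haplotype counts 5/1/1 and 1/1/1."""
    return make_fixture("table4_like")


@pytest.fixture(scope="session")
def two_pop_fixed():
    """Two populations of two specimens, each fixed for its own haplotype."""
    return make_fixture("two_pop_fixed")


@pytest.fixture(scope="session")
def star():
    """Central haplotype with five one-step satellites."""
    return make_fixture("star")


@pytest.fixture
def fasta_and_popmap(tmp_path):
    """Write a SimulatedDataset to disk; returns (fasta, popmap) paths."""

    def _write(dataset):
        fasta = tmp_path / "aln.fasta"
        popmap = tmp_path / "popmap.tsv"
        write_fasta(((r.id, r.sequence) for r in dataset.alignment.records), fasta)
        write_popmap(dataset.alignment, popmap)
        return fasta, popmap

    return _write
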
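import pytest

from svprio import Contig, GenomicRegion, Strand
from svprio import synthetic as syn


@pytest.fixture(scope="session")
def world():
    return syn.make_toy_annotation(seed=0)


@pytest.fixture(scope="session")
def resources(world, tmp_path_factory):
    """The toy annotation world written out in every on-disk format."""
    out = tmp_path_factory.mktemp("toy_world")
    return syn.write_world(world, out)


@pytest.fixture(scope="session")
def contig():
    return Contig("chr1", 1_000_000)


@pytest.fixture
def region(contig):
    def make(start, end, strand=Strand.POS, c=None):
        return GenomicRegion(c or contig, start, end, strand)

    return make


@pytest.fixture(scope="session")
def g01(world):
    """The canonical 3-exon coding toy gene (UTR5 100 bp, UTR3 200 bp)."""
    return world.gene("G01")
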
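import pytest

from srnasig import AlignedRead, Library
from srnasig.scenarios import mixed_class_library
from srnasig.simulate import PlantedLocusSpec, SimConfig, simulate_library


def read(chrom="chr1", strand="+", start=100, end=121, first_nt="N"):
    return AlignedRead(chrom=chrom, strand=strand, start=start, end=end, first_nt=first_nt)


@pytest.fixture
def dicer_pair_library():
    """The minimal qualifying duplex: plus [100,121), minus [98,119)."""
    return Library(reads=[read(start=100, end=121), read(strand="-", start=98, end=119)])


@pytest.fixture(scope="session")
def mixed_sim():
    """One mixed-class simulated library with manifest (seed 11)."""
    return mixed_class_library(seed=11, n_loci=40)


@pytest.fixture(scope="session")
def small_sim():
    """A compact multi-class library with genome, for I/O round-trips."""
    cfg = SimConfig(
        n_chroms=2,
        chrom_length=50_000,
        seed=3,
        loci_specs=[
            PlantedLocusSpec("dicer_duplex", "chr1", 1_000, 60),
            PlantedLocusSpec("pingpong_pirna", "chr1", 10_000, 100),
            PlantedLocusSpec("phased_pirna", "chr2", 5_000, 30),
            PlantedLocusSpec("mirna_like", "chr2", 20_000, 40),
        ],
        background_reads=300,
    )
    return simulate_library(cfg)
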
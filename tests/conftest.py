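import numpy as np
import pytest

from postasm.io_formats import GenomicInterval, RepeatFeature, SVRecord
from postasm.synthetic_data import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def sim_genome(sim_config):
    return simulate_genome(sim_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_interval(chrom="chr1", start=0, end=100, strand="."):
    return GenomicInterval(chrom, start, end, strand)


def make_repeat(chrom="chr1", start=0, end=100, strand="+", cls="LTR", fam="Gypsy"):
    return RepeatFeature(GenomicInterval(chrom, start, end, strand), cls, fam)


def make_sv(
    id="SV1",
    sv_type="DEL",
    chrom="chr1",
    pos=100,
    end=6_730,
    precise=True,
    pe=7,
    sr=3,
    mapq=40,
    filter_status="PASS",
    genotypes=("0/0", "0/1"),
):
    return SVRecord(
        id=id,
        sv_type=sv_type,
        chrom=chrom,
        pos=pos,
        end=end,
        precise=precise,
        pe=pe,
        sr=sr,
        mapq=mapq,
        filter_status=filter_status,
        genotypes=tuple(genotypes),
    )
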
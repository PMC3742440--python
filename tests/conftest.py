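import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from peakprox.models import GeneList, GeneRecord, GenomeModel, GenomicInterval, PeakSet

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_genome() -> GenomeModel:
    return GenomeModel({"chr1": 2_000_000, "chr2": 1_500_000})


@pytest.fixture
def plus_gene() -> GeneRecord:
    return GeneRecord("gA", "chr1", "+", 10_000, 10_000, 15_000)


@pytest.fixture
def minus_gene() -> GeneRecord:
    return GeneRecord("gB", "chr1", "-", 14_999, 10_000, 15_000)


def make_peaks(spans, chrom="chr1", label="peaks", genome=None) -> PeakSet:
    ivs = [
        GenomicInterval(chrom if isinstance(span[0], int) else span[0],
                        *(span if isinstance(span[0], int) else span[1:]))
        for span in spans
    ]
    return PeakSet(label, ivs, genome)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
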
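import numpy as np
import pytest

from lncbind.genome import GenomicInterval, TranscriptModel, filter_lncrnas
from lncbind.synthetic import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def scenario():
    """Default synthetic scenario, seed 1 (all planted truths realized)."""
    return generate_scenario(ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def filtered_ann(scenario):
    return filter_lncrnas(scenario.annotation, "same_strand")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_transcript(rng, chrom="chr1", coding=False):
    """A random valid transcript for property tests."""
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(1, 5))
    pos = int(rng.integers(0, 1000))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(50, 300))
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length + int(rng.integers(10, 500))
    cds = None
    biotype = "lncRNA"
    if coding:
        biotype = "protein_coding"
        lo = exons[0].start + int(rng.integers(1, exons[0].length()))
        hi = exons[-1].end - int(rng.integers(1, exons[-1].length()))
        if lo < hi:
            cds = (lo, hi)
    return TranscriptModel("tx1", "g1", "G1", biotype, tuple(exons), cds)
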
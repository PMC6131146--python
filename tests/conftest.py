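import numpy as np
import pytest

from sarclone.genome import GenomeModel, ProbeMap
from sarclone.intervals import GenomicInterval, SegmentProfile


@pytest.fixture
def tiny_genome() -> dict[str, int]:
    """A two-chromosome desk-scale genome for brute-force comparison."""
    return {"chrA": 5000, "chrB": 3000}


@pytest.fixture
def tiny_genome_model(tiny_genome) -> GenomeModel:
    return GenomeModel(chrom_lengths=dict(tiny_genome),
                       centromeres={"chrA": 2500, "chrB": 1500},
                       probe_spacing=50)


def profile(sample_id, *spans, probe_map=None) -> SegmentProfile:
    """Shorthand: spans are (chrom, start, end, state) tuples."""
    return SegmentProfile(
        sample_id,
        tuple(GenomicInterval(c, s, e, st) for c, s, e, st in spans),
        probe_map=probe_map)


@pytest.fixture
def make_profile():
    return profile


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180910)
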
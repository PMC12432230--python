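import numpy as np
import pytest

from l1select.diagnostics import ConsensusSet
from l1select.io_formats import GenomicInterval, RepeatAnnotation
from l1select.lineage_sim import SimParams, plant_copies, simulate_lineage


@pytest.fixture(scope="session")
def tiny_params() -> SimParams:
    """A fast desk-scale lineage: 4 subfamilies of a 600 bp element."""
    return SimParams(
        n_subfamilies=4,
        consensus_length=600,
        step_substitution_rate=0.03,
        copies_per_subfamily=5,
        copy_divergence=0.01,
        truncation_prob=0.3,
        genome_length=20_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_lineage(tiny_params) -> ConsensusSet:
    return simulate_lineage(tiny_params)


@pytest.fixture(scope="session")
def tiny_genome(tiny_params, tiny_lineage):
    return plant_copies(tiny_params, tiny_lineage)


def make_annotation(chrom, start, end, name, strand="+", repeat_class="LINE", repeat_family="L1"):
    return RepeatAnnotation(
        GenomicInterval(chrom, start, end, strand=strand, name=name),
        name,
        repeat_class,
        repeat_family,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
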
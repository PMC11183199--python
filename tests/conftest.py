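import numpy as np
import pytest

from convergemeth.io_formats import CytosineRecord, SampleMeta
from convergemeth.methylome import MethylomeSet


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def sample_meta():
    return SampleMeta("s1", "aml", "aml")


def make_methylome(records, sample_id="s1", species="aml"):
    return MethylomeSet(records, SampleMeta(sample_id, species, species))


@pytest.fixture
def simple_methylome(sample_meta):
    records = [
        CytosineRecord("chr1", 100, "+", 4, 6, "CpG"),
        CytosineRecord("chr1", 200, "+", 6, 4, "CpG"),
        CytosineRecord("chr1", 300, "+", 1, 9, "CHH"),
        CytosineRecord("chr1", 15000, "+", 8, 2, "CpG"),
    ]
    return MethylomeSet(records, sample_meta)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset shared across the suite."""
    from convergemeth.synthetic_data import GeneratorConfig, simulate

    return simulate(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_pipeline(default_dataset):
    from convergemeth.pipeline import run_pipeline

    return run_pipeline(default_dataset)
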
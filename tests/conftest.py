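import pytest

from mitocomp import datasets
from mitocomp.synthetic import SimSpec, make_genome


@pytest.fixture(scope="session")
def rj():
    """R. jiemuxiensis annotation (17,506 bp record)."""
    return datasets.rj_annotation()


@pytest.fixture(scope="session")
def rh():
    """R. hanluica annotation (17,505 bp record)."""
    return datasets.rh_annotation()


@pytest.fixture(scope="session")
def sim_genome():
    """One synthetic pattern-2 genome (annotation, sequence)."""
    return make_genome(SimSpec(seed=101))
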
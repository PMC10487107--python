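import numpy as np
import pytest

from aluedit.io_formats import PileupColumn, ReferenceSequence, reference_by_contig
from aluedit.synthetic_data import SimulationConfig, build_truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_reference():
    return ReferenceSequence("chrT", "ACGTACGTAACCGGTTATGC")


@pytest.fixture
def reference_dict(small_reference):
    return reference_by_contig([small_reference])


@pytest.fixture
def small_config():
    return SimulationConfig(
        seed=11, contig_length=3000, n_genes=2, n_alu=4,
        n_edit_sites=40, n_snps=10, mean_depth=30, n_samples=1, cohort_n=8,
    )


@pytest.fixture
def small_truth(small_config):
    return build_truth(small_config)


def make_column(contig, position, ref_base, **counts):
    return PileupColumn(contig=contig, position=position, ref_base=ref_base,
                        counts=counts)


@pytest.fixture
def make_pileup_column():
    return make_column
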
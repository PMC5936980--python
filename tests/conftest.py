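"""Shared fixtures: synthetic allele references and simulated runs."""

import pytest

import amplitype as at
from amplitype.simulate import DepthModel


@pytest.fixture(scope="session")
def allele_set():
    return at.synthetic_allele_set()


@pytest.fixture(scope="session")
def ggroups(allele_set):
    return at.build_ggroups(allele_set)


@pytest.fixture(scope="session")
def repeat_mask(allele_set):
    return at.repeat_mask_for(allele_set)


@pytest.fixture(scope="session")
def barcodes():
    return at.make_barcode_set(16)


@pytest.fixture(scope="session")
def small_run(allele_set, barcodes):
    """12 samples at depth 100 with the default error model."""
    truth = at.make_cohort(allele_set, 12, barcodes=barcodes, seed=11)
    run = at.simulate_run(truth, allele_set,
                          depth_model=DepthModel.constant(100), seed=12)
    return truth, run


def reads_of_sample(run, sample):
    """Plain sequences of one sample's reads, in file order."""
    return [seq for rid, seq, _ in run.reads
            if run.truth.reads[rid].sample == sample]
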
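"""Shared fixtures: small synthetic genomes and pre-simulated mixtures.

Session-scoped fixtures keep the expensive renders/samples to one per run;
every stochastic step is explicitly seeded so the suite is deterministic.
"""

import numpy as np
import pytest

import hicdeconv as hd
from hicdeconv import scenarios as sc


@pytest.fixture(scope="session")
def small_sizes():
    # ~60 Mb, 1,200 bins at 50 kb
    return sc.toy_chrom_sizes(0.2)


@pytest.fixture(scope="session")
def small_bins(small_sizes):
    return sc.toy_bins(0.2)


@pytest.fixture(scope="session")
def covariates(small_bins):
    return hd.simulate_covariates(small_bins, seed=11)


@pytest.fixture(scope="session")
def params():
    return hd.SimulationParams()


@pytest.fixture(scope="session")
def diploid(small_sizes):
    return sc.diploid_karyotype(small_sizes)


@pytest.fixture(scope="session")
def aneuploid(small_sizes):
    return sc.aneuploid_karyotype(small_sizes)


@pytest.fixture(scope="session")
def expected_diploid(diploid, small_bins, covariates, params):
    return hd.render_expected_map([(diploid, 1.0)], small_bins, covariates, params)


@pytest.fixture(scope="session")
def expected_aneuploid(aneuploid, small_bins, covariates, params):
    return hd.render_expected_map([(aneuploid, 1.0)], small_bins, covariates, params)


@pytest.fixture(scope="session")
def diploid_reads(expected_diploid):
    return hd.sample_reads(expected_diploid, 2e6, seed=101)


@pytest.fixture(scope="session")
def aneuploid_reads(expected_aneuploid):
    return hd.sample_reads(expected_aneuploid, 2e6, seed=102)


@pytest.fixture(scope="session")
def reference_model(expected_diploid, covariates):
    ref = hd.sample_reads(expected_diploid, 2e6, seed=103)
    return hd.fit_correction(hd.extract_diagonal(ref), covariates)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
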
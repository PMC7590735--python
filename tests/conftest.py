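from dataclasses import replace

import numpy as np
import pytest

from trionurture.experiments import (
    ANXIETY_TRIO,
    DEPRESSION_TRIO,
    run_pedigree_replicates,
    run_trio_replicates,
)
from trionurture.relatedness import build_relatedness
from trionurture.synthetic_data import GenerativeParams, simulate_trios


@pytest.fixture(scope="session")
def small_params() -> GenerativeParams:
    """Depression-model generative conditions at unit-test scale."""
    return replace(DEPRESSION_TRIO, n_trios=300, n_snps=400, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return simulate_trios(small_params)


@pytest.fixture(scope="session")
def small_relatedness(small_cohort):
    return build_relatedness(small_cohort)


@pytest.fixture(scope="session")
def depression_replicates():
    """Full-scale recovery experiment: 20 cohorts of 2,000 trios x 2,000 SNPs
    at the depression-model conditions, with single-matrix and
    mediator-adjusted fits."""
    return run_trio_replicates(DEPRESSION_TRIO, seeds=range(1, 21))


@pytest.fixture(scope="session")
def anxiety_replicates():
    return run_trio_replicates(ANXIETY_TRIO, seeds=range(1, 21), fit_greml=False)


@pytest.fixture(scope="session")
def pedigree_replicates():
    return run_pedigree_replicates(seeds=range(1, 21))


def mcse(series) -> float:
    return float(np.std(series, ddof=1) / np.sqrt(len(series)))
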
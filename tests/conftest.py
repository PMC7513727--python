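"""Shared fixtures: synthetic datasets at several scales.

The expensive default-scale dataset and its full analysis are session-scoped
so the recovery and direction checks share one run.
"""

import numpy as np
import pytest

from ecodiverge import (
    AnalysisParams,
    SimConfig,
    analyze_dataset,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """300-gene dataset with two planted modules — quick general-purpose."""
    cfg = SimConfig(seed=7, n_genes=300, n_intergenic_snps=500,
                    n_modules=2, module_size=30,
                    frac_tdsg=0.3, frac_drg=0.35)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_result(small_dataset):
    params = AnalysisParams(seed=7, n_perm=200)
    return analyze_dataset(small_dataset, params)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 90 samples, 2,000 genes."""
    return generate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_dataset):
    return analyze_dataset(default_dataset, AnalysisParams(seed=1, n_perm=1000))


@pytest.fixture(scope="session")
def null_dataset():
    """All planted effects zero; 500 genes (null calibration)."""
    return generate_dataset(SimConfig(seed=11).null(n_genes=500,
                                                    n_intergenic_snps=500))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
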
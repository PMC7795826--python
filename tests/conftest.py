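import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mpmburden import SubSurfaceGrid, build_forward_matrix, reference_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ref_cohort():
    return reference_cohort()


@pytest.fixture(scope="session")
def grid4000():
    return SubSurfaceGrid(n_subsurfaces=4000)


@pytest.fixture(scope="session")
def H4000(grid4000):
    """The 14 x 4001 hypergeometric mixture matrix; built once per session."""
    return build_forward_matrix(grid4000, n_draws=13)


@pytest.fixture(scope="session")
def ref_q(ref_cohort):
    """Fitted biopsy-count distribution of the completed reference cohort."""
    from mpmburden import biopsy_count_pmf, complete_cohort, fit_poisson_ls, positive_count_histogram

    hist = positive_count_histogram(complete_cohort(ref_cohort, target_n=13))
    return biopsy_count_pmf(fit_poisson_ls(hist))


@pytest.fixture(scope="session")
def ref_report():
    """Report of the one-shot reference reproduction; computed once per session."""
    from mpmburden import run_reference_pipeline

    return run_reference_pipeline()


@pytest.fixture(scope="session")
def tiny_grid():
    return SubSurfaceGrid(n_subsurfaces=6, biopsy_area_cm2=4.0, peritoneal_area_cm2=24.0)


@pytest.fixture(scope="session")
def H_tiny(tiny_grid):
    return build_forward_matrix(tiny_grid, n_draws=3)
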
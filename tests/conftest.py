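import numpy as np
import pytest

from zonula import geometry as geo
from zonula.experiments import (
    DEFAULT_CONVERGENCE_LADDER,
    StudyConfig,
    mesh_convergence,
    run_table_suite,
)
from zonula.mesh import Resolution


@pytest.fixture(scope="session")
def asymmetric_profile():
    spec = geo.asymmetric_lens_spec()
    return geo.build_profile(spec)


@pytest.fixture(scope="session")
def symmetric_profile():
    spec = geo.symmetric_lens_spec()
    return geo.build_profile(spec)


@pytest.fixture(scope="session")
def coarse_config():
    """Small study configuration for fast end-to-end checks."""
    return StudyConfig(resolution=Resolution(16, 8, 8))


@pytest.fixture(scope="session")
def suite_df():
    """The full 2-lens x 2-combination study at the default resolution.

    Shared across the quantitative-reproduction and directional-finding
    tests; takes a few minutes.
    """
    return run_table_suite(StudyConfig())


@pytest.fixture(scope="session")
def convergence_df():
    """Three-level mesh-refinement study of the asymmetric lens, combination A."""
    return mesh_convergence(
        StudyConfig(), list(DEFAULT_CONVERGENCE_LADDER), "asymmetric", "A"
    )
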
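import numpy as np
import pytest

from csfnmr.synthdata import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default three-group cohort on a reduced axis (fast, full structure)."""
    cfg = CohortConfig(seed=42, n_points=2**13)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def dense_axis():
    """High-resolution axis around the reference region for line-shape work."""
    return np.linspace(4.5, 6.0, 2**15)
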
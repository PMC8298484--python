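import numpy as np
import pytest
from dataclasses import replace

import circatemp as ct


@pytest.fixture(scope="session")
def archetypes():
    return ct.default_archetypes()


@pytest.fixture(scope="session")
def zero_noise():
    return ct.NoiseSpec(
        sigma=0.0, transient_magnitude=0.0, missing_fraction=0.0, quantization_step=0.0
    )


@pytest.fixture(scope="session")
def small_archetypes(archetypes):
    """Scaled-down cohort (same parameters, fewer subjects) for fast tests."""
    return [replace(a, n_subjects=n) for a, n in zip(archetypes, (15, 20, 10))]


@pytest.fixture(scope="session")
def small_cohort(small_archetypes):
    return ct.generate_cohort(small_archetypes, ct.NoiseSpec(sigma=0.1), seed=42)


@pytest.fixture(scope="session")
def minute_grid_48h():
    return np.arange(2880) / 60.0
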
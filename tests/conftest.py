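"""Shared fixtures: small deterministic synthetic studies."""

import numpy as np
import pytest

import traitscape as ts


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study at the default (field-design) configuration."""
    return ts.generate_study(ts.SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def coarse_study():
    """Default design at 20 m cells: faster, used where grid detail is moot."""
    return ts.generate_study(ts.SyntheticConfig(seed=11, cell_size_m=20.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
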
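import numpy as np
import pytest

from okfluor import MeasureConfig, PatternSpec, render_pattern


@pytest.fixture(scope="session")
def clean_spec() -> PatternSpec:
    """Noiseless default bull's-eye: 1000x600, boundary diameters 900/820/700/400."""
    return PatternSpec()


@pytest.fixture(scope="session")
def clean_pattern(clean_spec):
    """(RasterImage, ground-truth EdgeSet) for the noiseless default pattern."""
    return render_pattern(clean_spec)


@pytest.fixture(scope="session")
def default_config() -> MeasureConfig:
    return MeasureConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
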
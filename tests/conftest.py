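import pytest
from hypothesis import settings

from sbpsim import IntegrationGrid, RiskModel, SBPDistribution

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def dist():
    """Default virtual population: SBP ~ N(130, 20^2) mm Hg."""
    return SBPDistribution()


@pytest.fixture
def risk():
    """Default risk curve: k=20, l=100, m=140."""
    return RiskModel()


@pytest.fixture
def grid():
    """Default integration grid: [10, 250] mm Hg at 1 mm Hg steps."""
    return IntegrationGrid()


@pytest.fixture
def fine_grid():
    """0.01 mm Hg Simpson-reference grid."""
    return IntegrationGrid(step=0.01)
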
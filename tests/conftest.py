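import pytest
from hypothesis import settings

from fivec import synthetic_locus

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def study():
    """Default synthetic study (locus, anchored design, model, controls)."""
    return synthetic_locus.build_study(seed=1)


@pytest.fixture(scope="session")
def null_study():
    """Same locus geometry with no loops and no boundary insulation."""
    return synthetic_locus.build_study(seed=1, with_loops=False, boundary_insulation=1.0)
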
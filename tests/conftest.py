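import pytest
from hypothesis import HealthCheck, settings

import valueseq as vs

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def std_prior() -> vs.Belief:
    """Indifferent prior: mean at the adoption threshold, 2 effective pairs."""
    return vs.make_prior(0.0, 2.0, 10_000.0)


@pytest.fixture(scope="session")
def std_econ() -> vs.EconDesign:
    """Moderate design: maximum sample set at the one-stage ENBS optimum."""
    return vs.EconDesign(
        wtp=20_000.0,
        population_size=10_000.0,
        sampling_cost_per_pair=1_000.0,
        delay_pairs=30,
        max_pairs=166,
    )


@pytest.fixture(scope="session")
def std_boundary(std_prior, std_econ) -> vs.Boundary:
    grid = vs.GridSpec.from_prior(std_prior, std_econ)
    return vs.solve_boundary(std_prior, std_econ, grid)


@pytest.fixture(scope="session")
def hero():
    """Packaged synthetic fixture at hand-osteoarthritis trial scale."""
    return vs.hero_like_fixture()
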
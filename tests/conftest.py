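import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from syntce import (
    DesignConfig,
    FixtureSpec,
    SynTCESpec,
    default_config,
    default_energy_model,
    design_candidates,
    make_fixture_orf,
    part_from_candidate,
)


@pytest.fixture(scope="session")
def model():
    return default_energy_model()


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def ranked_candidates():
    """A seeded, ranked batch of default-architecture candidates."""
    return design_candidates(SynTCESpec(seed=42, n_candidates=50))


@pytest.fixture(scope="session")
def passing_candidates(ranked_candidates):
    passing = [c for c in ranked_candidates if c.passes]
    assert passing, "default design conditions must yield passing candidates"
    return passing


@pytest.fixture(scope="session")
def fixture_orfs():
    """Three deterministic synthetic ORFs sharing one RNG stream."""
    spec = FixtureSpec(seed=7)
    rng = np.random.default_rng(7)
    return [
        make_fixture_orf(spec, name=f"orf{i + 1}", length=120, rng=rng)
        for i in range(3)
    ]


@pytest.fixture(scope="session")
def tce_parts(passing_candidates):
    return [
        part_from_candidate(c, f"tce{i + 1}")
        for i, c in enumerate(passing_candidates[:2])
    ]
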
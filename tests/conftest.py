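import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# The two published worked-example frequency vectors, completed to all 12
# classes (the four unscored classes share the unassigned remainder).
EXAMPLE_1 = {
    "C>A": 27.0, "G>T": 19.0, "C>T": 8.0, "G>A": 12.0,
    "A>C": 0.0, "T>G": 0.0, "A>G": 3.0, "T>C": 5.0,
    "C>G": 7.0, "G>C": 7.0, "A>T": 6.0, "T>A": 6.0,
}
EXAMPLE_2 = {
    "C>A": 2.0, "G>T": 2.0, "C>T": 27.0, "G>A": 37.0,
    "A>C": 4.0, "T>G": 1.0, "A>G": 6.0, "T>C": 5.0,
    "C>G": 4.0, "G>C": 4.0, "A>T": 4.0, "T>A": 4.0,
}


@pytest.fixture
def example1_freqs():
    return dict(EXAMPLE_1)


@pytest.fixture
def example2_freqs():
    return dict(EXAMPLE_2)


def profile_from_freqs(freqs, sample_id="EX", target_mb=50.0):
    """A 100-substitution profile whose integer frequencies equal ``freqs``."""
    from easilung.spectrum import SpectrumProfile

    counts = {c: int(round(f)) for c, f in freqs.items()}
    assert sum(counts.values()) == 100
    return SpectrumProfile.from_counts(sample_id, counts, target_mb)


@pytest.fixture
def example1_profile():
    return profile_from_freqs(EXAMPLE_1, "EX1")


@pytest.fixture
def example2_profile():
    return profile_from_freqs(EXAMPLE_2, "EX2")


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic development cohort (n = 2000, seed 7)."""
    from easilung.synthetic_data import SimulationConfig, simulate_cohort

    cohort, truth = simulate_cohort(SimulationConfig(seed=7))
    return cohort, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
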
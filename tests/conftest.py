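import numpy as np
import pytest

from solodmr import fixtures


@pytest.fixture(scope="session")
def small_spec() -> fixtures.FixtureSpec:
    return fixtures.FixtureSpec(n_probes=2000, n_samples=60, seed=11)


@pytest.fixture(scope="session")
def small_manifest(small_spec):
    return fixtures.make_manifest(small_spec)


@pytest.fixture(scope="session")
def small_controls(small_spec, small_manifest):
    return fixtures.make_controls(small_spec, small_manifest)


@pytest.fixture(scope="session")
def cohort_spec() -> fixtures.FixtureSpec:
    """Full-scale synthetic control cohort (benchmark conditions)."""
    return fixtures.FixtureSpec(seed=20)


@pytest.fixture(scope="session")
def cohort(cohort_spec):
    manifest = fixtures.make_manifest(cohort_spec)
    controls = fixtures.make_controls(cohort_spec, manifest)
    return manifest, controls


@pytest.fixture(scope="session")
def sim_cache() -> dict:
    """Shared memo for Brown calibrations across benchmark runs."""
    return {}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
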
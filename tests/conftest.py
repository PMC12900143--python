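"""Shared fixtures: small, fast synthetic cohorts with known structure."""

import pytest

from vreeg.synth_eeg import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """A 2+2 cohort with short events, defaults otherwise."""
    return CohortSpec(
        n_experimental=2,
        n_control=2,
        event_durations=(10.0, 10.0, 16.0, 20.0),
        seed=1234,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def clean_spec() -> CohortSpec:
    """Artifact- and noise-free spec for deterministic spectral checks."""
    return CohortSpec(
        n_experimental=1,
        n_control=1,
        event_durations=(8.0, 8.0, 8.0, 8.0),
        noise_rms=0.0,
        artifact_rate=0.0,
        seed=99,
    )
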
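import pytest

from maizetrial import generate_trial


@pytest.fixture(scope="session")
def noise_free_trial():
    """Deterministic trial whose every metric equals the analytic ground truth."""
    return generate_trial(seed=11, noise=0.0)


@pytest.fixture(scope="session")
def noisy_trial():
    """One realistic-noise realization of the default 5-year, 2-hybrid, 3-replicate trial."""
    return generate_trial(seed=11, noise=1.0)
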
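import pytest
from hypothesis import HealthCheck, settings

import anisogamy as ag

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def obligate_params():
    """Obligate sex (no parthenogenesis), unlimited fertilisation window."""
    return ag.ModelParams(beta_z=1.0, beta_p=ag.INFINITE, phi=ag.INFINITE)


@pytest.fixture
def advantage_params():
    """Parthenogenetic advantage: survival scale below the zygotic one."""
    return ag.ModelParams(beta_z=1.0, beta_p=0.7, phi=ag.INFINITE)


@pytest.fixture
def disadvantage_params():
    """Parthenogenetic disadvantage: survival scale above the zygotic one."""
    return ag.ModelParams(beta_z=1.0, beta_p=1.3, phi=ag.INFINITE)
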
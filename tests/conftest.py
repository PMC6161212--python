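import pytest
from hypothesis import HealthCheck, settings

import meltflow as mf
from meltflow.synthetic import default_polymer_truth

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference():
    return mf.load_reference_dataset()


@pytest.fixture(scope="session")
def polymer_truth():
    """Ground-truth copovidone-like CY + WLF description at 150 °C."""
    return default_polymer_truth()
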
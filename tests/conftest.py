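import pytest

from beadcall.calling import CallConfig, call_assay
from beadcall.simulate import SimulationParams, simulate_assay


@pytest.fixture(scope="session")
def tight_assay():
    """A clean, well-separated 300-sample biallelic assay with truth."""
    return simulate_assay(SimulationParams(n_samples=300, seed=11))


@pytest.fixture(scope="session")
def tight_result(tight_assay):
    assay, _ = tight_assay
    return call_assay(assay, CallConfig())
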
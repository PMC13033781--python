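import pytest

from n2otracer.scenarios import packaged_scenarios
from n2otracer.simulate import simulate


@pytest.fixture(scope="session")
def scenarios():
    """Calibrated packaged scenarios (calibration runs once per session)."""
    return packaged_scenarios(seed=0)


@pytest.fixture(scope="session")
def vial(scenarios):
    return scenarios["RunA"].vial


@pytest.fixture(scope="session")
def ts_run_a(scenarios):
    return simulate(scenarios["RunA"])


@pytest.fixture(scope="session")
def ts_run_b(scenarios):
    return simulate(scenarios["RunB"])


@pytest.fixture(scope="session")
def ts_ara(scenarios):
    return simulate(scenarios["ARA"])
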
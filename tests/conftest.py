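import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def riva():
    from pbbmkit.synthetic import rivaroxaban_like

    return rivaroxaban_like()


@pytest.fixture(scope="session")
def tica():
    from pbbmkit.synthetic import ticagrelor_like

    return ticagrelor_like()


@pytest.fixture(scope="session")
def pb201():
    from pbbmkit.synthetic import pb201_like

    return pb201_like()


@pytest.fixture(scope="session")
def fasted_physiology():
    from pbbmkit.absorption import physiology_preset

    return physiology_preset("fasted")


@pytest.fixture(scope="session")
def small_bins(riva):
    """Coarse 5-bin discretization of the rivaroxaban-like formulation."""
    import dataclasses

    from pbbmkit.particles import discretize

    dist = dataclasses.replace(riva.dist, n_bins=5)
    return discretize(dist, riva.dose_mg, riva.drug.density)


@pytest.fixture(scope="session")
def riva_absorption(riva, fasted_physiology, small_bins):
    """One shared fasted GI absorption run for the rivaroxaban-like drug."""
    from pbbmkit.absorption import simulate_gi_absorption

    return simulate_gi_absorption(
        riva.drug, small_bins, riva.sol, riva.dis, riva.precip,
        fasted_physiology, peff=riva.peff_for_state("fasted"), duration_h=24.0,
    )
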
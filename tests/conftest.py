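import numpy as np
import pytest

from nmskit.fixtures import (FixtureConfig, get_demo_trial,
                             make_pendulum_ocp_fixture)


@pytest.fixture(scope="session")
def demo_nocontact():
    """Single-leg demo model + trial without contact (recovery fixtures)."""
    return get_demo_trial(FixtureConfig(seed=0, n_points=101,
                                        with_contact=False, legs=("r",)))


@pytest.fixture(scope="session")
def demo_contact():
    """Two-leg demo model + dynamically consistent trial with ground
    contact (51-point grid keeps the consistency optimization fast)."""
    return get_demo_trial(FixtureConfig(seed=0, n_points=51))


@pytest.fixture(scope="session")
def pendulum_ocp():
    """Synergy-driven pendulum fixture for the optimal-control tools."""
    return make_pendulum_ocp_fixture(n_intervals=20)


@pytest.fixture(scope="session")
def pendulum_form(pendulum_ocp):
    from nmskit.treatment import OcpFormulation, SynergyController
    fx = pendulum_ocp
    return OcpFormulation(
        model=fx["model"], controllers={"theta": "synergy"},
        muscle_params=fx["params"],
        synergies=[SynergyController(fx["group"], fx["muscles"],
                                     fx["W"])],
        mesh_intervals=fx["n_intervals"], final_time=fx["duration"],
        tracked={"coordinates": fx["q"][:, None],
                 "coordinates_names": ["theta"],
                 "loads": fx["tau"][:, None], "loads_names": ["theta"],
                 "activations": fx["activations"],
                 "activations_names": fx["muscles"]},
        periodic=True)


@pytest.fixture(scope="session")
def to_solution(pendulum_form, pendulum_ocp):
    """TO solved from a perturbed initial guess (shared by the VO/DO
    tests)."""
    from nmskit.treatment import TrackingOptimization
    fx = pendulum_ocp
    rng = np.random.default_rng(1)
    X0 = fx["states"] + rng.normal(0, 0.02, fx["states"].shape)
    U0 = fx["controls"] + rng.normal(0, 0.05, fx["controls"].shape)
    U0[:, 1:] = np.clip(U0[:, 1:], 0, None)
    return TrackingOptimization(pendulum_form, maxiter=400).solve(X0, U0)


@pytest.fixture(scope="session")
def vo_solution(pendulum_form, to_solution):
    from nmskit.treatment import VerificationOptimization
    return VerificationOptimization(pendulum_form,
                                    maxiter=400).solve(to_solution)
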
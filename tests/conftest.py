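import numpy as np
import pytest

from skitrack import fixtures as fx


@pytest.fixture(scope="session")
def oracle_models():
    return fx.make_oracle_models()


@pytest.fixture(scope="session")
def reduced_sys():
    """Reduced skier + 3-segment skis + 12 muscles on a 15 deg slope."""
    return fx.reduced_system()


@pytest.fixture(scope="session")
def full_sys():
    """Full 53-DOF model with the 94-muscle layout."""
    return fx.full_system()


@pytest.fixture(scope="session")
def turn_spec():
    """Conditions of the session's synthetic turn (scaled for test runtime)."""
    return fx.SyntheticTurnSpec(speed=8.0, radius=28.0, duration=1.2,
                                rate=25.0, noise_deg=1.0, seed=0)


@pytest.fixture(scope="session")
def synthetic_turn(reduced_sys, turn_spec):
    """(truth Solution, noisy TrackingData) shared by the end-to-end tests.

    Generated once per session: this is the expensive optimization.
    """
    return fx.synthesize_turn(turn_spec, reduced_sys,
                              solver_options={"max_iter": 140})


@pytest.fixture(scope="session")
def recovered_turn(reduced_sys, synthetic_turn):
    """Tracking solution recovered from the noisy synthetic data."""
    from skitrack.tracking import TrackingProblem, initial_guess, solve_tracking

    _, noisy = synthetic_turn
    prob = TrackingProblem(reduced_sys, noisy, q_ref=dict(fx._CROUCH))
    z0 = initial_guess(prob, "interpolate_data")
    pin = z0.reshape(prob.n_nodes, -1)[0][: reduced_sys.n_x].copy()
    wpin = np.concatenate([np.full(2 * reduced_sys.n_q, 1e3),
                           np.full(2 * reduced_sys.n_mus, 10.0)])
    prob = TrackingProblem(reduced_sys, noisy, q_ref=dict(fx._CROUCH),
                           x0_pin=pin, x0_pin_weight=wpin)
    return solve_tracking(prob, z0, {"max_iter": 120})
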
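"""Multibody model structure and implicit equations of motion."""

import numpy as np
import pytest

from skitrack import model_core as mc
from skitrack.model_core import (
    ModelError,
    SkiSpec,
    SystemState,
    assemble_full_model,
    build_ski_model,
    build_skier_model,
    dynamics_residual,
    forward_simulate,
    inverse_dynamics,
    mass_matrix,
    ski_joint_passive_moment,
)

G = mc.GRAVITY


class TestModelStructure:
    def test_default_skier_has_19_dofs(self):
        assert build_skier_model().n_q == 19

    def test_skier_dof_layout(self):
        model = build_skier_model()
        names = model.coord_names
        assert sum(n.startswith("pelvis") for n in names) == 6
        assert sum(n.startswith("lumbar") for n in names) == 3
        for side in "rl":
            assert sum(n.startswith("hip") and n.endswith(side) for n in names) == 3
            assert f"knee_flexion_{side}" in names
            assert f"ankle_dorsiflexion_{side}" in names

    def test_locking_knees_removes_two_dofs(self):
        model = build_skier_model({"locked": ["knee_flexion_r", "knee_flexion_l"]})
        assert model.n_q == 17

    def test_default_ski_18_segments_17_dofs(self):
        ski = build_ski_model()
        assert ski.n_bodies == 18
        assert ski.n_q == 17

    def test_ski_mass_and_length_conserved(self):
        ski = build_ski_model()
        assert sum(s.mass for s in ski.segments) == pytest.approx(2.1, rel=1e-12)
        assert sum(s.length for s in ski.segments) == pytest.approx(2.02, rel=1e-12)

    def test_tiny_ski_counts_propagate(self):
        ski = build_ski_model(SkiSpec(n_rear=1, n_center=1, n_front=1))
        assert ski.n_bodies == 3
        assert ski.n_q == 2

    def test_full_assembly_53_dofs(self):
        full = assemble_full_model(build_skier_model(), build_ski_model(), build_ski_model())
        assert full.n_q == 53

    def test_partial_assembly_additive(self):
        model = assemble_full_model(build_skier_model(), build_ski_model(), None)
        assert model.n_q == 19 + 17

    def test_double_weld_rejected(self):
        full = assemble_full_model(build_skier_model(), build_ski_model(),
                                   build_ski_model())
        with pytest.raises(ModelError, match="already carries"):
            assemble_full_model(full, build_ski_model(), None)

    def test_missing_foot_rejected(self):
        with pytest.raises(ModelError, match="cannot attach"):
            assemble_full_model(build_ski_model(), build_ski_model(), None)

    def test_invalid_config_names_field(self):
        with pytest.raises(ModelError, match="body_mass"):
            build_skier_model({"body_mass": -1.0})
        with pytest.raises(ModelError, match="unknown"):
            build_skier_model({"no_such_key": 1})

    def test_invalid_ski_spec(self):
        with pytest.raises(ModelError):
            build_ski_model(SkiSpec(length=-1.0))
        with pytest.raises(ModelError):
            build_ski_model(SkiSpec(mass=0.0))


class TestDynamics:
    def test_pendulum_eom(self, oracle_models):
        """Analytic pendulum: qdd = -(g/L) sin q gives zero residual."""
        pend = oracle_models["pendulum"]
        q = np.array([0.37])
        qd = np.array([0.81])
        qdd = -(G / 1.0) * np.sin(q)
        r = dynamics_residual(pend, SystemState(q, qd), SystemState(qd, qdd))
        assert np.max(np.abs(r)) < 1e-10

    def test_static_equilibrium_with_support(self, oracle_models):
        """Supporting torque exactly cancelling gravity gives zero residual."""
        pend = oracle_models["pendulum"]
        q = np.array([0.5])
        tau_gravity = inverse_dynamics(pend, q, np.zeros(1), np.zeros(1))
        r = dynamics_residual(pend, SystemState(q, np.zeros(1)),
                              SystemState(np.zeros(1), np.zeros(1)), tau_gravity)
        assert np.max(np.abs(r)) < 1e-12

    def test_residual_linear_in_qdd(self):
        """r(qdd) is affine: r(a+b) - r(a) - r(b) + r(0) = 0."""
        model = build_skier_model()
        rng = np.random.default_rng(0)
        q = rng.normal(0, 0.3, model.n_q)
        qd = rng.normal(0, 0.5, model.n_q)
        a, b = rng.normal(size=(2, model.n_q))
        f = lambda qdd: inverse_dynamics(model, q, qd, qdd)
        lhs = f(a + b) - f(a) - f(b) + f(np.zeros(model.n_q))
        assert np.max(np.abs(lhs)) < 1e-8

    def test_mass_matrix_spd(self):
        model = assemble_full_model(build_skier_model(), build_ski_model(),
                                    build_ski_model())
        rng = np.random.default_rng(1)
        for _ in range(3):
            q = rng.normal(0, 0.4, model.n_q)
            M = mass_matrix(model, q)
            assert np.max(np.abs(M - M.T)) < 1e-9
            assert np.min(np.linalg.eigvalsh(M)) > 0

    def test_rest_state_zero_residual_without_forces(self):
        model = build_skier_model({"gravity": [0.0, 0.0, 0.0]})
        rng = np.random.default_rng(2)
        q = rng.normal(0, 0.3, model.n_q)
        zero = np.zeros(model.n_q)
        r = dynamics_residual(model, SystemState(q, zero), SystemState(zero, zero))
        assert np.max(np.abs(r)) < 1e-12

    def test_converged_rollout_satisfies_residual(self, oracle_models):
        """States sampled from an implicit-Euler rollout satisfy the same
        one-step residual they were solved with."""
        dp = oracle_models["double_pendulum"]
        x0 = np.array([0.3, -0.2, 0.0, 0.0])
        h = 0.01
        traj = forward_simulate(dp, x0, h=h, n_steps=20, tol=1e-12)
        for k in (5, 20):
            x, xp = traj[k], traj[k - 1]
            xd = (x - xp) / h
            r = dynamics_residual(dp, SystemState(x[:2], x[2:]),
                                  SystemState(xd[:2], xd[2:]))
            assert np.max(np.abs(r)) < 1e-9


class TestSkiJointMoment:
    @pytest.mark.parametrize(
        "defl, rate, k, c, expected",
        [(0.0, 0.0, 300.0, 0.5, 0.0),
         (0.01, 0.0, 300.0, 0.0, -3.0),
         (0.0, 1.0, 0.0, 0.5, -0.5)],
    )
    def test_linear_law(self, defl, rate, k, c, expected):
        assert ski_joint_passive_moment(defl, rate, k, c) == pytest.approx(expected)

    def test_negative_stiffness_rejected(self):
        with pytest.raises(ModelError):
            ski_joint_passive_moment(0.1, 0.0, -1.0, 0.0)


class TestForwardSimulate:
    def test_scalar_decay_closed_form(self):
        """Implicit Euler on xdot = -x gives x_k = (1+h)^-k exactly."""
        h, n = 0.1, 20
        traj = forward_simulate(lambda x, xd, t: xd + x, np.array([1.0]),
                                h=h, n_steps=n, tol=1e-14)
        expected = (1.0 + h) ** -np.arange(n + 1)
        assert np.max(np.abs(traj.ravel() - expected)) < 1e-12

    def test_pendulum_energy_drift_first_order(self, oracle_models):
        """Energy drift of the (dissipative) implicit Euler decreases with h."""
        pend = oracle_models["pendulum"]

        def energy(x):
            q, qd = x[0], x[1]
            return 0.5 * qd**2 - G * np.cos(q)

        drifts = []
        for h in (0.02, 0.01, 0.005):
            traj = forward_simulate(pend, np.array([1.0, 0.0]),
                                    h=h, n_steps=int(round(0.5 / h)), tol=1e-12)
            drifts.append(abs(energy(traj[-1]) - energy(traj[0])))
        assert drifts[0] > drifts[1] > drifts[2]
        assert drifts[1] / drifts[2] == pytest.approx(2.0, rel=0.25)

    def test_equilibrium_stays_constant(self, oracle_models):
        pend = oracle_models["pendulum"]
        traj = forward_simulate(pend, np.zeros(2), h=0.05, n_steps=10)
        assert np.max(np.abs(traj)) < 1e-10

    def test_bad_step_size_rejected(self, oracle_models):
        with pytest.raises(ValueError):
            forward_simulate(oracle_models["pendulum"], np.zeros(2), h=-0.1)


class TestKinematicsInternals:
    def test_wrench_to_generalized_matches_potential_gradient(self):
        """A constant world force on a body equals -dV/dq of its potential."""
        model = build_skier_model()
        rng = np.random.default_rng(4)
        q = rng.normal(0, 0.3, model.n_q)
        body = model.body_index("shank_r")
        force = np.array([0.0, 0.0, -50.0])
        tau = mc.wrench_to_generalized(model, q, body, force,
                                       point=None)
        # numeric gradient of V = -force . p_origin(q)
        eps = 1e-7
        tau_fd = np.zeros(model.n_q)
        for j in range(model.n_q):
            qp, qm = q.copy(), q.copy()
            qp[j] += eps
            qm[j] -= eps
            pp = mc.body_kinematics(model, qp).p[body]
            pm = mc.body_kinematics(model, qm).p[body]
            tau_fd[j] = force @ (pp - pm) / (2 * eps)
        assert np.max(np.abs(tau - tau_fd)) < 1e-5
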
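"""Post-processing: RMSD, turn geometry, joint moments, knee loads."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skitrack import analysis as an
from skitrack import model_core as mc
from skitrack.analysis import (
    grf_distribution,
    intersegmental_knee_loads,
    rmsd,
    steering_phase,
    turn_radius,
)
from skitrack.model_core import ModelError
from skitrack.rotations import cross
from skitrack.ski_snow import SnowPlane


class TestRmsd:
    def test_identical_series_zero(self):
        x = np.sin(np.linspace(0, 5, 40))
        assert rmsd(x, x) == 0.0

    def test_constant_offset(self):
        x = np.linspace(0, 1, 17)
        assert rmsd(x, x + 0.3) == pytest.approx(0.3)

    def test_two_point_arithmetic(self):
        assert rmsd(np.array([3.0, 4.0]), np.zeros(2)) == pytest.approx(
            np.sqrt(25.0 / 2.0)
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ModelError):
            rmsd(np.zeros(3), np.zeros(4))

    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_metric_properties(self, vals):
        a = np.asarray(vals)
        b = a[::-1].copy()
        assert rmsd(a, b) == pytest.approx(rmsd(b, a))
        assert rmsd(a, b) >= 0
        assert rmsd(a, a) == 0


class TestTurnRadius:
    @pytest.mark.parametrize("R", [16.0, 32.0])
    def test_exact_on_circles(self, R):
        t = np.linspace(0, 1.2, 80)
        pts = R * np.stack([np.sin(t), 1 - np.cos(t)], axis=-1)
        radius, straight = turn_radius(pts, window=9)
        assert np.allclose(radius, R, rtol=1e-9)
        assert not straight.any()

    def test_straight_line_capped_and_flagged(self):
        pts = np.stack([np.linspace(0, 30, 60), np.zeros(60)], axis=-1)
        radius, straight = turn_radius(pts, window=9, cap=1000.0)
        assert np.all(radius == 1000.0)
        assert straight.all()

    def test_too_few_points_rejected(self):
        with pytest.raises(ModelError):
            turn_radius(np.zeros((2, 2)))


class TestSteeringPhase:
    def test_dip_below_sidecut(self):
        r = np.full(200, 40.0)
        r[40:121] = 20.0
        assert steering_phase(r, 32.0) == (40, 120)

    def test_never_below_is_empty(self):
        assert steering_phase(np.full(50, 35.0), 32.0) is None

    def test_always_below_is_whole_record(self):
        assert steering_phase(np.full(50, 20.0), 32.0) == (0, 49)


class TestGrfDistribution:
    def test_equal_forces(self):
        assert grf_distribution(np.full(10, 500.0), np.full(10, 500.0)) == 0.5

    def test_60_40_split(self):
        assert grf_distribution(np.full(10, 600.0), np.full(10, 400.0)) == pytest.approx(0.6)

    def test_airborne_inside_ski(self):
        assert grf_distribution(np.full(10, 700.0), np.zeros(10)) == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ModelError):
            grf_distribution(np.zeros(5), np.zeros(5))

    def test_phase_restriction(self):
        out = np.concatenate([np.full(5, 500.0), np.full(5, 900.0)])
        ins = np.concatenate([np.full(5, 500.0), np.full(5, 100.0)])
        assert grf_distribution(out, ins, phase=(5, 9)) == pytest.approx(0.9)


def _static_solution(system, q, n=5):
    """A constant-posture 'solution' for statics-based checks."""
    from skitrack.tracking import Solution, TrackingData, TrackingProblem

    N = n
    t = np.linspace(0, 0.1 * (N - 1), N)
    X = np.zeros((N, system.n_x))
    X[:, : system.n_q] = q
    data = TrackingData(t, {"pelvis_tx": q[0] * np.ones(N)})
    prob = TrackingProblem(system, data)
    return Solution(t, X, np.zeros((N, system.n_u)), 0.0, {}, "synthetic", 0.0, 0,
                    problem=prob)


class TestKneeLoads:
    def test_static_standing_force_is_distal_weight(self, reduced_sys):
        """Zero contact, zero acceleration: knee force = distal chain weight."""
        import copy

        sysm = copy.copy(reduced_sys)
        sysm.snow = None  # no contact forces
        model = sysm.model
        q = np.zeros(model.n_q)
        sol = _static_solution(sysm, q)
        loads = intersegmental_knee_loads(sol, sysm, side="r")
        distal = [b for b in range(model.n_bodies)]
        # distal chain mass: shank + foot + one ski
        m_chain = sum(
            model.segments[b].mass for b in range(model.n_bodies)
            if model.segments[b].name in ("shank_r", "foot_r")
            or model.segments[b].meta.get("ski_side") == "r"
        )
        F = loads["force"][2]  # mid node, (anterior, superior, medial)
        assert np.linalg.norm(F) == pytest.approx(m_chain * 9.81, rel=1e-9)
        # straight standing: the force is along the (vertical) shank axis
        assert F[1] == pytest.approx(m_chain * 9.81, rel=1e-9)

    def test_recursion_matches_whole_chain_balance(self, reduced_sys):
        """Segment-wise recursion equals an independent single balance of the
        whole distal subtree about the knee (dynamic case)."""
        sysm = reduced_sys
        model = sysm.model
        rng = np.random.default_rng(11)
        N = 6
        t = np.arange(N) * 0.02
        X = np.zeros((N, sysm.n_x))
        q0 = np.zeros(model.n_q)
        q0[2] = 0.9
        X[:, : model.n_q] = q0 + 0.05 * rng.normal(size=(N, model.n_q))
        X[:, model.n_q:2 * model.n_q] = rng.normal(0, 0.3, (N, model.n_q))
        from skitrack.tracking import Solution, TrackingData, TrackingProblem

        data = TrackingData(t, {"pelvis_tx": X[:, 0]})
        prob = TrackingProblem(sysm, data)
        sol = Solution(t, X, np.zeros((N, sysm.n_u)), 0.0, {}, "synthetic", 0.0, 0,
                       problem=prob)
        loads = intersegmental_knee_loads(sol, sysm, side="l")

        # independent oracle: one Newton-Euler balance of the whole subtree
        st_, std = an._state_derivatives(sol, sysm)
        kin = mc.body_kinematics(model, st_.q, st_.qdot, std.qdot)
        from skitrack.ski_snow import ski_contact_loads

        ext_f, ext_n = ski_contact_loads(model, kin, sysm.snow, sysm.contact)
        shank = model.body_index("shank_l")
        chain = []
        for b in range(model.n_bodies):
            a = b
            while a >= 0:
                if a == shank:
                    chain.append(b)
                    break
                a = model.joints[a].parent
        g = model.gravity
        f = np.zeros((N, 3))
        n_ = np.zeros((N, 3))
        p_knee = np.real(kin.p[:, shank])
        for b in chain:
            m = model.segments[b].mass
            I = np.asarray(model.segments[b].inertia, float)
            Iw = np.einsum("nij,jk,nlk->nil", np.real(kin.R[:, b]), I,
                           np.real(kin.R[:, b]))
            Fb = m * (np.real(kin.acom[:, b]) - g) - np.real(ext_f[:, b])
            Nb = (np.einsum("nij,nj->ni", Iw, np.real(kin.omegadot[:, b]))
                  + cross(np.real(kin.omega[:, b]),
                          np.einsum("nij,nj->ni", Iw, np.real(kin.omega[:, b])))
                  - np.real(ext_n[:, b]))
            f += Fb
            n_ += Nb + cross(np.real(kin.com[:, b]) - p_knee, Fb) \
                + cross(np.real(kin.p[:, b]) - p_knee,
                        np.zeros(3))  # ext torque already about origin
            n_ += cross(np.real(kin.p[:, b]) - p_knee, np.zeros(3))
        # express in the same shank frame components
        R = np.real(kin.R[:, shank])
        e_ant, e_left, e_sup = R[..., :, 0], R[..., :, 1], R[..., :, 2]
        sgn = -1.0
        F_cmp = np.stack([np.sum(f * e_ant, -1), np.sum(f * e_sup, -1),
                          np.sum(f * (sgn * e_left), -1)], axis=-1)
        assert np.max(np.abs(F_cmp - loads["force"])) < 1e-6

    def test_mirrored_motions_give_mirrored_loads(self, reduced_sys):
        sysm = reduced_sys
        model = sysm.model
        q = np.zeros(model.n_q)
        q[model.coord_index("hip_flexion_r")] = 0.7
        q[model.coord_index("knee_flexion_r")] = -0.9
        q[model.coord_index("hip_flexion_l")] = 0.4
        q[model.coord_index("knee_flexion_l")] = -0.5
        sol = _static_solution(sysm, q)
        loads_r = intersegmental_knee_loads(sol, sysm, side="r")
        qm = q.copy()
        for a, b in (("hip_flexion_r", "hip_flexion_l"),
                     ("knee_flexion_r", "knee_flexion_l")):
            qm[model.coord_index(a)], qm[model.coord_index(b)] = (
                q[model.coord_index(b)], q[model.coord_index(a)])
        sol_m = _static_solution(sysm, qm)
        loads_l = intersegmental_knee_loads(sol_m, sysm, side="l")
        assert np.allclose(loads_r["moment"], loads_l["moment"], atol=1e-8)
        assert np.allclose(loads_r["force"], loads_l["force"], atol=1e-8)

    def test_bad_side_rejected(self, reduced_sys):
        sol = _static_solution(reduced_sys, np.zeros(reduced_sys.n_q))
        with pytest.raises(ModelError):
            intersegmental_knee_loads(sol, reduced_sys, side="left_leg")

    def test_known_point_force_statics(self):
        """Massless distal chain under one known force F at point r from the
        knee: knee force = -F... (the joint transmits exactly -F and the
        moment -r x F), checked on a minimal two-body chain."""
        # shank (massless) with a 'ski segment' foot carrying one contact edge
        model = mc.MultibodyModel("mini", gravity=(0.0, 0.0, 0.0))
        shank = mc.Segment("shank_r", 0.0, np.zeros((3, 3)), np.zeros(3), 0.4)
        model.add_body(shank, mc.Joint("knee_r", "revolute", -1, np.zeros(3),
                                       np.array([[0.0, -1.0, 0.0]]), ["knee_flexion_r"]))
        foot = mc.Segment("foot_r", 0.0, np.zeros((3, 3)), np.zeros(3), 0.2,
                          meta={"ski_segment": True, "seg_length": 0.3,
                                "half_width": 0.0, "ski_side": "r"})
        model.add_body(foot, mc.Joint("ankle_r", "weld", 0,
                                      np.array([0.0, 0.0, -0.4])))
        model.finalize()
        from skitrack.muscles import MuscleSet
        from skitrack.system import SkiSystem

        sysm = SkiSystem(model, MuscleSet([]), SnowPlane(), boot=None)
        q = np.zeros((5, 1))
        q[:, 0] = 0.0
        X = np.zeros((5, sysm.n_x))
        X[:, 0] = 0.0
        # place the chain so the foot edge penetrates d = 1 cm
        # (knee at z = 0.39 puts the foot origin at -0.01)
        from skitrack.tracking import Solution, TrackingData, TrackingProblem

        # shift via the snow plane point instead: plane at z = -0.41
        sysm.snow = SnowPlane(point=np.array([0.0, 0.0, -0.39]))
        t = np.arange(5) * 0.01
        data = TrackingData(t, {"knee_flexion_r": np.zeros(5)})
        prob = TrackingProblem(sysm, data)
        sol = Solution(t, X, np.zeros((5, 0)), 0.0, {}, "synthetic", 0.0, 0,
                       problem=prob)
        loads = intersegmental_knee_loads(sol, sysm, side="r")
        # oracle: the contact wrench on the foot, transported to the knee
        st_, std = an._state_derivatives(sol, sysm)
        kin = mc.body_kinematics(model, st_.q, st_.qdot, std.qdot)
        from skitrack.ski_snow import ski_contact_loads

        ext_f, ext_n = ski_contact_loads(model, kin, sysm.snow, sysm.contact)
        Fc = np.real(ext_f[:, 1])
        Nc = np.real(ext_n[:, 1]) + cross(np.real(kin.p[:, 1]) - np.real(kin.p[:, 0]), Fc)
        assert np.linalg.norm(Fc[2]) > 1.0  # the edge really is loaded
        R = np.real(kin.R[:, 0])
        e_ant, e_left, e_sup = R[..., :, 0], R[..., :, 1], R[..., :, 2]
        F_cmp = np.stack([np.sum(-Fc * e_ant, -1), np.sum(-Fc * e_sup, -1),
                          np.sum(-Fc * e_left, -1)], axis=-1)
        assert np.allclose(loads["force"], F_cmp, atol=1e-9)


class TestSpeedSeries:
    def test_uniform_straight_motion(self, reduced_sys):
        sysm = reduced_sys
        N = 30
        t = np.arange(N) * 0.02
        X = np.zeros((N, sysm.n_x))
        X[:, 0] = 14.0 * t
        from skitrack.tracking import Solution, TrackingData, TrackingProblem

        data = TrackingData(t, {"pelvis_tx": X[:, 0]})
        sol = Solution(t, X, np.zeros((N, sysm.n_u)), 0.0, {}, "synthetic", 0.0, 0,
                       problem=TrackingProblem(sysm, data))
        v = an.speed_series(sol, sysm)
        assert np.allclose(v, 14.0, atol=1e-9)

    def test_stationary_zero(self, reduced_sys):
        sol = _static_solution(reduced_sys, np.zeros(reduced_sys.n_q), n=12)
        assert np.max(an.speed_series(sol, reduced_sys)) < 1e-12

    def test_circular_motion_speed(self, reduced_sys):
        sysm = reduced_sys
        N, R, om = 60, 15.0, 0.8
        t = np.arange(N) * 0.02
        X = np.zeros((N, sysm.n_x))
        X[:, 0] = R * np.sin(om * t)
        X[:, 1] = R * (1 - np.cos(om * t))
        from skitrack.tracking import Solution, TrackingData, TrackingProblem

        data = TrackingData(t, {"pelvis_tx": X[:, 0]})
        sol = Solution(t, X, np.zeros((N, sysm.n_u)), 0.0, {}, "synthetic", 0.0, 0,
                       problem=TrackingProblem(sysm, data))
        v = an.speed_series(sol, sysm)
        assert np.median(v) == pytest.approx(R * om, rel=0.01)


class TestNetJointMoments:
    def test_zero_activation_near_zero_moments(self, reduced_sys):
        """With activations ~0 and fibers slack the net moments vanish."""
        sysm = reduced_sys
        q = np.zeros(sysm.n_q)
        X = np.zeros((5, sysm.n_x))
        X[:, : sysm.n_q] = q
        # fibers well short of passive engagement, tendon slack
        geo = sysm.muscles.musculotendon_geometry(q)
        l_slack = sysm.muscles.param_array("l_slack")
        X[:, 2 * sysm.n_q: 2 * sysm.n_q + sysm.n_mus] = np.real(geo.l_mt) - 0.98 * l_slack
        from skitrack.tracking import Solution, TrackingData, TrackingProblem

        t = np.arange(5) * 0.02
        data = TrackingData(t, {"pelvis_tx": np.zeros(5)})
        sol = Solution(t, X, np.zeros((5, sysm.n_u)), 0.0, {}, "synthetic", 0.0, 0,
                       problem=TrackingProblem(sysm, data))
        mom = an.net_joint_moments(sol, sysm)
        peak = max(np.max(np.abs(v)) for v in mom.moments.values())
        assert peak < 0.05  # N*m/kg; only the smoothing force floor remains

    def test_capacity_bound(self, reduced_sys, recovered_turn):
        """Net moments never exceed the muscle set's capacity sum |R| Fmax."""
        sysm = reduced_sys
        mom = an.net_joint_moments(recovered_turn, sysm)
        st_ = sysm.unpack(recovered_turn.states)
        geo = sysm.muscles.musculotendon_geometry(st_.q)
        fmax = sysm.muscles.param_array("fmax")
        cap = np.einsum("nmk,m->nk", np.abs(np.real(geo.moment_arms)),
                        fmax * 2.8)  # 1.8 eccentric ceiling + 1.0 passive at bound
        for name, series in mom.raw.items():
            k = sysm.model.coord_index(name)
            assert np.all(np.abs(series) <= cap[:, k] + 1e-6)
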
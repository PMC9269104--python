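"""Hill-muscle curves, activation/contraction dynamics, routing, boot."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skitrack import muscles as mu
from skitrack.model_core import ModelError, build_skier_model
from skitrack.muscles import (
    BootParams,
    MuscleParams,
    MuscleSet,
    activation_residual,
    boot_moment,
    default_muscle_set,
    full_muscle_layout,
)

TAU_A, TAU_D = 0.010, 0.040


def simple_muscle(**kw):
    defaults = dict(name="m", fmax=1000.0, l_opt=0.1, l_slack=0.2,
                    pennation=0.2, path={"knee_flexion_r": [0.05]})
    defaults.update(kw)
    p = MuscleParams(**defaults)
    p.calibrate_l0({})
    return p


class TestActivationDynamics:
    def test_fixed_point(self):
        assert activation_residual(0.5, 0.0, 0.5) == pytest.approx(0.0)

    def test_full_excitation_rise_rate(self):
        """From rest with e = 1 the rise rate is (1-0)/10 ms = 100/s."""
        assert activation_residual(0.0, 100.0, 1.0) == pytest.approx(0.0, abs=1e-6)

    def test_full_deactivation_decay_rate(self):
        """From a = 1 with e = 0 the decay rate is -1/40 ms = -25/s."""
        assert activation_residual(1.0, -25.0, 0.0) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize(
        "e,a0,tau,t_end",
        [(1.0, 0.0, TAU_A, 0.022), (0.0, 1.0, TAU_D, 0.088)],
    )
    def test_step_response_matches_closed_form(self, e, a0, tau, t_end):
        """Integrated step response matches a(t) = e + (a0-e) exp(-t/tau) on
        each branch (horizon chosen so a stays clear of the e = a switch)."""
        from scipy.integrate import solve_ivp

        def rhs(t, a):
            # residual = 0 defines adot = (e - a)/tau(e, a)
            return -activation_residual(a, 0.0, e, switch_sharpness=400.0)

        sol = solve_ivp(rhs, (0.0, t_end), [a0], rtol=1e-12, atol=1e-14,
                        dense_output=True)
        t = np.linspace(0.0, t_end, 20)
        analytic = e + (a0 - e) * np.exp(-t / tau)
        assert np.max(np.abs(sol.sol(t)[0] - analytic)) < 1e-8

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_rate_sign_drives_a_toward_e(self, a, e):
        """The implied adot always points from a toward e (stays in [0,1])."""
        r = activation_residual(a, 0.0, e)
        adot = -r
        assert adot * (e - a) >= 0


class TestContractionDynamics:
    def test_isometric_force_at_optimum(self):
        """a=1, fiber at optimum, tendon at matching stretch:
        tendon force = Fmax cos(pennation) to 1e-10."""
        p = simple_muscle()
        ms = MuscleSet([p])
        s = p.l_opt * np.cos(p.pennation)
        # tendon stretch producing normalized force cos(pennation):
        target = np.cos(p.pennation)
        # invert the smooth tendon law by bisection
        lo, hi = 0.0, 1.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if mu.tendon_force_length(1.0 + mid) < target:
                lo = mid
            else:
                hi = mid
        lt = p.l_slack * (1.0 + 0.5 * (lo + hi))
        r, f = ms.contraction_residual(np.array([s]), np.zeros(1), np.ones(1),
                                       np.array([lt + s]))
        assert abs(r[0]) < 1e-10
        assert f[0] == pytest.approx(p.fmax * np.cos(p.pennation), rel=1e-9)

    def test_slack_muscle_force_floor(self):
        """a=0, fiber short, tendon below slack: force at most the floor."""
        p = simple_muscle()
        ms = MuscleSet([p])
        s = 0.8 * p.l_opt * np.cos(p.pennation)
        l_mt = s + 0.95 * p.l_slack
        _, f = ms.contraction_residual(np.array([s]), np.zeros(1), np.zeros(1),
                                       np.array([l_mt]))
        assert f[0] < 0.05 * p.fmax

    def test_passive_force_at_long_fiber(self):
        """a=0 at 1.5 l_opt: fiber force equals the shipped passive curve."""
        p = simple_muscle(pennation=0.0)
        ms = MuscleSet([p])
        s = np.array([1.5 * p.l_opt])
        fpe = mu.passive_force_length(1.5)
        assert fpe > 0
        # find the tendon length where the residual vanishes; the implied
        # tendon force then equals the passive fiber force
        lo, hi = np.full(1, 0.9), np.full(1, 1.2)
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            r, _ = ms.contraction_residual(s, np.zeros(1), np.zeros(1),
                                           s + p.l_slack * mid)
            lo = np.where(r < 0, mid, lo)
            hi = np.where(r >= 0, mid, hi)
        _, f = ms.contraction_residual(s, np.zeros(1), np.zeros(1),
                                       s + p.l_slack * 0.5 * (lo + hi))
        assert f[0] == pytest.approx(fpe * p.fmax, rel=1e-5)

    def test_curve_normalizations(self):
        assert mu.active_force_length(1.0) == 1.0
        assert mu.force_velocity(0.0) == pytest.approx(1.0, abs=1e-14)
        assert mu.passive_force_length(1.0) == 0.0
        assert mu.passive_force_length(1.6) == pytest.approx(1.0)

    def test_nonfinite_input_rejected(self):
        ms = MuscleSet([simple_muscle()])
        with pytest.raises(ModelError):
            ms.contraction_residual(np.array([np.nan]), np.zeros(1),
                                    np.zeros(1), np.ones(1))

    def test_residual_continuous_in_sdot(self):
        ms = MuscleSet([simple_muscle()])
        s = np.array([0.1])
        vals = [ms.contraction_residual(s, np.array([v]), np.full(1, 0.5),
                                        np.array([0.3]))[0][0]
                for v in np.linspace(-0.01, 0.01, 21)]
        assert np.max(np.abs(np.diff(vals))) < 0.05


class TestGeometry:
    def test_constant_moment_arm_linear_path(self):
        model = build_skier_model()
        p = simple_muscle()
        ms = MuscleSet([p], model)
        k = model.coord_index("knee_flexion_r")
        for qv in (-1.0, 0.0, 0.7):
            q = np.zeros(model.n_q)
            q[k] = qv
            geo = ms.musculotendon_geometry(q)
            assert geo.moment_arms[0, k] == pytest.approx(-0.05)
            assert geo.l_mt[0] == pytest.approx(p.l0 + 0.05 * qv)

    def test_moment_arms_match_negative_length_gradient(self):
        """R = -d l_mt/dq by central finite differences on random postures."""
        model = build_skier_model()
        ms = default_muscle_set(model)
        rng = np.random.default_rng(7)
        q = rng.normal(0, 0.5, model.n_q)
        geo = ms.musculotendon_geometry(q)
        eps = 1e-6
        for j in range(model.n_q):
            qp, qm = q.copy(), q.copy()
            qp[j] += eps
            qm[j] -= eps
            dl = (ms.musculotendon_geometry(qp).l_mt
                  - ms.musculotendon_geometry(qm).l_mt) / (2 * eps)
            assert np.max(np.abs(geo.moment_arms[:, j] + dl)) < 1e-6

    def test_mirrored_postures_give_mirrored_lengths(self):
        model = build_skier_model()
        ms = default_muscle_set(model)
        q = np.zeros(model.n_q)
        q[model.coord_index("hip_flexion_r")] = 0.8
        q2 = np.zeros(model.n_q)
        q2[model.coord_index("hip_flexion_l")] = 0.8
        l1 = ms.musculotendon_geometry(q).l_mt
        l2 = ms.musculotendon_geometry(q2).l_mt
        i_r = ms.names.index("hip_flexors_r")
        i_l = ms.names.index("hip_flexors_l")
        assert l1[i_r] == pytest.approx(l2[i_l], rel=1e-12)

    def test_out_of_range_flagged(self):
        model = build_skier_model()
        ms = default_muscle_set(model)
        q = np.zeros(model.n_q)
        q[model.coord_index("knee_flexion_r")] = 3.5
        assert ms.musculotendon_geometry(q).out_of_range


class TestJointMoments:
    def test_zero_force_zero_moment(self):
        model = build_skier_model()
        ms = default_muscle_set(model)
        tau = ms.muscle_joint_moments(np.zeros(model.n_q), np.zeros(ms.n_mus))
        assert np.max(np.abs(tau)) == 0.0

    def test_single_muscle_moment(self):
        """Moment arm 0.05 m with 1000 N tendon force gives 50 N*m."""
        model = build_skier_model()
        ms = MuscleSet([simple_muscle(path={"knee_flexion_r": [-0.05]})], model)
        k = model.coord_index("knee_flexion_r")
        geo = ms.musculotendon_geometry(np.zeros(model.n_q))
        assert geo.moment_arms[0, k] == pytest.approx(0.05)
        tau = ms.muscle_joint_moments(np.zeros(model.n_q), np.array([1000.0]))
        assert tau[k] == pytest.approx(50.0)
        tau[k] = 0.0
        assert np.max(np.abs(tau)) == 0.0

    def test_equal_antagonists_cancel(self):
        model = build_skier_model()
        ag = simple_muscle(name="ag", path={"knee_flexion_r": [0.05]})
        an = simple_muscle(name="an", path={"knee_flexion_r": [-0.05]})
        ms = MuscleSet([ag, an], model)
        tau = ms.muscle_joint_moments(np.zeros(model.n_q), np.array([500.0, 500.0]))
        assert np.max(np.abs(tau)) < 1e-12


class TestMuscleSets:
    def test_full_layout_has_94_muscles(self, full_sys):
        assert full_sys.muscles.n_mus == 94

    def test_full_layout_split_43_43_8(self):
        ms = full_muscle_layout()
        r = sum(1 for n in ms.names if n.endswith("_r"))
        leg_r = sum(1 for n in ms.names
                    if n.endswith("_r") and "spinae" not in n
                    and "abdominis" not in n and "obliquus" not in n)
        lumbar = ms.n_mus - 2 * leg_r
        assert leg_r == 43
        assert lumbar == 8

    def test_reduced_set_has_12(self, reduced_sys):
        assert reduced_sys.muscles.n_mus == 12

    def test_invalid_params_rejected(self):
        with pytest.raises(ModelError):
            MuscleParams("bad", fmax=-1, l_opt=0.1, l_slack=0.1).validate()
        with pytest.raises(ModelError):
            MuscleParams("bad", fmax=1, l_opt=0.1, l_slack=0.1,
                         tau_act=0.05, tau_deact=0.04).validate()


class TestBootMoment:
    def test_zero_at_neutral(self):
        boot = BootParams()
        assert boot_moment(boot.neutral_angle, 0.0, boot) == 0.0

    def test_cubic_stiffening(self):
        """The restoring moment more than doubles from 10 to 20 deg."""
        boot = BootParams()
        m10 = boot_moment(boot.neutral_angle + np.deg2rad(10), 0.0, boot)
        m20 = boot_moment(boot.neutral_angle + np.deg2rad(20), 0.0, boot)
        assert abs(m20) > 2 * abs(m10)

    def test_dorsiflexion_gives_negative_moment(self):
        """Dorsiflexion beyond neutral is resisted by a negative
        (plantarflexion-direction) boot moment, matching the reporting
        convention in which boot moments are negative."""
        boot = BootParams()
        assert boot_moment(boot.neutral_angle + 0.2, 0.0, boot) < 0

    def test_odd_monotone_about_neutral(self):
        boot = BootParams()
        d = np.linspace(0.01, 0.5, 40)
        plus = np.array([boot_moment(boot.neutral_angle + x, 0.0, boot) for x in d])
        minus = np.array([boot_moment(boot.neutral_angle - x, 0.0, boot) for x in d])
        assert np.allclose(plus, -minus)
        assert np.all(np.diff(np.abs(plus)) > 0)
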
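"""The complete musculoskeletal skier system in implicit form.

The state is ``x = (q, qdot, s, a)``: generalized coordinates and rates of
the skier+skis multibody model, projected muscle-fiber lengths, and muscle
activations.  The control is ``u = e``, the neural excitations.  The system
residual stacks

* the kinematic identity  ``d(q)/dt - qdot``,
* the multibody force balance  ``ID(q, qdot, d(qdot)/dt) - tau_applied``
  with muscle moments, passive ski-joint and boot moments, and ski-snow
  contact wrenches applied,
* the implicit Hill contraction residual per muscle,
* the activation-dynamics residual per muscle,

and is zero exactly on motions of the physical system.  Everything is
batched over time nodes and complex-step differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import model_core as mc
from .model_core import MultibodyModel, SystemState
from .muscles import BootParams, MuscleSet, boot_moment
from .ski_snow import ContactParams, SnowPlane, ski_contact_loads

__all__ = ["SkiSystem"]


class SkiSystem:
    """Multibody model + muscles + boot + snow contact, as one implicit system."""

    def __init__(
        self,
        model: MultibodyModel,
        muscles: MuscleSet,
        snow: Optional[SnowPlane] = None,
        contact: Optional[ContactParams] = None,
        boot: Optional[BootParams] = None,
    ):
        self.model = model
        self.muscles = muscles
        muscles.bind(model)
        self.snow = snow
        self.contact = contact or ContactParams()
        self.boot = boot if boot is not None else BootParams()
        self.n_q = model.n_q
        self.n_mus = muscles.n_mus

        # passive ski bending joints: (coordinate index, k, c)
        self._ski_springs = []
        for b, seg in enumerate(model.segments):
            k = seg.meta.get("bend_stiffness")
            if k is None:
                continue
            jnt = model.joints[b]
            if jnt.n_coords == 1:
                self._ski_springs.append((jnt.q_index, k, seg.meta["bend_damping"]))
        self._ankle_coords = [
            model.coord_index(n)
            for n in ("ankle_dorsiflexion_r", "ankle_dorsiflexion_l")
            if n in model.coord_names
        ]
        #: extra coordinate-space spring-dampers (name, k, c, q_neutral),
        #: e.g. to hold a test rig's attitude
        self.extra_springs: list[tuple] = []

    # -- state packing -----------------------------------------------------

    @property
    def n_x(self) -> int:
        return 2 * self.n_q + 2 * self.n_mus

    @property
    def n_u(self) -> int:
        return self.n_mus

    #: bounds on the neural excitations
    control_bounds = (0.0, 1.0)

    @property
    def effort_indices(self) -> range:
        """State-vector indices of the activations (muscle-effort term)."""
        return range(2 * self.n_q + self.n_mus, self.n_x)

    @property
    def state_names(self) -> list[str]:
        qn = self.model.coord_names
        mn = self.muscles.names
        return (
            qn
            + [f"{n}_dot" for n in qn]
            + [f"{n}_fiber" for n in mn]
            + [f"{n}_act" for n in mn]
        )

    def state_index(self, name: str) -> int:
        return self.state_names.index(name)

    def pack(self, q, qdot, s=None, a=None) -> np.ndarray:
        parts = [np.asarray(q), np.asarray(qdot)]
        if self.n_mus:
            parts += [np.asarray(s), np.asarray(a)]
        return np.concatenate(parts, axis=-1)

    def unpack(self, x) -> SystemState:
        x = np.asarray(x)
        nq, nm = self.n_q, self.n_mus
        return SystemState(
            x[..., :nq], x[..., nq:2 * nq],
            x[..., 2 * nq:2 * nq + nm], x[..., 2 * nq + nm:],
        )

    # -- applied generalized forces ---------------------------------------

    def passive_moments(self, q, qdot):
        """Ski bending spring-dampers and the boot restraint (generalized)."""
        tau = np.zeros_like(np.asarray(q))
        for k, stiff, damp in self._ski_springs:
            tau[..., k] = mc.ski_joint_passive_moment(q[..., k], qdot[..., k], stiff, damp)
        for k in self._ankle_coords:
            tau[..., k] = tau[..., k] + boot_moment(q[..., k], qdot[..., k], self.boot)
        for name, stiff, damp, q0 in self.extra_springs:
            k = self.model.coord_index(name)
            tau[..., k] = tau[..., k] - stiff * (q[..., k] - q0) - damp * qdot[..., k]
        return tau

    def boot_moment_series(self, q, qdot):
        """Per-ankle boot moments keyed by coordinate name (analysis helper)."""
        return {
            self.model.coord_names[k]: boot_moment(q[..., k], qdot[..., k], self.boot)
            for k in self._ankle_coords
        }

    # -- residual ----------------------------------------------------------

    def residual(self, x, xdot, u=None):
        """Implicit system residual f(x, xdot, u), batched over leading axes."""
        st, std = self.unpack(x), self.unpack(xdot)
        q, v = st.q, st.qdot
        r_kin = std.q - v

        tau = self.passive_moments(q, v)
        blocks = [r_kin]
        if self.n_mus:
            geo = self.muscles.musculotendon_geometry(q)
            r_con, f_t = self.muscles.contraction_residual(st.s, std.s, st.a, geo.l_mt)
            tau = tau + self.muscles.muscle_joint_moments(q, f_t, geo)
        kin = mc.body_kinematics(self.model, q, v, std.qdot)
        if self.snow is not None:
            ext_f, ext_n = ski_contact_loads(self.model, kin, self.snow, self.contact)
        else:
            ext_f = ext_n = None
        tau_id = mc.inverse_dynamics(self.model, q, v, std.qdot, ext_f, ext_n, kin=kin)
        blocks.append(tau_id - tau)
        if self.n_mus:
            blocks.append(r_con)
            e = np.zeros_like(st.a) if u is None else np.asarray(u)
            blocks.append(self.muscles.activation_residual(st.a, std.a, e))
        return np.concatenate(blocks, axis=-1)

    @property
    def residual_scale(self) -> np.ndarray:
        """Row scaling bringing all residual blocks to comparable magnitude.

        Kinematic rows are rad/s (O(1)), dynamics rows are N or N*m (O(100)),
        contraction rows are already normalized by Fmax, activation rows are
        1/s with rates up to 1/tau_act = 100.
        """
        s_dyn = 1.0 / (max(self.model.total_mass, 1.0) * mc.GRAVITY * 0.3)
        parts = [np.ones(self.n_q), np.full(self.n_q, s_dyn)]
        if self.n_mus:
            parts += [np.ones(self.n_mus), np.full(self.n_mus, 0.04)]
        return np.concatenate(parts)

    def default_bounds(self):
        """Box bounds on the state vector.

        Coordinates and rates are unbounded; projected fiber lengths stay in
        the physiological range [0.4, 1.6] optimal fiber lengths (beyond
        ~1.6 l_opt the exponential parallel element would deliver
        supra-physiological passive forces); activations in [0, 1].
        """
        nq, nm = self.n_q, self.n_mus
        l_opt = self.muscles.param_array("l_opt") if nm else np.zeros(0)
        lb = np.concatenate([
            np.full(nq, -np.inf), np.full(nq, -np.inf),
            0.4 * l_opt, np.zeros(nm),
        ])
        ub = np.concatenate([
            np.full(nq, np.inf), np.full(nq, np.inf),
            1.6 * l_opt, np.ones(nm),
        ])
        return lb, ub

    # -- simulation --------------------------------------------------------

    def forward_simulate(self, x0, excitation_fn=None, h: float = 0.01,
                         n_steps: int = 100, tol: float = 1e-9):
        """Implicit Euler rollout of the full system (oracle / fixtures).

        ``excitation_fn(t) -> e`` supplies neural excitations (default 0).
        """
        def residual(x, xd, t):
            e = None if excitation_fn is None else excitation_fn(t)
            return self.residual(x, xd, e) * self.residual_scale

        return mc.forward_simulate(residual, np.asarray(x0, float), h=h,
                                   n_steps=n_steps, tol=tol)

    # -- contact extraction ------------------------------------------------

    def grf_per_ski(self, q, qdot):
        """Total contact force vector per ski side, shape (..., 3) each.

        Returns a dict with keys present among {'l', 'r'} (assembled model)
        or {'ski'} for a bare ski model.
        """
        if self.snow is None:
            raise mc.ModelError("system has no snow plane")
        kin = mc.body_kinematics(self.model, q, qdot)
        F, _ = ski_contact_loads(self.model, kin, self.snow, self.contact)
        out = {}
        sides = {seg.meta.get("ski_side") for seg in self.model.segments
                 if seg.meta.get("ski_segment")}
        for side in sides:
            mask = np.array([
                seg.meta.get("ski_segment", False)
                and seg.meta.get("ski_side") == side
                for seg in self.model.segments
            ])
            out["ski" if side is None else side] = F[..., mask, :].sum(axis=-2)
        return out
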
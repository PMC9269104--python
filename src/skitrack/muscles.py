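"""Hill-type muscles: routing, activation and implicit contraction dynamics.

Each musculotendon actuator is a three-element Hill model: a contractile
element (CE) with active force-length and force-velocity scaling, a parallel
elastic element, and a series elastic tendon.  The muscle state is the
*projected* fiber length ``s`` (CE length measured along the tendon line of
action); contraction dynamics is posed implicitly as a force balance between
tendon and fiber, which is what the collocation transcription constrains.

Musculotendon path lengths are polynomials in the spanned generalized
coordinates, so moment arms are exact derivatives ``R = -d l_mt / dq``
(tension shortens the muscle; a positive moment arm produces a positive
generalized moment for a positive tendon force).

Curve shapes (Gaussian active force-length, logistic force-velocity,
exponential parallel element, linear-elastic tendon above slack) are standard
smooth normalized forms; the shipped constants are pinned by unit tests and
configurable per muscle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._smooth import logistic, smooth_max0
from .model_core import ModelError, MultibodyModel

__all__ = [
    "MuscleParams",
    "MuscleSet",
    "BootParams",
    "GeometryResult",
    "active_force_length",
    "force_velocity",
    "passive_force_length",
    "tendon_force_length",
    "activation_residual",
    "contraction_residual",
    "boot_moment",
    "default_muscle_set",
    "full_muscle_layout",
]

TAU_ACT = 0.010    # s, activation time constant
TAU_DEACT = 0.040  # s, deactivation time constant


# --------------------------------------------------------------------------
# normalized Hill curves
# --------------------------------------------------------------------------

def active_force_length(ln, width: float = 0.45):
    """Gaussian bell, exactly 1 at optimal fiber length (ln = 1)."""
    d = (ln - 1.0) / width
    return np.exp(-d * d)


def force_velocity(vn, shape: float = 4.0, ecc_gain: float = 1.6, floor: float = 0.2):
    """Logistic force-velocity curve; exactly 1 at vn = 0.

    ``vn`` is normalized fiber velocity (lengthening positive, in optimal
    fiber lengths per vmax-time).  Tends to ``floor`` in fast shortening and
    ``floor + ecc_gain`` in fast lengthening.
    """
    return floor + ecc_gain * logistic(shape * vn)


def passive_force_length(ln, kpe: float = 4.0, e0: float = 0.6):
    """Exponential parallel elastic element, 0 at ln = 1, 1 at ln = 1 + e0."""
    return (np.exp(kpe * (ln - 1.0) / e0) - 1.0) / (np.exp(kpe) - 1.0)


def tendon_force_length(ltn, k_t: float = 35.0, eps: float = 2e-3):
    """Linear-elastic tendon above slack length (normalized force).

    Smoothly floored at zero below slack (strain floor ``eps``); stiffness
    ``k_t`` in units of Fmax per unit strain.
    """
    return k_t * smooth_max0(ltn - 1.0, eps)


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass
class MuscleParams:
    """One musculotendon actuator.

    ``path`` maps coordinate name -> polynomial coefficients (c1, c2, ...)
    such that the path-length contribution is sum_p c_p * q^p; ``l0`` is the
    constant term of l_mt.
    """

    name: str
    fmax: float                  # N
    l_opt: float                 # m, optimal fiber length
    l_slack: float               # m, tendon slack length
    pennation: float = 0.0       # rad at optimal fiber length
    tau_act: float = TAU_ACT
    tau_deact: float = TAU_DEACT
    vmax: float = 10.0           # optimal fiber lengths / s
    tendon_stiffness: float = 35.0
    fl_width: float = 0.45
    path: dict = field(default_factory=dict)
    l0: float = 0.0              # m, constant term of l_mt(q)
    q_range: float = 2.5         # rad, fitted validity range of the path

    def validate(self) -> None:
        if self.fmax <= 0:
            raise ModelError(f"muscle {self.name!r}: fmax must be > 0")
        if self.l_opt <= 0 or self.l_slack <= 0:
            raise ModelError(f"muscle {self.name!r}: lengths must be > 0")
        if not 0.0 <= self.pennation < np.pi / 2:
            raise ModelError(f"muscle {self.name!r}: pennation out of [0, pi/2)")
        if not self.tau_act < self.tau_deact:
            raise ModelError(f"muscle {self.name!r}: requires tau_act < tau_deact")

    @property
    def height(self) -> float:
        """Constant pennation 'height' h = l_opt * sin(alpha0)."""
        return self.l_opt * np.sin(self.pennation)

    def calibrate_l0(self, q_ref: dict, tendon_strain: float = 0.0) -> "MuscleParams":
        """Set l0 so that at posture ``q_ref`` the fiber sits at its optimum
        and the tendon at slack length times (1 + tendon_strain)."""
        target = self.l_slack * (1.0 + tendon_strain) + self.l_opt * np.cos(self.pennation)
        val = 0.0
        for cname, coeffs in self.path.items():
            qv = q_ref.get(cname, 0.0)
            val += sum(c * qv ** (p + 1) for p, c in enumerate(coeffs))
        self.l0 = target - val
        return self


@dataclass
class GeometryResult:
    """Musculotendon lengths, moment arms, and a fitted-range warning flag."""

    l_mt: np.ndarray          # (..., n_mus)
    moment_arms: np.ndarray   # (..., n_mus, n_q); R = -d l_mt / dq
    out_of_range: bool = False


class MuscleSet:
    """An ordered set of muscles bound to a model's coordinates."""

    def __init__(self, muscles: list[MuscleParams], model: Optional[MultibodyModel] = None):
        self.muscles = list(muscles)
        for mus in self.muscles:
            mus.validate()
        self._model = None
        self._terms: list[list[tuple[int, np.ndarray]]] = []
        if model is not None:
            self.bind(model)

    def __len__(self) -> int:
        return len(self.muscles)

    @property
    def n_mus(self) -> int:
        return len(self.muscles)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.muscles]

    def param_array(self, attr: str) -> np.ndarray:
        return np.array([getattr(m, attr) for m in self.muscles])

    def bind(self, model: MultibodyModel) -> "MuscleSet":
        """Resolve path coordinate names against a model (silently dropping
        coordinates the model does not have, e.g. locked ones)."""
        self._model = model
        self._terms = []
        for mus in self.muscles:
            terms = []
            for cname, coeffs in mus.path.items():
                if cname in model.coord_names:
                    terms.append((model.coord_index(cname), np.asarray(coeffs, float)))
            self._terms.append(terms)
        return self

    # -- geometry ----------------------------------------------------------

    def musculotendon_geometry(self, q) -> GeometryResult:
        """l_mt(q) and the exact moment-arm matrix R = -d l_mt/dq."""
        if self._model is None:
            raise ModelError("muscle set is not bound to a model")
        q = np.asarray(q)
        n_q = self._model.n_q
        if q.shape[-1] != n_q:
            raise ModelError(f"q has {q.shape[-1]} coords, model has {n_q}")
        batch = q.shape[:-1]
        dt = complex if np.iscomplexobj(q) else float
        l_mt = np.zeros(batch + (self.n_mus,), dtype=dt)
        R = np.zeros(batch + (self.n_mus, n_q), dtype=dt)
        oor = False
        for im, (mus, terms) in enumerate(zip(self.muscles, self._terms)):
            lm = np.full(batch, mus.l0, dtype=dt) if batch else np.array(mus.l0, dtype=dt)
            for ci, coeffs in terms:
                qc = q[..., ci]
                if np.any(np.abs(np.real(qc)) > mus.q_range):
                    oor = True
                dl = np.zeros_like(qc)
                darm = np.zeros_like(qc)
                for p, c in enumerate(coeffs, start=1):
                    dl = dl + c * qc ** p
                    darm = darm + p * c * qc ** (p - 1)
                lm = lm + dl
                R[..., im, ci] = -darm
            l_mt[..., im] = lm
        return GeometryResult(l_mt, R, oor)

    def muscle_joint_moments(self, q, tendon_forces, geometry: GeometryResult | None = None):
        """Generalized moments tau = R^T F (additive over muscles)."""
        tendon_forces = np.asarray(tendon_forces)
        if tendon_forces.shape[-1] != self.n_mus:
            raise ModelError("tendon_forces length does not match the muscle set")
        geo = geometry if geometry is not None else self.musculotendon_geometry(q)
        return np.einsum("...mk,...m->...k", geo.moment_arms, tendon_forces)

    # -- dynamics ----------------------------------------------------------

    def activation_residual(self, a, adot, e, switch_sharpness: float = 50.0):
        """First-order activation dynamics residual adot - (e - a)/tau.

        The activation/deactivation time-constant switch (tau_act when e > a,
        tau_deact otherwise) is blended with a logistic of sharpness
        ``switch_sharpness`` to keep the residual smooth for the optimizer.
        """
        ta = self.param_array("tau_act")
        td = self.param_array("tau_deact")
        w = logistic(switch_sharpness * (e - a))
        tau = td + (ta - td) * w
        return adot - (e - a) / tau

    def contraction_residual(self, s, sdot, a, l_mt):
        """Implicit Hill contraction residual and tendon forces.

        Enforces the tendon-force / fiber-force balance along the tendon:
            f_t(l_t) = cos(alpha) * [a * fl * fv + fpe]
        with constant-height pennation (fiber length l_f = sqrt(s^2 + h^2)).
        Returns ``(residual, tendon_force_N)``; the residual is normalized by
        Fmax (dimensionless, O(1)).
        """
        s = np.asarray(s)
        for arr in (s, sdot, a, l_mt):
            if not np.all(np.isfinite(np.real(arr))):
                raise ModelError("non-finite input to contraction dynamics")
        l_opt = self.param_array("l_opt")
        l_slack = self.param_array("l_slack")
        fmax = self.param_array("fmax")
        h = np.array([m.height for m in self.muscles])
        vmax = self.param_array("vmax")
        kt = self.param_array("tendon_stiffness")
        width = self.param_array("fl_width")

        lf = np.sqrt(s * s + h * h)
        cosa = s / lf
        ln = lf / l_opt
        vn = (cosa * sdot) / (l_opt * vmax)  # fiber lengthening rate, normalized
        ltn = (l_mt - s) / l_slack
        f_t = tendon_force_length(ltn, kt)
        f_m = cosa * (a * active_force_length(ln, width) * force_velocity(vn)
                      + passive_force_length(ln))
        return f_t - f_m, f_t * fmax


# --------------------------------------------------------------------------
# passive boot moment
# --------------------------------------------------------------------------

@dataclass
class BootParams:
    """Passive ski-boot restraint at the ankle.

    Restoring moment about the dorsiflexion coordinate: zero at the boot's
    neutral forward-lean angle, cubic-stiffening with deflection, plus linear
    damping.  Dorsiflexion beyond neutral produces a plantarflexion-direction
    (negative) moment.  The curve is a plausible stand-in for bench-measured
    boot characteristics and fully configurable.
    """

    neutral_angle: float = np.deg2rad(15.0)  # rad dorsiflexion
    k_linear: float = 15.0                   # N*m/rad
    k_cubic: float = 4000.0                  # N*m/rad^3
    damping: float = 1.5                     # N*m*s/rad

    def validate(self) -> None:
        if self.k_linear < 0 or self.k_cubic < 0 or self.damping < 0:
            raise ModelError("boot stiffness and damping must be >= 0")


def boot_moment(ankle_angle, ankle_rate, boot: BootParams | None = None):
    """Passive boot moment (N*m) about the ankle dorsiflexion coordinate."""
    boot = boot or BootParams()
    d = ankle_angle - boot.neutral_angle
    return -(boot.k_linear * d + boot.k_cubic * d ** 3) - boot.damping * ankle_rate


# --------------------------------------------------------------------------
# residual-level convenience wrappers (single-muscle, used in tests/config)
# --------------------------------------------------------------------------

def activation_residual(a, adot, e, tau_act: float = TAU_ACT, tau_deact: float = TAU_DEACT,
                        switch_sharpness: float = 50.0):
    """Scalar/array activation-dynamics residual (module-level convenience)."""
    w = logistic(switch_sharpness * (np.asarray(e) - np.asarray(a)))
    tau = tau_deact + (tau_act - tau_deact) * w
    return np.asarray(adot) - (np.asarray(e) - np.asarray(a)) / tau


def contraction_residual(s, sdot, a, l_mt, params: MuscleParams):
    """Single-muscle implicit contraction residual, see MuscleSet version."""
    ms = MuscleSet([params])
    return ms.contraction_residual(
        np.asarray([s]) if np.ndim(s) == 0 else s,
        np.asarray([sdot]) if np.ndim(sdot) == 0 else sdot,
        np.asarray([a]) if np.ndim(a) == 0 else a,
        np.asarray([l_mt]) if np.ndim(l_mt) == 0 else l_mt,
    )


# --------------------------------------------------------------------------
# shipped muscle sets
# --------------------------------------------------------------------------

def _leg_muscles(side: str, sgn: float) -> list[MuscleParams]:
    """Reduced per-leg set: 4 muscles with constant (linear-path) moment arms.

    Arms in meters on the named coordinates; positive arm = positive moment
    for the coordinate's positive direction (hip flexion, knee extension).
    """
    hf, kf = f"hip_flexion_{side}", f"knee_flexion_{side}"
    return [
        MuscleParams(f"hip_flexors_{side}", 2200.0, 0.12, 0.13, 0.12,
                     path={hf: [0.055]}),
        MuscleParams(f"glutei_{side}", 3200.0, 0.15, 0.14, 0.15,
                     path={hf: [-0.065]}),
        MuscleParams(f"vasti_{side}", 5000.0, 0.09, 0.22, 0.08,
                     path={kf: [0.042]}),
        MuscleParams(f"hamstrings_{side}", 3000.0, 0.11, 0.33, 0.20,
                     path={hf: [-0.055], kf: [-0.030]}),
    ]


def _lumbar_muscles() -> list[MuscleParams]:
    """Reduced lumbar set: paired extensors and flexors with small lateral arms."""
    out = []
    for side, sgn in (("r", -1.0), ("l", +1.0)):
        out.append(
            MuscleParams(f"erector_spinae_{side}", 2500.0, 0.12, 0.10, 0.1,
                         path={"lumbar_extension": [0.055],
                               "lumbar_bending": [sgn * 0.030]})
        )
        out.append(
            MuscleParams(f"abdominals_{side}", 1500.0, 0.14, 0.12, 0.0,
                         path={"lumbar_extension": [-0.080],
                               "lumbar_bending": [sgn * 0.025]})
        )
    return out


def default_muscle_set(model: MultibodyModel, q_ref: Optional[dict] = None) -> MuscleSet:
    """Reduced default set (12 muscles: 4 per leg + 4 lumbar), calibrated so
    fibers sit at their optimum in the reference (crouched) posture."""
    q_ref = dict(q_ref or {
        "hip_flexion_r": 0.9, "hip_flexion_l": 0.9,
        "knee_flexion_r": -1.0, "knee_flexion_l": -1.0,
        "lumbar_extension": -0.35,
    })
    muscles = _leg_muscles("r", -1.0) + _leg_muscles("l", +1.0) + _lumbar_muscles()
    for mus in muscles:
        mus.calibrate_l0(q_ref, tendon_strain=0.0)
    return MuscleSet(muscles, model)


#: 40 lower-limb muscles of the source OpenSim-style layout, plus the three
#: deep hip muscles added for hip strength.
_LEG_MUSCLE_NAMES = [
    "addbrev", "addlong", "addmagDist", "addmagIsch", "addmagMid", "addmagProx",
    "bflh", "bfsh", "edl", "ehl", "fdl", "fhl", "gaslat", "gasmed",
    "glmax1", "glmax2", "glmax3", "glmed1", "glmed2", "glmed3",
    "glmin1", "glmin2", "glmin3", "grac", "iliacus", "perbrev", "perlong",
    "piri", "psoas", "recfem", "sart", "semimem", "semiten", "soleus",
    "tfl", "tibant", "tibpost", "vasint", "vaslat", "vasmed",
    "gem", "pect", "quadfem",
]

_LUMBAR_MUSCLE_NAMES = [
    "erector_spinae_r", "erector_spinae_l",
    "rectus_abdominis_r", "rectus_abdominis_l",
    "obliquus_externus_r", "obliquus_externus_l",
    "obliquus_internus_r", "obliquus_internus_l",
]

#: crude default action of each full-layout leg muscle:
#: (coordinate stem, moment arm m).  Multi-entry = biarticular.
_LEG_ACTIONS = {
    "glmax": [("hip_flexion", -0.06)], "glmed": [("hip_adduction", -0.05)],
    "glmin": [("hip_adduction", -0.04)], "iliacus": [("hip_flexion", 0.05)],
    "psoas": [("hip_flexion", 0.05)], "addbrev": [("hip_adduction", 0.04)],
    "addlong": [("hip_adduction", 0.05)], "addmag": [("hip_adduction", 0.05)],
    "bflh": [("hip_flexion", -0.05), ("knee_flexion", -0.03)],
    "bfsh": [("knee_flexion", -0.03)], "recfem": [("hip_flexion", 0.04), ("knee_flexion", 0.04)],
    "vas": [("knee_flexion", 0.042)], "semimem": [("hip_flexion", -0.05), ("knee_flexion", -0.03)],
    "semiten": [("hip_flexion", -0.05), ("knee_flexion", -0.03)],
    "gas": [("knee_flexion", -0.02), ("ankle_dorsiflexion", -0.05)],
    "soleus": [("ankle_dorsiflexion", -0.04)], "tibant": [("ankle_dorsiflexion", 0.04)],
    "tibpost": [("ankle_dorsiflexion", -0.02)], "per": [("ankle_dorsiflexion", -0.02)],
    "edl": [("ankle_dorsiflexion", 0.03)], "ehl": [("ankle_dorsiflexion", 0.03)],
    "fdl": [("ankle_dorsiflexion", -0.02)], "fhl": [("ankle_dorsiflexion", -0.02)],
    "sart": [("hip_flexion", 0.04), ("knee_flexion", -0.01)],
    "grac": [("hip_adduction", 0.03), ("knee_flexion", -0.01)],
    "tfl": [("hip_flexion", 0.03), ("hip_adduction", -0.03)],
    "piri": [("hip_rotation", -0.02)], "gem": [("hip_rotation", -0.02)],
    "quadfem": [("hip_rotation", -0.02)], "pect": [("hip_adduction", 0.03)],
}


def _leg_action(stem: str):
    for key, act in _LEG_ACTIONS.items():
        if stem.startswith(key):
            return act
    return [("hip_flexion", 0.03)]


def full_muscle_layout(model: Optional[MultibodyModel] = None) -> MuscleSet:
    """Full structural layout: 94 muscles (43 per leg + 8 lumbar).

    Per-muscle force and path parameters are generic defaults (the source
    cadaver-based parameter sets are not reproduced here); the layout serves
    the size and bookkeeping contract of the full model.
    """
    muscles = []
    for side in ("r", "l"):
        for stem in _LEG_MUSCLE_NAMES:
            path = {f"{coord}_{side}": [arm] for coord, arm in _leg_action(stem)}
            muscles.append(
                MuscleParams(f"{stem}_{side}", 1500.0, 0.10, 0.15, 0.1, path=path)
            )
    for name in _LUMBAR_MUSCLE_NAMES:
        sgn = -1.0 if name.endswith("_r") else 1.0
        arm = 0.05 if "erector" in name else -0.06
        muscles.append(
            MuscleParams(name, 1800.0, 0.12, 0.10, 0.1,
                         path={"lumbar_extension": [arm],
                               "lumbar_bending": [sgn * 0.03]})
        )
    for mus in muscles:
        mus.calibrate_l0({}, tendon_strain=0.0)
    ms = MuscleSet(muscles)
    if model is not None:
        ms.bind(model)
    return ms
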
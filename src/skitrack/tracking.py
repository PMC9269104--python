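"""Data-tracking optimal control by direct collocation with implicit Euler.

The continuous problem: find states ``x(t)`` and controls ``u(t)`` of the
musculoskeletal system minimizing

    J = (1/T) * int_0^T [ w1 ||err_q||^2 + w2 sum_i a_i^2
                          + w3 (||xdot||^2 + ||udot||^2) ] dt

subject to the implicit system dynamics f(x, xdot, u) = 0 and box bounds on
states and controls (activations and excitations in [0, 1]).  ``err_q`` is
the deviation of tracked coordinates (pelvis pose, lumbar/hip/knee/ankle
angles) from measurement; any subset of channels may be tracked, so the
problem handles over- and under-determined data, including the no-GRF case.

Transcription: states and controls are discretized at N nodes; the dynamics
become algebraic equality constraints via the implicit Euler formula

    f(x_k, (x_k - x_{k-1})/h, u_k) = 0,   k = 1..N-1,

and the integral objective is discretized with a left-rectangle rule on the
node intervals, consistent with implicit Euler.  The objective is exactly
quadratic in the decision vector; constraint Jacobians are sparse
block-bidiagonal and evaluated to machine precision by parity-colored
complex-step differentiation.  The resulting NLP is solved by a sparse
Gauss-Newton SQP with an l1 merit line search and bound projection (an
external large-scale interior-point solver would serve equally; a
scipy ``trust-constr`` backend is provided for small problems).
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model_core import ModelError
from .system import SkiSystem

__all__ = [
    "TrackingData",
    "ObjectiveWeights",
    "TrackingProblem",
    "Solution",
    "CustomSystem",
    "objective_value",
    "transcribe",
    "initial_guess",
    "solve",
    "solve_tracking",
    "extract_grf",
]


# --------------------------------------------------------------------------
# problem data
# --------------------------------------------------------------------------

@dataclass
class TrackingData:
    """Tracked coordinate trajectories on a uniform time grid.

    ``channels`` maps coordinate names (matching model coordinates) to value
    arrays; ``weights`` holds optional per-channel tracking weights
    (default 1).  Angles are radians, translations meters.
    """

    time: np.ndarray
    channels: dict
    weights: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        if self.time.ndim != 1 or len(self.time) < 2:
            raise ModelError("tracking data needs at least two time samples")
        if np.any(np.diff(self.time) <= 0):
            raise ModelError("tracking data time grid must be strictly increasing")
        for name, vals in self.channels.items():
            vals = np.asarray(vals, float)
            if vals.shape != self.time.shape:
                raise ModelError(f"channel {name!r} length does not match time grid")
            self.channels[name] = vals

    @property
    def rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time)))

    def interp(self, t) -> dict:
        return {k: np.interp(t, self.time, v) for k, v in self.channels.items()}


@dataclass
class ObjectiveWeights:
    """Weighting factors of the tracking objective (see module docstring)."""

    w1: float = 1.0     # tracking, per channel (rad^-2 / m^-2)
    w2: float = 0.1     # muscle effort (activation squared)
    w3: float = 1e-4    # regularization on state and control derivatives
    grf_weight: float = 0.0  # optional GRF-magnitude tracking term

    def validate(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ModelError("w1 and w2 must be >= 0")
        if not self.w3 > 0:
            raise ModelError("w3 must be > 0 (regularizes untracked directions)")


class CustomSystem:
    """Minimal implicit system for toy problems and oracles.

    ``residual_fn(x, xdot, u)`` must broadcast over leading batch axes and be
    complex-step safe.
    """

    def __init__(self, n_x, n_u, residual_fn, state_names=None,
                 effort_indices=(), control_bounds=(-np.inf, np.inf)):
        self.n_x, self.n_u = n_x, n_u
        self._fn = residual_fn
        self.state_names = state_names or [f"x{i}" for i in range(n_x)]
        self.effort_indices = list(effort_indices)
        self.control_bounds = control_bounds
        self.residual_scale = np.ones(n_x)

    def state_index(self, name):
        return self.state_names.index(name)

    def residual(self, x, xdot, u=None):
        return self._fn(x, xdot, u)

    def default_bounds(self):
        return np.full(self.n_x, -np.inf), np.full(self.n_x, np.inf)


@dataclass
class TrackingProblem:
    """A posed tracking problem: system + data + weights + discretization."""

    system: object                 # SkiSystem or CustomSystem
    data: TrackingData
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)
    n_nodes: Optional[int] = None  # default: one node per measurement sample
    x_lb: Optional[np.ndarray] = None
    x_ub: Optional[np.ndarray] = None
    q_ref: dict = field(default_factory=dict)  # default posture for guesses
    grf_target: Optional[np.ndarray] = None    # |GRF| target per node (N)
    x0_pin: Optional[np.ndarray] = None        # anchored initial state (NaN = free)
    x0_pin_weight: object = 1e3                # quadratic anchor weight (scalar or per-state)

    def __post_init__(self):
        self.weights.validate()
        if self.n_nodes is None:
            self.n_nodes = len(self.data.time)
        if self.n_nodes < 2:
            raise ModelError("need at least N = 2 collocation nodes")
        lb0, ub0 = self.system.default_bounds()
        self.x_lb = lb0 if self.x_lb is None else np.asarray(self.x_lb, float)
        self.x_ub = ub0 if self.x_ub is None else np.asarray(self.x_ub, float)
        if np.any(self.x_lb > self.x_ub):
            bad = int(np.argmax(self.x_lb > self.x_ub))
            raise ModelError(
                f"infeasible bounds on state {self.system.state_names[bad]!r}"
            )
        for name in self.data.channels:
            if name not in self.system.state_names:
                raise ModelError(f"tracked channel {name!r} is not a model coordinate")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(self.data.time[0], self.data.time[-1], self.n_nodes)

    @property
    def h(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def horizon(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class Solution:
    """Optimized trajectories plus solver diagnostics."""

    times: np.ndarray
    states: np.ndarray     # (N, n_x)
    controls: np.ndarray   # (N, n_u)
    objective: float
    terms: dict
    status: str
    max_residual: float    # max node-wise scaled dynamics residual (inf-norm)
    iterations: int
    message: str = ""
    problem: Optional[TrackingProblem] = None

    @property
    def converged(self) -> bool:
        return self.status == "converged"


# --------------------------------------------------------------------------
# objective
# --------------------------------------------------------------------------

def _tracking_targets(problem: TrackingProblem):
    """(state index, weight, target values at nodes) per tracked channel."""
    t = problem.times
    out = []
    for name, vals in problem.data.channels.items():
        idx = problem.system.state_index(name)
        wc = problem.data.weights.get(name, 1.0)
        out.append((idx, wc, np.interp(t, problem.data.time, vals)))
    return out


def objective_value(states, controls, problem: TrackingProblem):
    """Objective J and its term breakdown for given node trajectories."""
    X = np.atleast_2d(np.asarray(states, float))
    U = np.asarray(controls, float).reshape(X.shape[0], -1)
    N = problem.n_nodes
    if X.shape != (N, problem.system.n_x):
        raise ModelError(
            f"states shape {X.shape} does not match grid ({N}, {problem.system.n_x})"
        )
    h, T = problem.h, problem.horizon
    w = problem.weights
    # left-rectangle rule: nodes 0..N-2 weighted h
    sl = slice(0, N - 1)
    track = 0.0
    for idx, wc, y in _tracking_targets(problem):
        track += wc * np.sum((X[sl, idx] - y[sl]) ** 2)
    track *= w.w1 * h / T
    eff_idx = list(problem.system.effort_indices)
    effort = w.w2 * h / T * float(np.sum(X[sl][:, eff_idx] ** 2)) if eff_idx else 0.0
    dX = np.diff(X, axis=0) / h
    dU = np.diff(U, axis=0) / h if U.size else np.zeros((N - 1, 0))
    reg = w.w3 * h / T * float(np.sum(dX ** 2) + np.sum(dU ** 2))
    terms = {"tracking": float(track), "effort": float(effort), "regularization": reg}
    if w.grf_weight > 0.0 and problem.grf_target is not None:
        r = _grf_residual_values(problem, X)
        terms["grf"] = float(w.grf_weight * h / T * np.sum(r ** 2))
    return float(sum(terms.values())), terms


def _grf_residual_values(problem, X):
    sysm = problem.system
    st = sysm.unpack(X)
    grf = sysm.grf_per_ski(st.q, st.qdot)
    total = sum(np.linalg.norm(np.real(v), axis=-1) for v in grf.values())
    return total[: problem.n_nodes - 1] - np.asarray(problem.grf_target)[: problem.n_nodes - 1]


# --------------------------------------------------------------------------
# transcription
# --------------------------------------------------------------------------

class NLP:
    """Sparse NLP: quadratic objective, implicit-Euler equality constraints.

    Decision vector z stacks [x_k, u_k] per node.  ``constraints``/
    ``jacobian`` evaluate the scaled dynamics residuals and their exact
    sparse Jacobian (complex-step, parity-colored).
    """

    def __init__(self, problem: TrackingProblem):
        self.problem = problem
        sysm = problem.system
        self.N = problem.n_nodes
        self.n_x, self.n_u = sysm.n_x, sysm.n_u
        self.n_node = self.n_x + self.n_u
        self.n_z = self.N * self.n_node
        self.m = (self.N - 1) * self.n_x
        self.h = problem.h
        self.scale = np.asarray(sysm.residual_scale, float)
        self._build_bounds()
        self._build_quadratic()

    # -- layout ------------------------------------------------------------

    def split(self, z):
        Z = np.asarray(z).reshape(self.N, self.n_node)
        return Z[:, : self.n_x], Z[:, self.n_x:]

    def join(self, X, U):
        return np.concatenate(
            [np.asarray(X), np.asarray(U).reshape(self.N, self.n_u)], axis=1
        ).ravel()

    def _build_bounds(self):
        p = self.problem
        lbn = np.concatenate([p.x_lb, np.full(self.n_u, p.system.control_bounds[0])])
        ubn = np.concatenate([p.x_ub, np.full(self.n_u, p.system.control_bounds[1])])
        self.lb = np.tile(lbn, self.N)
        self.ub = np.tile(ubn, self.N)
        # the initial-state anchor is a soft quadratic penalty (see
        # _build_quadratic), not a hard bound: hard lb == ub pins interact
        # badly with the projected line search

    # -- constraints -------------------------------------------------------

    def _batch_residual(self, X, U):
        """Scaled implicit-Euler residuals for all intervals, (..., N-1, n_x).

        ``X``/``U`` may carry extra leading axes (e.g. complex-step colors);
        the node axis is second-to-last.
        """
        Xk, Xp = X[..., 1:, :], X[..., :-1, :]
        Xd = (Xk - Xp) / self.h
        r = self.problem.system.residual(
            Xk, Xd, U[..., 1:, :] if self.n_u else None)
        return r * self.scale

    def constraints(self, z):
        X, U = self.split(z)
        return np.real(self._batch_residual(X, U)).ravel()

    def jacobian(self, z) -> sp.csr_matrix:
        """Exact sparse Jacobian by parity-colored complex step.

        All 2*(n_x + n_u) colors are evaluated in a single batched residual
        call with a leading color axis; interval k depends on nodes k-1 and
        k, whose parities differ, so each color's derivative attributes
        unambiguously to one node.
        """
        X, U = self.split(z)
        hcs = 1e-20
        n_c = 2 * self.n_node
        Xc = np.broadcast_to(X.astype(complex), (n_c,) + X.shape).copy()
        Uc = np.broadcast_to(U.astype(complex), (n_c,) + U.shape).copy()
        node_par = np.arange(self.N) % 2
        for parity in (0, 1):
            pert = node_par == parity
            base = parity * self.n_node
            for j in range(self.n_x):
                Xc[base + j, pert, j] += 1j * hcs
            for j in range(self.n_u):
                Uc[base + self.n_x + j, pert, j] += 1j * hcs
        D = np.imag(self._batch_residual(Xc, Uc)) / hcs  # (n_c, N-1, n_x)

        m_node = self.n_x
        karr = np.arange(1, self.N)
        rows, cols, vals = [], [], []
        for parity in (0, 1):
            base = parity * self.n_node
            src_node = np.where(karr % 2 == parity, karr, karr - 1)
            for j in range(self.n_node):
                if j >= self.n_x:
                    sel = karr % 2 == parity  # controls: node k only
                else:
                    sel = np.ones_like(karr, bool)
                Dm = D[base + j]
                kk, ii = np.nonzero(Dm)
                use = sel[kk]
                kk, ii = kk[use], ii[use]
                if kk.size == 0:
                    continue
                rows.append(kk * m_node + ii)
                cols.append(src_node[kk] * self.n_node + j)
                vals.append(Dm[kk, ii])
        if rows:
            rows = np.concatenate(rows)
            cols = np.concatenate(cols)
            vals = np.concatenate(vals)
        else:  # pragma: no cover - degenerate
            rows = cols = vals = np.zeros(0)
        return sp.csr_matrix((vals, (rows, cols)), shape=(self.m, self.n_z))

    # -- quadratic objective ----------------------------------------------

    def _build_quadratic(self):
        p = self.problem
        w = p.weights
        N, nn = self.N, self.n_node
        h, T = self.h, p.horizon
        diag = np.zeros(self.n_z)
        g = np.zeros(self.n_z)
        const = 0.0
        # tracking term, nodes 0..N-2
        for idx, wc, y in _tracking_targets(p):
            wk = w.w1 * wc * h / T
            for k in range(N - 1):
                i = k * nn + idx
                diag[i] += 2 * wk
                g[i] -= 2 * wk * y[k]
                const += wk * y[k] ** 2
        # effort term
        for idx in p.system.effort_indices:
            for k in range(N - 1):
                diag[k * nn + idx] += 2 * w.w2 * h / T
        # soft anchor of the initial state (the first collocation interval
        # starts at node 1, so node 0 needs anchoring to stay physical)
        if p.x0_pin is not None:
            pin = np.asarray(p.x0_pin, float)
            wpin = np.broadcast_to(np.asarray(p.x0_pin_weight, float), pin.shape)
            for i in np.nonzero(np.isfinite(pin))[0]:
                diag[i] += 2 * wpin[i]
                g[i] -= 2 * wpin[i] * pin[i]
                const += wpin[i] * pin[i] ** 2
        H = sp.diags(diag).tolil()
        # regularization on first differences of all z entries
        rho = w.w3 / (T * h)
        i0 = np.arange((N - 1) * nn)
        i1 = i0 + nn
        D = sp.coo_matrix(
            (np.concatenate([np.full(i0.size, -1.0), np.ones(i1.size)]),
             (np.concatenate([np.arange(i0.size), np.arange(i1.size)]),
              np.concatenate([i0, i1]))),
            shape=((N - 1) * nn, self.n_z),
        ).tocsr()
        H = (H.tocsr() + 2 * rho * (D.T @ D)).tocsr()
        self.H, self.g, self.const = H, g, const

    def quadratic_objective(self, z):
        return float(0.5 * z @ (self.H @ z) + self.g @ z + self.const)

    def gradient(self, z):
        return self.H @ z + self.g


def transcribe(problem: TrackingProblem) -> NLP:
    """Transcribe a tracking problem to a sparse NLP (see :class:`NLP`)."""
    return NLP(problem)


# --------------------------------------------------------------------------
# initial guesses
# --------------------------------------------------------------------------

def _default_state_template(problem: TrackingProblem) -> np.ndarray:
    """One node state from q_ref posture with near-isometric muscle states."""
    sysm = problem.system
    x = np.zeros(sysm.n_x)
    if not isinstance(sysm, SkiSystem):
        return np.clip(x, problem.x_lb, problem.x_ub)
    q = np.zeros(sysm.n_q)
    for name, val in problem.q_ref.items():
        if name in sysm.model.coord_names:
            q[sysm.model.coord_index(name)] = val
    geo = sysm.muscles.musculotendon_geometry(q)
    l_slack = sysm.muscles.param_array("l_slack")
    s = np.maximum(np.real(geo.l_mt) - l_slack, 0.3 * sysm.muscles.param_array("l_opt"))
    a = np.full(sysm.n_mus, 0.1)
    return sysm.pack(q, np.zeros(sysm.n_q), s, a)


def initial_guess(problem: TrackingProblem, mode: str = "interpolate_data") -> np.ndarray:
    """Initial decision vector: 'schuss', 'interpolate_data' or 'midpoint'.

    * ``interpolate_data``: tracked channels copied from the data, remaining
      states from the reference posture; rates by finite differences.
    * ``schuss``: a straight fall-line run at the speed implied by the data's
      pelvis forward translation (lateral deviation zero), reference posture
      held.
    * ``midpoint``: midpoint of the (finite) bounds.

    All guesses are clipped into the bounds.
    """
    if mode not in ("schuss", "interpolate_data", "midpoint"):
        raise ModelError(f"unknown initial-guess mode {mode!r}")
    nlp = NLP(problem)
    sysm = problem.system
    N = problem.n_nodes
    t = problem.times
    X = np.tile(_default_state_template(problem), (N, 1))
    U = np.full((N, sysm.n_u), 0.1)

    if mode == "midpoint":
        lo = np.where(np.isfinite(problem.x_lb), problem.x_lb, 0.0)
        hi = np.where(np.isfinite(problem.x_ub), problem.x_ub, 0.0)
        X[:] = 0.5 * (lo + hi)
    elif mode == "interpolate_data":
        for idx, _, y in _tracking_targets(problem):
            X[:, idx] = y
    else:  # schuss: straight run down the fall line at matched initial speed
        if isinstance(sysm, SkiSystem) and "pelvis_tx" in sysm.model.coord_names:
            ix = sysm.state_index("pelvis_tx")
            ch = problem.data.channels
            if "pelvis_tx" in ch:
                v0 = np.gradient(ch["pelvis_tx"], problem.data.time)[0]
                x0 = ch["pelvis_tx"][0]
            else:
                v0, x0 = 10.0, 0.0
            X[:, ix] = x0 + v0 * (t - t[0])
            if "pelvis_tz" in ch:
                X[:, sysm.state_index("pelvis_tz")] = ch["pelvis_tz"][0] + (
                    np.interp(t, problem.data.time, ch["pelvis_tz"]) - ch["pelvis_tz"][0]
                ) * 0 + np.gradient(ch["pelvis_tz"], problem.data.time)[0] * (t - t[0])
    # rates by backward differences (consistent with the implicit Euler
    # collocation formula) of lightly smoothed positions — differencing raw
    # noisy angles would seed rate noise of O(noise * rate) — and muscle
    # fibers at per-node force equilibrium
    if isinstance(sysm, SkiSystem):
        nq = sysm.n_q
        Q = X[:, :nq]
        Qs = Q
        if N >= 5:
            pad = np.pad(Q, ((2, 2), (0, 0)), mode="reflect", reflect_type="odd")
            kernel = np.ones(5) / 5
            Qs = np.stack([np.convolve(pad[:, i], kernel, "valid")
                           for i in range(nq)], axis=-1)
        V = np.vstack([(Qs[1] - Qs[0]), np.diff(Qs, axis=0)]) / problem.h
        X[:, nq:2 * nq] = V
        if sysm.n_mus:
            geo = sysm.muscles.musculotendon_geometry(Q)
            l_mt = np.real(geo.l_mt)
            a = X[:, 2 * nq + sysm.n_mus:]
            X[:, 2 * nq:2 * nq + sysm.n_mus] = _equilibrium_fiber_length(
                sysm.muscles, l_mt, a
            )
    return np.clip(nlp.join(X, U), nlp.lb, nlp.ub)


def _equilibrium_fiber_length(muscles, l_mt, a, iters: int = 40):
    """Projected fiber lengths solving the isometric force balance.

    Bisection on s per muscle and node: the contraction residual is
    monotone decreasing in s (shorter tendon stretch, longer fiber).
    """
    l_opt = muscles.param_array("l_opt")
    lo = np.broadcast_to(0.2 * l_opt, l_mt.shape).copy()
    hi = np.maximum(l_mt - 0.5 * muscles.param_array("l_slack"), 2.0 * l_opt)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        r, _ = muscles.contraction_residual(mid, np.zeros_like(mid), a, l_mt)
        lo = np.where(r > 0, mid, lo)
        hi = np.where(r <= 0, mid, hi)
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# solver
# --------------------------------------------------------------------------

_DEFAULT_OPTIONS = dict(
    max_iter=150,
    tol_feas=1e-4,
    tol_stat=1e-3,
    reg_init=1e-4,
    step_cap=1.0,          # inf-norm trust limit on the SQP step
    verbose=False,
    method="sqp",          # 'sqp' | 'trust-constr'
    time_limit=None,       # seconds, soft
)


def solve(nlp: NLP, z0: Optional[np.ndarray] = None, options: Optional[dict] = None) -> Solution:
    """Solve the transcribed NLP; never raises on solver failure.

    Returns the best iterate with diagnostics; ``status='converged'`` means
    max scaled constraint violation <= tol_feas and projected-gradient
    stationarity <= tol_stat.
    """
    opts = dict(_DEFAULT_OPTIONS)
    opts.update(options or {})
    if z0 is None:
        z0 = initial_guess(nlp.problem, "interpolate_data")
    z0 = np.clip(np.asarray(z0, float), nlp.lb, nlp.ub)
    try:
        if opts["method"] == "trust-constr":
            return _solve_trust_constr(nlp, z0, opts)
        return _solve_sqp(nlp, z0, opts)
    except Exception as err:  # noqa: BLE001 - contract: no uncaught crash
        X, U = nlp.split(z0)
        J, terms = objective_value(X, U, nlp.problem)
        return Solution(
            nlp.problem.times, X, U, J, terms, "failed",
            float(np.max(np.abs(nlp.constraints(z0)))), 0,
            message=f"{type(err).__name__}: {err}", problem=nlp.problem,
        )


def _finalize(nlp, z, status, iters, msg=""):
    X, U = nlp.split(z)
    J, terms = objective_value(X, U, nlp.problem)
    viol = float(np.max(np.abs(nlp.constraints(z)))) if nlp.m else 0.0
    return Solution(nlp.problem.times, X, U, J, terms, status, viol, iters,
                    message=msg, problem=nlp.problem)


def _grf_gauss_newton(nlp, z):
    """Optional GRF-tracking term: value, gradient and GN Hessian updates."""
    p = nlp.problem
    w = p.weights
    if w.grf_weight <= 0.0 or p.grf_target is None:
        return 0.0, None, None
    X, _ = nlp.split(z)
    scale = w.grf_weight * nlp.h / p.horizon
    r = _grf_residual_values(p, X)
    # Jacobian by complex step, node-local (one sweep over state entries)
    hcs = 1e-20
    rows, cols, vals = [], [], []
    for j in range(nlp.n_x):
        Xc = X.astype(complex)
        Xc[:, j] += 1j * hcs
        d = np.imag(_grf_residual_values(p, Xc)) / hcs
        nz = np.nonzero(d)[0]
        rows.append(nz)
        cols.append(nz * nlp.n_node + j)
        vals.append(d[nz])
    Jr = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(r.size, nlp.n_z),
    )
    grad = 2 * scale * (Jr.T @ r)
    Hgn = 2 * scale * (Jr.T @ Jr)
    return scale * float(r @ r), grad, Hgn


def _solve_sqp(nlp: NLP, z0: np.ndarray, opts: dict) -> Solution:
    """Gauss-Newton SQP with l1 merit, second-order correction, and
    Levenberg-style adaptive proximal regularization."""
    z = z0.copy()
    nu = 10.0
    delta = opts["reg_init"]
    t_start = _time.monotonic()
    c = nlp.constraints(z)
    it = 0

    def merit_obj(zz):
        val = nlp.quadratic_objective(zz)
        p = nlp.problem
        if p.weights.grf_weight > 0 and p.grf_target is not None:
            X, _ = nlp.split(zz)
            val += p.weights.grf_weight * nlp.h / p.horizon * float(
                np.sum(_grf_residual_values(p, X) ** 2)
            )
        return val

    for it in range(1, opts["max_iter"] + 1):
        H, g = nlp.H, nlp.g
        _, grf_g, grf_H = _grf_gauss_newton(nlp, z)
        if grf_g is not None:
            g = g + grf_g - grf_H @ z  # linearize the GRF term about z
            H = H + grf_H
        A = nlp.jacobian(z)
        grad = H @ z + g
        lu = None
        for _ in range(8):
            K = sp.bmat(
                [[H + delta * sp.eye(nlp.n_z), A.T],
                 [A, -1e-10 * sp.eye(nlp.m)]],
                format="csc",
            )
            try:
                lu = spla.splu(K)
                sol = lu.solve(np.concatenate([-grad, -c]))
            except Exception:
                delta *= 100
                lu = None
                continue
            if not np.all(np.isfinite(sol)):
                delta *= 100
                lu = None
                continue
            dz, lam = sol[: nlp.n_z], sol[nlp.n_z:]
            break
        if lu is None:
            return _finalize(nlp, z, "failed", it, "singular KKT system")
        if lam.size:
            nu = max(1.2 * float(np.max(np.abs(lam))), 0.9 * nu, 1.0)
        stepn = float(np.max(np.abs(dz)))
        if stepn > opts["step_cap"]:
            dz *= opts["step_cap"] / stepn

        l1 = float(np.sum(np.abs(c)))
        phi0 = merit_obj(z) + nu * l1
        decrease = 1e-6 * nu * l1 + 1e-14

        # full step, then second-order correction, then backtracking
        alpha, accepted, soc = 1.0, False, False
        z_new = np.clip(z + dz, nlp.lb, nlp.ub)
        c_new = nlp.constraints(z_new)
        if merit_obj(z_new) + nu * np.sum(np.abs(c_new)) < phi0 - decrease:
            accepted = True
        else:
            corr = lu.solve(np.concatenate([np.zeros(nlp.n_z), -c_new]))[: nlp.n_z]
            z_soc = np.clip(z + dz + corr, nlp.lb, nlp.ub)
            c_soc = nlp.constraints(z_soc)
            if merit_obj(z_soc) + nu * np.sum(np.abs(c_soc)) < phi0 - decrease:
                z_new, c_new, accepted, soc = z_soc, c_soc, True, True
        if not accepted:
            alpha = 0.5
            for _ in range(16):
                z_new = np.clip(z + alpha * dz, nlp.lb, nlp.ub)
                c_new = nlp.constraints(z_new)
                if merit_obj(z_new) + nu * np.sum(np.abs(c_new)) < phi0 - alpha * decrease:
                    accepted = True
                    break
                alpha *= 0.5
        if not accepted:
            delta *= 10
            if delta > 1e8:
                return _finalize(nlp, z, "stalled", it, "line search failed")
            continue
        z, c = z_new, c_new
        if alpha > 0.9:
            delta = max(delta / 3, 1e-8)
        elif alpha < 0.2:
            delta *= 3
        feas = float(np.max(np.abs(c))) if c.size else 0.0
        gl = (H @ z + g) + (A.T @ lam if lam.size else 0.0)
        stat = float(np.max(np.abs(np.clip(z - gl, nlp.lb, nlp.ub) - z)))
        if opts["verbose"]:
            print(f"  sqp it {it:3d}: feas {feas:9.2e} stat {stat:9.2e} "
                  f"alpha {alpha:5.2f}{' soc' if soc else '    '} delta {delta:7.1e}")
        if feas <= opts["tol_feas"] and stat <= opts["tol_stat"]:
            return _finalize(nlp, z, "converged", it)
        if opts["time_limit"] and _time.monotonic() - t_start > opts["time_limit"]:
            return _finalize(nlp, z, "time_limit", it, "soft time limit reached")
    return _finalize(nlp, z, "max_iter", it, "iteration limit reached")


def _solve_trust_constr(nlp: NLP, z0: np.ndarray, opts: dict) -> Solution:
    from scipy.optimize import Bounds, NonlinearConstraint, minimize

    cons = NonlinearConstraint(nlp.constraints, 0.0, 0.0, jac=nlp.jacobian)
    res = minimize(
        nlp.quadratic_objective, z0, jac=nlp.gradient, hess=lambda z: nlp.H,
        method="trust-constr", bounds=Bounds(nlp.lb, nlp.ub), constraints=[cons],
        options=dict(maxiter=opts["max_iter"] * 20, gtol=opts["tol_stat"],
                     xtol=1e-12, verbose=0),
    )
    status = "converged" if res.constr_violation < 10 * opts["tol_feas"] else "max_iter"
    return _finalize(nlp, res.x, status, int(res.nit), res.message)


def solve_tracking(problem: TrackingProblem, z0: Optional[np.ndarray] = None,
                   options: Optional[dict] = None) -> Solution:
    """Robust two-phase driver for musculoskeletal tracking problems.

    Phase 1 projects the initial guess onto the dynamics manifold (proximal
    objective ``0.5*alpha*||z - z0||^2`` under the same constraints); phase 2
    optimizes the tracking objective warm-started from the projection.  Each
    phase restarts the SQP (resetting its damping and merit-penalty state)
    while that keeps improving feasibility — the contact and muscle
    nonlinearities are strong enough that a stale Levenberg state can stall
    an otherwise convergent iteration.
    """
    opts = dict(_DEFAULT_OPTIONS)
    opts.update(options or {})
    rounds = opts.pop("max_rounds", 4)
    proj_alpha = opts.pop("projection_weight", 1e-2)
    nlp = NLP(problem)
    if z0 is None:
        z0 = initial_guess(problem, "interpolate_data")
    z0 = np.clip(np.asarray(z0, float), nlp.lb, nlp.ub)

    # phase 1: the tracking objective plus a proximal anchor to the guess —
    # the anchor regularizes the untracked directions during projection while
    # the tracking term keeps the iterates on the measured maneuver
    H_full, g_full, const_full = nlp.H, nlp.g, nlp.const
    nlp.H = (H_full + proj_alpha * sp.eye(nlp.n_z)).tocsr()
    nlp.g = g_full - proj_alpha * z0
    nlp.const = const_full + 0.5 * proj_alpha * float(z0 @ z0)
    z, best = z0, None
    try:
        for _ in range(rounds):
            sol = _solve_sqp(nlp, z, opts)
            z = nlp.join(sol.states, sol.controls)
            improved = best is None or sol.max_residual < 0.5 * best
            best = sol.max_residual if best is None or sol.max_residual < best else best
            if sol.max_residual <= opts["tol_feas"] or not improved:
                break
        nlp.H, nlp.g, nlp.const = H_full, g_full, const_full
        best_sol, best_key = None, None
        for _ in range(rounds):
            sol = _solve_sqp(nlp, z, opts)
            z = nlp.join(sol.states, sol.controls)
            key = (max(sol.max_residual, opts["tol_feas"]), sol.objective)
            if best_key is None or key < best_key:
                best_sol, best_key = sol, key
            if sol.status == "converged":
                break
        if best_sol.status != "converged":
            # feasibility-restoration polish: project the near-optimal point
            # onto the dynamics manifold (tight proximal anchor); the
            # objective moves only marginally while the residual closes
            zb = nlp.join(best_sol.states, best_sol.controls)
            nlp.H = (10 * proj_alpha * sp.eye(nlp.n_z)).tocsr()
            nlp.g = -10 * proj_alpha * zb
            nlp.const = 5 * proj_alpha * float(zb @ zb)
            popts = dict(opts)
            popts["tol_stat"] = 1e-2
            for _ in range(2):
                sol = _solve_sqp(nlp, zb, popts)
                zb = nlp.join(sol.states, sol.controls)
                if sol.max_residual <= opts["tol_feas"]:
                    break
            nlp.H, nlp.g, nlp.const = H_full, g_full, const_full
            if sol.max_residual < best_sol.max_residual:
                X, U = nlp.split(zb)
                J, terms = objective_value(X, U, problem)
                status = ("converged" if sol.max_residual <= opts["tol_feas"]
                          else best_sol.status)
                best_sol = Solution(problem.times, X, U, J, terms, status,
                                    sol.max_residual,
                                    best_sol.iterations + sol.iterations,
                                    message="feasibility-polished",
                                    problem=problem)
        return best_sol
    except Exception as err:  # noqa: BLE001 - contract: no uncaught crash
        nlp.H, nlp.g, nlp.const = H_full, g_full, const_full
        X, U = nlp.split(z)
        J, terms = objective_value(X, U, problem)
        return Solution(problem.times, X, U, J, terms, "failed",
                        float(np.max(np.abs(nlp.constraints(z)))), 0,
                        message=f"{type(err).__name__}: {err}", problem=problem)


# --------------------------------------------------------------------------
# ground reaction force extraction
# --------------------------------------------------------------------------

def extract_grf(solution: Solution, system: Optional[SkiSystem] = None) -> dict:
    """Per-ski ground-reaction-force series from a solved trajectory.

    Returns ``{'sides': {side: (N, 3) force vectors}, 'magnitude': {...},
    'bw': {...}, 'total': (N,)}``; BW normalization uses the model weight.
    """
    sysm = system or solution.problem.system
    st = sysm.unpack(solution.states)
    grf = sysm.grf_per_ski(st.q, st.qdot)
    weight = sysm.model.total_mass * 9.81
    mag = {k: np.linalg.norm(np.real(v), axis=-1) for k, v in grf.items()}
    return {
        "sides": {k: np.real(v) for k, v in grf.items()},
        "magnitude": mag,
        "bw": {k: v / weight for k, v in mag.items()},
        "total": sum(mag.values()),
    }
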
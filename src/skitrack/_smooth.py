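"""Smooth scalar primitives shared by the contact, muscle and solver code.

Every function here is written to be *complex-step safe*: no branching on the
value, no ``abs``/``maximum``/comparisons that would break holomorphy.  The
whole dynamics pipeline is differentiated by complex-step perturbation, so any
non-smooth primitive would silently corrupt the NLP Jacobians.  Smoothness is
also a modelling requirement: the optimizer needs contact and muscle forces
that are C1 in the states.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "smooth_max0",
    "smooth_norm",
    "smooth_sat",
    "logistic",
]


def smooth_max0(x, eps: float = 1e-4):
    """Smooth approximation of max(x, 0): 0.5*(x + sqrt(x^2 + eps^2)).

    Exact to O(eps) away from 0; value eps/2 at x = 0.  Strictly positive and
    strictly increasing, hence never produces adhesion when used as a force
    floor.
    """
    return 0.5 * (x + np.sqrt(x * x + eps * eps))


def smooth_norm(v, eps: float = 1e-8, axis: int = -1):
    """sqrt(|v|^2 + eps^2): differentiable everywhere, ~|v| away from 0."""
    return np.sqrt(np.sum(v * v, axis=axis) + eps * eps)


def smooth_sat(x, eps):
    """Odd saturation x / sqrt(x^2 + eps^2) in (-1, 1); slope 1/eps at 0.

    Used to regularize Coulomb-type direction switching (friction, shear).
    """
    return x / np.sqrt(x * x + eps * eps)


def logistic(x):
    """Numerically safe logistic sigmoid, complex-step safe.

    Implemented via tanh, which is stable for large |Re x| and holomorphic.
    """
    return 0.5 * (1.0 + np.tanh(0.5 * x))
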
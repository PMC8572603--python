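"""Hill-type musculotendon force model.

Muscle force is assembled from dimensionless factors evaluated at the
current fiber state:

* ``f_l`` — active force-length factor, a Gaussian in normalized fiber
  length with width ``gamma`` (Thelen-style curve);
* ``f_v`` — force-velocity factor, hyperbolic on the shortening branch
  (zero at the maximum shortening speed, 1 at zero velocity) and
  saturating at ``f_M`` on the lengthening branch;
* ``f_PE`` — passive elastic factor, zero at or below optimal length
  and exponential above it, reaching 1 at strain ``eps0_M``;
* ``cos(phi)`` — pennation projection, with the pennation angle given
  by the constant-thickness model ``l_m sin(phi) = l_mopt sin(phi0)``.

The viscous damping element is negligible at elbow movement speeds and
is omitted.  Total fiber force is

    F_M = (a * f_l * f_v + f_PE) * F_0 * cos(phi)

with activation ``a`` obtained from normalized EMG through an
exponential ("A-shaped") nonlinearity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import FormulaParams, MuscleParams

__all__ = [
    "MuscleMechState",
    "emg_to_activation",
    "force_length_factor",
    "force_velocity_factor",
    "passive_force_factor",
    "pennation_angle",
    "muscle_force",
    "InfeasibleFiberLengthError",
]


class InfeasibleFiberLengthError(ValueError):
    """Fiber length incompatible with the constant-thickness pennation model."""


@dataclass(frozen=True)
class MuscleMechState:
    """Mechanical state of one muscle at one instant.

    Lengths in metres, angle in radians, factors dimensionless, force
    in Newtons.  ``l_mt`` and ``l_t`` are optional context (not every
    caller knows them); ``F_M`` is the assembled fiber force projected
    on the tendon line of action.
    """

    l_m: float
    v_n: float
    phi: float
    f_l: float
    f_v: float
    f_PE: float
    f_CE: float
    F_M: float
    l_mt: float = float("nan")
    l_t: float = float("nan")


def emg_to_activation(u, A_nl: float):
    """Map normalized EMG ``u`` in [0, 1] to activation in [0, 1].

    a = (exp(A_nl * u) - 1) / (exp(A_nl) - 1).  The map is monotone
    increasing with a(0) = 0 and a(1) = 1; negative ``A_nl`` bows the
    curve below the diagonal, matching the observed EMG-force
    relation.  Accepts scalars or arrays.
    """
    if A_nl == 0:
        raise ValueError(
            "A_nl = 0 is singular; use a small nonzero value for the "
            "near-linear limit"
        )
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u > 1):
        raise ValueError("normalized EMG must lie in [0, 1]")
    a = np.expm1(A_nl * u) / np.expm1(A_nl)
    return a if a.ndim else float(a)


def force_length_factor(l_m, l_mopt: float, gamma: float):
    """Active force-length factor f_l = exp(-((l_m/l_mopt - 1)^2) / gamma)."""
    l_m = np.asarray(l_m, dtype=float)
    if np.any(l_m <= 0) or l_mopt <= 0:
        raise ValueError("fiber lengths must be positive")
    f = np.exp(-((l_m / l_mopt - 1.0) ** 2) / gamma)
    return f if f.ndim else float(f)


def force_velocity_factor(v_n, A_s: float, f_M: float):
    """Force-velocity factor; shortening is v_n < 0.

    Shortening branch (v_n <= 0): f_v = (1 + v_n) / (1 - v_n / A_s),
    reaching 0 at v_n = -1 (the concentric limit); velocities below -1
    are clamped to 0 rather than producing negative force.  Lengthening
    branch (v_n > 0) rises from 1 toward the eccentric plateau f_M.
    """
    v = np.asarray(v_n, dtype=float)
    c = A_s * (f_M - 1.0) / 2.0 + 2.0 * A_s
    # np.where evaluates both branches; silence the off-branch singularities
    with np.errstate(divide="ignore", invalid="ignore"):
        shortening = (1.0 + v) / (1.0 - v / A_s)
        lengthening = (f_M * v + c) / (v + c)
    f = np.where(v <= 0, np.where(v < -1.0, 0.0, shortening), lengthening)
    return f if f.ndim else float(f)


def passive_force_factor(l_m, l_mopt: float, k_PE: float, eps0_M: float):
    """Passive elastic factor; zero at or below optimal fiber length.

    Above optimal length the factor follows the exponential
    f_PE = (exp(k_PE * strain / eps0_M) - 1) / (exp(k_PE) - 1) with
    strain = l_m/l_mopt - 1, reaching 1 at strain eps0_M.
    """
    l_m = np.asarray(l_m, dtype=float)
    if np.any(l_m <= 0) or l_mopt <= 0:
        raise ValueError("fiber lengths must be positive")
    strain = l_m / l_mopt - 1.0
    f = np.where(
        strain > 0,
        np.expm1(k_PE * np.clip(strain, 0.0, None) / eps0_M) / np.expm1(k_PE),
        0.0,
    )
    return f if f.ndim else float(f)


def pennation_angle(l_m, l_mopt: float, phi0: float, name: str = "muscle"):
    """Pennation angle phi = arcsin(l_mopt * sin(phi0) / l_m), radians.

    Constant-thickness model: the fiber sheet keeps the width
    l_mopt * sin(phi0), so pennation decreases as the fiber lengthens.
    """
    l_m = np.asarray(l_m, dtype=float)
    if np.any(l_m <= 0):
        raise ValueError("fiber lengths must be positive")
    arg = l_mopt * math.sin(phi0) / l_m
    if np.any(arg > 1.0):
        raise InfeasibleFiberLengthError(
            f"{name}: fiber length shorter than the fiber-sheet width "
            f"l_mopt*sin(phi0); pennation undefined"
        )
    phi = np.arcsin(arg)
    return phi if phi.ndim else float(phi)


def muscle_force(
    a,
    l_m,
    v_n,
    params: MuscleParams,
    fp: FormulaParams,
) -> tuple[float, MuscleMechState]:
    """Assemble the fiber force for one muscle at one instant.

    Returns ``(F_M, state)`` where ``F_M = (a*f_l*f_v + f_PE) * F_0 *
    cos(phi)`` is nonnegative, and ``state`` records every intermediate
    factor.  Scalar inputs only; the pipeline vectorizes over time by
    calling the factor functions on arrays.
    """
    a = float(a)
    if not 0.0 <= a <= 1.0:
        raise ValueError("activation must lie in [0, 1]")
    l_m = float(l_m)
    v_n = float(v_n)
    f_l = force_length_factor(l_m, params.l_mopt, fp.gamma)
    f_v = force_velocity_factor(v_n, fp.A_s, fp.f_M)
    f_PE = passive_force_factor(l_m, params.l_mopt, fp.k_PE, fp.eps0_M)
    phi = pennation_angle(l_m, params.l_mopt, params.phi0, params.name)
    f_CE = a * f_l * f_v
    F_M = (f_CE + f_PE) * params.F_0 * math.cos(phi)
    state = MuscleMechState(
        l_m=l_m, v_n=v_n, phi=phi, f_l=f_l, f_v=f_v, f_PE=f_PE, f_CE=f_CE, F_M=F_M
    )
    return F_M, state
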
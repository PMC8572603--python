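"""Planar (sagittal) musculotendon path kinematics of the elbow.

The joint centre is the origin of a right-handed frame with x anterior,
y medial and z superior; the forearm points along -z at full extension
(flexion angle 0) and rotates about +y toward +x as the elbow flexes.

Flexor paths are straight lines from a fixed origin on the humerus to
an insertion point that rotates with the forearm; biarticular muscles
carry an extra fixed segment ``l_0`` outside this triangle.  The
moment arm is the perpendicular distance from the joint centre to the
muscle line.  Extensor (triceps) paths wrap the humeral trochlea: their
shared moment arm shrinks linearly with flexion from ``r_0`` and the
path lengthens by the wrapped arc.

Fiber length follows from the path length by subtracting the tendon,
held at a fixed multiple (default 1.02) of its resting length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "JointTrajectory",
    "rotate_insertion",
    "rotation_matrix",
    "flexor_mt_length",
    "fiber_length",
    "flexor_moment_arm",
    "extensor_moment_arm",
    "extensor_mt_length",
    "fiber_velocity",
    "InfeasiblePostureError",
    "DegenerateGeometryError",
]


class InfeasiblePostureError(ValueError):
    """Posture leaves no room for a positive fiber length."""


class DegenerateGeometryError(ValueError):
    """Muscle path degenerates (coincident origin and insertion)."""


@dataclass(frozen=True)
class JointTrajectory:
    """Uniformly sampled elbow flexion angle series.

    ``theta`` in degrees, 0 = full extension, flexion positive;
    ``t`` in seconds with a constant step.
    """

    t: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        theta = np.asarray(self.theta, dtype=float)
        if t.ndim != 1 or t.size != theta.size:
            raise ValueError("t and theta must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("trajectory needs at least two samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time step must be uniform")
        if np.any(theta < 0) or np.any(theta > 150):
            raise ValueError("flexion angle must lie in [0, 150] degrees")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "theta", theta)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return self.t.size


def rotation_matrix(theta_deg: float) -> np.ndarray:
    """Forearm rotation about +y by the flexion angle (degrees)."""
    th = math.radians(theta_deg)
    c, s = math.cos(th), math.sin(th)
    return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])


def rotate_insertion(point_ext, theta_deg: float) -> np.ndarray:
    """Rotate a forearm-fixed point from its full-extension position."""
    p = np.asarray(point_ext, dtype=float)
    return rotation_matrix(theta_deg) @ p


def flexor_mt_length(origin, insertion_rotated, l_0: float = 0.0) -> float:
    """Straight-line musculotendon length: |origin - insertion| + l_0."""
    o = np.asarray(origin, dtype=float)
    p = np.asarray(insertion_rotated, dtype=float)
    d = float(np.linalg.norm(o - p))
    if d == 0.0:
        raise DegenerateGeometryError("origin and insertion coincide")
    return d + float(l_0)


def fiber_length(
    l_mt: float,
    l_topt: float,
    tendon_scale: float = 1.02,
    name: str = "muscle",
    theta_deg: float | None = None,
) -> tuple[float, float]:
    """Split the path into fiber and tendon: l_t fixed, l_m = l_mt - l_t."""
    l_t = tendon_scale * l_topt
    l_m = l_mt - l_t
    if l_m <= 0:
        where = f" at theta={theta_deg:g} deg" if theta_deg is not None else ""
        raise InfeasiblePostureError(
            f"{name}: musculotendon length {l_mt:.4f} m leaves no positive "
            f"fiber length (tendon {l_t:.4f} m){where}"
        )
    return l_m, l_t


def flexor_moment_arm(origin, insertion_rotated) -> float:
    """Perpendicular distance from the joint centre to the muscle line.

    Slope-intercept form of the line through origin (x1, z1) and
    rotated insertion (x3, z3) in the sagittal plane:
    r = |b| / sqrt(k^2 + 1), k = (z3 - z1)/(x3 - x1), b = -k*x1 + z1.
    A vertical line (x3 == x1) has distance |x1| from the origin.
    """
    x1, _, z1 = np.asarray(origin, dtype=float)
    x3, _, z3 = np.asarray(insertion_rotated, dtype=float)
    dx = x3 - x1
    if dx == 0.0:
        return abs(x1)
    k = (z3 - z1) / dx
    b = -k * x1 + z1
    return abs(b) / math.sqrt(k * k + 1.0)


def extensor_moment_arm(theta_deg, r_0: float, k_s: float):
    """Trochlea-wrapped extensor moment arm r = r_0 - k_s * theta/90.

    Shared by all three triceps heads (common olecranon tendon); it
    shrinks slightly and linearly as the elbow flexes.
    """
    if r_0 <= 0:
        raise ValueError("r_0 must be > 0")
    theta = np.asarray(theta_deg, dtype=float)
    r = r_0 - k_s * theta / 90.0
    if np.any(r <= 0):
        raise ValueError("extensor moment arm must stay positive")
    return r if r.ndim else float(r)


def extensor_mt_length(theta_deg, r, base_length: float, literal: bool = False):
    """Extensor path length: base plus the arc wrapped on the trochlea.

    Default is the arc length theta_rad * r; ``literal=True`` keeps the
    degree value unconverted (theta_deg * r / 180), an audit mode for
    the alternative printed reading.
    """
    theta = np.asarray(theta_deg, dtype=float)
    arc = theta * np.asarray(r) / 180.0 if literal else np.radians(theta) * np.asarray(r)
    out = base_length + arc
    return out if np.ndim(out) else float(out)


def fiber_velocity(l_m_series, t_series, l_mopt: float, v_max_factor: float) -> np.ndarray:
    """Normalized fiber velocity from the fiber length series.

    Central differences in the interior, one-sided at the ends;
    normalized by the maximum contraction speed v_max_factor * l_mopt
    so shortening gives v_n < 0.
    """
    l_m = np.asarray(l_m_series, dtype=float)
    t = np.asarray(t_series, dtype=float)
    if l_m.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    if l_m.size != t.size:
        raise ValueError("length and time series must align")
    dldt = np.gradient(l_m, t)
    return dldt / (v_max_factor * l_mopt)
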
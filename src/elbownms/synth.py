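"""Synthetic study inputs: the planned trajectory and activation traces.

The reference task is a 2-second flexion-extension: the elbow flexes
from full extension to 90 degrees in the first second and returns in
the second, following theta(t) = 45 + 45*sin(pi*t - pi/2) degrees.

Activation traces emulate computed-muscle-control exports for that
task: smooth unimodal (Gaussian-bump) profiles per muscle, floored at
0.02 (solvers keep activations slightly above zero), with flexor bumps
peaking during the lift and small triceps bumps centred at peak
flexion.  Genuine solver exports in .sto/.mot or CSV form can replace
the generator through :mod:`elbownms.io` without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import JointTrajectory

__all__ = [
    "ActivationSet",
    "planned_trajectory",
    "synthetic_activations",
    "DEFAULT_PROFILES",
]

# (peak, t_peak s, width s) per muscle for the 2-s reference task
DEFAULT_PROFILES: dict[str, dict[str, float]] = {
    "biceps_long": {"peak": 0.55, "t_peak": 0.75, "width": 0.28},
    "biceps_short": {"peak": 0.35, "t_peak": 0.75, "width": 0.28},
    "brachialis": {"peak": 0.50, "t_peak": 0.80, "width": 0.30},
    "triceps_long": {"peak": 0.15, "t_peak": 1.00, "width": 0.20},
    "triceps_lateral": {"peak": 0.08, "t_peak": 1.00, "width": 0.25},
    "triceps_medial": {"peak": 0.08, "t_peak": 1.00, "width": 0.25},
}


@dataclass(frozen=True)
class ActivationSet:
    """Per-muscle activation series aligned to a trajectory time base."""

    t: np.ndarray
    data: pd.DataFrame  # one column per muscle, values in [floor, 1]

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if len(self.data) != t.size:
            raise ValueError("activation rows must match the time base")
        vals = self.data.to_numpy(dtype=float)
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("activations must lie in [0, 1]")
        object.__setattr__(self, "t", t)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out.insert(0, "time", self.t)
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ActivationSet":
        if "time" not in frame.columns:
            raise ValueError("activation table needs a 'time' column")
        t = frame["time"].to_numpy(dtype=float)
        return cls(t=t, data=frame.drop(columns=["time"]).reset_index(drop=True))


def planned_trajectory(
    duration_s: float = 2.0, dt: float = 0.01, theta_peak: float = 90.0
) -> JointTrajectory:
    """The planned flexion-extension angle profile.

    theta(t) = (theta_peak/2) * (1 + sin(2*pi*t/duration - pi/2)):
    zero at t = 0, theta_peak at mid-movement, zero again at the end.
    At the defaults this is exactly theta = 45 + 45*sin(pi*t - pi/2).
    """
    if duration_s <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    n = int(round(duration_s / dt)) + 1
    t = np.arange(n) * dt
    theta = (theta_peak / 2.0) * (
        1.0 + np.sin(2.0 * np.pi * t / duration_s - np.pi / 2.0)
    )
    theta = np.clip(theta, 0.0, None)  # guard tiny negative roundoff at endpoints
    return JointTrajectory(t=t, theta=theta)


def synthetic_activations(
    trajectory: JointTrajectory,
    profiles: dict[str, dict[str, float]] | None = None,
    floor: float = 0.02,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> ActivationSet:
    """Generate smooth bump-shaped activation traces for each muscle.

    Each trace is floor + (peak - floor) * exp(-(t - t_peak)^2 /
    (2 width^2)), plus optional seeded Gaussian noise, clipped back to
    [floor, 1].  Profiles map muscle name to {peak, t_peak, width}.
    """
    profiles = profiles if profiles is not None else DEFAULT_PROFILES
    if not 0 <= floor < 1:
        raise ValueError("floor must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    t = trajectory.t
    cols = {}
    for name, prof in profiles.items():
        peak, t_peak, width = prof["peak"], prof["t_peak"], prof["width"]
        if not floor <= peak <= 1:
            raise ValueError(f"{name}: peak must lie in [floor, 1]")
        if width <= 0:
            raise ValueError(f"{name}: width must be positive")
        a = floor + (peak - floor) * np.exp(-((t - t_peak) ** 2) / (2 * width**2))
        if noise_sd > 0:
            a = a + rng.normal(0.0, noise_sd, size=t.shape)
        cols[name] = np.clip(a, floor, 1.0)
    return ActivationSet(t=t, data=pd.DataFrame(cols))
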
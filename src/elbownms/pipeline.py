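"""Per-muscle torque assembly and the resultant elbow moment.

For every sample of a joint-angle trajectory, each muscle's path
geometry yields its musculotendon length and moment arm; subtracting
the (fixed-stretch) tendon gives the fiber length series, whose time
derivative gives the normalized fiber velocity; the Hill model then
produces the fiber force, and moment arm times force gives the muscle
torque.  Flexion is the positive torque direction, so extensor torques
enter with a negative sign, and the resultant elbow moment is the
signed sum over muscles.

The same machinery runs the improved six-muscle arm and the classic
two-muscle baseline (whose triceps stays on a straight-line path — the
anatomical shortcut the trochlea-arc model corrects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry, hill
from .params import ArmModel, FormulaParams, ModelOptions, MuscleParams
from .synth import ActivationSet

__all__ = [
    "MuscleSeries",
    "TorqueResult",
    "simulate",
    "simulate_model",
    "simulate_double_muscle",
]


@dataclass(frozen=True)
class MuscleSeries:
    """State histories of one muscle over the trajectory (SI units)."""

    name: str
    l_mt: np.ndarray
    l_m: np.ndarray
    v_n: np.ndarray
    phi: np.ndarray
    f_l: np.ndarray
    f_v: np.ndarray
    f_PE: np.ndarray
    F_M: np.ndarray
    r: np.ndarray
    tau: np.ndarray


@dataclass(frozen=True)
class TorqueResult:
    """Per-muscle histories plus the resultant elbow torque (N·m)."""

    t: np.ndarray
    theta: np.ndarray
    per_muscle: dict[str, MuscleSeries]
    tau_sum: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per (time, muscle)."""
        rows = []
        for m in self.per_muscle.values():
            rows.append(
                pd.DataFrame(
                    {
                        "time": self.t,
                        "muscle": m.name,
                        "l_mt": m.l_mt,
                        "l_m": m.l_m,
                        "v_n": m.v_n,
                        "f_l": m.f_l,
                        "f_v": m.f_v,
                        "f_PE": m.f_PE,
                        "F_M": m.F_M,
                        "r": m.r,
                        "tau": m.tau,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def resultant_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.t, "tau_sum": self.tau_sum})


def _muscle_geometry(
    m: MuscleParams,
    traj: geometry.JointTrajectory,
    fp: FormulaParams,
    opts: ModelOptions,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample (l_mt, l_m, r) for one muscle."""
    n = len(traj)
    if m.path == "line":
        l_mt = np.empty(n)
        r = np.empty(n)
        for i, th in enumerate(traj.theta):
            ins = geometry.rotate_insertion(m.insertion, th)
            l_mt[i] = geometry.flexor_mt_length(m.origin, ins, m.l_0)
            r[i] = geometry.flexor_moment_arm(m.origin, ins)
    else:
        r = np.asarray(geometry.extensor_moment_arm(traj.theta, m.r_0, fp.k_s))
        if opts.extensor_base == "slack":
            base = m.l_mopt + fp.tendon_scale * m.l_topt
        else:  # literal: optimal fiber length alone as the extension baseline
            base = m.l_mopt
        l_mt = np.asarray(
            geometry.extensor_mt_length(traj.theta, r, base, opts.literal_eq15)
        )
    l_m = np.empty(n)
    for i in range(n):
        l_m[i], _ = geometry.fiber_length(
            l_mt[i], m.l_topt, fp.tendon_scale, m.name, float(traj.theta[i])
        )
    return l_mt, l_m, r


def simulate(
    trajectory: geometry.JointTrajectory,
    activations: ActivationSet,
    muscles: list[MuscleParams] | tuple[MuscleParams, ...],
    fp: FormulaParams,
    options: ModelOptions | None = None,
) -> TorqueResult:
    """Run the full geometry -> Hill -> torque pipeline.

    ``activations`` must share the trajectory's time base and provide a
    column for every muscle.  Returns per-muscle state histories and
    the resultant torque series (flexion positive).
    """
    opts = options or ModelOptions()
    if not np.allclose(activations.t, trajectory.t, rtol=0, atol=1e-9):
        raise ValueError("activation and trajectory time bases differ")
    missing = [m.name for m in muscles if m.name not in activations.columns]
    if missing:
        raise ValueError(f"no activation column for muscles: {missing}")

    per: dict[str, MuscleSeries] = {}
    tau_sum = np.zeros(len(trajectory))
    for m in muscles:
        l_mt, l_m, r = _muscle_geometry(m, trajectory, fp, opts)
        v_n = geometry.fiber_velocity(l_m, trajectory.t, m.l_mopt, fp.v_max_factor)
        a = activations[m.name]
        f_l = np.asarray(hill.force_length_factor(l_m, m.l_mopt, fp.gamma))
        f_v = np.asarray(hill.force_velocity_factor(v_n, fp.A_s, fp.f_M))
        f_PE = np.asarray(
            hill.passive_force_factor(l_m, m.l_mopt, fp.k_PE, fp.eps0_M)
        )
        phi = np.asarray(hill.pennation_angle(l_m, m.l_mopt, m.phi0, m.name))
        F_M = (a * f_l * f_v + f_PE) * m.F_0 * np.cos(phi)
        tau = m.sign * r * F_M
        per[m.name] = MuscleSeries(
            name=m.name, l_mt=l_mt, l_m=l_m, v_n=v_n, phi=phi,
            f_l=f_l, f_v=f_v, f_PE=f_PE, F_M=F_M, r=np.broadcast_to(r, F_M.shape).copy(),
            tau=tau,
        )
        tau_sum = tau_sum + tau
    return TorqueResult(
        t=trajectory.t, theta=trajectory.theta, per_muscle=per, tau_sum=tau_sum
    )


def simulate_model(
    trajectory: geometry.JointTrajectory,
    activations: ActivationSet,
    model: ArmModel,
) -> TorqueResult:
    """Convenience wrapper: run ``simulate`` with an :class:`ArmModel`."""
    return simulate(
        trajectory, activations, model.muscles, model.formula, model.options
    )


def simulate_double_muscle(
    trajectory: geometry.JointTrajectory,
    activations: ActivationSet,
    baseline: ArmModel,
) -> TorqueResult:
    """Run the classic two-muscle baseline (lumped biceps + triceps).

    Both muscles, including the triceps, use the straight-line path
    model; the contract is otherwise identical to :func:`simulate`.
    """
    if len(baseline.muscles) != 2:
        raise ValueError("baseline model must have exactly two muscles")
    if any(m.path != "line" for m in baseline.muscles):
        raise ValueError("baseline muscles must both use straight-line paths")
    return simulate_model(trajectory, activations, baseline)
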
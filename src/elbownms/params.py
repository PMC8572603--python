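"""Model parameters: shared curve constants and per-muscle anatomy.

Two parameter families drive the simulator:

* :class:`FormulaParams` — curve-shape constants shared by every muscle
  (force-length width, force-velocity asymptotes, passive-curve shape,
  the EMG-to-activation nonlinearity, and the fixed tendon stretch
  factor).
* :class:`MuscleParams` — per-muscle physiological constants (optimal
  fiber length, resting tendon length, maximum isometric force, rest
  pennation) plus the geometric path description.  A muscle path is
  either a straight line between an origin and an insertion point in
  the elbow-centred sagittal frame (with an optional out-of-triangle
  segment ``l_0`` for biarticular muscles), or a trochlea arc described
  by the moment arm ``r_0`` at full extension.

Parameters are loaded from YAML files; :func:`default_params` returns
the packaged six-muscle arm, :func:`baseline_params` the classic lumped
biceps/triceps two-muscle arm used as the comparison model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

__all__ = [
    "FormulaParams",
    "MuscleParams",
    "ModelOptions",
    "ArmModel",
    "load_params",
    "default_params",
    "baseline_params",
]


class ParameterError(ValueError):
    """Raised when a parameter file violates a model invariant."""


@dataclass(frozen=True)
class FormulaParams:
    """Shared curve constants of the Hill model.

    Attributes
    ----------
    gamma : float
        Width (shape) coefficient of the active force-length curve.
    A_s : float
        Force-velocity curve parameter.
    f_M : float
        Maximum normalized force during fiber elongation (eccentric
        plateau of the force-velocity curve).
    v_max_factor : float
        Maximum contraction speed in optimal fiber lengths per second;
        normalizes fiber velocity.
    k_PE : float
        Passive force curve shape parameter.
    eps0_M : float
        Maximum passive muscle tension strain: the fractional stretch
        beyond optimal length at which the passive factor reaches 1.
    k_s : float
        Extensor moment-arm shape parameter (metres per 90 degrees of
        flexion).
    A_nl : float
        Nonlinearity of the EMG-to-activation map.  Negative values
        give the physiological concave-up ("A-shaped") curve; the
        default -1.0 sits mid-range of the values reported in the
        EMG-driven-modelling literature.
    tendon_scale : float
        Real-time tendon length as a multiple of resting tendon length
        (tendon compliance is collapsed to this fixed stretch).
    """

    gamma: float = 0.5
    A_s: float = 0.25
    f_M: float = 1.8
    v_max_factor: float = 8.0
    k_PE: float = 4.0
    eps0_M: float = 0.5
    k_s: float = 0.004
    A_nl: float = -1.0
    tendon_scale: float = 1.02

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ParameterError("gamma must be > 0")
        if self.A_s <= 0:
            raise ParameterError("A_s must be > 0")
        if self.f_M <= 1:
            raise ParameterError("f_M must be > 1")
        if self.v_max_factor <= 0:
            raise ParameterError("v_max_factor must be > 0")
        if self.k_PE <= 0:
            raise ParameterError("k_PE must be > 0")
        if self.eps0_M <= 0:
            raise ParameterError("eps0_M must be > 0")
        if self.tendon_scale < 1:
            raise ParameterError("tendon_scale must be >= 1")
        if self.A_nl == 0:
            raise ParameterError(
                "A_nl must be nonzero; for a linear EMG-to-activation map "
                "use a small value such as -1e-6"
            )


@dataclass(frozen=True)
class MuscleParams:
    """Physiological and geometric constants of one musculotendon unit.

    Exactly one path parameterization must be populated: ``origin`` /
    ``insertion`` (+ ``l_0``) for a straight-line path, or ``r_0`` for
    a trochlea-arc path.  ``group`` sets the torque sign (flexor
    positive), independently of the path model, so the classic
    two-muscle baseline can run its triceps on a straight line.
    """

    name: str
    group: Literal["flexor", "extensor"]
    l_mopt: float  # optimal fiber length, m
    l_topt: float  # resting tendon length, m
    F_0: float  # maximum isometric force, N
    phi0_deg: float = 0.0  # rest pennation angle, degrees
    origin: tuple[float, float, float] | None = None
    insertion: tuple[float, float, float] | None = None
    l_0: float = 0.0  # path length outside the triangular relation, m
    r_0: float | None = None  # moment arm at full extension, m (arc path)

    def __post_init__(self) -> None:
        if self.l_mopt <= 0 or self.l_topt < 0 or self.F_0 <= 0:
            raise ParameterError(
                f"{self.name}: l_mopt, F_0 must be > 0 and l_topt >= 0"
            )
        if self.l_0 < 0:
            raise ParameterError(f"{self.name}: l_0 must be >= 0")
        if self.group not in ("flexor", "extensor"):
            raise ParameterError(f"{self.name}: group must be flexor|extensor")
        has_line = self.origin is not None and self.insertion is not None
        has_arc = self.r_0 is not None
        if has_line == has_arc:
            raise ParameterError(
                f"{self.name}: exactly one of origin+insertion (line path) "
                f"or r_0 (arc path) must be given"
            )
        if has_arc and self.r_0 <= 0:
            raise ParameterError(f"{self.name}: r_0 must be > 0")
        if has_line:
            object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
            object.__setattr__(
                self, "insertion", tuple(float(v) for v in self.insertion)
            )

    @property
    def path(self) -> Literal["line", "arc"]:
        return "arc" if self.r_0 is not None else "line"

    @property
    def phi0(self) -> float:
        """Rest pennation angle in radians."""
        return math.radians(self.phi0_deg)

    @property
    def sign(self) -> int:
        """Torque sign: +1 for flexors, -1 for extensors."""
        return 1 if self.group == "flexor" else -1

    def scaled(self, length_scale: float) -> "MuscleParams":
        """Uniformly scale all lengths (subject scaling by height).

        Scales l_mopt, l_topt, l_0, r_0 and path coordinates; F_0 is a
        strength parameter and is left unchanged (it must be measured,
        not scaled geometrically).
        """
        if length_scale <= 0:
            raise ParameterError("length_scale must be > 0")
        s = float(length_scale)
        return replace(
            self,
            l_mopt=self.l_mopt * s,
            l_topt=self.l_topt * s,
            l_0=self.l_0 * s,
            r_0=None if self.r_0 is None else self.r_0 * s,
            origin=None if self.origin is None else tuple(s * v for v in self.origin),
            insertion=None
            if self.insertion is None
            else tuple(s * v for v in self.insertion),
        )


@dataclass(frozen=True)
class ModelOptions:
    """Switches for deliberately ambiguous geometry readings.

    extensor_base
        Musculotendon length of an arc-path muscle at full extension.
        ``"slack"`` (default): optimal fiber length plus the stretched
        tendon, so the fiber sits exactly at its optimal length at 0
        degrees and is stretched beyond it during flexion.  ``"literal"``
        uses the optimal fiber length alone as the baseline; with
        realistic tendon lengths this can leave no room for a positive
        fiber length and is kept only for auditing the alternative
        reading.
    literal_eq15
        If True, the extensor arc term is theta * r / 180 (degrees
        carried through unconverted); default False uses the
        dimensionally consistent arc length theta_rad * r.
    """

    extensor_base: Literal["slack", "literal"] = "slack"
    literal_eq15: bool = False


@dataclass(frozen=True)
class ArmModel:
    """A complete parameter set: formula constants + muscle list."""

    formula: FormulaParams
    muscles: tuple[MuscleParams, ...]
    options: ModelOptions = field(default_factory=ModelOptions)
    profiles: dict | None = None  # synthetic activation profiles, optional

    def muscle(self, name: str) -> MuscleParams:
        for m in self.muscles:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.muscles]

    def scaled(self, length_scale: float) -> "ArmModel":
        return replace(
            self, muscles=tuple(m.scaled(length_scale) for m in self.muscles)
        )


def _muscle_from_dict(d: dict) -> MuscleParams:
    known = {
        "name",
        "group",
        "l_mopt",
        "l_topt",
        "F_0",
        "phi0_deg",
        "origin",
        "insertion",
        "l_0",
        "r_0",
    }
    extra = set(d) - known
    if extra:
        raise ParameterError(f"unknown muscle fields: {sorted(extra)}")
    return MuscleParams(**d)


def load_params(path: str | Path) -> ArmModel:
    """Load an :class:`ArmModel` from a YAML parameter file.

    The file has a ``formula:`` block (any subset of the
    :class:`FormulaParams` fields; omitted fields take their defaults),
    a ``muscles:`` list, and optional ``options:`` and ``profiles:``
    blocks.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return params_from_dict(raw)


def params_from_dict(raw: dict) -> ArmModel:
    if not isinstance(raw, dict) or "muscles" not in raw:
        raise ParameterError("parameter file must contain a 'muscles' list")
    formula = FormulaParams(**(raw.get("formula") or {}))
    muscles = tuple(_muscle_from_dict(m) for m in raw["muscles"])
    if len({m.name for m in muscles}) != len(muscles):
        raise ParameterError("duplicate muscle names")
    options = ModelOptions(**(raw.get("options") or {}))
    return ArmModel(
        formula=formula,
        muscles=muscles,
        options=options,
        profiles=raw.get("profiles"),
    )


def _packaged(name: str) -> ArmModel:
    ref = resources.files("elbownms.data").joinpath(name)
    with resources.as_file(ref) as p:
        return load_params(p)


def default_params() -> ArmModel:
    """The packaged six-muscle arm (``arm_default``).

    Encodes the published optimal fiber lengths, tendon lengths,
    maximum isometric forces, pennation angles and flexor path points
    for the long/short biceps heads, brachialis and the three triceps
    heads.  The triceps moment arm at full extension is a fixture
    choice (0.022 m, in the range reported for the elbow extensors),
    marked as such in the file.
    """
    return _packaged("arm_default.yaml")


def baseline_params() -> ArmModel:
    """The classic two-muscle (lumped biceps/triceps) baseline arm.

    Both muscles run on straight-line paths, including the triceps —
    the known anatomical deviation of the classic model, which the
    trochlea-arc path of the six-muscle model corrects.  Lumping is a
    fixture choice: biceps heads merged onto the long-head path with
    summed maximal forces, triceps heads merged onto a straight
    posterior line with summed maximal forces.
    """
    return _packaged("arm_baseline.yaml")
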
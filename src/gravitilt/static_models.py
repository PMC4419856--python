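"""Closed-form static models of perceived tilt in altered gravity.

All models map a static orientation (tilt axis, signed angle in degrees,
gravito-inertial level ``G`` in Earth-G units) to a perceived tilt angle in
degrees:

* ``utricular_shear``  -- perceived tilt proportional to the utricular shear
  force, ``K * G * sin(theta)`` (traditional form, ``K = 60 deg/G``).
* ``tangent_model``    -- ``atan(G * tan(theta))``; accounts empirically for
  the compression component of otolith stimulation.
* ``mittelstaedt``     -- vector sum of a (nonlinearly transduced)
  graviceptor estimate and an idiotropic vector along the body z axis.
* ``modified_shear_roll``  -- shear model with the hyper-gravity term scaled
  by an extra free parameter ``M`` and a per-subject intercept ``rho``:
  ``rho + K * sin(theta) * [1 + M * (G - 1)]``.
* ``modified_shear_pitch`` -- the same modification expressed about the
  pitched-up utricular plane,
  ``K * sin(delta + theta_u) * [1 + M * (G - 1)] - theta_u``.

Angles are degrees at the API surface and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConditionError, UnknownModelError
from .frames import utricle_normal

__all__ = [
    "TiltCondition",
    "StaticModelParams",
    "MittelstaedtParams",
    "utricular_shear",
    "tangent_model",
    "mittelstaedt",
    "modified_shear_roll",
    "modified_shear_pitch",
    "evaluate_model",
    "MODEL_REGISTRY",
    "TRADITIONAL_SHEAR_K",
]

#: Fixed proportionality constant of the traditional utricular shear model.
TRADITIONAL_SHEAR_K = 60.0


@dataclass(frozen=True)
class TiltCondition:
    """One static orientation.

    Attributes
    ----------
    axis : {"roll", "pitch"}
    angle_deg : float
        Signed tilt, degrees. Positive roll = tilt to the left; negative
        pitch = nose down.
    g_level : float
        Magnitude of the net gravito-inertial force in Earth G; must be > 0.
    """

    axis: str
    angle_deg: float
    g_level: float = 1.0

    def __post_init__(self):
        if self.axis not in ("roll", "pitch"):
            raise InvalidConditionError(f"axis must be roll or pitch, got {self.axis!r}")
        if not np.isfinite(self.g_level) or self.g_level <= 0.0:
            raise InvalidConditionError(
                f"g_level must be positive (0 G is a singularity), got {self.g_level}"
            )
        if abs(self.angle_deg) > 90.0:
            raise InvalidConditionError(
                f"|angle_deg| must be <= 90 for static models, got {self.angle_deg}"
            )


@dataclass(frozen=True)
class StaticModelParams:
    """Coefficients of the modified utricular shear model.

    Defaults are the hierarchical-regression estimates for static roll tilt
    (K = 64.6 deg/G, M = 0.26, rho = -0.29 deg); ``theta_utricle_deg`` is the
    nose-up pitch of the utricular plane used by the pitch form.
    """

    K: float = 64.6
    M: float = 0.26
    rho: float = -0.29
    theta_utricle_deg: float = 30.0

    def __post_init__(self):
        if self.K <= 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        if not 0.0 <= self.theta_utricle_deg <= 45.0:
            raise ValueError(
                f"theta_utricle_deg must lie in [0, 45], got {self.theta_utricle_deg}"
            )


@dataclass(frozen=True)
class MittelstaedtParams:
    """Parameters of the idiotropic-vector model.

    The exact transduction and morphology constants of the published model
    are defined in an external appendix; these defaults are provisional and
    chosen so that 1 G roll predictions are near-veridical at small angles.
    """

    idiotropic_magnitude: float = 0.1
    theta_utricle_deg: float = 30.0
    transduction_exponent: float = 1.0

    def __post_init__(self):
        if self.idiotropic_magnitude < 0:
            raise ValueError("idiotropic_magnitude must be >= 0")
        if self.transduction_exponent <= 0:
            raise ValueError("transduction_exponent must be > 0")


def _check_g(cond: TiltCondition):
    if cond.g_level <= 0:  # defensive; TiltCondition already validates
        raise InvalidConditionError(f"g_level must be > 0, got {cond.g_level}")


def utricular_shear(cond: TiltCondition, K: float = TRADITIONAL_SHEAR_K) -> float:
    """Traditional utricular shear model for roll, ``K * G * sin(theta)``."""
    _check_g(cond)
    if cond.axis != "roll":
        raise InvalidConditionError("utricular_shear takes the roll form only")
    return K * cond.g_level * np.sin(np.radians(cond.angle_deg))


def tangent_model(cond: TiltCondition) -> float:
    """Tangent model, ``atan(G * tan(theta))``; +/-90 deg are fixed points."""
    _check_g(cond)
    if abs(cond.angle_deg) == 90.0:
        return np.copysign(90.0, cond.angle_deg)  # analytic limit
    t = np.tan(np.radians(cond.angle_deg))
    return np.degrees(np.arctan(cond.g_level * t))


def mittelstaedt(cond: TiltCondition, params: MittelstaedtParams = MittelstaedtParams()) -> float:
    """Idiotropic-vector model.

    The GIF is expressed in the utricule-aligned frame, each component is
    passed through an odd power-law transduction, the vector is rotated back
    to head coordinates and summed with an idiotropic vector of magnitude
    ``m`` along the body longitudinal (+z) axis; the perceived tilt is the
    angle of the sum in the tilt plane.
    """
    _check_g(cond)
    from .frames import gif_direction

    f = cond.g_level * gif_direction(cond.axis, cond.angle_deg)
    t = np.radians(params.theta_utricle_deg)
    # head -> utricule frame: pitch nose-down by theta_u aligns the plane
    c, s = np.cos(t), np.sin(t)
    R = np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])
    fu = R @ f
    e = params.transduction_exponent
    fu = np.sign(fu) * np.abs(fu) ** e
    v = R.T @ fu
    v = v + np.array([0.0, 0.0, params.idiotropic_magnitude])
    if cond.axis == "roll":
        return float(np.degrees(np.arctan2(v[1], v[2])))
    return float(np.degrees(np.arctan2(-v[0], v[2])))


def modified_shear_roll(cond: TiltCondition, params: StaticModelParams = StaticModelParams()) -> float:
    """Modified utricular shear model for roll.

    ``rho + K * sin(theta) * [1 + M * (G - 1)]``; at 1 G the result is
    independent of ``M`` and reduces to the traditional model plus ``rho``.
    """
    _check_g(cond)
    if cond.axis != "roll":
        raise InvalidConditionError("modified_shear_roll requires a roll condition")
    s = np.sin(np.radians(cond.angle_deg))
    return params.rho + params.K * s * (1.0 + params.M * (cond.g_level - 1.0))


def modified_shear_pitch(
    cond: TiltCondition,
    params: StaticModelParams = StaticModelParams(),
    intercept: float = 0.0,
) -> float:
    """Modified utricular shear model for pitch.

    ``K * sin(delta + theta_u) * [1 + M * (G - 1)] - theta_u``; ``K`` and
    ``M`` are taken from the roll fit and applied directly. The printed form
    carries no intercept; an optional one is accepted and defaults to 0.
    At ``delta = -theta_u`` the utricular plane is normal to the GIF and the
    prediction equals the actual angle at every gravity level.
    """
    _check_g(cond)
    if cond.axis != "pitch":
        raise InvalidConditionError("modified_shear_pitch requires a pitch condition")
    tu = params.theta_utricle_deg
    s = np.sin(np.radians(cond.angle_deg + tu))
    return intercept + params.K * s * (1.0 + params.M * (cond.g_level - 1.0)) - tu


def _dispatch_modified_shear(cond, params):
    if cond.axis == "roll":
        return modified_shear_roll(cond, params)
    return modified_shear_pitch(cond, params)


#: Registry of named static models: name -> (callable(cond, params), params type).
MODEL_REGISTRY = {
    "shear": (lambda cond, params=None: utricular_shear(
        cond, TRADITIONAL_SHEAR_K if params is None else params.K), StaticModelParams),
    "tangent": (lambda cond, params=None: tangent_model(cond), type(None)),
    "mittelstaedt": (lambda cond, params=None: mittelstaedt(
        cond, params or MittelstaedtParams()), MittelstaedtParams),
    "modshear": (lambda cond, params=None: _dispatch_modified_shear(
        cond, params or StaticModelParams()), StaticModelParams),
}


def evaluate_model(name: str, cond: TiltCondition, params=None) -> float:
    """Evaluate a registered static model by name."""
    try:
        fn, _ = MODEL_REGISTRY[name]
    except KeyError:
        raise UnknownModelError(name, MODEL_REGISTRY) from None
    return float(fn(cond, params))
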
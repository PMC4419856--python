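"""Unit and property tests for the closed-form static models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gravitilt import (
    InvalidConditionError,
    MittelstaedtParams,
    MODEL_REGISTRY,
    StaticModelParams,
    TiltCondition,
    UnknownModelError,
    evaluate_model,
    mittelstaedt,
    modified_shear_pitch,
    modified_shear_roll,
    tangent_model,
    utricular_shear,
)

angles = st.floats(-90.0, 90.0, allow_nan=False)
pos_angles = st.floats(0.5, 90.0, allow_nan=False)
g_levels = st.floats(0.05, 3.0, allow_nan=False)


# ---------------------------------------------------------------- conditions

def test_condition_validation():
    with pytest.raises(InvalidConditionError):
        TiltCondition("yaw", 10.0, 1.0)
    with pytest.raises(InvalidConditionError):
        TiltCondition("roll", 10.0, 0.0)
    with pytest.raises(InvalidConditionError):
        TiltCondition("roll", 10.0, -1.0)
    with pytest.raises(InvalidConditionError):
        TiltCondition("roll", 95.0, 1.0)


def test_param_validation():
    with pytest.raises(ValueError):
        StaticModelParams(K=-1.0)
    with pytest.raises(ValueError):
        StaticModelParams(theta_utricle_deg=60.0)
    with pytest.raises(ValueError):
        MittelstaedtParams(idiotropic_magnitude=-0.1)
    with pytest.raises(ValueError):
        MittelstaedtParams(transduction_exponent=0.0)


# ------------------------------------------------------------ shear (Eq.-1)

def test_shear_examples():
    assert utricular_shear(TiltCondition("roll", 30, 2.0), K=60.0) == pytest.approx(60.0)
    assert utricular_shear(TiltCondition("roll", 0, 1.5), K=60.0) == 0.0
    assert utricular_shear(TiltCondition("roll", 20, 1.5), K=60.0) == pytest.approx(
        30.78, abs=0.005)


def test_shear_rejects_pitch():
    with pytest.raises(InvalidConditionError):
        utricular_shear(TiltCondition("pitch", 10, 1.0))


# ----------------------------------------------------------- tangent (Eq.-2)

def test_tangent_examples():
    assert tangent_model(TiltCondition("roll", 45, 1.0)) == pytest.approx(45.0)
    assert tangent_model(TiltCondition("roll", 90, 2.0)) == 90.0
    assert tangent_model(TiltCondition("roll", -90, 0.5)) == -90.0
    assert tangent_model(TiltCondition("roll", 45, 2.0)) == pytest.approx(
        np.degrees(np.arctan(2.0)))


@given(theta=angles)
@settings(max_examples=50, deadline=None)
def test_tangent_identity_at_1g(theta):
    assert tangent_model(TiltCondition("roll", theta, 1.0)) == pytest.approx(
        theta, abs=1e-9)


@given(g=g_levels)
@settings(max_examples=25, deadline=None)
def test_tangent_fixed_points(g):
    for theta in (0.0, 90.0, -90.0):
        assert tangent_model(TiltCondition("roll", theta, g)) == theta


# ------------------------------------------------------ modified shear roll

def test_modshear_roll_examples():
    p0 = StaticModelParams(rho=0.0)
    # exact value 64.6*sin(20 deg) = 22.0945; quoted rounded as 22.10
    assert modified_shear_roll(TiltCondition("roll", 20, 1.0), p0) == pytest.approx(
        22.10, abs=0.01)
    p = StaticModelParams()  # rho = -0.29
    assert modified_shear_roll(TiltCondition("roll", 20, 2.0), p) == pytest.approx(
        27.55, abs=0.005)


@given(theta=angles, g=g_levels, m=st.floats(0.0, 1.0))
@settings(max_examples=50, deadline=None)
def test_modshear_roll_odd_with_zero_intercept(theta, g, m):
    p = StaticModelParams(M=m, rho=0.0)
    plus = modified_shear_roll(TiltCondition("roll", theta, g), p)
    minus = modified_shear_roll(TiltCondition("roll", -theta, g), p)
    assert minus == pytest.approx(-plus, abs=1e-9)


@given(theta=angles, m=st.floats(0.0, 1.0))
@settings(max_examples=50, deadline=None)
def test_modshear_equals_shear_plus_rho_at_1g(theta, m):
    p = StaticModelParams(M=m, rho=-0.29)
    lhs = modified_shear_roll(TiltCondition("roll", theta, 1.0), p)
    rhs = p.rho + utricular_shear(TiltCondition("roll", theta, 1.0), K=p.K)
    assert lhs == pytest.approx(rhs, abs=1e-12)


@given(theta=pos_angles, g=g_levels)
@settings(max_examples=50, deadline=None)
def test_modshear_increment_ratio_equals_m(theta, g):
    if abs(g - 1.0) < 1e-3:
        return
    p = StaticModelParams()
    inc = (modified_shear_roll(TiltCondition("roll", theta, g), p)
           - modified_shear_roll(TiltCondition("roll", theta, 1.0), p))
    ratio = inc / (p.K * np.sin(np.radians(theta)) * (g - 1.0))
    assert ratio == pytest.approx(p.M, abs=1e-9)


def test_modshear_monotone_in_g():
    p = StaticModelParams(rho=0.0)
    for theta in (5.0, 20.0, 45.0, 80.0):
        vals = [modified_shear_roll(TiltCondition("roll", theta, g), p)
                for g in np.linspace(0.05, 2.0, 12)]
        assert np.all(np.diff(vals) > 0)


def test_modshear_roll_rejects_pitch():
    with pytest.raises(InvalidConditionError):
        modified_shear_roll(TiltCondition("pitch", 10, 1.0))


# ----------------------------------------------------- modified shear pitch

def test_modshear_pitch_examples():
    p = StaticModelParams()
    assert modified_shear_pitch(TiltCondition("pitch", 0, 1.0), p) == pytest.approx(
        2.30, abs=0.005)
    assert modified_shear_pitch(TiltCondition("pitch", 0, 2.0), p) == pytest.approx(
        10.70, abs=0.005)


@given(g=g_levels)
@settings(max_examples=25, deadline=None)
def test_modshear_pitch_null_at_minus_theta_u(g):
    p = StaticModelParams()
    out = modified_shear_pitch(TiltCondition("pitch", -p.theta_utricle_deg, g), p)
    assert out == -p.theta_utricle_deg  # exact: sin(0) == 0.0


def test_modshear_pitch_rejects_roll():
    with pytest.raises(InvalidConditionError):
        modified_shear_pitch(TiltCondition("roll", 10, 1.0))


def test_modshear_pitch_optional_intercept():
    p = StaticModelParams()
    base = modified_shear_pitch(TiltCondition("pitch", 10, 1.5), p)
    assert modified_shear_pitch(TiltCondition("pitch", 10, 1.5), p,
                                intercept=2.0) == pytest.approx(base + 2.0)


# -------------------------------------------------------------- mittelstaedt

def test_mittelstaedt_examples():
    assert mittelstaedt(TiltCondition("roll", 0, 1.7)) == pytest.approx(0.0)
    p = MittelstaedtParams(idiotropic_magnitude=0.0, theta_utricle_deg=0.0,
                           transduction_exponent=1.0)
    assert mittelstaedt(TiltCondition("roll", 60, 1.0), p) == pytest.approx(60.0)
    p = MittelstaedtParams(idiotropic_magnitude=0.5, theta_utricle_deg=0.0,
                           transduction_exponent=1.0)
    out = mittelstaedt(TiltCondition("roll", 60, 1.0), p)
    assert 0.0 < out < 60.0  # A-effect: biased toward the body axis


@given(theta=angles, g=g_levels)
@settings(max_examples=50, deadline=None)
def test_mittelstaedt_roll_odd(theta, g):
    plus = mittelstaedt(TiltCondition("roll", theta, g))
    minus = mittelstaedt(TiltCondition("roll", -theta, g))
    assert minus == pytest.approx(-plus, abs=1e-9)


# ------------------------------------------------------------------ registry

def test_registry_names_and_dispatch():
    assert set(MODEL_REGISTRY) == {"shear", "tangent", "mittelstaedt", "modshear"}
    cond = TiltCondition("roll", 20, 2.0)
    assert evaluate_model("modshear", cond) == pytest.approx(27.55, abs=0.005)
    assert evaluate_model("tangent", TiltCondition("roll", 45, 1.0)) == pytest.approx(45.0)


def test_unknown_model_lists_registered():
    with pytest.raises(UnknownModelError) as exc:
        evaluate_model("nope", TiltCondition("roll", 10, 1.0))
    for name in MODEL_REGISTRY:
        assert name in str(exc.value)
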
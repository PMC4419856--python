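"""Canal-otolith observer model of orientation perception with utricular
plane weighting.

The central nervous system is modeled as a state estimator: internal models
of the semicircular-canal and otolith dynamics predict the afferent signals
expected from the current central estimates, and weighted feedback of the
prediction errors corrects those estimates.  The central states are the
head-frame gravity-direction estimate ``g_hat`` (unit magnitude, re-normalized
every step), the angular-velocity estimate ``omega_hat`` and the
linear-acceleration estimate ``a_hat``; the internal physical law is
``a_hat = f_hat - g_hat`` with ``|g_hat| = 1``, so in altered gravity the
excess gravito-inertial magnitude is attributed to an illusory linear
acceleration.

Sensor pathways
---------------
* Canals transduce angular velocity through a first-order high-pass filter
  with time constant ``tau_canal``; an internal copy filters ``omega_hat``.
  Their difference (gain ``k_w``) feeds the angular-velocity estimate, and a
  coupled copy (gain ``k_wf``) rotates the gravity estimate.
* Otoliths transduce the specific force ``f`` directly.  The expected otolith
  signal is ``f_hat = g_hat + a_hat`` where the linear-acceleration estimate
  follows the otolith error proportionally, ``a_hat = k_f * W (f - f_hat)``.
* ``W`` is the utricular weighting: otolith feedback errors are resolved in
  the utricule-aligned frame (head frame pitched nose-up by
  ``theta_utricle_deg``) and the component normal to the utricular plane is
  scaled by ``utricular_weight``.  With weight 1 the observer is the
  unmodified one and static tilt perception is veridical at every gravity
  level; the calibrated anisotropy produces overestimation of roll tilt in
  hyper-gravity and underestimation in hypo-gravity.
* The rotational otolith error, the axis-angle misalignment between the
  weighted expected and actual otolith signals, rotates the gravity estimate
  toward consistency (gain ``k_fw``).

Static tilt perception is extracted by quasi-static relaxation: the observer
is integrated under constant sensory input until the perceived tilt angle
settles, and the signed angle of ``g_hat`` in the tilt plane is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    CalibrationError,
    ConvergenceError,
    InvalidConditionError,
    SingularityError,
)
from .frames import (
    gif_direction,
    perceived_pitch_deg,
    perceived_roll_deg,
    utricle_weight_matrix,
)
from .static_models import TiltCondition

__all__ = [
    "ObserverParams",
    "ObserverState",
    "PerceptualState",
    "MotionProfile",
    "Observer",
    "simulate",
    "static_tilt_perception",
    "calibrate_utricular_weight",
    "sweep",
]

_DEG = np.pi / 180.0


@dataclass(frozen=True)
class ObserverParams:
    """Observer configuration.

    Gains and the canal time constant are configuration, not code constants;
    the packaged file ``params/observer_default.yaml`` carries the default
    set (canal time constant and feedback gains from the observer-model
    lineage, utricular weight calibrated on the 20 deg roll / 2 G case).
    """

    tau_canal: float = 5.7          # s, canal high-pass time constant
    k_w: float = 8.0                # angular-velocity error gain
    k_f: float = 4.0                # linear-acceleration (otolith) error gain
    k_fw: float = 8.0               # rotational otolith error gain, 1/s
    k_wf: float = 1.0               # canal-to-gravity coupling gain
    utricular_weight: float = 1.9786  # scale on out-of-plane otolith error
    theta_utricle_deg: float = 30.0
    dt: float = 0.05                # s, integration step
    settle_time: float = 60.0       # s, window over which the rate must stay low
    settle_tol: float = 1e-3        # deg/s, perceived-angle rate threshold
    max_horizon: float = 1800.0     # s, relaxation time limit

    def __post_init__(self):
        if self.tau_canal <= 0 or self.dt <= 0:
            raise ValueError("tau_canal and dt must be positive")
        if self.utricular_weight < 0:
            raise ValueError("utricular_weight must be >= 0")
        for g in (self.k_w, self.k_f, self.k_fw, self.k_wf):
            if not np.isfinite(g):
                raise ValueError("feedback gains must be finite")

    @classmethod
    def from_file(cls, path=None) -> "ObserverParams":
        """Load parameters from a YAML file (packaged defaults if None)."""
        from .io import load_observer_params

        return load_observer_params(path)


@dataclass
class ObserverState:
    """Internal estimator state: gravity estimate plus canal filter states."""

    g_hat: np.ndarray                 # (3,) unit vector
    canal_state: np.ndarray           # (3,) filter state of the actual pathway, rad/s
    canal_state_internal: np.ndarray  # (3,) filter state of the internal copy, rad/s

    def copy(self) -> "ObserverState":
        return ObserverState(self.g_hat.copy(), self.canal_state.copy(),
                             self.canal_state_internal.copy())


@dataclass(frozen=True)
class PerceptualState:
    """Derived perceptual outputs at one instant."""

    g_hat: np.ndarray            # head-frame gravity direction estimate, unit
    omega_hat: np.ndarray        # perceived angular velocity, deg/s
    a_hat: np.ndarray            # perceived linear acceleration, Earth G
    perceived_roll_deg: float
    perceived_pitch_deg: float


@dataclass(frozen=True)
class MotionProfile:
    """Uniformly sampled head-frame motion: angular velocity and specific force.

    ``omega`` is in deg/s, ``f`` in Earth G; both are (n, 3) with n >= 2.
    """

    dt: float
    omega: np.ndarray
    f: np.ndarray

    def __post_init__(self):
        om = np.atleast_2d(np.asarray(self.omega, dtype=float))
        f = np.atleast_2d(np.asarray(self.f, dtype=float))
        object.__setattr__(self, "omega", om)
        object.__setattr__(self, "f", f)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if om.shape != f.shape or om.ndim != 2 or om.shape[1] != 3:
            raise ValueError("omega and f must both be (n, 3) arrays")
        if om.shape[0] < 2:
            raise ValueError("a motion profile needs at least 2 samples")
        mags = np.linalg.norm(f, axis=1)
        if np.any(mags <= 0):
            i = int(np.argmin(mags))
            raise SingularityError(
                f"|f| = 0 at sample {i}: 0 G cannot be simulated (gravity "
                "direction normalization is singular)"
            )

    @property
    def n(self) -> int:
        return self.omega.shape[0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n) * self.dt

    @classmethod
    def constant(cls, omega_dps, f_g, dt: float, duration: float) -> "MotionProfile":
        """Constant-input profile of the given duration."""
        n = max(2, int(round(duration / dt)) + 1)
        return cls(dt,
                   np.tile(np.asarray(omega_dps, dtype=float), (n, 1)),
                   np.tile(np.asarray(f_g, dtype=float), (n, 1)))

    @classmethod
    def static_tilt(cls, cond: TiltCondition, dt: float, duration: float) -> "MotionProfile":
        """Zero rotation, constant GIF for a static tilt condition."""
        f = cond.g_level * gif_direction(cond.axis, cond.angle_deg)
        return cls.constant(np.zeros(3), f, dt, duration)


class _Core:
    """Precomputed matrices and batched observer dynamics.

    States are (n, 3) arrays so that many conditions relax in one pass.
    Internally everything is in radians and rad/s.
    """

    def __init__(self, params: ObserverParams):
        self.p = params
        W = utricle_weight_matrix(params.utricular_weight, params.theta_utricle_deg)
        self.W = W
        # f_hat solves f_hat = g + k_f W (f - f_hat)  =>  (I + k_f W) f_hat = g + k_f W f
        A = np.linalg.inv(np.eye(3) + params.k_f * W)
        self.A = A                  # maps g
        self.C = A @ (params.k_f * W)  # maps f

    def f_hat(self, g: np.ndarray, f: np.ndarray) -> np.ndarray:
        return g @ self.A.T + f @ self.C.T

    def omega_hat(self, alpha, xh, e_r):
        p = self.p
        return alpha + (p.k_w * xh + p.k_fw * e_r) / (1.0 + p.k_w)

    def derivs(self, xc, xh, g, om, f):
        """Time derivatives of the states; also returns omega_hat (rad/s)."""
        p = self.p
        alpha = om - xc
        fh = self.f_hat(g, f)
        fw = f @ self.W.T
        fhw = fh @ self.W.T
        # axis-angle misalignment of the weighted otolith signals; the sign
        # is such that dg/dt = -omega_hat x g rotates g_hat toward making
        # the expected otolith signal parallel to the actual one
        cross = np.cross(fw, fhw)
        denom = (np.linalg.norm(fhw, axis=-1) * np.linalg.norm(fw, axis=-1))
        e_r = cross / denom[..., None]
        w_hat = self.omega_hat(alpha, xh, e_r)
        e_w = alpha - (w_hat - xh)  # alpha - alpha_hat
        dg = -np.cross(w_hat + p.k_wf * e_w, g)
        dxc = (om - xc) / p.tau_canal
        dxh = (w_hat - xh) / p.tau_canal
        return dxc, dxh, dg, w_hat

    def rk4(self, xc, xh, g, om, f):
        """One fixed-step RK4 update; re-normalizes g afterwards."""
        dt = self.p.dt
        k1 = self.derivs(xc, xh, g, om, f)
        k2 = self.derivs(xc + 0.5 * dt * k1[0], xh + 0.5 * dt * k1[1],
                         g + 0.5 * dt * k1[2], om, f)
        k3 = self.derivs(xc + 0.5 * dt * k2[0], xh + 0.5 * dt * k2[1],
                         g + 0.5 * dt * k2[2], om, f)
        k4 = self.derivs(xc + dt * k3[0], xh + dt * k3[1], g + dt * k3[2], om, f)
        xc = xc + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        xh = xh + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        g = g + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        g = g / np.linalg.norm(g, axis=-1, keepdims=True)
        return xc, xh, g

    def perceive(self, xc, xh, g, om, f) -> tuple:
        """omega_hat (rad/s), f_hat, a_hat for output."""
        *_, w_hat = self.derivs(xc, xh, g, om, f)
        fh = self.f_hat(g, f)
        return w_hat, fh, fh - g


class Observer:
    """Stateful single-trajectory interface around the batched core."""

    def __init__(self, params: ObserverParams = None, init_g=None):
        self.params = params or ObserverParams()
        self._core = _Core(self.params)
        g = np.array([0.0, 0.0, 1.0]) if init_g is None else np.asarray(init_g, float)
        n = np.linalg.norm(g)
        if n == 0:
            raise SingularityError("initial gravity estimate has zero magnitude")
        self.state = ObserverState(g / n, np.zeros(3), np.zeros(3))

    @classmethod
    def from_specific_force(cls, f_g, params: ObserverParams = None) -> "Observer":
        """'auto' initialization: g_hat along the initial specific force."""
        f = np.asarray(f_g, dtype=float)
        if np.linalg.norm(f) == 0:
            raise SingularityError("cannot initialize at 0 G")
        return cls(params, init_g=f)

    def step(self, omega_dps, f_g) -> PerceptualState:
        """Advance one integration step and return the perceptual state."""
        f = np.asarray(f_g, dtype=float)
        if np.linalg.norm(f) == 0:
            raise SingularityError("|f| = 0: 0 G cannot be simulated")
        om = np.asarray(omega_dps, dtype=float) * _DEG
        s = self.state
        xc, xh, g = (s.canal_state[None], s.canal_state_internal[None], s.g_hat[None])
        xc, xh, g = self._core.rk4(xc, xh, g, om[None], f[None])
        self.state = ObserverState(g[0], xc[0], xh[0])
        return self.perceptual(f)

    def perceptual(self, f_g) -> PerceptualState:
        """Perceptual outputs at the current state under specific force f."""
        f = np.asarray(f_g, dtype=float)
        s = self.state
        w_hat, fh, ah = self._core.perceive(
            s.canal_state[None], s.canal_state_internal[None], s.g_hat[None],
            np.zeros((1, 3)), f[None])
        return PerceptualState(
            g_hat=s.g_hat.copy(),
            omega_hat=w_hat[0] / _DEG,
            a_hat=ah[0],
            perceived_roll_deg=float(perceived_roll_deg(s.g_hat)),
            perceived_pitch_deg=float(perceived_pitch_deg(s.g_hat)),
        )


def simulate(profile: MotionProfile, params: ObserverParams = None, init="auto"):
    """Integrate the observer over a motion profile.

    Parameters
    ----------
    profile : MotionProfile
    params : ObserverParams, optional
    init : "auto" or array-like
        "auto" aligns the initial gravity estimate with the initial specific
        force; otherwise a 3-vector initial ``g_hat``.

    Returns
    -------
    pandas.DataFrame
        Columns ``t_s, ghat_x..z, what_x..z (deg/s), ahat_x..z (G),
        perceived_roll_deg, perceived_pitch_deg``, one row per sample.
    """
    import pandas as pd

    params = params or ObserverParams()
    core = _Core(params)
    om = profile.omega * _DEG
    f = profile.f
    if init == "auto":
        g = f[0] / np.linalg.norm(f[0])
    else:
        g = np.asarray(init, dtype=float)
        g = g / np.linalg.norm(g)
    xc = np.zeros((1, 3))
    xh = np.zeros((1, 3))
    g = g[None]
    rows = []
    for i in range(profile.n):
        try:
            w_hat, fh, ah = core.perceive(xc, xh, g, om[i][None], f[i][None])
        except FloatingPointError as exc:  # pragma: no cover - defensive
            raise ConvergenceError(f"observer failed at sample {i}: {exc}")
        rows.append(np.concatenate([
            [i * profile.dt], g[0], w_hat[0] / _DEG, ah[0],
            [float(perceived_roll_deg(g[0])), float(perceived_pitch_deg(g[0]))]]))
        if i < profile.n - 1:
            xc, xh, g = core.rk4(xc, xh, g, om[i][None], f[i][None])
    cols = (["t_s"] + [f"ghat_{c}" for c in "xyz"] + [f"what_{c}" for c in "xyz"]
            + [f"ahat_{c}" for c in "xyz"] + ["perceived_roll_deg", "perceived_pitch_deg"])
    return pd.DataFrame(rows, columns=cols)


def _relax(f_vecs: np.ndarray, angle_fn, params: ObserverParams, g0: np.ndarray):
    """Relax a batch of constant-input conditions to steady state.

    ``f_vecs`` is (n, 3); ``angle_fn`` maps (n, 3) g_hat to the perceived
    angle (deg) per condition.  Returns the settled angles; raises
    ConvergenceError if any condition fails to settle within the horizon.
    """
    core = _Core(params)
    n = f_vecs.shape[0]
    om = np.zeros((n, 3))
    xc = np.zeros((n, 3))
    xh = np.zeros((n, 3))
    g = g0 / np.linalg.norm(g0, axis=-1, keepdims=True)

    check_dt = max(params.dt, 0.5)                      # s between rate checks
    steps_per_check = max(1, int(round(check_dt / params.dt)))
    window = max(1, int(np.ceil(params.settle_time / check_dt)))
    history = [angle_fn(g)]
    t = 0.0
    while t < params.max_horizon:
        for _ in range(steps_per_check):
            xc, xh, g = core.rk4(xc, xh, g, om, f_vecs)
        t += steps_per_check * params.dt
        history.append(angle_fn(g))
        if len(history) > window + 1:
            history.pop(0)
        if len(history) == window + 1:
            rates = np.abs(np.diff(np.asarray(history), axis=0)) / check_dt
            if np.all(rates < params.settle_tol):
                return angle_fn(g)
    angles = angle_fn(g)
    rates = np.abs(np.diff(np.asarray(history), axis=0)) / check_dt
    worst = float(np.max(rates[-1])) if len(history) > 1 else np.inf
    raise ConvergenceError(
        f"steady state not reached within {params.max_horizon} s "
        f"(residual rate {worst:.3g} deg/s)",
        last_value=angles, residual_rate=worst)


def static_tilt_perception(cond: TiltCondition, params: ObserverParams = None,
                           init="auto") -> float:
    """Steady-state perceived tilt (deg) for a static condition.

    Builds the constant sensory input for the tilt (zero rotation, GIF of
    magnitude ``g_level`` along the tilted vertical), relaxes the observer
    until the perceived-angle rate stays below ``settle_tol`` for
    ``settle_time``, and returns the signed angle of ``g_hat`` in the tilt
    plane.
    """
    params = params or ObserverParams()
    if cond.g_level <= 0:
        raise SingularityError("0 G cannot be simulated")
    f = cond.g_level * gif_direction(cond.axis, cond.angle_deg)
    angle_fn = perceived_roll_deg if cond.axis == "roll" else perceived_pitch_deg
    if init == "auto":
        g0 = f[None] / np.linalg.norm(f)
    else:
        g0 = np.asarray(init, dtype=float)[None]
    out = _relax(f[None], angle_fn, params, g0)
    return float(out[0])


def calibrate_utricular_weight(target: TiltCondition, target_perception: float,
                               params: ObserverParams = None,
                               tol_deg: float = 0.05) -> ObserverParams:
    """Fit the utricular weight so one steady-state case matches a datum.

    One-dimensional root-find on ``utricular_weight`` such that
    ``static_tilt_perception(target)`` equals ``target_perception`` within
    ``tol_deg``; every other parameter is left unchanged.  The weight is
    unidentifiable at 1 G (perception is veridical for every weight there).
    """
    from scipy.optimize import brentq

    params = params or ObserverParams()
    if target.g_level == 1.0:
        raise InvalidConditionError(
            "the utricular weight is unidentifiable at 1 G: the steady state "
            "is weight-independent there")

    def miss(w: float) -> float:
        p = replace(params, utricular_weight=w)
        return static_tilt_perception(target, p) - target_perception

    probes = [1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 0.75, 0.5, 0.25]
    vals = {}
    bracket = None
    prev = None
    for w in probes:
        try:
            vals[w] = miss(w)
        except (ConvergenceError, FloatingPointError):
            continue
        if prev is not None and np.sign(vals[w]) != np.sign(vals[prev]):
            bracket = tuple(sorted((prev, w)))
            break
        prev = w
    if bracket is None:
        raise CalibrationError(
            f"no sign change found for target {target_perception} deg at "
            f"{target}; probed weights {sorted(vals)} -> misses "
            f"{[round(vals[k], 3) for k in sorted(vals)]}")
    w_star = brentq(miss, *bracket, xtol=1e-4)
    fitted = replace(params, utricular_weight=float(w_star))
    residual = abs(static_tilt_perception(target, fitted) - target_perception)
    if residual > tol_deg:
        raise CalibrationError(
            f"calibration residual {residual:.4f} deg exceeds {tol_deg} deg")
    return fitted


def sweep(conditions, params: ObserverParams = None):
    """Steady-state perception for a list of conditions (batched).

    Returns a DataFrame with columns ``axis, angle_deg, g_level,
    perceived_deg, error_deg, error`` in the input order; per-condition
    failures are recorded in the ``error`` column rather than raised.
    """
    import pandas as pd

    params = params or ObserverParams()
    conditions = list(conditions)
    rows = []
    # batch by axis so a single relaxation handles each group
    for axis in ("roll", "pitch"):
        idx = [i for i, c in enumerate(conditions) if c.axis == axis]
        if not idx:
            continue
        f_vecs = np.array([
            conditions[i].g_level * gif_direction(axis, conditions[i].angle_deg)
            for i in idx])
        angle_fn = perceived_roll_deg if axis == "roll" else perceived_pitch_deg
        g0 = f_vecs / np.linalg.norm(f_vecs, axis=-1, keepdims=True)
        try:
            angles = _relax(f_vecs, angle_fn, params, g0)
            errs = [""] * len(idx)
        except ConvergenceError as exc:
            angles = (exc.last_value if exc.last_value is not None
                      else np.full(len(idx), np.nan))
            errs = [str(exc)] * len(idx)
        for j, i in enumerate(idx):
            c = conditions[i]
            rows.append((i, c.axis, c.angle_deg, c.g_level, float(angles[j]),
                         float(angles[j]) - c.angle_deg, errs[j]))
    rows.sort()
    return pd.DataFrame(
        [r[1:] for r in rows],
        columns=["axis", "angle_deg", "g_level", "perceived_deg", "error_deg", "error"],
    )
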
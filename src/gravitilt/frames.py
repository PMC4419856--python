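"""Head-fixed coordinate conventions and small rotation helpers.

The head frame is right-handed with x pointing forward (out of the nose),
y pointing left through the interaural axis, and z toward the head vertex.
A stationary upright head in 1 G senses a specific force of +1 G along +z.
Sign conventions follow the tilt-perception literature: positive roll is a
tilt to the left (the gravito-inertial force acquires a +y component) and
positive pitch is nose-up (the GIF acquires a -x component).

The utricular plane is modeled as the head horizontal plane pitched nose-up
by ``theta_utricle`` about the interaural (y) axis; its unit normal is
``n = (sin(theta_u), 0, cos(theta_u))``.  The GIF component within the plane
is the utricular shear, the component along ``n`` the compression.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "gif_direction",
    "utricle_normal",
    "utricle_weight_matrix",
    "perceived_roll_deg",
    "perceived_pitch_deg",
]


def gif_direction(axis: str, angle_deg: float) -> np.ndarray:
    """Unit head-frame direction of the gravito-inertial force for a static tilt.

    Parameters
    ----------
    axis : {"roll", "pitch"}
        Tilt axis. Roll tilts the head about x, pitch about y.
    angle_deg : float
        Signed tilt angle in degrees; positive roll = left ear down toward
        the floor is *not* used here -- positive roll means tilt to the left,
        so the upward GIF acquires a +y component; positive pitch = nose up,
        so the GIF acquires a -x component.
    """
    a = np.radians(angle_deg)
    if axis == "roll":
        return np.array([0.0, np.sin(a), np.cos(a)])
    if axis == "pitch":
        return np.array([-np.sin(a), 0.0, np.cos(a)])
    raise ValueError(f"axis must be 'roll' or 'pitch', got {axis!r}")


def utricle_normal(theta_utricle_deg: float) -> np.ndarray:
    """Unit normal of the utricular plane in head coordinates."""
    t = np.radians(theta_utricle_deg)
    return np.array([np.sin(t), 0.0, np.cos(t)])


def utricle_weight_matrix(weight: float, theta_utricle_deg: float) -> np.ndarray:
    """Symmetric matrix scaling the out-of-plane (compression) component.

    ``W = I + (weight - 1) n n^T``: vectors in the utricular plane are left
    untouched, the component along the plane normal is multiplied by
    ``weight``. ``weight = 1`` gives the identity (unmodified observer).
    """
    n = utricle_normal(theta_utricle_deg)
    return np.eye(3) + (weight - 1.0) * np.outer(n, n)


def perceived_roll_deg(g_hat: np.ndarray) -> np.ndarray:
    """Signed roll angle (deg) of a gravity-direction estimate.

    Angle of the estimate projected into the head y-z plane; positive for a
    perceived tilt to the left. Works on (..., 3) arrays.
    """
    g = np.asarray(g_hat)
    return np.degrees(np.arctan2(g[..., 1], g[..., 2]))


def perceived_pitch_deg(g_hat: np.ndarray) -> np.ndarray:
    """Signed pitch angle (deg) of a gravity-direction estimate.

    Angle in the head x-z plane; positive for a perceived nose-up pitch.
    """
    g = np.asarray(g_hat)
    return np.degrees(np.arctan2(-g[..., 0], g[..., 2]))
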
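"""Joint-coordinate kinematics for the tibiofemoral joint.

Convention (right knee, all frames right-handed):

* X anterior, Y proximal, Z lateral.
* Flexion is a rotation of the tibia about the femoral -Z axis (distal
  tibia swings posteriorly for positive flexion).
* Valgus (abduction) is a rotation about the floating -X axis (distal
  tibia swings laterally for positive valgus).
* Internal rotation is a rotation about the tibial +Y axis (toes turn
  medially for positive values on a right knee).

The relative rotation femur -> tibia is the floating-axis composition

    R = Rz(-flexion) @ Rx(-valgus) @ Ry(internal)

which is the Grood–Suntay-style joint coordinate system expressed as a
Z-X-Y Euler factorization. Angles cross the public API in degrees; all
internals are radians.
"""

from __future__ import annotations

import warnings

import numpy as np

COORD_NAMES = ("tx", "ty", "tz", "flexion", "valgus", "introt")

_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])


def _rx(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def jcs_rotation(flexion: float, valgus: float, introt: float,
                 degrees: bool = True) -> np.ndarray:
    """Rotation matrix femur->tibia for the given clinical angles."""
    if degrees:
        flexion, valgus, introt = np.deg2rad([flexion, valgus, introt])
    return _rz(-flexion) @ _rx(-valgus) @ _ry(introt)


def jcs_angles(rotation: np.ndarray, degrees: bool = True) -> tuple[float, float, float]:
    """Inverse of :func:`jcs_rotation`.

    Returns ``(flexion, valgus, introt)``. Near the gimbal singularity
    (|valgus| -> 90 deg, which is far outside physiology) the flexion /
    internal-rotation split is ill-defined; a warning is emitted and the
    flexion axis absorbs the indeterminacy.
    """
    r = np.asarray(rotation, dtype=float)
    sb = np.clip(r[2, 1], -1.0, 1.0)
    b = np.arcsin(sb)
    if abs(sb) > 1.0 - 1e-9:
        warnings.warn("gimbal-degenerate pose: valgus at +/-90 deg; "
                      "flexion/internal rotation are not separable", stacklevel=2)
        a = np.arctan2(r[1, 0], r[0, 0])
        c = 0.0
    else:
        c = np.arctan2(-r[2, 0], r[2, 2])
        a = np.arctan2(-r[0, 1], r[1, 1])
    flexion, valgus, introt = -a, -b, c
    if degrees:
        return tuple(np.rad2deg([flexion, valgus, introt]))
    return flexion, valgus, introt


def coord_rotation(q: np.ndarray) -> np.ndarray:
    """Rotation matrix from a 6-coordinate vector (angles in radians)."""
    return _rz(-q[3]) @ _rx(-q[4]) @ _ry(q[5])


def rotation_axes(q: np.ndarray) -> np.ndarray:
    """Instantaneous axes conjugate to the three angle coordinates.

    Row i is the world-frame (femur-frame) axis such that the generalized
    moment on coordinate ``(flexion, valgus, introt)[i]`` equals the torque
    vector dotted with that axis. Angles in ``q`` are radians.
    """
    rz = _rz(-q[3])
    a_flex = -_Z
    a_valg = -(rz @ _X)
    a_int = rz @ _rx(-q[4]) @ _Y
    return np.vstack([a_flex, a_valg, a_int])
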
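"""6-D spatial vector algebra for rigid-body dynamics.

Motion vectors are stacked ``[angular; linear]`` and expressed in a named
frame; Pluecker coordinate transforms follow the convention where
``xform(E, r)`` maps motion vectors from frame A to frame B when frame B's
origin sits at ``r`` (expressed in A) and ``E`` rotates A coordinates into
B coordinates.  Force vectors transform with the inverse transpose.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "skew",
    "rot",
    "xform",
    "xform_inv",
    "homog",
    "homog_inv",
    "crm",
    "crf",
    "spatial_inertia",
]


def skew(v: np.ndarray) -> np.ndarray:
    """Cross-product matrix: skew(v) @ w == v x w."""
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def rot(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix rotating vectors by ``angle`` about unit ``axis`` (Rodrigues)."""
    a = np.asarray(axis, dtype=float)
    K = skew(a)
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def xform(E: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Motion-vector coordinate transform (6x6) for rotation ``E`` and origin shift ``r``."""
    X = np.zeros((6, 6))
    X[:3, :3] = E
    X[3:, 3:] = E
    X[3:, :3] = -E @ skew(r)
    return X


def xform_inv(E: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Inverse of ``xform(E, r)``, i.e. ``xform(E.T, -E @ r)``."""
    return xform(E.T, -E @ np.asarray(r, dtype=float))


def homog(R: np.ndarray, p: np.ndarray) -> np.ndarray:
    """4x4 homogeneous transform from (rotation, translation)."""
    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = p
    return T


def homog_inv(T: np.ndarray) -> np.ndarray:
    R = T[:3, :3]
    return homog(R.T, -R.T @ T[:3, 3])


def crm(v: np.ndarray) -> np.ndarray:
    """Spatial cross product (motion x motion) matrix for motion vector ``v``."""
    w, vo = v[:3], v[3:]
    M = np.zeros((6, 6))
    M[:3, :3] = skew(w)
    M[3:, 3:] = skew(w)
    M[3:, :3] = skew(vo)
    return M


def crf(v: np.ndarray) -> np.ndarray:
    """Spatial cross product (motion x force) matrix: crf(v) = -crm(v).T."""
    return -crm(v).T


def spatial_inertia(mass: float, com: np.ndarray, inertia_com: np.ndarray) -> np.ndarray:
    """6x6 spatial inertia about the body-frame origin.

    ``inertia_com`` is the rotational inertia about the center of mass,
    expressed in body coordinates.
    """
    c = skew(np.asarray(com, dtype=float))
    I = np.zeros((6, 6))
    I[:3, :3] = np.asarray(inertia_com, dtype=float) + mass * (c @ c.T)
    I[:3, 3:] = mass * c
    I[3:, :3] = mass * c.T
    I[3:, 3:] = mass * np.eye(3)
    return I
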
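"""Internal vectorised geometry kernels.

Coordinates are plain ``numpy`` arrays of shape ``(n_particles, dim)`` in
Angstrom.  Angle/dihedral routines operate on index tuples and return both the
angle values and, where requested, analytic derivatives with respect to the
participating particle positions.  Derivative conventions are validated against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "pair_distances",
    "bend_angles",
    "bend_angle_gradients",
    "dihedral_angles",
    "dihedral_angle_gradients",
    "superpose",
]

_EPS = 1e-12


def pair_distances(x: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Distances between particle pairs. ``pairs`` is ``(k, 2)`` of indices."""
    d = x[pairs[:, 0]] - x[pairs[:, 1]]
    return np.sqrt(np.sum(d * d, axis=1))


def bend_angles(x: np.ndarray, triples: np.ndarray) -> np.ndarray:
    """Bend angle (radians) at the middle index of each ``(i, j, k)`` triple."""
    u = x[triples[:, 0]] - x[triples[:, 1]]
    v = x[triples[:, 2]] - x[triples[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    c = np.sum(u * v, axis=1) / np.maximum(nu * nv, _EPS)
    return np.arccos(np.clip(c, -1.0, 1.0))


def bend_angle_gradients(
    x: np.ndarray, triples: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Angles plus ``dtheta/dr`` for the three participants.

    Returns ``(theta, g_i, g_j, g_k)`` with gradient arrays of shape ``(k, dim)``.
    Near-collinear triples (sin(theta) ~ 0) get a zero gradient, which is the
    correct one-sided limit for the harmonic bending energies built on top.
    """
    u = x[triples[:, 0]] - x[triples[:, 1]]
    v = x[triples[:, 2]] - x[triples[:, 1]]
    nu = np.maximum(np.linalg.norm(u, axis=1), _EPS)
    nv = np.maximum(np.linalg.norm(v, axis=1), _EPS)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    c = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
    s = np.sqrt(np.maximum(1.0 - c * c, 0.0))
    theta = np.arccos(c)
    inv_s = np.where(s > 1e-8, 1.0 / np.maximum(s, _EPS), 0.0)
    g_i = (c[:, None] * uh - vh) * (inv_s / nu)[:, None]
    g_k = (c[:, None] * vh - uh) * (inv_s / nv)[:, None]
    g_j = -(g_i + g_k)
    return theta, g_i, g_j, g_k


def _dihedral_frames(x: np.ndarray, quads: np.ndarray):
    b1 = x[quads[:, 1]] - x[quads[:, 0]]
    b2 = x[quads[:, 2]] - x[quads[:, 1]]
    b3 = x[quads[:, 3]] - x[quads[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    return b1, b2, b3, n1, n2


def dihedral_angles(x: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Signed dihedral angle (radians, IUPAC sign) for ``(i, j, k, l)`` quads."""
    b1, b2, b3, n1, n2 = _dihedral_frames(x, quads)
    nb2 = np.maximum(np.linalg.norm(b2, axis=1), _EPS)
    m = np.cross(n1, b2 / nb2[:, None])
    return np.arctan2(np.sum(m * n2, axis=1), np.sum(n1 * n2, axis=1))


def dihedral_angle_gradients(x: np.ndarray, quads: np.ndarray):
    """Dihedrals plus ``dphi/dr`` for the four participants.

    Returns ``(phi, g_i, g_j, g_k, g_l)``; gradients are exact except at the
    singular collinear configurations, where they are zeroed.
    """
    b1, b2, b3, n1, n2 = _dihedral_frames(x, quads)
    nb2 = np.maximum(np.linalg.norm(b2, axis=1), _EPS)
    m = np.cross(n1, b2 / nb2[:, None])
    phi = np.arctan2(np.sum(m * n2, axis=1), np.sum(n1 * n2, axis=1))

    n1sq = np.sum(n1 * n1, axis=1)
    n2sq = np.sum(n2 * n2, axis=1)
    ok1 = n1sq > 1e-14
    ok2 = n2sq > 1e-14
    g_i = np.where(
        ok1[:, None], (nb2 / np.maximum(n1sq, _EPS))[:, None] * n1, 0.0
    )
    g_l = np.where(
        ok2[:, None], -(nb2 / np.maximum(n2sq, _EPS))[:, None] * n2, 0.0
    )
    t = (np.sum(b1 * b2, axis=1) / nb2**2)[:, None]
    s = (np.sum(b3 * b2, axis=1) / nb2**2)[:, None]
    g_j = -(1.0 + t) * g_i + s * g_l
    g_k = -(1.0 + s) * g_l + t * g_i
    return phi, g_i, g_j, g_k, g_l


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rmsd, rotation, translation)`` such that
    ``mobile @ rotation.T + translation`` best matches ``reference`` in the
    least-squares sense.  Coordinates with dim < 3 are zero-padded into 3-D, so
    the rotation is always a proper 3x3 matrix (det = +1).
    """
    if mobile.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: mobile {mobile.shape} vs reference {reference.shape}"
        )
    n, dim = mobile.shape
    if dim < 3:
        pad = np.zeros((n, 3 - dim))
        mobile = np.hstack([mobile, pad])
        reference = np.hstack([reference, pad])
    mob_mean = mobile.mean(axis=0)
    ref_mean = reference.mean(axis=0)
    mc = mobile - mob_mean
    rc = reference - ref_mean
    rot, rssd = Rotation.align_vectors(rc, mc)
    rmsd = float(rssd) / np.sqrt(n)
    rotation = rot.as_matrix()
    translation = ref_mean - rotation @ mob_mean
    return rmsd, rotation, translation
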
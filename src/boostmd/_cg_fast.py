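"""Numba-compiled evaluator for the coarse-grained helix.

A single scalar-loop kernel computes the full energy decomposition and the
split (non-dihedral / dihedral) gradient in one pass.  It is an optimisation
only: the per-term numpy implementations in :mod:`boostmd.models` remain the
reference, and the test suite pins the two paths together to tight tolerance.
When numba is unavailable the package silently falls back to the term loop.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco


@njit(cache=True)
def _cg_kernel(
    x,
    bond_r0,
    bond_k,
    theta0,
    angle_k,
    phi0,
    torsion_k,
    torsion_barrier,
    contact_pairs,
    contact_r0,
    contact_eps,
    rep_pairs,
    rep_sigma,
    rep_eps,
):
    n = x.shape[0]
    g_nd = np.zeros((n, 3))
    g_d = np.zeros((n, 3))
    v_bond = 0.0
    v_angle = 0.0
    v_tors = 0.0
    v_cont = 0.0
    v_rep = 0.0

    # bonds: consecutive beads
    for b in range(n - 1):
        dx = x[b] - x[b + 1]
        r = np.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
        dr = r - bond_r0
        v_bond += bond_k * dr * dr
        c = 2.0 * bond_k * dr / r
        for d in range(3):
            g_nd[b, d] += c * dx[d]
            g_nd[b + 1, d] -= c * dx[d]

    # pseudo-angles: consecutive triples
    for a in range(n - 2):
        u = x[a] - x[a + 1]
        v = x[a + 2] - x[a + 1]
        nu = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
        nv = np.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
        cth = (u[0] * v[0] + u[1] * v[1] + u[2] * v[2]) / (nu * nv)
        if cth > 1.0:
            cth = 1.0
        elif cth < -1.0:
            cth = -1.0
        sth = np.sqrt(1.0 - cth * cth)
        theta = np.arccos(cth)
        dth = theta - theta0
        v_angle += angle_k * dth * dth
        if sth > 1e-8:
            coef = 2.0 * angle_k * dth / sth
            for d in range(3):
                gi = (cth * u[d] / nu - v[d] / nv) / nu * coef
                gk = (cth * v[d] / nv - u[d] / nu) / nv * coef
                g_nd[a, d] += gi
                g_nd[a + 2, d] += gk
                g_nd[a + 1, d] -= gi + gk

    # pseudo-dihedrals: consecutive quadruples (the dihedral component)
    for q in range(n - 3):
        b1 = x[q + 1] - x[q]
        b2 = x[q + 2] - x[q + 1]
        b3 = x[q + 3] - x[q + 2]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
        m = np.cross(n1, b2 / nb2)
        y = m[0] * n2[0] + m[1] * n2[1] + m[2] * n2[2]
        xx = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
        phi = np.arctan2(y, xx)
        dphi = phi - phi0
        v_tors += torsion_k * (1.0 - np.cos(dphi)) + torsion_barrier * (
            1.0 - np.cos(3.0 * dphi)
        )
        dv = torsion_k * np.sin(dphi) + 3.0 * torsion_barrier * np.sin(3.0 * dphi)
        n1sq = n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2
        n2sq = n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2
        if n1sq > 1e-14 and n2sq > 1e-14:
            t = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / nb2**2
            s = (b3[0] * b2[0] + b3[1] * b2[1] + b3[2] * b2[2]) / nb2**2
            for d in range(3):
                gi = nb2 / n1sq * n1[d]
                gl = -nb2 / n2sq * n2[d]
                gj = -(1.0 + t) * gi + s * gl
                gk = -(1.0 + s) * gl + t * gi
                g_d[q, d] += dv * gi
                g_d[q + 1, d] += dv * gj
                g_d[q + 2, d] += dv * gk
                g_d[q + 3, d] += dv * gl

    # native-contact 12-10 wells
    for p in range(contact_pairs.shape[0]):
        i = contact_pairs[p, 0]
        j = contact_pairs[p, 1]
        dx = x[i] - x[j]
        r = np.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
        sr = contact_r0[p] / r
        s10 = sr**10
        s12 = s10 * sr * sr
        v_cont += contact_eps * (5.0 * s12 - 6.0 * s10)
        coef = 60.0 * contact_eps * (s10 - s12) / (r * r)
        for d in range(3):
            g_nd[i, d] += coef * dx[d]
            g_nd[j, d] -= coef * dx[d]

    # excluded-volume repulsion on non-native pairs
    for p in range(rep_pairs.shape[0]):
        i = rep_pairs[p, 0]
        j = rep_pairs[p, 1]
        dx = x[i] - x[j]
        r = np.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
        s12 = (rep_sigma / r) ** 12
        v_rep += rep_eps * s12
        coef = -12.0 * rep_eps * s12 / (r * r)
        for d in range(3):
            g_nd[i, d] += coef * dx[d]
            g_nd[j, d] -= coef * dx[d]

    v_nd = v_bond + v_angle + v_cont + v_rep
    return v_nd, v_tors, g_nd, g_d


class CGFastEvaluator:
    """Bound kernel arguments for one CG-helix parameterisation."""

    def __init__(
        self,
        bond_r0,
        bond_k,
        theta0,
        angle_k,
        phi0,
        torsion_k,
        torsion_barrier,
        contact_pairs,
        contact_r0,
        contact_eps,
        rep_pairs,
        rep_sigma,
        rep_eps,
    ):
        self.args = (
            float(bond_r0),
            float(bond_k),
            float(theta0),
            float(angle_k),
            float(phi0),
            float(torsion_k),
            float(torsion_barrier),
            np.ascontiguousarray(contact_pairs, dtype=np.int64),
            np.ascontiguousarray(contact_r0, dtype=np.float64),
            float(contact_eps),
            np.ascontiguousarray(rep_pairs, dtype=np.int64),
            float(rep_sigma),
            float(rep_eps),
        )

    def __call__(self, x: np.ndarray):
        v_nd, v_d, g_nd, g_d = _cg_kernel(
            np.ascontiguousarray(x, dtype=np.float64), *self.args
        )
        return v_nd + v_d, v_d, g_nd, g_d
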
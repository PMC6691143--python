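"""Desk-scale model systems with analytic energies and gradients.

Two families of systems are provided:

* :func:`make_double_well` — a one-particle, one-dimensional quartic double
  well with a known Boltzmann distribution.  It is the workhorse for checking
  the boost/reweighting mathematics against quadrature.
* :func:`make_cg_helix` — a coarse-grained, one-bead-per-residue Gō-like
  helical peptide.  Harmonic bonds and pseudo-angles, periodic pseudo-dihedral
  torsions (these constitute the "dihedral" energy component V_D), attractive
  12-10 wells on the native contacts of an ideal-helix reference, and
  inverse-power excluded-volume repulsion elsewhere.  The reference structure
  is constructed analytically, so no external data is needed.

Units throughout: Angstrom, kcal/mol, amu, radians internally for angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _geometry as geom

__all__ = [
    "EnergyTerm",
    "ModelSystem",
    "make_double_well",
    "make_cg_helix",
    "ideal_helix_coords",
    "extended_coords",
    "perturbed_extended_coords",
    "HELIX_RADIUS",
    "HELIX_RISE",
    "HELIX_TWIST_DEG",
]

# Standard alpha-helix C-alpha trace geometry.
HELIX_RADIUS = 2.3  # Angstrom
HELIX_RISE = 1.5  # Angstrom per residue
HELIX_TWIST_DEG = 100.0  # degrees per residue


class EnergyTerm:
    """A named energy component mapping coordinates to (energy, gradient)."""

    name: str = "term"
    is_dihedral: bool = False

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        raise NotImplementedError

    def energy(self, x: np.ndarray) -> float:
        return self.energy_gradient(x)[0]

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.energy_gradient(x)[1]


class QuarticDoubleWell(EnergyTerm):
    """V(x) = h * ((x/w)^2 - 1)^2 for a single 1-D particle."""

    name = "double_well"

    def __init__(self, barrier_height: float, half_separation: float):
        self.h = float(barrier_height)
        self.w = float(half_separation)

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        s = x[0, 0] / self.w
        q = s * s - 1.0
        e = self.h * q * q
        g = np.array([[4.0 * self.h * q * x[0, 0] / (self.w * self.w)]])
        return e, g


class HarmonicBonds(EnergyTerm):
    """Sum_b k * (r_b - r0)^2 over bonded pairs."""

    name = "bonds"

    def __init__(self, pairs: np.ndarray, r0: float, k: float):
        self.pairs = np.asarray(pairs, dtype=int)
        self.r0 = float(r0)
        self.k = float(k)

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        i, j = self.pairs[:, 0], self.pairs[:, 1]
        d = x[i] - x[j]
        r = np.sqrt(np.sum(d * d, axis=1))
        dr = r - self.r0
        e = self.k * float(np.sum(dr * dr))
        coef = (2.0 * self.k * dr / np.maximum(r, 1e-12))[:, None]
        g = np.zeros_like(x)
        np.add.at(g, i, coef * d)
        np.add.at(g, j, -coef * d)
        return e, g


class HarmonicAngles(EnergyTerm):
    """Sum_a k * (theta_a - theta0)^2 over consecutive bead triples."""

    name = "angles"

    def __init__(self, triples: np.ndarray, theta0: float, k: float):
        self.triples = np.asarray(triples, dtype=int)
        self.theta0 = float(theta0)
        self.k = float(k)

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        theta, g_i, g_j, g_k = geom.bend_angle_gradients(x, self.triples)
        dt = theta - self.theta0
        e = self.k * float(np.sum(dt * dt))
        coef = (2.0 * self.k * dt)[:, None]
        g = np.zeros_like(x)
        np.add.at(g, self.triples[:, 0], coef * g_i)
        np.add.at(g, self.triples[:, 1], coef * g_j)
        np.add.at(g, self.triples[:, 2], coef * g_k)
        return e, g


class PeriodicTorsions(EnergyTerm):
    """Torsion energy on consecutive bead quadruples (the dihedral component V_D).

    Per quadruple: ``k (1 - cos(phi - phi0)) + b (1 - cos 3(phi - phi0))``.
    The 1-fold term biases toward the helical pseudo-dihedral; the 3-fold
    barrier term creates metastable rotamer states (minima at phi0 and
    phi0 +- 120 degrees) so that folding requires crossing torsional
    barriers — the landscape feature dihedral boosting is built to flatten.
    """

    name = "torsions"
    is_dihedral = True

    def __init__(self, quads: np.ndarray, phi0: float, k: float, barrier_k: float = 0.0):
        self.quads = np.asarray(quads, dtype=int)
        self.phi0 = float(phi0)
        self.k = float(k)
        self.barrier_k = float(barrier_k)

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        phi, g_i, g_j, g_k, g_l = geom.dihedral_angle_gradients(x, self.quads)
        dphi = phi - self.phi0
        e = float(
            self.k * np.sum(1.0 - np.cos(dphi))
            + self.barrier_k * np.sum(1.0 - np.cos(3.0 * dphi))
        )
        coef = (
            self.k * np.sin(dphi) + 3.0 * self.barrier_k * np.sin(3.0 * dphi)
        )[:, None]
        g = np.zeros_like(x)
        np.add.at(g, self.quads[:, 0], coef * g_i)
        np.add.at(g, self.quads[:, 1], coef * g_j)
        np.add.at(g, self.quads[:, 2], coef * g_k)
        np.add.at(g, self.quads[:, 3], coef * g_l)
        return e, g


class NativeContactWells(EnergyTerm):
    """Go-like 12-10 wells: eps * (5 (r0/r)^12 - 6 (r0/r)^10), minimum -eps at r0."""

    name = "contacts"

    def __init__(self, pairs: np.ndarray, r0: np.ndarray, eps: float):
        self.pairs = np.asarray(pairs, dtype=int)
        self.r0 = np.asarray(r0, dtype=float)
        self.eps = float(eps)

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        g = np.zeros_like(x)
        if len(self.pairs) == 0:
            return 0.0, g
        i, j = self.pairs[:, 0], self.pairs[:, 1]
        d = x[i] - x[j]
        r = np.sqrt(np.sum(d * d, axis=1))
        s10 = (self.r0 / r) ** 10
        s12 = s10 * (self.r0 / r) ** 2
        e = self.eps * float(np.sum(5.0 * s12 - 6.0 * s10))
        dV_dr = 60.0 * self.eps * (s10 - s12) / r
        coef = (dV_dr / np.maximum(r, 1e-12))[:, None]
        np.add.at(g, i, coef * d)
        np.add.at(g, j, -coef * d)
        return e, g


class InversePowerRepulsion(EnergyTerm):
    """Excluded volume on non-native pairs: eps_rep * (sigma/r)^12."""

    name = "repulsion"

    def __init__(self, pairs: np.ndarray, sigma: float, eps_rep: float = 1.0):
        self.pairs = np.asarray(pairs, dtype=int)
        self.sigma = float(sigma)
        self.eps_rep = float(eps_rep)

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        g = np.zeros_like(x)
        if len(self.pairs) == 0:
            return 0.0, g
        i, j = self.pairs[:, 0], self.pairs[:, 1]
        d = x[i] - x[j]
        r = np.sqrt(np.sum(d * d, axis=1))
        s12 = (self.sigma / r) ** 12
        e = self.eps_rep * float(np.sum(s12))
        dV_dr = -12.0 * self.eps_rep * s12 / r
        coef = (dV_dr / np.maximum(r, 1e-12))[:, None]
        np.add.at(g, i, coef * d)
        np.add.at(g, j, -coef * d)
        return e, g


@dataclass
class ModelSystem:
    """A particle system whose total energy is a sum of named components.

    ``n_res`` and ``n_atom`` feed the boost-threshold formulas; for the
    coarse-grained helix both equal the bead count, while callers working with
    the analytic one-particle systems supply effective counts to the threshold
    estimator directly.
    """

    name: str
    dim: int
    masses: np.ndarray
    n_res: int
    n_atom: int
    terms: tuple[EnergyTerm, ...]
    reference: np.ndarray | None = field(default=None, repr=False)
    fast_evaluate: object | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if self.n_res < 1 or self.n_atom < 1:
            raise ValueError("n_res and n_atom must be >= 1")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if self.dim not in (1, 2, 3):
            raise ValueError("dim must be 1, 2 or 3")

    @property
    def n_particles(self) -> int:
        return len(self.masses)

    def check_coords(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_particles, self.dim):
            raise ValueError(
                f"coordinates shape {x.shape} != ({self.n_particles}, {self.dim})"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite coordinates")
        return x

    def energy(self, x: np.ndarray) -> float:
        if self.fast_evaluate is not None:
            return float(self.fast_evaluate(x)[0])
        return float(sum(t.energy(x) for t in self.terms))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        if self.fast_evaluate is not None:
            _, _, g_nd, g_d = self.fast_evaluate(x)
            return g_nd + g_d
        g = np.zeros_like(np.asarray(x, dtype=float))
        for t in self.terms:
            g += t.gradient(x)
        return g

    def dihedral_energy(self, x: np.ndarray) -> float:
        return float(sum(t.energy(x) for t in self.terms if t.is_dihedral))

    def energy_components(self, x: np.ndarray) -> dict[str, float]:
        return {t.name: t.energy(x) for t in self.terms}

    def evaluate(
        self, x: np.ndarray
    ) -> tuple[float, float, np.ndarray, np.ndarray]:
        """One-pass evaluation: ``(V_total, V_D, grad_nondihedral, grad_dihedral)``."""
        if self.fast_evaluate is not None:
            return self.fast_evaluate(x)
        v_nd = 0.0
        v_d = 0.0
        g_nd = np.zeros_like(x)
        g_d = np.zeros_like(x)
        for t in self.terms:
            e, g = t.energy_gradient(x)
            if t.is_dihedral:
                v_d += e
                g_d += g
            else:
                v_nd += e
                g_nd += g
        return v_nd + v_d, v_d, g_nd, g_d


def make_double_well(
    barrier_height: float, half_separation: float, mass: float = 10.0
) -> ModelSystem:
    """One-particle 1-D quartic double well V(x) = h ((x/w)^2 - 1)^2.

    Minima at x = +-w with V = 0; barrier V(0) = h.  The dihedral component is
    identically zero, so only the total-potential boost is meaningful here.
    """
    if barrier_height <= 0 or half_separation <= 0 or mass <= 0:
        raise ValueError("barrier_height, half_separation and mass must be > 0")
    return ModelSystem(
        name="double_well",
        dim=1,
        masses=np.array([mass]),
        n_res=1,
        n_atom=1,
        terms=(QuarticDoubleWell(barrier_height, half_separation),),
    )


def ideal_helix_coords(
    n_res: int,
    radius: float = HELIX_RADIUS,
    rise: float = HELIX_RISE,
    twist_deg: float = HELIX_TWIST_DEG,
) -> np.ndarray:
    """C-alpha-trace coordinates of an ideal right-handed alpha helix."""
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    k = np.arange(n_res)
    ang = np.deg2rad(twist_deg) * k
    return np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), rise * k]
    )


def extended_coords(n_res: int, spacing: float = 3.8) -> np.ndarray:
    """Collinear bead chain along z at uniform spacing (a fully extended start)."""
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    out = np.zeros((n_res, 3))
    out[:, 2] = spacing * np.arange(n_res)
    return out


def perturbed_extended_coords(
    n_res: int, spacing: float = 3.8, amplitude: float = 0.1
) -> np.ndarray:
    """Extended chain with a small deterministic transverse perturbation.

    A perfectly collinear chain is a symmetry trap for a bead model: all
    transverse forces vanish and attractive contacts collapse the beads along
    the line.  The helical-phase perturbation (default 0.1 Angstrom) breaks
    the degeneracy without meaningfully changing the starting geometry.
    """
    x = extended_coords(n_res, spacing)
    k = np.arange(n_res)
    x[:, 0] += amplitude * np.cos(2.0 * k)
    x[:, 1] += amplitude * np.sin(2.0 * k)
    return x


def make_cg_helix(
    n_res: int,
    bond_k: float = 40.0,
    angle_k: float = 15.0,
    torsion_k: float = 1.5,
    torsion_barrier: float = 3.0,
    contact_eps: float = 1.5,
    repulsion_sigma: float = 4.0,
    bond_r0: float = 3.8,
    mass: float = 110.0,
    contact_cutoff: float = 7.0,
    min_seq_sep: int = 2,
) -> ModelSystem:
    """Coarse-grained Go-like helical peptide, one bead per residue.

    The ideal-helix trace is the native reference: pseudo-angle and
    pseudo-dihedral equilibria are measured from it, native-contact pairs are
    extracted from it with the same non-adjacent < 7 Angstrom rule used by the
    trajectory analysis, and the attractive wells sit at the native pair
    distances.  Pairs at sequence separation >= 3 that are not native contacts
    get purely repulsive excluded volume.
    """
    if n_res < 5:
        raise ValueError("n_res must be >= 5 (needs at least two pseudo-dihedrals)")
    ref = ideal_helix_coords(n_res)
    idx = np.arange(n_res)
    bonds = np.column_stack([idx[:-1], idx[1:]])
    triples = np.column_stack([idx[:-2], idx[1:-1], idx[2:]])
    quads = np.column_stack([idx[:-3], idx[1:-2], idx[2:-1], idx[3:]])
    theta0 = float(geom.bend_angles(ref, triples)[0])
    phi0 = float(geom.dihedral_angles(ref, quads)[0])

    from .analysis import native_contacts  # deferred: analysis imports models

    contacts = native_contacts(ref, cutoff=contact_cutoff, min_seq_sep=min_seq_sep)
    r0 = geom.pair_distances(ref, contacts.pairs)

    contact_keys = {tuple(p) for p in contacts.pairs}
    rep_pairs = np.array(
        [
            (i, j)
            for i in range(n_res)
            for j in range(i + 3, n_res)
            if (i, j) not in contact_keys
        ],
        dtype=int,
    ).reshape(-1, 2)

    terms: tuple[EnergyTerm, ...] = (
        HarmonicBonds(bonds, bond_r0, bond_k),
        HarmonicAngles(triples, theta0, angle_k),
        PeriodicTorsions(quads, phi0, torsion_k, torsion_barrier),
        NativeContactWells(contacts.pairs, r0, contact_eps),
        InversePowerRepulsion(rep_pairs, repulsion_sigma),
    )
    from ._cg_fast import HAVE_NUMBA, CGFastEvaluator

    fast = None
    if HAVE_NUMBA:
        fast = CGFastEvaluator(
            bond_r0, bond_k, theta0, angle_k, phi0, torsion_k, torsion_barrier,
            contacts.pairs, r0, contact_eps, rep_pairs, repulsion_sigma, 1.0,
        )
    return ModelSystem(
        name=f"cg_helix_{n_res}",
        dim=3,
        masses=np.full(n_res, float(mass)),
        n_res=n_res,
        n_atom=n_res,
        terms=terms,
        reference=ref,
        fast_evaluate=fast,
    )
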
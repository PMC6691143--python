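"""Folding metrics and trajectory clustering.

All metrics operate on residue-trace coordinate arrays of shape
``(n_res, dim)`` (one bead / C-alpha per residue).  The native-contact
convention is: a pair of residues at sequence separation >= ``min_seq_sep``
(default 2, i.e. excluding only sequence neighbours) whose trace distance is
strictly below the cutoff (default 7.0 Angstrom).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import _geometry as geom

__all__ = [
    "ContactSet",
    "ClusterResult",
    "superpose_rmsd",
    "radius_of_gyration",
    "native_contacts",
    "fraction_native",
    "helix_content",
    "pairwise_rmsd_matrix",
    "cluster_trajectory",
]


@dataclass(frozen=True)
class ContactSet:
    """Deduplicated native-contact pair list with its defining parameters."""

    pairs: np.ndarray  # (k, 2) int, i < j
    cutoff: float
    min_seq_sep: int
    source: str = "reference"

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ClusterResult:
    """Agglomerative clustering of trajectory frames on pairwise RMSD."""

    labels: np.ndarray  # per-frame cluster id, 0-based, ordered by population
    populations: np.ndarray  # fraction per cluster, descending
    representatives: np.ndarray  # frame index per cluster
    rmsd_of_representative_to_native: np.ndarray | None = None
    linkage: str = "average"
    n_clusters: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_clusters = len(self.populations)


def _apply_selection(coords: np.ndarray, selection) -> np.ndarray:
    if selection is None:
        return coords
    sel = np.asarray(selection, dtype=int)
    return coords[sel]


def superpose_rmsd(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection=None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Optimal-superposition (Kabsch) RMSD over a selection.

    Returns ``(rmsd, rotation, translation)``; the rotation is proper
    (det = +1) and applying ``mobile @ R.T + t`` aligns the mobile selection
    onto the reference selection in the least-squares sense.
    """
    m = np.asarray(mobile, dtype=float)
    r = np.asarray(reference, dtype=float)
    ms = _apply_selection(m, selection)
    rs = _apply_selection(r, selection)
    if ms.shape != rs.shape:
        raise ValueError("mobile and reference selections differ in shape")
    if not (np.all(np.isfinite(ms)) and np.all(np.isfinite(rs))):
        raise ValueError("non-finite coordinates")
    if ms.shape[1] == 3 and len(ms) >= 3:
        rank = np.linalg.matrix_rank(ms - ms.mean(axis=0), tol=1e-9)
        if rank < 2:
            warnings.warn(
                "degenerate (collinear) selection: superposition is not unique",
                stacklevel=2,
            )
    with warnings.catch_warnings():
        # align_vectors warns for rank-deficient inputs; handled above.
        warnings.simplefilter("ignore", UserWarning)
        return geom.superpose(ms, rs)


def radius_of_gyration(
    coords: np.ndarray, masses: np.ndarray | None = None, selection=None
) -> float:
    """Mass-weighted radius of gyration about the selection centre of mass."""
    x = _apply_selection(np.asarray(coords, dtype=float), selection)
    if len(x) == 0:
        raise ValueError("empty selection")
    if masses is None:
        m = np.ones(len(x))
    else:
        m = _apply_selection(np.asarray(masses, dtype=float), selection)
        if np.any(m <= 0):
            raise ValueError("masses must be positive")
    com = np.average(x, axis=0, weights=m)
    d2 = np.sum((x - com) ** 2, axis=1)
    return float(np.sqrt(np.average(d2, weights=m)))


def native_contacts(
    reference: np.ndarray,
    cutoff: float = 7.0,
    min_seq_sep: int = 2,
    source: str = "reference",
) -> ContactSet:
    """Native contacts of a residue trace: |i - j| >= min_seq_sep, r < cutoff."""
    ref = np.asarray(reference, dtype=float)
    n = len(ref)
    pairs = []
    for i in range(n):
        for j in range(i + min_seq_sep, n):
            if np.linalg.norm(ref[i] - ref[j]) < cutoff:
                pairs.append((i, j))
    arr = np.array(pairs, dtype=int).reshape(-1, 2)
    return ContactSet(pairs=arr, cutoff=cutoff, min_seq_sep=min_seq_sep, source=source)


def fraction_native(frame: np.ndarray, contacts: ContactSet) -> float:
    """Fraction of the native-contact pairs formed in a frame (same cutoff)."""
    if len(contacts) == 0:
        raise ValueError("empty contact set: fraction of native contacts undefined")
    x = np.asarray(frame, dtype=float)
    if np.max(contacts.pairs) >= len(x):
        raise ValueError("frame has fewer residues than the contact indices require")
    r = geom.pair_distances(x, contacts.pairs)
    return float(np.mean(r < contacts.cutoff))


def _ideal_pseudo_dihedral() -> float:
    from .models import ideal_helix_coords  # deferred to avoid import cycle

    ref = ideal_helix_coords(4)
    return float(geom.dihedral_angles(ref, np.array([[0, 1, 2, 3]]))[0])


def helix_content(
    frame: np.ndarray,
    window_deg: float = 30.0,
    phi0: float | None = None,
) -> float:
    """Fraction of pseudo-dihedrals within ``window_deg`` of the helical value.

    This is a trace-level stand-in for fractional native helix content: a
    consecutive-quadruple pseudo-dihedral counts as helical when it lies within
    the window around the ideal-helix pseudo-dihedral (about +50 degrees for
    standard C-alpha helix geometry).
    """
    x = np.asarray(frame, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("helix content needs >= 4 residues")
    if phi0 is None:
        phi0 = _ideal_pseudo_dihedral()
    idx = np.arange(n)
    quads = np.column_stack([idx[:-3], idx[1:-2], idx[2:-1], idx[3:]])
    phi = geom.dihedral_angles(x, quads)
    dev = np.angle(np.exp(1j * (phi - phi0)))  # wrapped difference
    return float(np.mean(np.abs(dev) <= np.deg2rad(window_deg)))


def pairwise_rmsd_matrix(frames: np.ndarray, selection=None) -> np.ndarray:
    """Symmetric matrix of pairwise superposed RMSDs between frames."""
    f = np.asarray(frames, dtype=float)
    n = len(f)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rmsd, _, _ = superpose_rmsd(f[i], f[j], selection)
            mat[i, j] = mat[j, i] = rmsd
    return mat


def cluster_trajectory(
    frames: np.ndarray,
    selection=None,
    n_clusters: int | None = None,
    rmsd_cutoff: float | None = None,
    native: np.ndarray | None = None,
) -> ClusterResult:
    """Average-linkage clustering of frames on the pairwise-RMSD matrix.

    Exactly one of ``n_clusters`` / ``rmsd_cutoff`` selects the flat
    clustering.  Cluster ids are reassigned in descending-population order;
    each representative is the frame minimising the mean RMSD to its cluster
    (earliest frame on ties).  If a ``native`` structure is given, the
    representative-to-native RMSD is reported per cluster.
    """
    if (n_clusters is None) == (rmsd_cutoff is None):
        raise ValueError("specify exactly one of n_clusters or rmsd_cutoff")
    f = np.asarray(frames, dtype=float)
    n = len(f)
    if n_clusters is not None and n < n_clusters:
        raise ValueError("fewer frames than requested clusters")
    mat = pairwise_rmsd_matrix(f, selection)
    if not np.all(np.isfinite(mat)):
        raise ValueError("non-finite pairwise RMSD matrix")
    if n == 1:
        raw = np.array([1])
    else:
        z = linkage(squareform(mat, checks=False), method="average")
        if n_clusters is not None:
            raw = fcluster(z, t=n_clusters, criterion="maxclust")
        else:
            raw = fcluster(z, t=rmsd_cutoff, criterion="distance")

    ids, counts = np.unique(raw, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    ids, counts = ids[order], counts[order]
    labels = np.empty(n, dtype=int)
    reps = np.empty(len(ids), dtype=int)
    for new_id, old_id in enumerate(ids):
        members = np.flatnonzero(raw == old_id)
        labels[members] = new_id
        sub = mat[np.ix_(members, members)]
        mean_rmsd = sub.mean(axis=1)
        reps[new_id] = members[int(np.argmin(mean_rmsd))]  # argmin takes earliest tie
    populations = counts / n

    rep_to_native = None
    if native is not None:
        rep_to_native = np.array(
            [superpose_rmsd(f[r], native, selection)[0] for r in reps]
        )
    return ClusterResult(
        labels=labels,
        populations=populations,
        representatives=reps,
        rmsd_of_representative_to_native=rep_to_native,
        linkage="average",
    )
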
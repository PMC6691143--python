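"""Boost-parameter estimation from a short unbiased run.

The thresholds and strengths of the two boost branches are set from the mean
total and dihedral potential energies of an unbiased pre-run::

    E_D = E_D' + a1 * N_res / 5      alpha_D = a1 * N_res / 5
    E_P = E_P' + a2 * N_atom         alpha_P = a2 * N_atom

with defaults a1 = 3.5 and a2 = 0.2 kcal/mol.  By construction the thresholds
sit above the sampled means (alpha = E - E' exactly), so the boost is active
in the typical region.  For systems where residue/atom counts have no direct
meaning (the analytic one-particle wells) the caller supplies effective
counts sized so that alpha is commensurate with the barriers of interest.
"""

from __future__ import annotations

import numpy as np

from .engine import BoostParams, TrajectoryRecord

__all__ = ["DEFAULT_A1", "DEFAULT_A2", "average_energies", "estimate_thresholds"]

DEFAULT_A1 = 3.5  # kcal/mol, dihedral branch coefficient
DEFAULT_A2 = 0.2  # kcal/mol per atom, total branch coefficient


def average_energies(
    traj: TrajectoryRecord, burn_in: float = 0.5
) -> tuple[float, float]:
    """Mean total and dihedral potential energy of an unbiased trajectory.

    ``burn_in`` is the fraction of leading frames discarded as equilibration
    (default: first half, since the pre-run follows heating).  Returns
    ``(E_P_prime, E_D_prime)``.
    """
    if traj.config.boost_mode != "none":
        raise ValueError("threshold estimation requires an unbiased (boost-off) run")
    if traj.n_frames < 2:
        raise ValueError("need at least two frames to average")
    if not 0.0 <= burn_in < 1.0:
        raise ValueError("burn_in must be in [0, 1)")
    start = int(np.floor(traj.n_frames * burn_in))
    start = min(start, traj.n_frames - 1)
    return float(np.mean(traj.V[start:])), float(np.mean(traj.V_D[start:]))


def estimate_thresholds(
    E_P_prime: float,
    E_D_prime: float,
    a1: float = DEFAULT_A1,
    a2: float = DEFAULT_A2,
    N_res: int = 1,
    N_atom: int = 1,
) -> BoostParams:
    """Boost thresholds/strengths from pre-run averages and system size."""
    if a1 <= 0 or a2 <= 0:
        raise ValueError("a1 and a2 must be > 0")
    if N_res < 1 or N_atom < 1:
        raise ValueError("N_res and N_atom must be >= 1")
    alpha_D = a1 * N_res / 5.0
    alpha_P = a2 * N_atom
    return BoostParams(
        E_P=E_P_prime + alpha_P,
        alpha_P=alpha_P,
        E_D=E_D_prime + alpha_D,
        alpha_D=alpha_D,
        E_P_prime=E_P_prime,
        E_D_prime=E_D_prime,
        a1=a1,
        a2=a2,
        N_res=N_res,
        N_atom=N_atom,
    )
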
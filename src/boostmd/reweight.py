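"""Recovering canonical free energies from boosted trajectories.

Each frame of a boosted run is reweighted by the Boltzmann factor of its bias
energy, ``w_i proportional to exp(dV_i / k_B T)``, computed in log space with
max-subtraction so arbitrarily large biases stay finite.  The weighted 2-D
histogram over two collective variables (by convention RMSD-to-native on the
first axis and radius of gyration on the second) gives the probability
surface, and ``F = -k_B T ln p`` shifted to zero at the occupied minimum gives
the free-energy landscape.  For a single boosted trajectory the multi-window
weighted-histogram estimator reduces to exactly this one-window weighted
histogram; a concatenating combiner covers the multi-seed case.

A second-order cumulant-expansion estimator (``method="cumulant2"``) is
offered for high-variance biases: per-bin
``F = -kT ln p_boosted - <dV> - Var(dV)/(2 kT)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .engine import KB, TrajectoryRecord

__all__ = [
    "FESGrid",
    "frame_weights",
    "weighted_fes",
    "weighted_fes_from_arrays",
    "combine_trajectories",
    "lowest_free_energy_state",
    "effective_sample_size",
]


@dataclass
class FESGrid:
    """2-D binned probability / free-energy surface over two collective variables.

    Empty bins carry probability 0 and free energy ``+inf`` (flagged by
    ``occupied``), distinct from occupied high-energy bins.  Per-frame bin
    assignments and normalised weights are retained so representative frames
    can be pulled out of any bin.
    """

    cv1_edges: np.ndarray
    cv2_edges: np.ndarray
    probability: np.ndarray  # (n1, n2), sums to 1
    free_energy: np.ndarray  # kcal/mol, min occupied bin = 0, empty = +inf
    counts: np.ndarray  # raw frame counts per bin
    n_eff: np.ndarray  # per-bin effective sample size
    temperature: float
    frame_bins: np.ndarray  # (n_frames, 2) bin index per frame
    weights: np.ndarray  # normalised per-frame weights

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    @property
    def cv1_centers(self) -> np.ndarray:
        return 0.5 * (self.cv1_edges[:-1] + self.cv1_edges[1:])

    @property
    def cv2_centers(self) -> np.ndarray:
        return 0.5 * (self.cv2_edges[:-1] + self.cv2_edges[1:])

    @property
    def n_eff_total(self) -> float:
        return effective_sample_size(self.weights)


def frame_weights(deltaV_series: np.ndarray, temperature: float) -> np.ndarray:
    """Normalised canonical reweighting factors exp(dV / k_B T).

    Computed in log space with max-subtraction: finite for any finite bias.
    """
    dv = np.asarray(deltaV_series, dtype=float)
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if np.any(dv < 0):
        raise ValueError("negative deltaV violates the boost contract")
    logw = dv / (KB * temperature)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def effective_sample_size(weights: np.ndarray) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    w = np.asarray(weights, dtype=float)
    s = w.sum()
    if s == 0:
        return 0.0
    return float(s * s / np.sum(w * w))


def _padded_edges(series: np.ndarray, bins: int, pad: float = 0.05) -> np.ndarray:
    lo, hi = float(np.min(series)), float(np.max(series))
    span = hi - lo
    if span == 0.0:  # degenerate CV: give it a token width
        lo, hi = lo - 0.5, hi + 0.5
    else:
        lo, hi = lo - pad * span, hi + pad * span
    return np.linspace(lo, hi, bins + 1)


def weighted_fes_from_arrays(
    deltaV: np.ndarray,
    cv1_series: np.ndarray,
    cv2_series: np.ndarray,
    temperature: float,
    bins: int | tuple[int, int] = 50,
    cv1_edges: np.ndarray | None = None,
    cv2_edges: np.ndarray | None = None,
    method: str = "exponential",
) -> FESGrid:
    """Weighted 2-D histogram free-energy surface from raw series."""
    dv = np.asarray(deltaV, dtype=float)
    c1 = np.asarray(cv1_series, dtype=float)
    c2 = np.asarray(cv2_series, dtype=float)
    if not (len(dv) == len(c1) == len(c2)):
        raise ValueError("deltaV and collective-variable series differ in length")
    if method not in ("exponential", "cumulant2"):
        raise ValueError("method must be 'exponential' or 'cumulant2'")
    if isinstance(bins, int):
        b1 = b2 = bins
    else:
        b1, b2 = bins
    if cv1_edges is None:
        cv1_edges = _padded_edges(c1, b1)
    if cv2_edges is None:
        cv2_edges = _padded_edges(c2, b2)

    w = frame_weights(dv, temperature)
    i1 = np.clip(np.digitize(c1, cv1_edges) - 1, 0, len(cv1_edges) - 2)
    i2 = np.clip(np.digitize(c2, cv2_edges) - 1, 0, len(cv2_edges) - 2)
    shape = (len(cv1_edges) - 1, len(cv2_edges) - 1)
    counts = np.zeros(shape)
    wsum = np.zeros(shape)
    w2sum = np.zeros(shape)
    np.add.at(counts, (i1, i2), 1.0)
    np.add.at(wsum, (i1, i2), w)
    np.add.at(w2sum, (i1, i2), w * w)

    kt = KB * temperature
    occ = counts > 0
    if occ.sum() == 1:
        warnings.warn("all frames fell in a single bin", stacklevel=2)

    if method == "exponential":
        prob = wsum / wsum.sum()
        with np.errstate(divide="ignore"):
            fe = np.where(occ, -kt * np.log(np.where(occ, prob, 1.0)), np.inf)
    else:  # cumulant expansion to 2nd order on the unweighted boosted histogram
        dv_sum = np.zeros(shape)
        dv2_sum = np.zeros(shape)
        np.add.at(dv_sum, (i1, i2), dv)
        np.add.at(dv2_sum, (i1, i2), dv * dv)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_boost = counts / counts.sum()
            mean_dv = np.where(occ, dv_sum / np.maximum(counts, 1), 0.0)
            var_dv = np.where(
                occ, dv2_sum / np.maximum(counts, 1) - mean_dv**2, 0.0
            )
            fe = np.where(
                occ,
                -kt * np.log(np.where(occ, p_boost, 1.0))
                - mean_dv
                - np.maximum(var_dv, 0.0) / (2.0 * kt),
                np.inf,
            )
        logp = -fe[occ] / kt
        logp -= logp.max()
        prob = np.zeros(shape)
        prob[occ] = np.exp(logp)
        prob /= prob.sum()
        fe = np.where(occ, -kt * np.log(np.where(occ, prob, 1.0)), np.inf)

    fe = np.where(occ, fe - fe[occ].min(), np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        n_eff = np.where(occ, wsum * wsum / np.where(occ, w2sum, 1.0), 0.0)
    return FESGrid(
        cv1_edges=cv1_edges,
        cv2_edges=cv2_edges,
        probability=prob,
        free_energy=fe,
        counts=counts,
        n_eff=n_eff,
        temperature=temperature,
        frame_bins=np.column_stack([i1, i2]),
        weights=w,
    )


def weighted_fes(
    traj: TrajectoryRecord,
    cv1_series: np.ndarray,
    cv2_series: np.ndarray,
    bins: int | tuple[int, int] = 50,
    temperature: float | None = None,
    **kwargs,
) -> FESGrid:
    """Free-energy surface of one trajectory over two collective variables.

    Weights come from the per-frame bias energy; an unbiased trajectory gives
    uniform weights and the surface equals the plain histogram estimate.
    Temperature defaults to the run's thermostat target.
    """
    t = traj.config.temperature if temperature is None else temperature
    return weighted_fes_from_arrays(
        traj.deltaV, cv1_series, cv2_series, temperature=t, bins=bins, **kwargs
    )


def combine_trajectories(
    trajs: list[TrajectoryRecord],
    cv1_list: list[np.ndarray],
    cv2_list: list[np.ndarray],
    bins: int | tuple[int, int] = 50,
    temperature: float | None = None,
    **kwargs,
) -> FESGrid:
    """Multi-seed combiner: concatenated frames, jointly normalised weights."""
    if not trajs:
        raise ValueError("no trajectories to combine")
    t = trajs[0].config.temperature if temperature is None else temperature
    dv = np.concatenate([tr.deltaV for tr in trajs])
    c1 = np.concatenate([np.asarray(c) for c in cv1_list])
    c2 = np.concatenate([np.asarray(c) for c in cv2_list])
    return weighted_fes_from_arrays(dv, c1, c2, temperature=t, bins=bins, **kwargs)


def lowest_free_energy_state(fes: FESGrid) -> tuple[float, float, int]:
    """Bin-centre coordinates and representative frame of the occupied minimum.

    The representative is the highest-weight frame inside the minimum bin,
    ties broken by earliest frame index.
    """
    if not np.any(fes.occupied):
        raise ValueError("empty free-energy surface")
    masked = np.where(fes.occupied, fes.free_energy, np.inf)
    i1, i2 = np.unravel_index(int(np.argmin(masked)), masked.shape)
    in_bin = np.flatnonzero(
        (fes.frame_bins[:, 0] == i1) & (fes.frame_bins[:, 1] == i2)
    )
    wb = fes.weights[in_bin]
    rep = int(in_bin[int(np.argmax(wb))])  # argmax returns first max: earliest tie
    return float(fes.cv1_centers[i1]), float(fes.cv2_centers[i2]), rep
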
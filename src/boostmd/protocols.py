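"""End-to-end experiment protocols chaining the pipeline stages.

These are the package's reproducible demonstrations: each takes a master seed
and deterministic sizes, runs pre-run -> threshold estimation -> boosted and
unboosted dynamics -> reweighting/analytics, and returns plain-dict summaries.
They back the ``demo-fold`` CLI subcommand, the acceptance tests and the
acceptance script.

Conventions fixed here (documented in the methods note):

* Double well: barrier 6 kcal/mol, half-separation 2 Angstrom, particle mass
  10 amu, 300 K, collision frequency 1/ps, timestep 0.01 ps.  The effective
  atom count for the total-boost threshold is 35 (alpha_P = 7 kcal/mol,
  commensurate with the barrier); the dihedral branch is inactive (V_D = 0).
* CG helix: 15 residues, dihedral-only boost with the native counts
  (N_res = N_atom = 15), timestep 0.01 ps, 300 K.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate

from .analysis import (
    cluster_trajectory,
    fraction_native,
    native_contacts,
    radius_of_gyration,
    superpose_rmsd,
)
from .aparam import average_energies, estimate_thresholds
from .engine import (
    KB,
    BoostParams,
    SimulationConfig,
    TrajectoryRecord,
    first_passage_steps,
    run_simulation,
)
from .models import (
    extended_coords,
    ideal_helix_coords,
    make_cg_helix,
    make_double_well,
    perturbed_extended_coords,
)
from .reweight import combine_trajectories, lowest_free_energy_state, weighted_fes_from_arrays

__all__ = [
    "double_well_system",
    "double_well_thresholds",
    "double_well_pmf_experiment",
    "double_well_mfpt_experiment",
    "exact_double_well_pmf",
    "cg_fold_experiment",
    "planted_mixture_frames",
    "clustering_recovery_experiment",
]

# Double-well study conditions
DW_BARRIER = 6.0  # kcal/mol
DW_HALFSEP = 2.0  # Angstrom
DW_MASS = 10.0  # amu
DW_TEMPERATURE = 300.0  # K
DW_TIMESTEP = 0.01  # ps
DW_N_ATOM_EFF = 35  # effective atom count: alpha_P = 7 kcal/mol
DW_PRERUN_STEPS = 50_000

# CG-helix study conditions
CG_N_RES = 15
CG_TEMPERATURE = 300.0
CG_TIMESTEP = 0.01
CG_HEAT_RAMP_STEPS = 5_000
CG_PRERUN_STEPS = 30_000


def _subseed(master: int, k: int) -> int:
    """Derived stream seeds, kept below 2**31."""
    return int(np.random.SeedSequence([master, k]).generate_state(1)[0] % (2**31))


def double_well_system():
    return make_double_well(DW_BARRIER, DW_HALFSEP, mass=DW_MASS)


def double_well_thresholds(seed: int) -> tuple[BoostParams, TrajectoryRecord]:
    """Unbiased pre-run from one well, then threshold estimation."""
    system = double_well_system()
    cfg = SimulationConfig(
        timestep=DW_TIMESTEP,
        temperature=DW_TEMPERATURE,
        n_steps=DW_PRERUN_STEPS,
        save_interval=10,
        seed=_subseed(seed, 0),
        boost_mode="none",
    )
    x0 = np.array([[-DW_HALFSEP]])
    prerun = run_simulation(system, x0, cfg)
    e_p, e_d = average_energies(prerun)
    params = estimate_thresholds(e_p, e_d, N_res=1, N_atom=DW_N_ATOM_EFF)
    return params, prerun


def exact_double_well_pmf(edges: np.ndarray, temperature: float = DW_TEMPERATURE):
    """Quadrature reference: per-bin -kT ln integral exp(-V/kT) dx, min-shifted."""
    kt = KB * temperature

    def boltz(x):
        v = DW_BARRIER * ((x / DW_HALFSEP) ** 2 - 1.0) ** 2
        return np.exp(-v / kt)

    masses = np.array(
        [integrate.quad(boltz, a, b)[0] for a, b in zip(edges[:-1], edges[1:])]
    )
    total = masses.sum()
    with np.errstate(divide="ignore"):
        fe = -kt * np.log(masses / total)
    return fe - fe.min()


def double_well_pmf_experiment(
    seed: int,
    amd_steps: int = 600_000,
    save_interval: int = 5,
    bins: int = 48,
    min_n_eff: float = 100.0,
) -> dict:
    """Dual-run protocol on the double well, PMF recovery check.

    Runs the pre-run/threshold stage, a total-boost trajectory, reweights it
    over (x, const) and compares with quadrature on bins holding at least
    ``min_n_eff`` effective samples.  Also measures how far the *unweighted*
    boosted histogram underestimates the barrier.
    """
    system = double_well_system()
    params, _ = double_well_thresholds(seed)
    cfg = SimulationConfig(
        timestep=DW_TIMESTEP,
        temperature=DW_TEMPERATURE,
        n_steps=amd_steps,
        save_interval=save_interval,
        seed=_subseed(seed, 1),
        boost_mode="total",
    )
    traj = run_simulation(system, np.array([[-DW_HALFSEP]]), cfg, boost=params)

    x = traj.coords[:, 0, 0]
    zeros = np.zeros_like(x)
    kt = KB * DW_TEMPERATURE
    fes = weighted_fes_from_arrays(
        traj.deltaV, x, zeros, temperature=DW_TEMPERATURE, bins=(bins, 1)
    )
    fe_rw = fes.free_energy[:, 0]
    n_eff = fes.n_eff[:, 0]
    fe_exact = exact_double_well_pmf(fes.cv1_edges)

    good = (n_eff >= min_n_eff) & np.isfinite(fe_rw)
    fe_rw_s = fe_rw[good] - fe_rw[good].min()
    fe_ex_s = fe_exact[good] - fe_exact[good].min()
    max_err_kt = float(np.max(np.abs(fe_rw_s - fe_ex_s)) / kt)

    # Unweighted (uncorrected) histogram of the boosted run on the same bins.
    fes_unw = weighted_fes_from_arrays(
        np.zeros_like(traj.deltaV), x, zeros,
        temperature=DW_TEMPERATURE, cv1_edges=fes.cv1_edges,
        cv2_edges=fes.cv2_edges,
    )
    fe_unw = fes_unw.free_energy[:, 0]

    def barrier(fe: np.ndarray, edges: np.ndarray) -> float:
        centers = 0.5 * (edges[:-1] + edges[1:])
        top = int(np.argmin(np.abs(centers)))  # bin at x ~ 0
        finite = np.isfinite(fe)
        return float(fe[top] - fe[finite].min())

    barrier_exact = barrier(fe_exact, fes.cv1_edges)
    barrier_unw = barrier(fe_unw, fes.cv1_edges)
    barrier_rw = barrier(fe_rw, fes.cv1_edges)
    return {
        "boost_params": params.as_dict(),
        "n_frames": traj.n_frames,
        "max_pmf_error_kT": max_err_kt,
        "n_compared_bins": int(good.sum()),
        "barrier_exact_kT": barrier_exact / kt,
        "barrier_reweighted_kT": barrier_rw / kt,
        "barrier_unweighted_kT": barrier_unw / kt,
        "unweighted_barrier_underestimate_kT": (barrier_exact - barrier_unw) / kt,
    }


def double_well_mfpt_experiment(
    seed: int,
    n_seeds: int = 20,
    max_steps: int = 10_000_000,
) -> dict:
    """Mean first-passage steps across the barrier: plain vs boosted dynamics.

    Each replicate starts at the left minimum and stops on reaching the right
    minimum.  Thresholds come from one shared unbiased pre-run.  Returns the
    per-method means with normal-approximation 95% confidence intervals.
    """
    system = double_well_system()
    params, _ = double_well_thresholds(seed)
    results: dict[str, list[int]] = {"md": [], "amd": []}
    for k in range(n_seeds):
        for mode, key, boost in (("none", "md", None), ("total", "amd", params)):
            cfg = SimulationConfig(
                timestep=DW_TIMESTEP,
                temperature=DW_TEMPERATURE,
                n_steps=1,
                seed=_subseed(seed, 100 + 2 * k + (0 if key == "md" else 1)),
                boost_mode=mode,
            )
            fpt = first_passage_steps(
                system, -DW_HALFSEP, DW_HALFSEP, cfg, boost=boost, max_steps=max_steps
            )
            if fpt is None:
                fpt = max_steps  # censored; conservative for the comparison
            results[key].append(fpt)

    out: dict = {"n_seeds": n_seeds, "boost_params": params.as_dict()}
    for key, vals in results.items():
        arr = np.array(vals, dtype=float)
        mean = arr.mean()
        half = 1.96 * arr.std(ddof=1) / np.sqrt(len(arr))
        out[key] = {
            "mean_steps": float(mean),
            "ci95": [float(mean - half), float(mean + half)],
            "censored": int(np.sum(arr >= max_steps)),
        }
    out["speedup"] = out["md"]["mean_steps"] / out["amd"]["mean_steps"]
    out["ci_separated"] = out["amd"]["ci95"][1] < out["md"]["ci95"][0]
    return out


def cg_fold_experiment(
    seed: int,
    n_seeds: int = 5,
    n_res: int = CG_N_RES,
    amd_steps: int = 200_000,
    save_interval: int = 100,
    boost_mode: str = "dihedral",
    fold_rmsd: float = 1.5,
    fold_q: float = 0.8,
    run_md_control: bool = False,
) -> dict:
    """Fold the coarse-grained helix from an extended start under boosted dynamics.

    Per replicate: minimize the extended chain, heat, run an unbiased pre-run
    for thresholds (native residue/atom counts), then the boosted production
    run.  A replicate counts as folded when the median RMSD-to-ideal-helix and
    median native-contact fraction over the final 20% of frames pass the
    thresholds.  The reweighted (RMSD, Rg) landscape over all replicates
    locates the lowest-free-energy state.
    """
    system = make_cg_helix(n_res)
    native = system.reference
    contacts = native_contacts(native)
    x0 = perturbed_extended_coords(n_res)

    def metric_series(traj: TrajectoryRecord):
        rmsd = np.array(
            [superpose_rmsd(f, native)[0] for f in traj.coords]
        )
        q = np.array([fraction_native(f, contacts) for f in traj.coords])
        rg = np.array(
            [radius_of_gyration(f, system.masses) for f in traj.coords]
        )
        return rmsd, q, rg

    per_seed = []
    trajs, rmsds, rgs = [], [], []
    for k in range(n_seeds):
        pre_cfg = SimulationConfig(
            timestep=CG_TIMESTEP,
            temperature=CG_TEMPERATURE,
            n_steps=CG_PRERUN_STEPS,
            save_interval=10,
            seed=_subseed(seed, 200 + 2 * k),
            boost_mode="none",
            heat_ramp_steps=CG_HEAT_RAMP_STEPS,
            minimize_first=True,
        )
        prerun = run_simulation(system, x0, pre_cfg)
        e_p, e_d = average_energies(prerun)
        params = estimate_thresholds(e_p, e_d, N_res=n_res, N_atom=system.n_atom)

        amd_cfg = SimulationConfig(
            timestep=CG_TIMESTEP,
            temperature=CG_TEMPERATURE,
            n_steps=amd_steps,
            save_interval=save_interval,
            seed=_subseed(seed, 201 + 2 * k),
            boost_mode=boost_mode,
            heat_ramp_steps=0,
            minimize_first=False,
        )
        traj = run_simulation(system, prerun.coords[-1], amd_cfg, boost=params)
        rmsd, q, rg = metric_series(traj)
        tail = slice(int(0.8 * len(rmsd)), None)
        folded = bool(
            np.median(rmsd[tail]) < fold_rmsd and np.median(q[tail]) > fold_q
        )
        entry = {
            "seed_index": k,
            "folded": folded,
            "tail_median_rmsd": float(np.median(rmsd[tail])),
            "tail_median_q": float(np.median(q[tail])),
            "min_rmsd": float(rmsd.min()),
            "boost_params": params.as_dict(),
        }
        if run_md_control:
            md_cfg = SimulationConfig(
                timestep=CG_TIMESTEP,
                temperature=CG_TEMPERATURE,
                n_steps=amd_steps,
                save_interval=save_interval,
                seed=_subseed(seed, 201 + 2 * k),
                boost_mode="none",
            )
            md_traj = run_simulation(system, prerun.coords[-1], md_cfg)
            md_rmsd, md_q, _ = metric_series(md_traj)
            entry["md_tail_median_rmsd"] = float(np.median(md_rmsd[tail]))
            entry["md_tail_median_q"] = float(np.median(md_q[tail]))
        per_seed.append(entry)
        trajs.append(traj)
        rmsds.append(rmsd)
        rgs.append(rg)

    fes = combine_trajectories(trajs, rmsds, rgs, bins=40)
    cv1_star, cv2_star, rep = lowest_free_energy_state(fes)
    n_folded = sum(e["folded"] for e in per_seed)
    return {
        "n_res": n_res,
        "n_seeds": n_seeds,
        "boost_mode": boost_mode,
        "per_seed": per_seed,
        "n_folded": n_folded,
        "fold_fraction": n_folded / n_seeds,
        "majority_folded": n_folded > n_seeds / 2,
        "lfes_rmsd": cv1_star,
        "lfes_rg": cv2_star,
        "lfes_frame": rep,
    }


def planted_mixture_frames(
    seed: int,
    n_frames: int = 200,
    fractions: tuple[float, ...] = (0.8, 0.15, 0.05),
    n_res: int = 12,
    jitter: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Frames drawn from three rigid conformers with Gaussian jitter.

    Conformers: ideal helix, extended chain, and a half-helix/half-extended
    hybrid.  Returns ``(frames, planted_labels)`` with labels in planted
    population order.
    """
    rng = np.random.default_rng(seed)
    helix = ideal_helix_coords(n_res)
    ext = extended_coords(n_res)
    half = helix.copy()
    k = n_res // 2
    direction = helix[k] - helix[k - 1]
    direction /= np.linalg.norm(direction)
    for i in range(k, n_res):
        half[i] = helix[k] + 3.8 * (i - k) * direction
    conformers = [helix, ext, half]
    counts = np.round(np.array(fractions) * n_frames).astype(int)
    counts[-1] = n_frames - counts[:-1].sum()
    labels = np.repeat(np.arange(len(conformers)), counts)
    rng.shuffle(labels)
    frames = np.array(
        [
            conformers[lab] + jitter * rng.standard_normal((n_res, 3))
            for lab in labels
        ]
    )
    return frames, labels


def clustering_recovery_experiment(seed: int, n_frames: int = 200) -> dict:
    """Recover the planted 80/15/5 mixture populations by RMSD clustering."""
    frames, labels = planted_mixture_frames(seed, n_frames=n_frames)
    result = cluster_trajectory(frames, n_clusters=3)
    planted = np.sort(np.bincount(labels) / n_frames)[::-1]
    recovered = result.populations[:3]
    return {
        "planted_fractions": planted.tolist(),
        "recovered_fractions": recovered.tolist(),
        "max_abs_error": float(np.max(np.abs(planted - recovered))),
    }
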
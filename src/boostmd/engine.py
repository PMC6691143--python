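"""Langevin dynamics with optional dual-boost acceleration.

The accelerated-dynamics scheme raises the potential wherever it falls below a
threshold::

    V'(r) = V(r) + dV(r)
    dV(r) = (E_P - V)^2 / (a_P + E_P - V)    [when V   < E_P, else 0]
          + (E_D - V_D)^2 / (a_D + E_D - V_D)  [when V_D < E_D, else 0]

with V_D the dihedral component of the potential.  The boosted force follows
by the chain rule: each boosted branch scales its gradient by
``alpha^2 / (alpha + E - V)^2``, a factor in (0, 1], so basins are flattened
and barrier crossing accelerates while the landscape above the thresholds is
untouched.  Reweighting by exp(dV / k_B T) (see :mod:`boostmd.reweight`)
recovers canonical statistics.

Integrator: BAOAB splitting of Langevin dynamics.  With collision frequency 0
and no boost it reduces to velocity Verlet.  Units: Angstrom, ps, amu,
kcal/mol, Kelvin; k_B = 0.0019872041 kcal/mol/K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize as _opt

from .models import ModelSystem, QuarticDoubleWell

__all__ = [
    "KB",
    "ACC",
    "SimulationConfig",
    "BoostParams",
    "TrajectoryRecord",
    "ForceComposition",
    "boost_energy",
    "boost_force_scale",
    "dual_boost",
    "evaluate_forces",
    "langevin_step",
    "run_simulation",
    "minimize",
    "MinimizeResult",
    "first_passage_steps",
]

KB = 0.0019872041  # kcal/mol/K
ACC = 418.4  # (amu Angstrom^2/ps^2) per kcal/mol

BOOST_MODES = ("none", "dihedral", "total", "dual")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one Langevin run.

    ``collision_frequency`` defaults to 1.0 / ps; ``heat_ramp_steps`` > 0
    starts from zero velocity and ramps the thermostat target linearly up to
    ``temperature`` before production.  ``nested_total_boost`` switches the
    dual-boost composition from two independent additive branches (default) to
    the nested form in which the dihedral-boosted energy feeds the total
    boost.
    """

    timestep: float  # ps
    temperature: float  # K
    n_steps: int
    collision_frequency: float = 1.0  # 1/ps
    save_interval: int = 10
    seed: int = 0
    boost_mode: str = "none"
    heat_ramp_steps: int = 0
    minimize_first: bool = False
    energy_ceiling: float = 1e8  # kcal/mol; |V| above this aborts the run
    nested_total_boost: bool = False

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.collision_frequency < 0:
            raise ValueError("collision_frequency must be >= 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.save_interval < 1:
            raise ValueError("save_interval must be >= 1")
        if self.boost_mode not in BOOST_MODES:
            raise ValueError(f"boost_mode must be one of {BOOST_MODES}")


@dataclass(frozen=True)
class BoostParams:
    """Thresholds and strengths of the two boost branches, with provenance.

    ``E_P``/``alpha_P`` act on the total potential, ``E_D``/``alpha_D`` on the
    dihedral component.  The provenance fields record the unbiased-run
    averages and the per-size coefficients that produced the thresholds.
    """

    E_P: float = 0.0
    alpha_P: float = 0.0
    E_D: float = 0.0
    alpha_D: float = 0.0
    E_P_prime: float | None = None
    E_D_prime: float | None = None
    a1: float | None = None
    a2: float | None = None
    N_res: int | None = None
    N_atom: int | None = None

    def validate_for_mode(self, mode: str) -> None:
        if mode in ("total", "dual") and self.alpha_P <= 0:
            raise ValueError(f"boost mode {mode!r} requires alpha_P > 0")
        if mode in ("dihedral", "dual") and self.alpha_D <= 0:
            raise ValueError(f"boost mode {mode!r} requires alpha_D > 0")

    def as_dict(self) -> dict:
        return {
            "E_P": self.E_P,
            "alpha_P": self.alpha_P,
            "E_D": self.E_D,
            "alpha_D": self.alpha_D,
            "E_P_prime": self.E_P_prime,
            "E_D_prime": self.E_D_prime,
            "a1": self.a1,
            "a2": self.a2,
            "N_res": self.N_res,
            "N_atom": self.N_atom,
        }


def boost_energy(V, E, alpha):
    """Single-branch boost: (E - V)^2 / (alpha + E - V) when V < E, else 0."""
    if np.any(np.asarray(alpha) <= 0):
        raise ValueError("alpha must be > 0")
    V = np.asarray(V, dtype=float)
    diff = E - V
    denom = alpha + np.maximum(diff, 0.0)  # never zero: alpha > 0
    out = np.where(diff > 0, diff * diff / denom, 0.0)
    return float(out) if out.ndim == 0 else out


def boost_force_scale(V, E, alpha):
    """Gradient attenuation dV'/dV = alpha^2 / (alpha + E - V)^2 below E, else 1.

    Continuous at V = E and confined to (0, 1]; the boosted force is the
    unboosted force times this factor.
    """
    if np.any(np.asarray(alpha) <= 0):
        raise ValueError("alpha must be > 0")
    V = np.asarray(V, dtype=float)
    diff = E - V
    denom = alpha + np.maximum(diff, 0.0)
    out = np.where(diff > 0, (alpha / denom) ** 2, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ForceComposition:
    """How to assemble the boosted gradient from the split plain gradient.

    ``grad(V') = total_scale * (g_nondihedral + g_dihedral)
               + dihedral_extra * g_dihedral``.
    """

    total_scale: float = 1.0
    dihedral_extra: float = 0.0

    def modified_gradient(self, g_nd: np.ndarray, g_d: np.ndarray) -> np.ndarray:
        return self.total_scale * (g_nd + g_d) + self.dihedral_extra * g_d


def dual_boost(
    V: float,
    V_D: float,
    params: BoostParams,
    mode: str,
    nested: bool = False,
) -> tuple[float, ForceComposition]:
    """Boost energy and force-composition rule for one configuration.

    In the default (independent) composition the total-potential branch is
    thresholded against V itself; with ``nested=True`` the dihedral-boosted
    energy V + dV_D feeds the total branch, as in some production codes.
    """
    if mode not in BOOST_MODES:
        raise ValueError(f"unknown boost mode {mode!r}")
    if mode == "none":
        return 0.0, ForceComposition()
    params.validate_for_mode(mode)

    if mode == "dihedral":
        dv_d = boost_energy(V_D, params.E_D, params.alpha_D)
        s_d = boost_force_scale(V_D, params.E_D, params.alpha_D)
        return dv_d, ForceComposition(1.0, s_d - 1.0)
    if mode == "total":
        dv_p = boost_energy(V, params.E_P, params.alpha_P)
        s_p = boost_force_scale(V, params.E_P, params.alpha_P)
        return dv_p, ForceComposition(s_p, 0.0)
    # dual
    dv_d = boost_energy(V_D, params.E_D, params.alpha_D)
    s_d = boost_force_scale(V_D, params.E_D, params.alpha_D)
    if nested:
        v_eff = V + dv_d
        dv_p = boost_energy(v_eff, params.E_P, params.alpha_P)
        s_p = boost_force_scale(v_eff, params.E_P, params.alpha_P)
        return dv_d + dv_p, ForceComposition(s_p, s_p * (s_d - 1.0))
    dv_p = boost_energy(V, params.E_P, params.alpha_P)
    s_p = boost_force_scale(V, params.E_P, params.alpha_P)
    return dv_d + dv_p, ForceComposition(s_p, s_d - 1.0)


def evaluate_forces(
    system: ModelSystem,
    x: np.ndarray,
    boost: BoostParams | None,
    mode: str,
    nested: bool = False,
) -> tuple[np.ndarray, float, float, float]:
    """Boosted force and energies at ``x``: ``(force, V, V_D, deltaV)``."""
    V, V_D, g_nd, g_d = system.evaluate(x)
    if mode == "none" or boost is None:
        if mode != "none":
            raise ValueError(f"boost mode {mode!r} requires BoostParams")
        return -(g_nd + g_d), V, V_D, 0.0
    dv, rule = dual_boost(V, V_D, boost, mode, nested=nested)
    return -rule.modified_gradient(g_nd, g_d), V, V_D, dv


def _kinetic_energy(v: np.ndarray, masses: np.ndarray) -> float:
    return 0.5 * float(np.sum(masses[:, None] * v * v)) / ACC


def _instantaneous_temperature(v: np.ndarray, masses: np.ndarray) -> float:
    ndof = v.size
    return 2.0 * _kinetic_energy(v, masses) / (KB * ndof)


def _draw_velocities(
    rng: np.random.Generator, masses: np.ndarray, dim: int, temperature: float
) -> np.ndarray:
    sigma = np.sqrt(KB * max(temperature, 0.0) * ACC / masses)
    return sigma[:, None] * rng.standard_normal((len(masses), dim))


def langevin_step(
    system: ModelSystem,
    x: np.ndarray,
    v: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    boost: BoostParams | None = None,
    force: np.ndarray | None = None,
    temperature: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[float, float, float]]:
    """One BAOAB update.  Returns ``(x, v, force_new, (V, V_D, deltaV))``.

    ``force`` may carry the force evaluated at ``x`` on the previous step to
    avoid recomputation; ``temperature`` overrides the config target (used by
    the heating ramp).  The random kick is drawn even when the collision
    frequency is zero so that the seed stream is identical across thermostat
    settings.
    """
    dt = config.timestep
    temp = config.temperature if temperature is None else temperature
    masses = system.masses[:, None]
    if force is None:
        force, _, _, _ = evaluate_forces(
            system, x, boost, config.boost_mode, config.nested_total_boost
        )
    half_kick = 0.5 * dt * ACC / masses

    v = v + half_kick * force
    x = x + 0.5 * dt * v
    c1 = math.exp(-config.collision_frequency * dt)
    c2 = math.sqrt(max(1.0 - c1 * c1, 0.0))
    sigma = np.sqrt(KB * max(temp, 0.0) * ACC / system.masses)[:, None]
    noise = rng.standard_normal(x.shape)
    v = c1 * v + c2 * sigma * noise
    x = x + 0.5 * dt * v
    force_new, V, V_D, dv = evaluate_forces(
        system, x, boost, config.boost_mode, config.nested_total_boost
    )
    if not (np.isfinite(V) and np.all(np.isfinite(force_new))):
        raise FloatingPointError("non-finite energy or force")
    v = v + half_kick * force_new
    return x, v, force_new, (V, V_D, dv)


@dataclass
class TrajectoryRecord:
    """Frames of one run: coordinates plus per-frame scalars.

    ``status`` is "ok" for a completed run and "diverged" when the energy
    ceiling was hit; in that case the record holds the frames saved up to the
    failure and ``error_step`` points at the offending integration step.
    """

    times: np.ndarray  # ps
    coords: np.ndarray  # (n_frames, n_particles, dim)
    V: np.ndarray
    V_D: np.ndarray
    deltaV: np.ndarray
    T_inst: np.ndarray
    config: SimulationConfig
    boost: BoostParams | None = None
    status: str = "ok"
    error_step: int | None = None

    def __post_init__(self) -> None:
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if np.any(self.deltaV < -1e-12):
            raise ValueError("deltaV must be non-negative on every frame")
        if self.config.boost_mode == "none" and np.any(self.deltaV != 0.0):
            raise ValueError("deltaV must be identically zero without boost")

    @property
    def n_frames(self) -> int:
        return len(self.times)


def run_simulation(
    system: ModelSystem,
    x0: np.ndarray,
    config: SimulationConfig,
    boost: BoostParams | None = None,
) -> TrajectoryRecord:
    """Run Langevin (optionally boosted) dynamics and record frames.

    Stages: optional minimization, velocity initialisation, optional linear
    heating ramp, then ``n_steps`` of production with a frame recorded every
    ``save_interval`` steps (the state entering production is frame 0).  The
    seed in ``config`` fully determines the output.
    """
    if config.boost_mode != "none":
        if boost is None:
            raise ValueError("boost parameters required unless boost_mode='none'")
        boost.validate_for_mode(config.boost_mode)
    x = system.check_coords(x0).copy()
    if config.minimize_first:
        x = minimize(system, x).coords
    rng = np.random.default_rng(config.seed)

    if config.heat_ramp_steps > 0:
        v = np.zeros_like(x)
        force = None
        for step in range(config.heat_ramp_steps):
            t_target = config.temperature * (step + 1) / config.heat_ramp_steps
            x, v, force, _ = langevin_step(
                system, x, v, config, rng, boost, force, temperature=t_target
            )
    else:
        v = _draw_velocities(rng, system.masses, system.dim, config.temperature)
        force = None

    times, coords, vs, vds, dvs, temps = [], [], [], [], [], []

    def record(step: int, V: float, V_D: float, dv: float) -> None:
        times.append(step * config.timestep)
        coords.append(x.copy())
        vs.append(V)
        vds.append(V_D)
        dvs.append(dv)
        temps.append(_instantaneous_temperature(v, system.masses))

    force, V, V_D, dv = _initial_eval(system, x, config, boost)
    status, error_step = "ok", None
    record(0, V, V_D, dv)
    for step in range(1, config.n_steps + 1):
        try:
            x, v, force, (V, V_D, dv) = langevin_step(
                system, x, v, config, rng, boost, force
            )
        except FloatingPointError:
            status, error_step = "diverged", step
            break
        if abs(V) > config.energy_ceiling:
            status, error_step = "diverged", step
            break
        if step % config.save_interval == 0:
            record(step, V, V_D, dv)

    return TrajectoryRecord(
        times=np.array(times),
        coords=np.array(coords),
        V=np.array(vs),
        V_D=np.array(vds),
        deltaV=np.array(dvs),
        T_inst=np.array(temps),
        config=config,
        boost=boost,
        status=status,
        error_step=error_step,
    )


def _initial_eval(system, x, config, boost):
    return evaluate_forces(
        system, x, boost, config.boost_mode, config.nested_total_boost
    )


@dataclass
class MinimizeResult:
    coords: np.ndarray
    energy: float
    grad_norm: float
    converged: bool
    message: str


def minimize(
    system: ModelSystem,
    coords: np.ndarray,
    max_iter: int = 1000,
    gtol: float = 1e-6,
    sd_fraction: float = 0.2,
) -> MinimizeResult:
    """Steepest descent followed by conjugate-gradient refinement.

    The descent phase uses backtracking line search (energy never increases
    across accepted steps); the remaining iteration budget goes to scipy's
    nonlinear CG.  Convergence means the gradient max-norm fell below
    ``gtol``.
    """
    x = system.check_coords(coords).copy()
    sd_iters = max(1, int(max_iter * sd_fraction))
    alpha = 1e-3
    e = system.energy(x)
    for _ in range(sd_iters):
        g = system.gradient(x)
        gnorm = float(np.max(np.abs(g)))
        if gnorm <= gtol:
            return MinimizeResult(x, e, gnorm, True, "converged in steepest descent")
        for _ in range(40):
            x_new = x - alpha * g
            e_new = system.energy(x_new)
            if e_new <= e:
                x, e = x_new, e_new
                alpha *= 1.25
                break
            alpha *= 0.5
        else:
            break  # line search stalled; hand over to CG

    shape = x.shape

    def fun(flat: np.ndarray) -> float:
        return system.energy(flat.reshape(shape))

    def jac(flat: np.ndarray) -> np.ndarray:
        return system.gradient(flat.reshape(shape)).ravel()

    res = _opt.minimize(
        fun,
        x.ravel(),
        jac=jac,
        method="CG",
        options={"maxiter": max(1, max_iter - sd_iters), "gtol": gtol},
    )
    x_out = res.x.reshape(shape)
    if res.fun > e:  # CG must not hand back something worse
        x_out, res_fun = x, e
    else:
        res_fun = float(res.fun)
    gnorm = float(np.max(np.abs(system.gradient(x_out))))
    return MinimizeResult(
        coords=x_out,
        energy=res_fun,
        grad_norm=gnorm,
        converged=gnorm <= gtol,
        message=str(res.message),
    )


def first_passage_steps(
    system: ModelSystem,
    x_start: float,
    x_target: float,
    config: SimulationConfig,
    boost: BoostParams | None = None,
    max_steps: int = 20_000_000,
) -> int | None:
    """Steps until a 1-D, one-particle system first reaches ``x_target``.

    Starts from rest-frame Maxwell velocities at the target temperature.  For
    the quartic double well a scalar fast path replicates the BAOAB update
    with plain floats; other systems go through the generic integrator.
    Returns ``None`` when ``max_steps`` elapse without a crossing.
    """
    if system.dim != 1 or system.n_particles != 1:
        raise ValueError("first_passage_steps supports one-particle 1-D systems")
    if config.boost_mode != "none" and boost is None:
        raise ValueError("boost parameters required unless boost_mode='none'")
    upward = x_target > x_start
    rng = np.random.default_rng(config.seed)

    term = system.terms[0]
    if len(system.terms) == 1 and isinstance(term, QuarticDoubleWell):
        return _fast_double_well_fpt(
            term, system.masses[0], x_start, x_target, config, boost, rng, max_steps
        )

    x = np.array([[float(x_start)]])
    v = _draw_velocities(rng, system.masses, 1, config.temperature)
    force = None
    for step in range(1, max_steps + 1):
        x, v, force, _ = langevin_step(system, x, v, config, rng, boost, force)
        pos = x[0, 0]
        if (upward and pos >= x_target) or (not upward and pos <= x_target):
            return step
    return None


def _fast_double_well_fpt(
    term: QuarticDoubleWell,
    mass: float,
    x_start: float,
    x_target: float,
    config: SimulationConfig,
    boost: BoostParams | None,
    rng: np.random.Generator,
    max_steps: int,
) -> int | None:
    h, w = term.h, term.w
    dt = config.timestep
    accf = ACC / mass
    half_kick = 0.5 * dt * accf
    c1 = math.exp(-config.collision_frequency * dt)
    c2 = math.sqrt(max(1.0 - c1 * c1, 0.0))
    sigma = math.sqrt(KB * config.temperature * ACC / mass)
    mode = config.boost_mode
    use_total = mode in ("total", "dual")
    E_P = boost.E_P if boost is not None else 0.0
    a_P = boost.alpha_P if boost is not None else 1.0
    upward = x_target > x_start

    def force_at(x: float) -> float:
        q = (x / w) ** 2 - 1.0
        f = -4.0 * h * q * x / (w * w)
        if use_total:
            V = h * q * q
            if V < E_P:
                s = a_P / (a_P + E_P - V)
                f *= s * s
        return f

    x = float(x_start)
    v = sigma * float(rng.standard_normal())
    f = force_at(x)
    chunk = 8192
    step = 0
    while step < max_steps:
        noise = rng.standard_normal(chunk)
        for i in range(chunk):
            v += half_kick * f
            x += 0.5 * dt * v
            v = c1 * v + c2 * sigma * noise[i]
            x += 0.5 * dt * v
            f = force_at(x)
            v += half_kick * f
            step += 1
            if (upward and x >= x_target) or (not upward and x <= x_target):
                return step
            if step >= max_steps:
                break
    return None
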
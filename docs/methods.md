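# Methods

## Scope and model philosophy

`boostmd` is a reference implementation of dual-boost accelerated dynamics
with canonical reweighting.  Instead of an all-atom force field in explicit
solvent — where none of the interesting quantities can be checked on one
core — it carries two model systems chosen so that every pipeline stage has
an independent oracle:

* a **1-D quartic double well** `V(x) = h((x/w)² − 1)²` whose Boltzmann
  distribution is computable by quadrature, used to verify the boost forms,
  the integrator and the reweighting estimator quantitatively; and
* a **coarse-grained Gō-like helical peptide** (one bead per residue) whose
  native state is an analytically constructed ideal helix, used to exercise
  the full folding workflow: pre-run → thresholds → boosted dynamics →
  RMSD/contacts/Rg/helix-content/clustering → reweighted free-energy
  landscape.

Units everywhere: Å, ps, amu, kcal/mol, Kelvin; `k_B = 0.0019872041`
kcal/mol/K.

## The boost potential and its forces

A single boost branch adds `ΔV = (E − V)²/(α + E − V)` whenever `V < E` and
nothing otherwise.  The branch `ΔV = 0` for `V ≥ E` is implied by the
requirement that the boost be non-negative and is standard practice; both
`ΔV` and the force correction are continuous at `V = E`.  The boosted force
follows from the chain rule: the gradient of a boosted branch is the plain
gradient times `s(V) = α²/(α + E − V)²`, a factor in (0, 1].

Dual boost composes two independent additive branches: the total-potential
branch is thresholded against `V` itself, not against the dihedral-boosted
energy.  The modified gradient is

```
∇V' = s_P(V)·∇V + (s_D(V_D) − 1)·∇V_D ,
```

which is the exact gradient of `V + ΔV_P(V) + ΔV_D(V_D)` (asserted against
finite differences in the tests).  Some production codes instead feed the
dihedral-boosted energy into the total branch; that nested composition is
available behind `nested_total_boost` and its force is likewise the exact
gradient of the nested `V'`.

## Threshold estimation

`E_D = E_D' + a1·N_res/5`, `α_D = a1·N_res/5`, `E_P = E_P' + a2·N_atom`,
`α_P = a2·N_atom`, with `a1 = 3.5`, `a2 = 0.2` kcal/mol as defaults.  The
pre-run averages discard the first half of frames by default (`burn_in =
0.5`): the pre-run follows a heating ramp, so an equilibration allowance is
the conservative reading; on a stationary series the choice does not shift
the means (tested).  The structural identities `α = E − E'` hold exactly, so
the boost is always active in the typical sampled region.

For the analytic one-particle systems, residue/atom counts have no physical
meaning and the caller supplies effective counts.  The double-well protocol
fixes `N_atom_eff = 35`, making `α_P = 7` kcal/mol — commensurate with the
6 kcal/mol barrier, so the boost flattens the wells without erasing the
landscape.  This is a protocol constant chosen once, not a fitted quantity.

## Integrator

BAOAB splitting of Langevin dynamics: half-kick, half-drift,
Ornstein–Uhlenbeck velocity refresh (`c1 = e^{−γΔt}`,
`c2 = √(1 − c1²)·√(k_BT/m)`), half-drift, half-kick.  With `γ = 0` the
update reduces exactly to velocity Verlet (tested bit-wise against the
closed form), and energy is conserved to < 1% over 10⁴ steps at
`Δt = period/100`.  The Gaussian kick is drawn every step even when `γ = 0`
so that the random stream — and hence the trajectory — is identical across
thermostat and boost settings; this is what makes the "inactive boost ≡
plain dynamics" check bit-for-bit.  The default collision frequency is
1.0 ps⁻¹.  Heating ramps the thermostat target linearly from 0 K to the
production temperature over `heat_ramp_steps`, starting from zero
velocities; ramping the O-step target rather than rescaling velocities keeps
a single integrator path.  Instantaneous temperature is `2·KE/(k_B·n_dof)`
with `n_dof = n_particles·dim` (the Langevin thermostat does not conserve
momentum, so no degrees of freedom are subtracted).

Timesteps: 0.01 ps throughout the shipped protocols.  The stiffest CG term
is the bond (`k = 40` kcal/mol/Å², `m = 110` amu → ω ≈ 17 ps⁻¹), giving
ωΔt ≈ 0.17, comfortably inside the BAOAB stability region; the double well
at `m = 10` amu has ω ≈ 22 ps⁻¹ at the minima, ωΔt ≈ 0.22.  Runs whose
|V| exceeds a configurable ceiling (default 10⁸ kcal/mol) or whose forces go
non-finite are truncated and flagged `diverged` with the offending step.

## Minimisation

Steepest descent with backtracking line search (energy non-increasing by
construction), then nonlinear conjugate gradient (scipy) for the remaining
iteration budget.  Convergence is declared on the gradient max-norm.

## The coarse-grained helix

Geometry: Cα-trace helix with radius 2.3 Å, rise 1.5 Å/residue, 100°
twist/residue (standard α-helix trace values; configurable).  The energy:

| term | form | default |
|---|---|---|
| bonds | `k_b (r − 3.8 Å)²` | `k_b = 40` kcal/mol/Å² |
| pseudo-angles | `k_a (θ − θ₀)²`, θ₀ ≈ 91° from the reference | `k_a = 15` kcal/mol/rad² |
| pseudo-dihedrals (= V_D) | `k_t (1 − cos Δφ) + b (1 − cos 3Δφ)`, Δφ = φ − φ₀, φ₀ ≈ −50° | `k_t = 1.5`, `b = 3.0` kcal/mol |
| native contacts | 12-10 well `ε(5(r₀/r)¹² − 6(r₀/r)¹⁰)` at the native distance | `ε = 1.5` kcal/mol |
| excluded volume | `(σ/r)¹²` on non-native pairs, sep ≥ 3 | `σ = 4` Å |

Native contacts are extracted from the ideal-helix reference with the same
non-adjacent (|i−j| ≥ 2), strictly-< 7.0 Å rule the analysis module uses, so
model and metrics are internally consistent.  The 3-fold torsional term is
what makes folding a rare event: it creates rotamer minima at φ₀ ± 120° with
escape barriers of ≈ 4.5 kcal/mol (≈ 7.5 k_BT at 300 K), so minimisation
from an extended chain lands in kinked traps and plain dynamics stays
trapped on the 10⁵-step scale, while the dihedral boost flattens exactly
these barriers.  All CG parameters are this package's own design choices —
sized once so that the native state is thermally stable at 300 K and the
boosted runs fold on a laptop — and are exposed in the config; no published
force field is being reproduced.

The folding demo uses **dihedral-only boost** by default.  In a solvent-free
model the total potential at the native state sits far below any plausible
threshold derived from unfolded-state averages (`E_P − V` is large compared
to `α_P` because there is no solvent bath dominating V), so the total-branch
force scale — bounded by `(α_P/(2α_P + E_P' − V))² < 0.25` — would flatten
the native well itself and melt the fold.  Dihedral boosting targets the
torsional barriers and leaves the contact funnel intact.  Dual mode remains
available in the config for systems where it is appropriate.

A perfectly collinear extended chain is a measure-zero symmetry trap
(transverse forces vanish identically), so protocol starts use
`perturbed_extended_coords`: a deterministic 0.1 Å transverse helical-phase
offset.

## Reweighting and free-energy surfaces

Frame weights `w_i ∝ exp(ΔV_i/k_BT)` are computed in log space with
max-subtraction, so arbitrarily large biases stay finite.  For a single
boosted trajectory the multi-window weighted-histogram estimator reduces to
a one-window weighted histogram, which is what is implemented; multiple
seeds are combined by concatenating frames and normalising weights jointly.
Default grid: 50 × 50 bins over the observed CV range padded by 5%; a
degenerate (constant) CV gets a token unit-width bin.  Empty bins carry
probability 0 and free energy +∞, distinct from occupied high-energy bins;
the occupied minimum is shifted to zero.  Per-bin Kish effective sample
sizes `(Σw)²/Σw²` are reported, and all quantitative PMF statements are
conditioned on bins with ≥ 100 effective samples.  A second-order
cumulant-expansion estimator (per-bin `−kT ln p* − ⟨ΔV⟩ − Var(ΔV)/2kT`) is
available behind `method="cumulant2"` for high-variance biases; it is an
alternative estimator from the general reweighting literature, not the
default.  Exponential reweighting on these few-degree-of-freedom systems is
well conditioned (ΔV spans only a few k_BT within a bin), which is why the
double-well PMF matches quadrature to < 0.2 k_BT in the shipped experiment.

The lowest-free-energy state is the occupied bin with minimal F; its
representative frame is the highest-weight frame in the bin, earliest frame
on ties.

## Analysis conventions

* **RMSD**: Kabsch least-squares superposition (proper rotation enforced)
  over a configurable selection; the CG system defaults to all beads.
  Near-collinear selections are computed with a warning (the rotation is not
  unique).
* **Native contacts**: "non-adjacent" is read literally as |i − j| ≥ 2;
  stricter conventions (≥ 3, ≥ 4) are a parameter.  Cutoff comparisons are
  strict (< 7.0 Å).
* **Helix content**: fraction of consecutive-quadruple pseudo-dihedrals
  within ±30° (configurable) of the ideal-helix value.  This is an artifact
  definition at trace resolution — no secondary-structure assignment (DSSP
  etc.) is attempted.
* **Clustering**: average-linkage agglomerative clustering on the pairwise
  superposed-RMSD matrix; deterministic given frame order.  Populations are
  reported in descending order; a cluster's representative minimises the
  mean RMSD to its members (earliest frame on ties).  The linkage name is
  recorded in the result.

## Problem sizes of the shipped experiments

Chosen so the whole suite runs on one core in a few minutes: double-well
pre-runs 5×10⁴ steps; PMF production 6×10⁵ steps (1.2×10⁵ frames, 48 bins);
first-passage 20 replicates per method (typical plain-dynamics crossings
arrive within ~10⁶ steps at `h = 6` kcal/mol, 300 K); folding demo 5
replicates × 2×10⁵ boosted steps for the 15-residue helix; clustering 200
frames.  The numba-compiled CG force kernel makes these sizes cheap; without
numba the same code runs ~10× slower through the per-term numpy path.

## Known limitations

* Model systems only: no all-atom force fields, solvent, electrostatics,
  or constraint algorithms; nothing here calibrates against experimental
  folding data.  Passing tests demonstrate the correctness of the boost,
  reweighting and analysis machinery, not the realism of the CG landscape —
  real proteins have rugged, many-basin landscapes the single-funnel Gō
  model deliberately lacks.
* Exponential reweighting degrades exponentially with the within-bin
  variance of ΔV; for large solvated systems the cumulant estimator (or
  per-term reweighting schemes beyond this package's scope) would be
  required.
* No error bars on free-energy surfaces (bootstrap machinery is future
  work); effective sample sizes are reported instead.
* First-passage measurements use a scalar fast path for the double well
  that replicates the BAOAB update with plain floats; it is statistically
  equivalent but not bit-identical to the array integrator.
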
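# boostmd

Dual-boost accelerated Langevin dynamics, canonical reweighting and folding
analytics on desk-scale model systems.

## The problem

Plain molecular dynamics spends nearly all of its time trapped in low-energy
basins: barrier crossings are exponentially rare, so slow conformational
events such as protein folding are out of reach at accessible simulation
lengths.  Accelerated molecular dynamics (aMD) attacks this without choosing
a reaction coordinate in advance.  Wherever the potential falls below a
threshold *E* it adds a non-negative boost

```
V'(r) = V(r) + ΔV(r),
ΔV(r) = (E_P − V(r))² / (α_P + E_P − V(r))  +  (E_D − V_D(r))² / (α_D + E_D − V_D(r))
```

with one branch acting on the total potential *V* and one on the dihedral
component *V_D* ("dual boost").  Basins are flattened, barriers shrink, and
transitions speed up while the landscape above the thresholds is untouched.
The four parameters come from a short unbiased pre-run:

```
E_D = E_D' + a1·N_res/5    α_D = a1·N_res/5
E_P = E_P' + a2·N_atom     α_P = a2·N_atom
```

where `E_P'`, `E_D'` are the pre-run mean total/dihedral energies,
`a1 = 3.5` and `a2 = 0.2` kcal/mol by default, and `N_res`, `N_atom` are
residue and atom counts.  Canonical statistics are recovered afterwards by
weighting every boosted frame with the Boltzmann factor of its bias,
`w_i ∝ exp(ΔV_i / k_B T)`, and free-energy landscapes are built as weighted
histograms over collective variables — here RMSD to the native structure and
radius of gyration, with `F = −k_B T ln p` shifted to zero at the minimum.

`boostmd` implements this whole pipeline — boost potential and modified
forces, BAOAB Langevin integration, threshold estimation, exponential
reweighting, and the folding metrics used to judge convergence (optimal
superposition RMSD, fraction of native contacts *Q* at the non-adjacent
< 7 Å convention, radius of gyration, helix content, average-linkage
trajectory clustering) — on model systems small enough that every stage is
verifiable against closed forms or quadrature: a 1-D quartic double well and
a coarse-grained Gō-like helical peptide (one bead per residue, with
torsional rotamer barriers so that folding is a genuine rare event).  It is
aimed at method developers and students who want an end-to-end, testable
aMD reference rather than a production MD engine.

## Worked example

Fold the 15-residue coarse-grained helix from an extended chain, boosted vs
plain dynamics, three replicates:

```bash
boostmd demo-fold --seed 1 --n-seeds 3 --steps 150000 --out demo_out
```

Output (about a minute; details under `demo_out/summary.json`):

```
INFO boostmd: folding demo: 3 replicates, 150000 steps each, master seed 1
INFO boostmd: folded 3/3 replicates; lowest free-energy state at RMSD=0.45 A, Rg=7.05 A
{"n_folded": 3, "n_seeds": 3, "lfes_rmsd": 0.4457528001474946, "lfes_rg": 7.048346796119004}
```

Each replicate runs minimisation, a heating ramp, an unbiased pre-run that
sets the boost thresholds, then dihedral-boost production.  "Folded" means
the median RMSD to the ideal helix stays below 1.5 Å and the median
native-contact fraction above 0.8 over the final fifth of the trajectory.
The reweighted (RMSD, Rg) free-energy landscape over all replicates puts the
lowest free-energy state at RMSD ≈ 0.45 Å — the native helix — while the
matched plain-MD controls in `summary.json` stay trapped at 3–4 Å.  The
`simulate`, `thresholds`, `analyze` and `reweight` subcommands expose the
individual stages on a YAML config (see `boostmd --help`).

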
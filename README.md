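# bindkin

Reusable analysis pipeline for reconstructing **small-molecule binding
kinetics and thermodynamics** from molecular-dynamics trajectories of a
receptor–ligand system, in the style used for ligand binding to aminergic
GPCRs: binary protein–ligand contact featurization → TICA → k-means
discretization → reversible Markov state model (MSM) → PCCA metastable
macrostates with a bulk split → core-set re-estimation → mean first passage
times, association rate and per-state free energies.  It also covers the two
companion analyses such a study needs: radioligand competition-assay
arithmetic (IC50 fitting, Cheng–Prusoff K_i, mutant fold shifts, ΔG) and
structure geometry (χ1/χ2 sidechain rotamers, Kabsch superposition, key
distances, representative-pose selection).

## Who it is for

Computational chemists and structural bioinformaticians who have (or
simulate) unbiased ligand-binding trajectories and want interpretable state
models and kinetic constants, plus a fully synthetic testbed so the whole
machinery can be validated without any proprietary trajectory data.

## The model

Frames are described by two binary contact representations: a residue
contact map (residue *r* is in contact if any of its heavy atoms is < 5 Å
from a ligand feature atom — ligand O, N, and C without bonded hydrogens)
and a bulk flag (ligand < 10 Å from any protein Cα).  TICA solves
`C_τ v = λ C_0 v` for the slowest linear collective coordinates; the
projected data is clustered (mini-batch k-means), transition counts at lag τ
are turned into a maximum-likelihood **reversible** transition matrix `T`
(detailed balance `π_i T_ij = π_j T_ji` enforced by the estimator), and
PCCA lumps the clusters into metastable macrostates; the bulk flag then
splits a separate bulk state out, and core-set milestoning suppresses
spurious recrossings before the final re-estimation.

Kinetics follow from the linear solve `m_i = τ + Σ_j T_ij m_j` (MFPT with
the target states absorbing), the effective concentration of one ligand in
the flat-bottom restraint volume `C_eff = 1/(N_A V)`, and

```
k_on = 1 / (MFPT_on × C_eff),     ΔG_s = −RT ln(π_s / π_bulk),
K_i  = IC50 / (1 + L/K_d),        ΔG_exp = RT ln(K_i / 1 M).
```

A synthetic-data module generates ground-truth 5-state binding chains
(bulk ↔ vestibule → bound, with an intermediate route and an off-pathway
state), toy Langevin binding trajectories under a flat-bottom cuboid
restraint, ideal-geometry phenylalanine fragments, and dose-response curves
— so every stage has an analytic or enumerable oracle.

## Worked example

```python
from bindkin import kinetics as kin, affinity
from bindkin.pipeline import run_synthetic_recovery

box = kin.FlatBottomBox((-20, 20, -20, 20, -20, 35))   # Å
c_eff = kin.effective_concentration(kin.box_volume(box))

ki = affinity.cheng_prusoff(6.8e-9, 1e-9, 1e-9)        # IC50, L, K_d in M
dg = affinity.delta_g_from_ki(ki, 298.0)

r = run_synthetic_recovery(n_traj=200, n_steps=500, seed=1)
```

prints (via the formatting in `scripts/acceptance.py` or your own):

```
restraint volume : 88.0 nm^3
effective conc.  : 18.9 mM
K_i (wt)         : 3.4 nM
dG_exp           : -11.55 kcal/mol
fold shift I183F : 14.0
macrostates      : 5
frame agreement  : 99.8 %
MFPT_on          : 7.28 us  (truth 7.00 us)
k_on             : 7.28e+06 /M/s
indirect pathway : 32.3 %  (truth 33.3 %)
```

The restraint cuboid encloses 88 nm³, so a single confined ligand copy is at
18.9 mM; a 3.4 nM inhibition constant corresponds to −11.6 kcal/mol of
binding free energy; and on synthetic ground-truth data the full pipeline
recovers all five macrostates, the bulk→bound mean first passage time, and
the split between the direct route and the less-populated route through the
intermediate state.

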
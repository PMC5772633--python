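# Methods

This note documents the models, defaults and design choices behind bindkin,
in the spirit of the methods documentation of established kinetic-modelling
packages.

## Contact featurization

Two binary per-frame representations drive everything downstream:

* **Residue contact map.** A protein residue is "in contact" when any of
  its heavy atoms lies strictly closer than 5 Å to any ligand *feature
  atom*.  Feature atoms are the ligand's oxygens and nitrogens plus carbons
  that carry no bonded hydrogen; "not attached to hydrogens" is read as a
  restriction on carbons only — O and N are always included, the standard
  polar-atom convention.  Bonds are inferred from coordinates when no bond
  table exists (cutoff 1.2 × the sum of single-bond covalent radii).
* **Bulk flag.** 1 when any feature atom is strictly closer than 10 Å to
  any protein Cα; flag 0 marks the ligand as free in solvent.  The flag uses
  the same feature atoms as the contact map.

Ties exactly at a cutoff are non-contacts (the criterion is "less than").
Distances are plain Euclidean without periodic wrapping: the analysis
assumes a flat-bottom restraint keeps the ligand in the receptor's primary
image.  Both backbone and sidechain heavy atoms count toward residue
contacts.

PDB input is parsed with biotite; alternate locations are resolved per
(chain, residue, atom-name) group to the highest occupancy, ties to altloc
'A'.  Elements missing from the element column are inferred from atom names
with a warning.

## TICA

Instantaneous (C0) and time-lagged (Cτ) covariances are pooled over
trajectories with a sliding window; the mean and C0 are taken over both the
leading and lagged windows and Cτ is symmetrized, which makes the estimator
exactly invariant under time reversal and keeps eigenvalues real and ≤ 1 up
to sampling noise.  The generalized problem Cτ v = λ C0 v is solved after
projecting onto C0's eigenspace above 1e-8 × its largest eigenvalue —
binary contact data is routinely rank-deficient (constant or linearly
dependent residues).  Components have unit C0-norm; no kinetic-map scaling
is applied.  Note the rank cutoff makes eigenvalues invariant under feature
rescaling only as long as no retained direction is pushed below the
threshold.  The TICA lag is configurable (pipeline default 20 frames, the
same candidate as the MSM lag).

## MSM estimation

Frames are discretized by mini-batch k-means (default k = 800 for
production-scale data; the synthetic validation uses k = 50) with the final
assignment recomputed as exact nearest-center so the rule does not depend
on the mini-batch path.  Sliding-window transition counts at lag τ are
restricted to the largest strongly connected component, and a reversible
maximum-likelihood transition matrix is obtained by the standard fixed-point
iteration on symmetrized flows, x_ij ← (c_ij + c_ji)/(c_i/x_i + c_j/x_j),
converged at a maximum relative change of 1e-10 (hard failure after 1e5
iterations).  π follows from the row sums of x; the spectrum is computed by
symmetrizing with √π, so eigenvalues are exactly real.  Implied timescales
t_i = −τ/ln λ_i over a ladder of lags guide the choice of the working lag
(plateau criterion); non-positive eigenvalues yield NaN with a warning.

## Macrostates, bulk split, cores

PCCA+-style lumping: the top n_macro right eigenvectors form spectral
coordinates, simplex vertices are located by furthest-point (inner-simplex)
search, and memberships are the linear transform mapping vertices to unit
vectors, clipped to [0, 1] and row-normalized; crisp labels are argmax
memberships.  The fuzzy variant is used because core sets need memberships.
After lumping, clusters whose frames are majority (≥ 50%, ties included)
flag-0 are split into an additional bulk macrostate, at cluster granularity
and after PCCA, matching the order of the production protocol.

Core sets are clusters with membership ≥ 0.9 (configurable); a macrostate
whose core would be empty falls back to its maximum-membership cluster with
a warning.  Milestoning operates at cluster granularity: frames outside all
cores take the label of the last visited core cluster, and leading
unassigned frames are discarded.  When bulk flags are available a frame
counts as a core visit only if the two contact representations agree —
its flag must read bulk exactly when its cluster belongs to the bulk
macrostate.  This consistency requirement suppresses single-frame spurious
transitions (e.g., an interacting pose whose contact pattern momentarily
reads as bulk), which would otherwise fabricate binding/unbinding events;
it is the milestoning analogue of using the flag to separate bulk from
interacting states in the first place.

## Kinetics and thermodynamics

MFPTs are solved on the cluster-level (core-level after re-estimation)
transition matrix, m_i = τ + Σ_j T_ij m_j with the target set absorbing;
the source value is the π-weighted average over the source macrostate's
clusters (the source-weighting convention is a design choice; π-weighting
treats the source as locally equilibrated).  MFPT(s→s) ≡ 0.

The effective concentration of one ligand copy in the flat-bottom volume V
is C_eff = 1/(N_A V); the default cuboid [−20, 20] × [−20, 20] × [−20, 35] Å
gives 88 nm³ and 18.9 mM.  k_on = 1/(MFPT_on × C_eff).  Per-state free
energies are ΔG_s = −RT ln(π_s/π_bulk) with R = 1.98720×10⁻³ kcal/(mol·K)
and default T = 298 K; a standard-state-corrected column
ΔG_s + RT ln(C_eff/1 M) is reported alongside, since published per-state
values do not always state which convention they use.

A binding event is the maximal segment from the last bulk visit to the
first subsequent bound visit; it is *indirect* when a marker (intermediate)
macrostate occurs inside the segment.  Fractions are taken over all events,
counted on milestoned macrostate sequences.  Uncertainties come from a
trajectory bootstrap (resample trajectories with replacement, re-estimate
from the count matrix onward, default 100 replicates); replicates that lose
bulk–bound connectivity are skipped and counted, with a warning above 20%.

## Assay arithmetic

Dose-response curves are fit to %inh = 100/(1 + (IC50/c)^h) by bounded
least squares in log10(IC50) (both parameters then have comparable scale),
initialized at the concentration nearest 50%.  The Hill coefficient is
fitted rather than fixed at 1.  Fits whose IC50 leaves the tested range
scaled by [0.01, 100], or flat responses, are flagged rather than raised.
K_i = IC50/(1 + L/K_d); fold shift = K_i^mut/K_i^wt; ΔG = RT ln(K_i/1 M)
at a default 298 K — assays are commonly run at 37 °C, but room-temperature
RT is the convention that reproduces typical reported ΔG values from
nanomolar K_i to within rounding, and the temperature is an explicit
argument everywhere.

## Structure geometry

Dihedrals use the signed IUPAC atan2 convention with results in
(−180°, 180°]; χ1 = N–CA–CB–CG, χ2 = CA–CB–CG–CD1.  χ2 of Phe is reported
as the raw CD1 dihedral — no ring-symmetry folding into (−90, 90] — since
published rotamer surveys list values above 90°.  Superposition is Kabsch
(centroid shift + SVD with reflection correction), requiring ≥ 3
non-collinear pairs; atom pairings across different receptors must be
supplied by the caller (no automatic sequence alignment).  Rotamer outliers
are judged by the circular χ1 distance to a reference set (default
threshold 30°).  Representative poses minimize pocket-atom RMSD after
superposing on a caller-stated alignment selection, ties to the lowest
frame index.

## Synthetic ground truth

The default 5-state chain (bulk, vestibule, intermediate, bound, off-path)
is reversible *by construction*: forward rates were chosen and backward
rates derived from a target stationary distribution π ∝ (0.9, 1, 1, 10, 5),
since the maximum-likelihood estimator assumes detailed balance and an
irreversible truth would confound recovery tests.  Bulk ↔ vestibule
exchange is fast (≈10-step scale), vestibule → bound entry is
rate-limiting, an alternative route runs through the intermediate, and the
off-pathway state exchanges only with bound.  The rates give an analytic
bulk→bound MFPT of 85 steps and an indirect-pathway share of ≈30% of
binding events, and the default step length of 0.0824 μs places MFPT_on at
7.0 μs — the regime reported for slow drug binding to aminergic GPCRs, so
the testbed exercises the pipeline under realistic kinetic contrasts.

States are emitted as 20 binary contact features from per-state template
patterns with every bit flipped independently at 5%, plus a bulk flag
wrong at 5%.  This emulates the *statistical* structure the analysis
assumes — metastable states with distinct contact signatures and imperfect
featurization — but not the continuous geometry of real trajectories: noise
here is frame-i.i.d., so single-frame "teleports" between distant states
can occur, which real dynamics forbids.  Passing recovery tests therefore
demonstrates correctness of the estimators and robustness to label noise,
not force-field-level realism.

The toy Langevin simulator is Euler–Maruyama with isotropic,
position-independent diffusion among Gaussian wells; outside the restraint
cuboid a force of magnitude k_fb × (distance beyond the boundary) pulls
toward the reference receptor site.  The restraint is harmonic in the
*boundary excess*, not in the full distance to the reference — the
published description is ambiguous between the two and the boundary-excess
form leaves interior dynamics strictly unbiased, which is the stated
purpose of a flat-bottom potential.  At temperature 0 the update
degenerates to noiseless gradient descent with step D per unit force (the
fluctuation–dissipation prefactor D/kT is undefined at T = 0).  Trajectory
sampling uses one substream per trajectory derived from (seed, index), so
increasing the trajectory count never alters earlier trajectories.

## Problem sizes and numerical defaults

The self-validation experiment runs 1000 trajectories × 1000 steps
(10⁶ frames), k = 50 clusters, TICA/MSM lag 5 steps, PCCA into 4
macrostates + bulk split, core threshold 0.9 — sizes at which the analytic
truth is recovered well within sampling error (frame agreement ≈ 99.7%,
MFPT error < 2%, pathway split within ~2 percentage points) and a full run
takes well under a minute on one CPU.  The adaptive-sampling respawn rule
(weights ∝ 1/(1 + visit count)) is a documented stand-in for the published
protocol, whose exact criterion is specified elsewhere; it preserves the
qualitative behaviour (under-visited states are favoured, all-zero counts
reduce to uniform).

## Known limitations

* No hidden-Markov or Bayesian MSM estimators; errors are trajectory
  bootstrap only, which understates model-selection uncertainty.
* PCCA+ uses inner-simplex initialization without the subsequent
  feasibility optimization; adequate for well-separated metastable spectra,
  less so for nearly degenerate eigenvalues.
* The contact featurizer reads PDB plus plain-text XYZ/array coordinates;
  binary MD formats (DCD/XTC) are out of scope.
* k_on is the reciprocal of MFPT_on times C_eff; averaging conventions
  (e.g., per-bootstrap harmonic means) can shift the central value by tens
  of percent within the same uncertainty band, so published central values
  computed differently need not coincide with the reciprocal formula.
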
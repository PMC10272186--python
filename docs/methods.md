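# Methods

This note documents the models, algorithms, default parameters and design
choices behind `allostate`, and what the toy studies do and do not show.

## Toy dynamics

**Integrator.** Overdamped (Brownian) Euler–Maruyama:
`x_{t+1} = x_t − (Δt/γ) ∇U(x_t) + √(2kT Δt/γ) ξ_t`, with ξ standard
normal. Its stationary law is `exp(−U/kT)/Z`, which is all the downstream
statistics need; inertial detail, thermostats and barostats of a real MD
engine are irrelevant at this scale and deliberately omitted. Energies are
in kT, time in integrator steps; no physical unit conversion is attempted.
One named random generator per trajectory, seeded from (run seed,
trajectory index) through a `SeedSequence`, makes seed sets reproducible
under parallel launch and independent of launch order.

**Potential.** The two-basin landscape is a tilted quartic along the axis
joining the declared minima. With `u` the fractional position between
minima `m0` and `m1` and `v` the transverse displacement:

    U = 16 b u²(1−u)² + Δ u²(3−2u) + ½ k_t v² + c u(1−u) v

- `b` (`barrier_scale`, default 2.5 kT; 2.2 kT in the standard toy study)
  is the barrier height of the untilted well.
- `Δ = d_a − d_b` is the depth difference; the smoothstep tilt has zero
  slope at u = 0, 1, so the declared minima are exact stationary points and
  the energy gap between them is exactly `Δ`.
- `k_t` (`stiffness`, default 10 kT per unit²) confines the transverse
  coordinate; `c` (`coupling`, default 0) skews the saddle region without
  moving the minima.

This form was chosen over e.g. a Gaussian-well mixture because it keeps the
declared minima exact, has an analytic gradient, and grows at large |u|, so
the Boltzmann weight is normalisable (a Gaussian mixture flattens at
infinity and has no equilibrium).

**Steering.** A harmonic restraint on one feature whose force constant
ramps linearly from 0 to k over `ramp_steps` while the centre holds at the
start value — the force-application stage — after which the centre moves
linearly to the target, reaching it at `total_steps`. The post-ramp centre
schedule is not dictated by the real protocol being emulated; linear is the
simplest choice and is documented as such. Flat-bottom restraints
contribute zero energy inside `[lower, upper]` and half-harmonic energy
`½k·excess²` outside, as used to keep weakly bound ligands posed.

**Blow-up handling.** Non-finite coordinates at a save point abort with the
integrator step named. Intermediate overflow warnings are suppressed; the
explicit finiteness check is the detector.

## Featurization

- RMSD uses Kabsch superposition (SVD rotation after centroid alignment),
  with the residual evaluated on the superposed coordinates rather than an
  rssd-style formula, which loses half the machine precision to
  cancellation. The fit set equals the measured set. Fewer than three
  non-collinear atoms make the rotation ill-defined: a warning is issued
  and a translation-only fit used.
- Dihedrals follow the IUPAC sign convention (positive = clockwise rotation
  of the far bond viewed along the central bond), range (−180°, 180°].
  Rotamer labels depend on this convention; the rotamer histogram's windows
  are stated in it.
- "Backbone" means atoms N, CA, C, O; selections match on (1-based residue
  id, atom name), as in PDB records.
- Multi-model PDB parsing is delegated to biotite; frame order follows
  MODEL order, and an atom-count mismatch names the offending model. Plain
  XYZ and delimited feature tables are parsed directly.

## Seeding

"Evenly sampling" the steered coordinate is read as even in *coordinate
value*: targets are linearly spaced over the observed [min, max] and each
target takes its nearest frame (earliest frame on ties). Two targets can
pick the same frame when the coordinate is coarsely sampled; duplicates are
collapsed and the shortfall reported rather than silently padded, so the
swarm size is never quietly inflated with identical replicas.

## Markov state models

- **Counting** is sliding-window: every pair (x_t, x_{t+τ}) of every
  trajectory contributes; trajectories are never concatenated.
- **Active set**: the largest strongly connected component of the count
  graph (ties broken towards more counts). States outside it keep π = 0 —
  the same convention as "microstates a system never visits have zero
  stationary probability". Whether the emulated protocol applied ergodic
  trimming is not documented; this behaviour is the package's own and is
  stated here rather than asserted of anyone else's.
- **Estimation** is reversible maximum likelihood by default (the default
  of standard MSM tooling), via the self-consistent fixed-point iteration
  on the symmetric flux matrix `x_ij = (C_ij + C_ji)/(c_i/x_i + c_j/x_j)`,
  iterated to a max elementwise change below 1e-12 on the normalised flux.
  Non-reversible row normalisation is available and tested. Tolerances:
  rows of T sum to 1 within 1e-12; πT = π within 1e-10; detailed balance
  within 1e-8.
- **Spectra**: reversible models are diagonalised through the symmetrised
  matrix `diag(√π) T diag(1/√π)` (real spectrum guaranteed); non-reversible
  models use a general eigensolver and sort by |λ|.
- **Implied timescales** `t_i = −τ/ln|λ_{i+1}|` are reported per lag;
  non-positive eigenvalues or insufficient data yield NaN — flagged, not
  dropped.
- **Chapman–Kolmogorov**: macrostate-aggregated `T^m` against re-estimated
  models at lag mτ, with binomial-approximation error bars
  `√(p(1−p)/N_A)`, N_A the transition count out of the macrostate at that
  lag.
- **PCCA+** uses the inner-simplex construction on the first m right
  eigenvectors (simplex vertices found by successive orthogonal
  projection, memberships by the inverse vertex matrix, clipped and
  renormalised; crisp assignment is the argmax). Non-reversible models are
  reversibilised (symmetrised flux) for this analysis. The macrostate whose
  member microstates have the lower mean first-feature value (an RMSD-like
  coordinate: low = closed = active) is labelled "active"; with more than
  two macrostates, only the lowest-mean one is active.

## Multi-system comparison

All systems are discretised with a single k-means model fitted on pooled
frames (k-means++ with one deterministic initialisation per seed, Lloyd
iterations, up to 500; assignment is nearest centre with the lowest index
on ties). The reference PCCA partition is transferred to all k microstates,
with reference-unsampled microstates assigned inactive — a conservative
choice: population a ligand system moves into conformations the reference
never visits can only *lower* its active-state probability.

Bootstrapping draws `n_traj` trajectories with replacement per iteration
(resampling with replacement is the standard bootstrap and the only reading
under which drawing 200 of 200 available trajectories is a resample),
re-estimates the transition model at the fixed lag with the fixed
microstate and macrostate definitions, and records the active-state
probability. An iteration whose resample has no connected counts records 0
with a warning. Classification compares medians with an absolute threshold
δ = 0.05: the underlying decision in the emulated workflow is visual, so
both medians and the full distributions (plus the fraction of system
values inside the reference range) are reported for users who prefer other
rules.

## Ensemble reweighting

A frame in microstate i gets weight `p_i / n_i` (n_i frames observed in i),
so weighted microstate frequencies reproduce the probabilities exactly;
probability mass on microstates with no frames cannot be represented and is
dropped with a warning, then renormalised. Frames are resampled with
replacement (10,000 draws by default). Metastable (per-macrostate)
distributions are membership-weighted, π-reweighted microstate
probabilities, renormalised — the natural formula for a quantity usually
named without one. Rotamer windows: "up" = [−120°, 0°), "down" =
[−180°, −120°) ∪ [120°, 180°], anchored at the −60° ("up") and −180°
("down") χ1 readings; they are configurable.

## Workflow defaults and the standard toy study

`ProtocolConfig` defaults mirror the printed protocol of the emulated
workflow: 100 seeds per steering direction (200 seeded trajectories per
system), 5000 saved frames per trajectory, 100 microstates, lag 2000
frames, 100 bootstrap iterations over 200 resampled trajectories, two
macrostates, δ = 0.05. Steering runs in both directions and the two seed
lists are interleaved. All stage seeds derive from the master seed and the
*system label* (via CRC-32), so adding or removing one system never
perturbs another system's simulations; the pooled cluster model, by
construction, does depend on which systems are pooled.

The standard toy study (`toy_experiment_config`) scales this down so the
full protocol runs in ~10 s: basins at (0.5, 0.3) ("active") and
(2.5, 0.9) ("inactive"), depths 3.5 kT, barrier 2.2 kT, kT = 1, Δt = 0.008,
γ = 1; 2 × 30 seeds → 60 trajectories of 2000 frames (stride 10) per
system; 30 microstates; lag 10 frames; bootstrap 40 × 60. These sizes come
from a design-stage variance pilot: they put the replicate-to-replicate
spread of the control shift (SD ≈ 0.018) well below the 0.05 decision
threshold, so a planted 2 kT destabilisation (true shift ≈ −0.35) is
essentially always recovered while an identical-potential control is
essentially always called "no effect". The lag sits past the knee of the
implied-timescale curve for this landscape (slow process ≈ 330 frames,
next ≈ 27).

## What the toy data do and do not show

The generator reproduces the *statistical structure* the protocol relies
on: metastable two-basin dynamics in a 2-D feature plane, steering that
manufactures transitions, swarms that relax locally, and population shifts
induced by basin destabilisation. It does not emulate real protein data:
features are sampled exactly (no projection noise from discarded degrees
of freedom), the dynamics are genuinely Markovian in the feature plane (no
hidden slow degrees of freedom beyond the two coordinates), trajectories
are statistically homogeneous, and ligands act directly on the potential
rather than through binding-pose kinetics. Passing tests therefore
validate the estimators, the lumping, the transfer/bootstrap logic and the
classification — not the adequacy of any particular feature choice for a
real protein, which remains the user's modelling decision.

## Known limitations

- Steering acts on a single collective variable; multi-CV schedules are
  not implemented.
- No Bayesian MSM errors, TICA, hidden Markov models or VAMP scoring; the
  bootstrap is the only uncertainty quantification.
- The CK error bars use a binomial approximation that ignores frame
  correlation within trajectories, so "within 3 error bars" is a
  diagnostic, not a calibrated test.
- Binary trajectory formats (DCD/XTC) are out of scope for the readers;
  convert to multi-model PDB, XYZ or feature tables first.
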
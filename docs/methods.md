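# Methods

## The model

Each subject-run data matrix (voxels × timepoints, demeaned and
variance-normalised per voxel) is factorised as

    D[s,r] = P[s] · diag(h[s,r]) · A[s,r] + ε[s,r]

- **Spatial maps `P[s]`** (voxels × modes) are shared across a subject's
  runs. Every voxel-mode weight follows a double-Gaussian mixture: a
  *signal* component `N(μ[v,k], 1/τ_sig[v,k])` whose mean is the
  hierarchical group map, and a *background noise* component
  `N(0, 1/τ_noise[v,k])`, with a per-voxel-mode membership probability
  `π[v,k]`. The group holds conjugate posteriors over all four fields:
  Gaussian (signal means), Gamma (signal and noise precisions) and Beta
  (memberships).
- **Timecourses `A[s,r]`** (modes × timepoints) follow a Gaussian process
  prior `vec(A) ~ N(0, α⁻¹ ⊗ Q)`, where `α` is the run's cross-mode
  precision matrix and `Q` is a fixed temporal kernel with unit diagonal,
  `Q = 0.8·K_hrf + 0.2·I`: the stationary autocorrelation of white noise
  convolved with the canonical double-gamma haemodynamic response plus a
  white floor. The additive kernel realises the timecourse
  signal-plus-noise split as one Gaussian prior, which keeps the per-run
  posterior an exact joint Gaussian (see *Numerics*).
- **Cross-mode precisions `α[s,r]`** have Wishart posteriors with a
  hierarchical link: the prior on each run's precision is
  `Wishart(G⁻¹, ν_link)` where the group-level inverse scale `G` itself
  carries a Wishart posterior. This parameterisation is exactly conjugate
  in both directions (the subject update adds one pseudo-count per
  timepoint plus the `Q`-metric timecourse scatter; the group update
  accumulates expected subject precisions). `ν_link` (default
  `n_modes + 20`) sets how strongly run precisions shrink to the group.
- **Amplitudes `h[s,r]`** are positive per-mode scalings modelled on the
  log scale with a hierarchical Gaussian group mean (diagonal covariance,
  per-run spread `amplitude_log_sd = 0.5`). Their updates are exact
  coordinate maximisers of the variational objective (point-mass
  convention; a Laplace curvature is reported as posterior spread).
  This is deliberate: a Laplace-approximate "posterior" would break the
  free-energy monotonicity guarantee that every other (conjugate) update
  enjoys.
- **Residuals** have per-run Gamma posteriors over an isotropic precision.

The split of a mode's magnitude between `h`, the map norm and the
timecourse norm is a gauge freedom; only their product is identifiable,
and the evaluation utilities treat it accordingly.

### Free energy

`free_energy` returns the evidence lower bound with a per-term ledger
(data fit, spatial/temporal/precision/noise KL terms, amplitude log-prior,
group KL). All expectations are taken consistently with the update
equations, so each single-factor update provably does not decrease the
full-data objective — a property the test suite asserts per factor. With
a subject subset and `scale = N` (the number of batches), the local terms
are multiplied by `N`, giving the unbiased batch estimate used by the
stochastic engine (verified exactly by enumeration at S=6, K=2).

## Stochastic inference

Group posteriors are the global variables of stochastic variational
inference. Per batch: subjects are drawn without replacement with
weights `1/(1 + visits)`; first visits are initialised from the initial
maps, revisits resume stored posteriors; `n_initial_updates` sweeps run
with the group frozen (aligning subjects to the group), then
`n_full_updates` joint sweeps produce an intermediate group state with
the factor-`N` scaling; finally the running state is blended,
`θ_t = (1−ρ_t)·θ_{t−1} + ρ_t·θ̂_t` with `ρ_t = (t+τ)^(−β)`, once per
batch, in natural parameters (for every factor here, elementwise convex
combination of the stored conjugate parameters). Defaults mirror the
reference large-cohort operating point: batches of 50, τ = 5, β = 0.6,
10 initial + 20 full updates. After the last batch every subject is
re-updated against the frozen final group so all posteriors refer to one
group model. With one whole-population batch and ρ = 1 the engine is
bit-for-bit classic full-batch VB (tested).

Two engine details are not dictated by the model and were fixed as
design choices: the batch index for `ρ_t` increments once per batch (not
per sweep), and blending happens once per batch using the group state
after the last full update. Subject posteriors can be stored on disk
(one file per subject) so resident memory scales with the batch, not the
population; the in-memory store is the default at the scales used here.

A mode whose membership mass collapses for a subject carries no evidence
and cannot recover by coordinate ascent (the "missing mode" degeneracy).
`run_batch` therefore re-seeds collapsed modes (< 0.5% membership mass)
from the current group model between the frozen-group and joint sweeps —
a restart of a degenerate local optimum, not part of the variational
calculus; the final pass never does this, preserving its fixed-point
property.

### Initialisation

MIGP (incremental group PCA) visits subjects one at a time, keeping a
running time-reduced matrix of at most `2·n_modes` rows (strict
one-subject-at-a-time streaming). Fixed-point ICA (FastICA, logcosh) on
the singular-value-weighted basis yields `n_modes` initial maps with
fixed conventions (nonnegative skewness, unit variance, descending
explained variance, deterministic seed). Initialisation only needs to
place the group in a realistic ballpark; the hierarchical inference is
the estimator. The same ICA code path provides the baseline's group
maps, so comparisons never reflect a different PCA stage. The initial
maps also seed the group model with pseudo-evidence worth
`init_weight = 5` subjects on the signal means and memberships, which
anchors mode identities during the first batches.

## Simulator

The generator reproduces the study conditions; its defaults are not
tuning knobs.

- **Group maps**: modes are unions of 1–3 contiguous voxel blocks on a
  circular 1-D "brain" (roughly half single-block, half distributed);
  in-mode weights are i.i.d. Gamma(3, 1); block sizes are rescaled so the
  realised mean mode size matches the configuration. Non-overlapping
  layouts place all blocks disjointly (raising an error if infeasible);
  overlapping layouts place blocks uniformly at random. The default
  15-mode configuration (`mean_mode_size = 0.04`) is calibrated to
  ~1.3 modes per active voxel.
- **Subject maps**: each subject receives one smooth low-frequency
  displacement field (4 random Fourier components, unit mean magnitude);
  every block shifts rigidly by the field value at its centre scaled to
  the per-mode misalignment fraction, block boundaries jitter by ±1
  voxel, and background Gaussian noise (sd 0.15) is added. A coherent
  per-subject field, rather than independent random shifts per block,
  is what anatomical misalignment looks like: all of a subject's modes
  move together, preserving their relative geometry and hence their
  identity. (Independent per-block shifts were tried and discarded: they
  make a subject's mode *k* land on the group's mode *j*, so no
  estimator — including the generative truth's population average — can
  identify group modes at high misalignment.) The misalignment fraction
  equals the expected fraction of a mode's support displaced, so
  subject-group overlap is approximately `1 − misalignment` by
  construction (e.g. 0.577 → ~42% overlap).
- **Timecourses**: run precisions are Wishart draws centred on a random
  unit-diagonal group precision (dof `5·n_modes`); neural series are
  correlated Gaussian series with power amplified below 0.1 Hz
  (white + 3.5× low-passed, ~70% of power below 0.1 Hz); BOLD series
  convolve them with a per-run random draw from a canonical-dominant
  three-function HRF basis and are row-normalised. Amplitudes are
  log-normal (sd 0.3).
- **Noise**: Gaussian, scaled to `noise_snr = 0.5` (signal variance over
  noise variance of the whole matrix). The noise level is not printed in
  the source material; 0.5 was calibrated once against the printed
  accuracy statistics — in particular the group-above-subject accuracy
  ordering of the high-dimensional scenarios — and then frozen.

### Scenario presets

- `set1_default`: 15 overlapping modes, 17% misalignment (~83% overlap),
  500 subjects × 2 runs at 10,000 voxels × 300 timepoints (TR 0.72 s).
- `misalignment_{23.1,34.6,46.2,57.7}`: 15 *non-overlapping* modes with
  the stated per-mode misalignment fraction. The printed mode size
  (8.6%) is infeasible for 15 disjoint modes (129% of the brain);
  these presets use 5.8% so the layout exists while the misalignment
  percentages are kept exactly.
- `overlap_{20,30,40}`: modes of mean size 8.6% with an absolute warp of
  3% of the voxel grid per mode; 40 modes give ~3.5 modes per active
  voxel.
- `modesize_{20,30,40}`: constant total overlap with sizes
  6.5% → 3.25%, and a constant physical displacement budget of 1.3% of
  the grid per mode, so shrinking modes are fractionally more misaligned
  — the property that makes small modes hard at the subject level.

### What the simulator does and does not emulate

The 1-D circular geometry preserves the statistics that matter to the
factorisation (mode sizes, overlaps, misalignment fractions, temporal
structure, SNR) but not 3-D anatomy: there is no spatial smoothness of
the noise, no physiological or acquisition artefact modes, and no
haemodynamic variability across voxels. Tests passing on these
populations demonstrate correct inference under the stated generative
assumptions, not performance on real scanner data.

## Evaluation protocol

Estimated decompositions are identifiable only up to mode permutation
and sign, so comparisons pair modes by optimal assignment (Hungarian
algorithm on absolute Pearson correlations), with signs chosen to make
paired correlations positive. Group-level accuracies pair the estimated
group maps against the true group maps once. Subject-map accuracies pair
each subject's maps against that subject's own ground truth: under heavy
misalignment a subject's modes legitimately sit far from the group
layout, and per-subject pairing scores map recovery without conflating
it with group-level identity errors. One-to-one flags use the
|r| > 0.7 criterion with a two-standard-deviation gap to the next-best
match. All metrics are invariant to relabelling and sign flips.
"Accuracy" is the mean of per-mode correlations, averaged over modes
then subjects; missing (all-zero) modes are excluded from means and
counted separately.

## Numerics

- The temporal posterior is computed exactly by simultaneous
  diagonalisation: with `B` solving the generalized eigenproblem of the
  likelihood Gram against `E[α]`, every rotated-timepoint covariance is
  `B·diag(1/(w + 1/q_j))·Bᵀ`, turning T matrix inversions into one K×K
  decomposition.
- Spatial modes are swept sequentially (each mode sees the others'
  freshest expectations), which is what makes the sweep a chain of exact
  coordinate updates.
- SPD repairs: symmetrise plus `1e-8·trace/n` jitter; amplitude Newton
  iterations are safeguarded by a grid scan on the first sweep; variance
  normalisation floors row variances at `1e-8` and zeroes (and flags)
  constant voxels.
- Degenerate inputs raise errors early: empty masks, all-constant data,
  infeasible mode layouts, rank-deficient dual-regression designs (with
  the collinear modes named), invalid Wishart degrees of freedom.

## Problem sizes

The packaged evaluation (scripts/acceptance.py) runs the three
high-dimensional scenarios at 100 subjects × 2 runs, 2000 voxels, 150
timepoints, with stochastic schedules of 10–12 batches of 20 subjects
(misalignment: 10 initial + 20 full updates; overlap/mode-size: 6 + 10).
The test suite uses 40 subjects × 1200 voxels × 100 timepoints for the
scenario criteria and smaller toys for the exact-identity properties.
These sizes are the package's reduced-scale operating points; the
generative settings (mode counts, sizes, overlaps, misalignment
fractions, SNR) are identical to the full-scale configuration.

## Known limitations

- Group-map accuracy is bounded by the population-consensus ceiling
  (the best any hierarchical average can do under misalignment) and by
  the identifiability of the ICA initialisation under heavy overlap;
  at 3.5 modes per voxel both bind, and the extreme-overlap scenario's
  group accuracies run below the subject-level ones.
- The amplitude/map-norm/timecourse-norm gauge means absolute amplitude
  values are not comparable across models, only their orderings and
  products.
- Membership probabilities are treated with a conjugate Beta group
  posterior; whether the original treats them hierarchically or as group
  point estimates is not documented.
- The engine is single-process; the memory contract comes from the
  disk-backed subject store, not from distribution.
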
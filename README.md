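# spfm — stochastic probabilistic functional modes

`spfm` infers **probabilistic functional modes** — paired spatial maps,
timecourses, amplitudes and between-mode precision matrices — from
multi-subject resting-state fMRI, using a hierarchical Bayesian matrix
factorisation fitted with **stochastic variational inference**. Because
the group model is updated from small random subject batches with a
decaying step size, populations far larger than memory can be analysed;
a final pass re-aligns every subject to the converged group model. The
package is aimed at researchers who want subject-specific functional
modes that remain anchored to a population model, and at methodologists
who need a controlled testbed for comparing mode-estimation pipelines.

Each subject-run data matrix is modelled as

    D[s,r] = P[s] · diag(h[s,r]) · A[s,r] + ε[s,r]

with a double-Gaussian mixture (signal + background, plus a membership
probability per voxel and mode) on the spatial maps `P`, an
HRF-informed Gaussian-process prior on the timecourses `A` whose
cross-mode precision `α[s,r]` is tied to the group through a Wishart
hierarchy, positive amplitudes `h` on the log scale, and Gaussian
residuals. Group-level conjugate posteriors over the spatial fields, the
precision hierarchy and the amplitude means are the global variables of
stochastic VB: per batch, subjects are locally optimised and accumulated
as if the whole population were present, then blended into the running
group state as `θ_t = (1−ρ_t)θ_{t−1} + ρ_t·θ̂_t`, `ρ_t = (t+τ)^(−β)`.

The package also ships:

- a **calibrated multi-subject simulator** (contiguous-parcel modes with
  Gamma weights, smooth per-subject warp fields, hierarchically
  Wishart-correlated HRF-convolved timecourses, controlled overlap /
  misalignment / mode-size / noise) with named evaluation scenarios;
- **MIGP**, incremental group PCA that visits subjects one at a time
  with bounded memory, and a deterministic spatial-ICA initialiser;
- the standard **ICA + dual-regression** comparison pipeline with
  amplitudes and Tikhonov-regularised partial NetMats;
- **evaluation utilities**: optimal mode pairing, accuracy against
  ground truth, subject-to-subject / subject-to-group consistency,
  spatial NetMats with Fisher r-to-Z.

## Worked example

```python
import spfm

cfg = spfm.scenario_presets("set1_default", n_subjects=20, seed=1,
                            n_voxels=1500, n_timepoints=120)
bundle = spfm.simulate(cfg)           # data + full ground truth

def preprocess(d):
    d = d - d.mean(axis=1, keepdims=True)
    return d / d.std(axis=1, keepdims=True)

data = [[preprocess(bundle.data[s, r]) for r in range(cfg.n_runs)]
        for s in range(cfg.n_subjects)]

basis = spfm.migp((d for runs in data for d in runs),
                  n_components=2 * cfg.n_modes)
init = spfm.spatial_ica_init(basis, cfg.n_modes, seed=1)
result = spfm.fit(data, init,
                  config=spfm.StochasticConfig(batch_size=5, n_batches=10,
                                               n_initial_updates=6,
                                               n_full_updates=10, seed=1),
                  model_config=spfm.ModelConfig(n_modes=cfg.n_modes, tr=cfg.tr))

group_acc = spfm.accuracy_report(result.group_maps(), bundle.group_maps)
subject_acc = spfm.accuracy_report(result.group_maps(), bundle.group_maps,
                                   result.subject_maps(), bundle.subject_maps,
                                   pair_per_subject=True)
print(group_acc.mean_group_map_corr, subject_acc.mean_subject_map_corr)
```

This prints `0.799 0.910` (see `examples/fit_hierarchical_model.py`):
after optimal mode pairing, the recovered group maps correlate 0.80 with
the generating group maps and the per-subject maps correlate 0.91 with
each subject's own warped ground truth — the hierarchical model tracks
individual deviations from the group rather than just copying the group
map into every subject. The `examples/` directory holds one short
script per capability (simulation, fitting, the ICA-DR baseline,
evaluation tables, streaming PCA), each printing the numbers it
computes and what they mean.

A thin command-line interface mirrors the pipeline stages for file-based
use (`spfm simulate / migp / init / fit / icadr / evaluate`; see
`spfm --help`).

## Layout

```
src/spfm/
  simulate.py        multi-subject generator + scenario presets
  data_io.py         masked datasets, preprocessing, incremental PCA
  initialization.py  spatial-ICA initial maps
  model.py           conjugate variational updates + free energy
  engine.py          stochastic batching, blending, final pass
  icadr.py           group ICA + dual regression baseline
  metrics.py         pairing, accuracy, consistency, NetMats
  cli.py             thin command-line wrappers
docs/methods.md      model, simulator and protocol details
examples/            one narrative script per capability
```
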
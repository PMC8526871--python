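"""Stochastic variational inference over subject batches.

The group model is treated as the global variable of stochastic VB: random
subject batches are visited, each batch's subjects are locally optimised
and accumulated into an intermediate group state as if the whole
population were present (local terms scaled by the number of batches),
and the running group state is blended with the intermediate one using a
decaying step size rho_t = (t + tau)^-beta. Subjects keep a memory of
their own previous visits; a final pass re-aligns every subject with the
converged group model so that all posteriors refer to the same group.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import model as M
from .data_io import MaskedDataset, preprocess as _preprocess
from .initialization import InitialMaps

__all__ = [
    "StochasticConfig",
    "VisitLedger",
    "SubjectStore",
    "FitResult",
    "step_size",
    "sample_batch",
    "blend_global",
    "run_batch",
    "final_pass",
    "fit",
]


@dataclass
class StochasticConfig:
    """Stochastic inference settings (defaults mirror the large-cohort run)."""

    batch_size: int = 50
    n_batches: Optional[int] = None  # default: ~2.5 visits per subject
    tau: float = 5.0
    beta: float = 0.6
    n_initial_updates: int = 10
    n_full_updates: int = 20
    n_final_updates: Optional[int] = None  # default n_initial_updates
    rho_override: Optional[float] = None  # fixed step size (e.g. 1.0 recovers full-batch VB)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.beta <= 1.0:
            raise ValueError("beta must lie in (0.5, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class VisitLedger:
    """Per-subject visit counts and batch membership history."""

    n_visits: np.ndarray
    history: list = field(default_factory=list)

    @classmethod
    def empty(cls, n_subjects: int) -> "VisitLedger":
        return cls(n_visits=np.zeros(n_subjects, dtype=int))

    def record(self, batch: np.ndarray) -> None:
        self.n_visits[batch] += 1
        self.history.append(np.array(batch, dtype=int))


def step_size(t: int, tau: float, beta: float) -> float:
    """Decreasing stochastic step size rho_t = (t + tau)^-beta."""
    if not 0.5 < beta <= 1.0:
        raise ValueError("beta must lie in (0.5, 1]")
    if tau <= 0:
        raise ValueError("tau must be positive")
    if t < 1:
        raise ValueError("batch index starts at 1")
    return float((t + tau) ** (-beta))


def visit_weights(n_visits: np.ndarray) -> np.ndarray:
    """Selection weights, strictly decreasing in the visit count."""
    return 1.0 / (1.0 + n_visits.astype(float))


def sample_batch(
    ledger: VisitLedger,
    batch_size: int,
    rng: np.random.Generator,
    weight_policy: Callable[[np.ndarray], np.ndarray] = visit_weights,
) -> np.ndarray:
    """Sample a batch of distinct subjects, preferring rarely-visited ones.

    Returns sorted subject indices and records them in the ledger.
    """
    s = len(ledger.n_visits)
    if batch_size > s:
        raise ValueError("batch_size cannot exceed the number of subjects")
    w = np.asarray(weight_policy(ledger.n_visits), dtype=float)
    if np.any(w <= 0):
        raise ValueError("weight policy must return positive weights")
    batch = rng.choice(s, size=batch_size, replace=False, p=w / w.sum())
    batch = np.sort(batch)
    ledger.record(batch)
    return batch


def blend_global(theta_prev: M.GroupModel, theta_hat: M.GroupModel, rho: float) -> M.GroupModel:
    """Natural-parameter convex blend of two group states."""
    return theta_prev.blend(theta_hat, rho)


class SubjectStore:
    """Persistence of subject posteriors between batch visits.

    ``backing=None`` keeps subjects in memory; a directory path stores one
    pickle per subject and keeps none of them resident, so the engine's
    memory footprint scales with the batch, not the population.
    """

    def __init__(self, n_subjects: int, backing: Optional[Union[str, Path]] = None):
        self.n_subjects = n_subjects
        self.backing = Path(backing) if backing is not None else None
        if self.backing is not None:
            self.backing.mkdir(parents=True, exist_ok=True)
        self._mem: dict[int, M.SubjectModel] = {}

    def __contains__(self, idx: int) -> bool:
        if self.backing is None:
            return idx in self._mem
        return (self.backing / f"subject_{idx:05d}.pkl").exists()

    def load(self, idx: int) -> M.SubjectModel:
        if self.backing is None:
            return self._mem[idx]
        with open(self.backing / f"subject_{idx:05d}.pkl", "rb") as f:
            return pickle.load(f)

    def save(self, idx: int, subject: M.SubjectModel) -> None:
        if self.backing is None:
            self._mem[idx] = subject
        else:
            with open(self.backing / f"subject_{idx:05d}.pkl", "wb") as f:
                pickle.dump(subject, f)

    def indices(self):
        return range(self.n_subjects)


@dataclass
class FitResult:
    """Converged model state plus convergence monitors."""

    group: M.GroupModel
    subjects: SubjectStore
    ledger: VisitLedger
    history: pd.DataFrame
    initial_maps: InitialMaps
    model_config: M.ModelConfig
    stochastic_config: StochasticConfig

    def group_maps(self) -> np.ndarray:
        """Group map summary: membership-weighted group signal means."""
        pi = self.group.mem_a / (self.group.mem_a + self.group.mem_b)
        return pi * self.group.e_mu()

    def subject_maps(self) -> np.ndarray:
        return np.stack(
            [M.expected_map(self.subjects.load(i).spatial) for i in self.subjects.indices()]
        )


def _as_arrays(runs, do_preprocess: bool) -> list:
    out = []
    for r in runs:
        if isinstance(r, MaskedDataset):
            ds = _preprocess(r) if do_preprocess else r
            out.append(ds.data)
        else:
            arr = np.asarray(r, dtype=float)
            if do_preprocess:
                arr = arr - arr.mean(axis=1, keepdims=True)
                sd = arr.std(axis=1)
                good = sd > 1e-8
                arr[good] /= sd[good][:, None]
                arr[~good] = 0.0
            out.append(arr)
    return out


def _rescue_dead_modes(subject: M.SubjectModel, group: M.GroupModel, mass_frac: float = 0.005) -> int:
    """Re-seed subject modes whose membership mass has collapsed.

    Returns the number of modes reset. The spatial posterior of a dead
    mode is replaced by the group model's current signal means and
    membership probabilities so the next joint sweeps can re-evaluate it
    against the data.
    """
    sp = subject.spatial
    v = sp.membership.shape[0]
    mass = sp.membership.sum(axis=0)
    dead = np.flatnonzero(mass < mass_frac * v)
    if len(dead) == 0:
        return 0
    pi = group.mem_a / (group.mem_a + group.mem_b)
    membership = sp.membership.copy()
    sig_mean = sp.signal_mean.copy()
    sig_var = sp.signal_var.copy()
    noise_mean = sp.noise_mean.copy()
    e_mu, e_tau = group.e_mu(), group.e_tau_sig()
    for k in dead:
        membership[:, k] = np.clip(pi[:, k], 0.02, 0.98)
        sig_mean[:, k] = e_mu[:, k]
        sig_var[:, k] = 1.0 / e_tau[:, k]
        noise_mean[:, k] = 0.0
    subject.spatial = M.SpatialPosterior(
        membership=membership,
        signal_mean=sig_mean,
        signal_var=sig_var,
        noise_mean=noise_mean,
        noise_var=sp.noise_var.copy(),
    )
    for amp in subject.amplitude:
        amp.log_mean[dead] = group.e_amp_mean()[dead]
    return len(dead)


def run_batch(
    batch: np.ndarray,
    data: Sequence,
    group: M.GroupModel,
    store: SubjectStore,
    init_maps: InitialMaps,
    config: StochasticConfig,
    kernel: M.TemporalKernel,
    scale: float,
    do_preprocess: bool = True,
) -> tuple[dict, M.GroupModel]:
    """Local optimisation of one batch plus the intermediate group state.

    First-visit subjects are initialised from the initial maps; revisited
    subjects resume their stored posteriors. ``n_initial_updates`` sweeps
    run with the group frozen, then ``n_full_updates`` joint sweeps
    produce the intermediate global state (subject statistics scaled by
    ``scale``, the number of batches).
    """
    if len(batch) == 0:
        raise ValueError("empty batch")
    batch_data = {int(i): _as_arrays(data[int(i)], do_preprocess) for i in batch}
    subjects = {}
    for i in batch:
        i = int(i)
        if i in store:
            subjects[i] = store.load(i)
        else:
            runs = batch_data[i]
            subjects[i] = M.init_subject(
                group, init_maps.maps, len(runs), runs[0].shape[1]
            )
        subjects[i].n_visits += 1

    for _ in range(config.n_initial_updates):
        for i in batch:
            M.update_subject(batch_data[int(i)], group, subjects[int(i)], kernel)

    # restart collapsed modes from the group before the joint updates: a
    # subject mode whose membership mass has died carries no evidence and
    # cannot recover on its own (a degenerate local optimum)
    for i in batch:
        _rescue_dead_modes(subjects[int(i)], group)

    theta_hat = group
    for _ in range(config.n_full_updates):
        for i in batch:
            M.update_subject(batch_data[int(i)], theta_hat, subjects[int(i)], kernel)
        theta_hat = M.accumulate_and_update_group(
            [subjects[int(i)] for i in batch], theta_hat, scale=scale
        )

    for i in batch:
        store.save(int(i), subjects[int(i)])
    return subjects, theta_hat


def final_pass(
    data: Sequence,
    group: M.GroupModel,
    store: SubjectStore,
    init_maps: InitialMaps,
    kernel: M.TemporalKernel,
    n_updates: int = 10,
    do_preprocess: bool = True,
) -> list:
    """Re-update every subject against the frozen final group model.

    Subjects never visited during inference are initialised first. Returns
    the visit log (each subject exactly once).
    """
    log = []
    for i in store.indices():
        runs = _as_arrays(data[i], do_preprocess)
        if i in store:
            subject = store.load(i)
        else:
            subject = M.init_subject(group, init_maps.maps, len(runs), runs[0].shape[1])
        for _ in range(n_updates):
            M.update_subject(runs, group, subject, kernel)
        store.save(i, subject)
        log.append(i)
    return log


def fit(
    data: Sequence,
    init_maps: InitialMaps,
    config: Optional[StochasticConfig] = None,
    model_config: Optional[M.ModelConfig] = None,
    tr: float = 0.72,
    store_backing: Optional[Union[str, Path]] = None,
    do_preprocess: bool = True,
    track_free_energy: bool = True,
) -> FitResult:
    """Full stochastic inference over a population.

    ``data[s]`` is the list of runs (arrays or MaskedDatasets) of subject
    ``s``; all runs must share the voxel grid. Returns the fitted group
    model, the per-subject posteriors after the final alignment pass, and
    a per-batch convergence log (free energy of the batch estimate, step
    size, group-map and group-precision deltas).
    """
    config = config or StochasticConfig()
    s_total = len(data)
    batch_size = min(config.batch_size, s_total)
    n_batches = config.n_batches
    if n_batches is None:
        n_batches = max(1, int(np.ceil(2.5 * s_total / batch_size)))

    first = _as_arrays(data[0], do_preprocess)
    n_voxels, n_timepoints = first[0].shape
    if model_config is None:
        model_config = M.ModelConfig(n_modes=init_maps.n_modes, tr=tr)
    kernel = M.TemporalKernel.get(n_timepoints, model_config.tr, model_config.temporal_noise_floor)

    group = M.init_group_model(model_config, n_voxels, init_maps.maps)
    store = SubjectStore(s_total, backing=store_backing)
    ledger = VisitLedger.empty(s_total)
    rng = np.random.default_rng(config.seed)
    scale = float(n_batches)

    rows = []
    prev_maps = None
    prev_prec = None
    for t in range(1, n_batches + 1):
        batch = sample_batch(ledger, batch_size, rng)
        subjects, theta_hat = run_batch(
            batch, data, group, store, init_maps, config, kernel, scale, do_preprocess
        )
        rho = (
            config.rho_override
            if config.rho_override is not None
            else step_size(t, config.tau, config.beta)
        )
        group = blend_global(group, theta_hat, rho)

        pi = group.mem_a / (group.mem_a + group.mem_b)
        gmaps = pi * group.e_mu()
        gprec = group.e_g()
        row = {"batch": t, "rho": rho}
        if track_free_energy:
            fe = M.free_energy(
                group,
                [subjects[int(i)] for i in batch],
                [_as_arrays(data[int(i)], do_preprocess) for i in batch],
                scale=scale,
            )
            row["free_energy"] = fe.total
        row["group_map_delta"] = (
            float(np.abs(gmaps - prev_maps).mean()) if prev_maps is not None else np.nan
        )
        row["group_precision_delta"] = (
            float(np.abs(gprec - prev_prec).mean()) if prev_prec is not None else np.nan
        )
        rows.append(row)
        prev_maps, prev_prec = gmaps, gprec

    n_final = config.n_final_updates if config.n_final_updates is not None else config.n_initial_updates
    final_pass(data, group, store, init_maps, kernel, n_updates=n_final, do_preprocess=do_preprocess)

    return FitResult(
        group=group,
        subjects=store,
        ledger=ledger,
        history=pd.DataFrame(rows),
        initial_maps=init_maps,
        model_config=model_config,
        stochastic_config=config,
    )
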
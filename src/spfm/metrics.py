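"""Evaluation machinery: mode pairing, accuracy, consistency, NetMats.

Estimated decompositions are identifiable only up to mode permutation and
sign, so every comparison starts by pairing estimated and reference modes
with an optimal assignment on absolute spatial correlations. Accuracy
against simulated ground truth is then reported as Pearson correlations
of group maps, subject maps and subject timecourses; population stability
is summarised with subject-to-subject (S2S) and subject-to-group (S2G)
consistencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ModePairing",
    "AccuracyReport",
    "pair_modes",
    "accuracy_report",
    "consistency",
    "spatial_netmat",
    "fisher_z",
    "accuracy_tables",
]


def _cross_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson cross-correlation matrix, NaN for zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    sa = np.sqrt((ac**2).sum(axis=0))
    sb = np.sqrt((bc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (ac.T @ bc) / np.outer(sa, sb)
    c[~np.isfinite(c)] = np.nan
    return c


@dataclass
class ModePairing:
    """Assignment of estimated modes to reference modes."""

    permutation: np.ndarray  # est index -> ref index (-1 if unpaired)
    signs: np.ndarray  # +-1 per estimated mode
    correlations: np.ndarray  # |r| of each paired estimated mode (NaN if unpaired)
    one_to_one: np.ndarray  # bool per estimated mode
    cross_correlation: np.ndarray  # full |r| matrix est x ref

    @property
    def mean_correlation(self) -> float:
        return float(np.nanmean(self.correlations))


def pair_modes(
    est_maps: np.ndarray,
    ref_maps: np.ndarray,
    one_to_one_threshold: float = 0.7,
    one_to_one_sds: float = 2.0,
) -> ModePairing:
    """Optimal one-to-one pairing maximising total absolute correlation.

    Rectangular problems are allowed; unmatched estimated modes get
    permutation -1. A pair is flagged one-to-one when its |r| exceeds
    ``one_to_one_threshold`` and beats the next-best reference mode by at
    least ``one_to_one_sds`` standard deviations of that estimated mode's
    correlation profile.
    """
    c = _cross_correlation(est_maps, ref_maps)
    zero_var = np.all(np.isnan(c), axis=1)
    absc = np.abs(np.where(np.isnan(c), 0.0, c))
    rows, cols = linear_sum_assignment(-absc)

    n_est = est_maps.shape[1]
    perm = np.full(n_est, -1, dtype=int)
    signs = np.ones(n_est)
    corrs = np.full(n_est, np.nan)
    o2o = np.zeros(n_est, dtype=bool)
    for i, j in zip(rows, cols):
        if zero_var[i]:
            continue
        perm[i] = j
        corrs[i] = absc[i, j]
        signs[i] = 1.0 if c[i, j] >= 0 else -1.0
        profile = absc[i]
        rest = np.delete(profile, j)
        if len(rest) > 0:
            gap_ok = profile[j] >= rest.max() + one_to_one_sds * profile.std()
        else:
            gap_ok = True
        o2o[i] = (profile[j] > one_to_one_threshold) and gap_ok
    return ModePairing(
        permutation=perm,
        signs=signs,
        correlations=corrs,
        one_to_one=o2o,
        cross_correlation=absc,
    )


@dataclass
class AccuracyReport:
    """Correlation-with-truth accuracies for one estimated decomposition."""

    group_map_corr: np.ndarray  # per paired mode
    subject_map_corr: Optional[np.ndarray]  # (S, K) per subject-mode
    subject_timecourse_corr: Optional[np.ndarray]  # (S, R, K)
    n_missing_modes: int
    pairing: ModePairing

    @property
    def mean_group_map_corr(self) -> float:
        return float(np.nanmean(self.group_map_corr))

    @property
    def mean_subject_map_corr(self) -> float:
        return float(np.nanmean(np.nanmean(self.subject_map_corr, axis=1)))

    @property
    def mean_subject_timecourse_corr(self) -> float:
        return float(np.nanmean(self.subject_timecourse_corr))


def _paired_columns_corr(est: np.ndarray, ref: np.ndarray, pairing: ModePairing) -> np.ndarray:
    out = np.full(est.shape[1], np.nan)
    for i, j in enumerate(pairing.permutation):
        if j < 0:
            continue
        e, r_ = est[:, i], ref[:, j]
        if e.std() == 0 or r_.std() == 0:
            continue
        out[i] = abs(np.corrcoef(e, r_)[0, 1])
    return out


def accuracy_report(
    est_group_maps: np.ndarray,
    true_group_maps: np.ndarray,
    est_subject_maps: Optional[np.ndarray] = None,  # (S, V, K)
    true_subject_maps: Optional[np.ndarray] = None,
    est_timecourses: Optional[np.ndarray] = None,  # (S, R, K, T)
    true_timecourses: Optional[np.ndarray] = None,
    pair_per_subject: bool = False,
) -> AccuracyReport:
    """Accuracy of an estimated decomposition against simulator ground truth.

    Modes are paired on the group maps; subject maps and timecourses reuse
    that pairing unless ``pair_per_subject`` re-pairs each subject's maps
    against its own truth. All-zero estimated modes count as missing and
    are excluded from the means.
    """
    pairing = pair_modes(est_group_maps, true_group_maps)
    group_corr = _paired_columns_corr(est_group_maps, true_group_maps, pairing)
    n_missing = int(np.sum(est_group_maps.std(axis=0) == 0))

    subj_corr = None
    if est_subject_maps is not None:
        s = est_subject_maps.shape[0]
        subj_corr = np.full((s, est_subject_maps.shape[2]), np.nan)
        for i in range(s):
            if pair_per_subject:
                p_i = pair_modes(est_subject_maps[i], true_subject_maps[i])
            else:
                p_i = pairing
            subj_corr[i] = _paired_columns_corr(
                est_subject_maps[i], true_subject_maps[i], p_i
            )

    tc_corr = None
    if est_timecourses is not None:
        s, r_, k, _ = est_timecourses.shape
        tc_corr = np.full((s, r_, k), np.nan)
        for i in range(s):
            for j in range(r_):
                tc_corr[i, j] = _paired_columns_corr(
                    est_timecourses[i, j].T, true_timecourses[i, j].T, pairing
                )

    return AccuracyReport(
        group_map_corr=group_corr,
        subject_map_corr=subj_corr,
        subject_timecourse_corr=tc_corr,
        n_missing_modes=n_missing,
        pairing=pairing,
    )


def _flatten(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 2 and x.shape[0] == x.shape[1]:
        iu = np.triu_indices(x.shape[0], 1)
        return x[iu]
    return x.ravel()


def consistency(subject_elements: Sequence[np.ndarray], group_element: Optional[np.ndarray] = None) -> dict:
    """Subject-to-subject and subject-to-group consistency of one element.

    Elements may be maps (V, K), NetMats (K, K; upper triangle used) or
    amplitude vectors. Returns mean pairwise cross-subject correlation
    (S2S) and, when a group element is given, the mean subject-group
    correlation (S2G).
    """
    flats = [_flatten(e) for e in subject_elements]
    s = len(flats)
    if s < 2:
        raise ValueError("need at least two subjects")
    mat = np.corrcoef(np.stack(flats))
    iu = np.triu_indices(s, 1)
    out = {"s2s": float(mat[iu].mean())}
    if group_element is not None:
        g = _flatten(group_element)
        out["s2g"] = float(
            np.mean([np.corrcoef(f, g)[0, 1] for f in flats])
        )
    return out


def spatial_netmat(maps: np.ndarray, fisher: bool = False) -> np.ndarray:
    """Mode-by-mode Pearson correlation of spatial maps across voxels."""
    if maps.shape[1] < 2:
        raise ValueError("need at least two modes")
    sd = maps.std(axis=0)
    if np.any(sd < 1e-12):
        raise ValueError(f"zero-variance maps: {list(np.flatnonzero(sd < 1e-12))}")
    c = np.corrcoef(maps.T)
    return fisher_z(c) if fisher else c


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher r-to-Z transform; the unit diagonal maps to 0 for NetMats."""
    r = np.asarray(r, dtype=float)
    out = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    if r.ndim == 2 and r.shape[0] == r.shape[1]:
        np.fill_diagonal(out, 0.0)
    return out


def accuracy_tables(scenario_results: dict) -> pd.DataFrame:
    """Tidy long-format accuracy summary across scenarios and methods.

    ``scenario_results[scenario][method]`` is an :class:`AccuracyReport`;
    the output has one row per (scenario, method, element) with the mean
    and standard deviation of the per-mode/per-subject correlations.
    """
    rows = []
    for scenario, methods in scenario_results.items():
        for method, report in methods.items():
            elements = {"group_maps": report.group_map_corr}
            if report.subject_map_corr is not None:
                elements["subject_maps"] = np.nanmean(report.subject_map_corr, axis=1)
            if report.subject_timecourse_corr is not None:
                elements["subject_timecourses"] = np.nanmean(
                    report.subject_timecourse_corr, axis=(1, 2)
                )
            for element, vals in elements.items():
                rows.append(
                    {
                        "scenario": scenario,
                        "method": method,
                        "element": element,
                        "mean": float(np.nanmean(vals)),
                        "sd": float(np.nanstd(vals)),
                    }
                )
    return pd.DataFrame(rows, columns=["scenario", "method", "element", "mean", "sd"])
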
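"""Haemodynamic response function (HRF) kernels and temporal priors.

The BOLD signal is a delayed, dispersed transform of underlying neural
activity. Both the simulator (which convolves neural series into BOLD
series) and the temporal model (which places an HRF-informed
autocorrelation prior on mode timecourses) share the kernels defined here.

The basis is the canonical double-gamma HRF plus its temporal and
dispersion derivatives — the standard three-function expansion used to
absorb latency and width variability of the haemodynamic response.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = [
    "double_gamma_hrf",
    "hrf_basis",
    "sample_hrf",
    "hrf_autocorr_kernel",
    "temporal_prior_kernel",
]


def _gamma_pdf(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    t = np.maximum(t, 0.0)
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp(
        (shape - 1.0) * np.log(tp) - tp / scale - gammaln(shape) - shape * np.log(scale)
    )
    return out


def double_gamma_hrf(
    tr: float,
    duration: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the repetition time ``tr``.

    Returns a kernel normalised to unit peak.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, duration, tr)
    h = _gamma_pdf(t, peak_delay / peak_disp, peak_disp) - undershoot_ratio * _gamma_pdf(
        t, undershoot_delay / undershoot_disp, undershoot_disp
    )
    return h / np.abs(h).max()


def hrf_basis(tr: float, duration: float = 32.0) -> np.ndarray:
    """Three-function HRF basis: canonical, temporal and dispersion derivative.

    Shape ``(3, n_lags)``; each row has unit L2 norm.
    """
    h0 = double_gamma_hrf(tr, duration)
    dd = 0.1
    h_t = (double_gamma_hrf(tr, duration, peak_delay=6.0 + dd) - h0) / dd
    h_d = (double_gamma_hrf(tr, duration, peak_disp=1.0 + dd) - h0) / dd
    basis = np.vstack([h0, h_t, h_d])
    norms = np.linalg.norm(basis, axis=1, keepdims=True)
    return basis / norms


def sample_hrf(tr: float, rng: np.random.Generator, duration: float = 32.0) -> np.ndarray:
    """Random haemodynamic kernel: canonical-dominant mixture of the basis.

    The canonical coefficient is fixed at 1 and the derivative coefficients
    are small Gaussian perturbations, so every draw remains a plausible,
    positive-peak response.
    """
    basis = hrf_basis(tr, duration)
    coef = np.array([1.0, 0.2 * rng.standard_normal(), 0.2 * rng.standard_normal()])
    h = coef @ basis
    return h / np.linalg.norm(h)


def hrf_autocorr_kernel(n_timepoints: int, tr: float, duration: float = 32.0) -> np.ndarray:
    """Stationary autocorrelation matrix of white noise convolved with the HRF.

    Toeplitz ``(T, T)`` matrix with unit diagonal; this is the temporal
    signature the haemodynamic response imposes on any mode timecourse.
    """
    h = double_gamma_hrf(tr, duration)
    full = np.correlate(h, h, mode="full")
    mid = len(h) - 1
    ac = np.zeros(n_timepoints)
    upto = min(n_timepoints, len(h))
    ac[:upto] = full[mid : mid + upto] / full[mid]
    idx = np.abs(np.subtract.outer(np.arange(n_timepoints), np.arange(n_timepoints)))
    return ac[idx]


def temporal_prior_kernel(
    n_timepoints: int,
    tr: float,
    noise_floor: float = 0.2,
    jitter: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the temporal prior covariance Q.

    Q combines an HRF-autocorrelation signal kernel with a white-noise floor,

        Q = (1 - noise_floor) * K_hrf + noise_floor * I,

    realising the signal-plus-Gaussian-noise structure of the timecourse
    model as one additive kernel with unit diagonal. Returns
    ``(eigenvalues, eigenvectors)`` with eigenvalues clipped away from zero.
    """
    if not 0.0 < noise_floor <= 1.0:
        raise ValueError("noise_floor must be in (0, 1]")
    q = (1.0 - noise_floor) * hrf_autocorr_kernel(n_timepoints, tr) + noise_floor * np.eye(
        n_timepoints
    )
    evals, evecs = np.linalg.eigh(q)
    evals = np.maximum(evals, jitter)
    return evals, evecs
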
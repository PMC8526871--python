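"""Hierarchical variational model for probabilistic functional modes.

One subject-run's data matrix is factorised as

    D = P @ diag(h) @ A + eps,

with a double-Gaussian mixture (signal + background noise, plus a per
voxel-mode membership probability) on the spatial maps ``P``, an
HRF-informed Gaussian process prior on the timecourses ``A`` whose
cross-mode precision ``alpha`` carries a hierarchical Wishart link to the
group, positive amplitudes ``h`` modelled on the log scale with a
hierarchical Gaussian group mean, and a Gamma posterior on the residual
precision of ``eps``.

Everything is conjugate-exponential, so each factor's coordinate update is
closed form and provably does not decrease the variational free energy;
amplitudes are the one exception and are handled as exact coordinate
maximisers (point-mass convention in the free energy) with a Laplace
curvature reported as posterior spread.

The group model holds conjugate-family posteriors for the hierarchical
parameters: per voxel-mode Gaussian signal means, Gamma signal/noise
precisions, Beta memberships; a Wishart over the temporal prior inverse
scale; and Gaussians over group log-amplitude means. Subject evidence is
accumulated into these with an optional multiplier ``N`` so a random batch
can stand in for the whole population during stochastic inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import digamma, gammaln, multigammaln

from .hrf import temporal_prior_kernel

__all__ = [
    "ModelConfig",
    "SpatialPosterior",
    "TemporalPosterior",
    "AmplitudePosterior",
    "NoiseModel",
    "SubjectModel",
    "GroupModel",
    "FreeEnergyLedger",
    "TemporalKernel",
    "init_group_model",
    "init_subject",
    "dgmm_spatial_update",
    "temporal_update",
    "precision_update",
    "amplitude_update",
    "noise_update",
    "update_subject",
    "accumulate_and_update_group",
    "free_energy",
    "expected_map",
]

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ModelConfig:
    """Model dimensions and hyperprior settings.

    Hyperpriors are weakly informative: the membership Beta prior has mean
    ``membership_prior_mean`` (sparse modes), the signal-precision Gamma is
    centred on maps of unit scale, the noise component is tighter around
    zero, and the Wishart link strength ``precision_link_dof`` sets how
    strongly subject-run precision matrices shrink to the group.
    """

    n_modes: int
    tr: float = 0.72
    # spatial hyperpriors
    signal_mean_prior_mean: float = 0.0
    signal_mean_prior_prec: float = 0.1
    signal_prec_a: float = 2.0
    signal_prec_b: float = 2.0
    noise_prec_a: float = 2.0
    noise_prec_b: float = 0.5
    membership_prior_mean: float = 0.05
    membership_prior_conc: float = 10.0
    # temporal hyperpriors
    wishart_prior_dof: Optional[float] = None  # default n_modes + 2
    precision_link_dof: Optional[float] = None  # default n_modes + 20
    temporal_noise_floor: float = 0.2
    # amplitude hyperpriors
    amplitude_log_sd: float = 0.5
    amplitude_group_prior_prec: float = 1.0
    # residual noise
    noise_gamma_a: float = 1e-3
    noise_gamma_b: float = 1e-3
    jitter: float = 1e-8

    @property
    def beta_a0(self) -> float:
        return self.membership_prior_mean * self.membership_prior_conc

    @property
    def beta_b0(self) -> float:
        return (1.0 - self.membership_prior_mean) * self.membership_prior_conc

    @property
    def nu0(self) -> float:
        return self.wishart_prior_dof if self.wishart_prior_dof is not None else self.n_modes + 2.0

    @property
    def nu_link(self) -> float:
        return (
            self.precision_link_dof
            if self.precision_link_dof is not None
            else self.n_modes + 20.0
        )


class TemporalKernel:
    """Cached eigendecomposition of the HRF temporal prior for one run length."""

    def __init__(self, n_timepoints: int, tr: float, noise_floor: float = 0.2):
        self.n_timepoints = n_timepoints
        self.tr = tr
        self.evals, self.evecs = temporal_prior_kernel(n_timepoints, tr, noise_floor)

    _cache: dict = {}

    @classmethod
    def get(cls, n_timepoints: int, tr: float, noise_floor: float = 0.2) -> "TemporalKernel":
        key = (n_timepoints, round(tr, 9), round(noise_floor, 9))
        if key not in cls._cache:
            cls._cache[key] = cls(n_timepoints, tr, noise_floor)
        return cls._cache[key]


# ---------------------------------------------------------------------------
# posterior containers


@dataclass
class SpatialPosterior:
    """Per voxel-mode DGMM posterior: q(z, P) = q(z) q(P | z)."""

    membership: np.ndarray  # (V, K) probability of the signal component
    signal_mean: np.ndarray
    signal_var: np.ndarray
    noise_mean: np.ndarray
    noise_var: np.ndarray

    def __post_init__(self) -> None:
        # moments are memoised; posteriors are replaced, never mutated
        object.__setattr__(self, "_memo", {})

    def _cached(self, key, fn):
        if key not in self._memo:
            self._memo[key] = fn()
        return self._memo[key]

    def expected(self) -> np.ndarray:
        r = self.membership
        return self._cached(
            "expected", lambda: r * self.signal_mean + (1.0 - r) * self.noise_mean
        )

    def second_moment(self) -> np.ndarray:
        r = self.membership
        return self._cached(
            "second_moment",
            lambda: r * (self.signal_mean**2 + self.signal_var)
            + (1.0 - r) * (self.noise_mean**2 + self.noise_var),
        )

    def gram(self) -> np.ndarray:
        """E[P^T P]: mean Gram with per-voxel variance on the diagonal."""

        def _compute():
            e_p = self.expected()
            g = e_p.T @ e_p
            g[np.diag_indices_from(g)] += np.sum(self.second_moment() - e_p**2, axis=0)
            return g

        return self._cached("gram", _compute)


@dataclass
class TemporalPosterior:
    """Per-run posterior over timecourses and their cross-mode precision."""

    mean_timecourses: np.ndarray  # (K, T)
    second_moment: np.ndarray  # (K, K) = E[A A^T]
    scatter_qinv: np.ndarray  # (K, K) = E[A Q^-1 A^T]
    logdet_cov_sum: float  # sum_j log|Sigma_j| of the rotated-time covariances
    sum_log_evals: float  # sum_j log q_j of the prior kernel eigenvalues
    prec_scale: np.ndarray  # (K, K) Wishart scale of q(alpha)
    prec_dof: float

    def kl_timecourses(self) -> float:
        """KL(q(A) || p(A | alpha)) with expectations over q(alpha)."""
        k, t = self.mean_timecourses.shape
        e_alpha = self.expected_precision()
        return 0.5 * float(
            np.einsum("kl,lk->", e_alpha, self.scatter_qinv)
            - t * k
            - t * self.expected_logdet_precision()
            + k * self.sum_log_evals
            - self.logdet_cov_sum
        )

    def expected_precision(self) -> np.ndarray:
        return self.prec_dof * self.prec_scale

    def expected_logdet_precision(self) -> float:
        return _wishart_elogdet(self.prec_scale, self.prec_dof)


@dataclass
class AmplitudePosterior:
    """Per-run positive amplitudes, log-domain location and Laplace spread."""

    log_mean: np.ndarray  # (K,)
    log_var: np.ndarray  # (K,)

    @property
    def mean(self) -> np.ndarray:
        return np.exp(self.log_mean)


@dataclass
class NoiseModel:
    """Gamma posterior over one run's residual precision."""

    a: float
    b: float

    @property
    def expected_precision(self) -> float:
        return self.a / self.b

    @property
    def expected_log_precision(self) -> float:
        return float(digamma(self.a) - np.log(self.b))


@dataclass
class SubjectModel:
    """All per-subject factors; the spatial map is shared across runs."""

    spatial: SpatialPosterior
    temporal: list  # list[TemporalPosterior], one per run
    amplitude: list  # list[AmplitudePosterior]
    noise: list  # list[NoiseModel]
    n_visits: int = 0

    @property
    def n_runs(self) -> int:
        return len(self.temporal)


@dataclass
class GroupModel:
    """Conjugate-family group posteriors (the global/stochastic state).

    Gaussian factors are stored as (precision, precision*mean) so that
    convex blending of the stored arrays is exactly natural-parameter
    blending for every factor.
    """

    config: ModelConfig
    # per voxel-mode spatial parameters
    sig_mean_prec: np.ndarray  # (V, K)
    sig_mean_mp: np.ndarray  # (V, K) precision * mean
    sig_prec_a: np.ndarray
    sig_prec_b: np.ndarray
    noise_prec_a: np.ndarray
    noise_prec_b: np.ndarray
    mem_a: np.ndarray
    mem_b: np.ndarray
    # Wishart over the temporal prior inverse scale G
    g_scale_inv: np.ndarray  # (K, K) accumulated inverse scale
    g_dof: float
    # group mean of log-amplitudes
    amp_prec: np.ndarray  # (K,)
    amp_mp: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        # expectation memo; instances are treated as immutable once built
        # (accumulation and blending always construct new objects)
        object.__setattr__(self, "_memo", {})

    def _cached(self, key: str, fn):
        memo = self._memo
        if key not in memo:
            memo[key] = fn()
        return memo[key]

    # ---- expectations -------------------------------------------------
    def e_mu(self) -> np.ndarray:
        return self._cached("e_mu", lambda: self.sig_mean_mp / self.sig_mean_prec)

    def var_mu(self) -> np.ndarray:
        return self._cached("var_mu", lambda: 1.0 / self.sig_mean_prec)

    def e_tau_sig(self) -> np.ndarray:
        return self._cached("e_tau_sig", lambda: self.sig_prec_a / self.sig_prec_b)

    def e_log_tau_sig(self) -> np.ndarray:
        return self._cached(
            "e_log_tau_sig", lambda: digamma(self.sig_prec_a) - np.log(self.sig_prec_b)
        )

    def e_tau_noise(self) -> np.ndarray:
        return self._cached("e_tau_noise", lambda: self.noise_prec_a / self.noise_prec_b)

    def e_log_tau_noise(self) -> np.ndarray:
        return self._cached(
            "e_log_tau_noise", lambda: digamma(self.noise_prec_a) - np.log(self.noise_prec_b)
        )

    def e_log_pi(self) -> np.ndarray:
        return self._cached(
            "e_log_pi", lambda: digamma(self.mem_a) - digamma(self.mem_a + self.mem_b)
        )

    def e_log_1mpi(self) -> np.ndarray:
        return self._cached(
            "e_log_1mpi", lambda: digamma(self.mem_b) - digamma(self.mem_a + self.mem_b)
        )

    def e_g(self) -> np.ndarray:
        return self._cached("e_g", lambda: self.g_dof * np.linalg.inv(self.g_scale_inv))

    def e_logdet_g(self) -> float:
        return self._cached(
            "e_logdet_g",
            lambda: _wishart_elogdet(np.linalg.inv(self.g_scale_inv), self.g_dof),
        )

    def e_amp_mean(self) -> np.ndarray:
        return self.amp_mp / self.amp_prec

    def var_amp_mean(self) -> np.ndarray:
        return 1.0 / self.amp_prec

    # ---- blending -----------------------------------------------------
    _BLEND_FIELDS = (
        "sig_mean_prec",
        "sig_mean_mp",
        "sig_prec_a",
        "sig_prec_b",
        "noise_prec_a",
        "noise_prec_b",
        "mem_a",
        "mem_b",
        "g_scale_inv",
        "g_dof",
        "amp_prec",
        "amp_mp",
    )

    def blend(self, other: "GroupModel", rho: float) -> "GroupModel":
        """Natural-parameter convex combination (1-rho)*self + rho*other."""
        if not 0.0 <= rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        for f_ in ("sig_mean_prec",):
            if getattr(self, f_).shape != getattr(other, f_).shape:
                raise ValueError("mismatched model shapes")
        if rho == 0.0:
            return self
        if rho == 1.0:
            return other
        kw = {
            name: (1.0 - rho) * getattr(self, name) + rho * getattr(other, name)
            for name in self._BLEND_FIELDS
        }
        return GroupModel(config=self.config, **kw)


@dataclass
class FreeEnergyLedger:
    """Total variational free energy and its per-term decomposition."""

    total: float
    terms: dict
    history: list = field(default_factory=list)

    def check(self, rtol: float = 1e-6) -> bool:
        s = sum(self.terms.values())
        return bool(abs(s - self.total) <= rtol * max(1.0, abs(self.total)))


# ---------------------------------------------------------------------------
# divergence helpers (shared by the ledger and its tests)


def gaussian_kl(m_q, v_q, m_p, v_p) -> np.ndarray:
    return 0.5 * (np.log(v_p / v_q) + (v_q + (m_q - m_p) ** 2) / v_p - 1.0)


def gamma_kl(a_q, b_q, a_p, b_p) -> np.ndarray:
    return (
        (a_q - a_p) * digamma(a_q)
        - gammaln(a_q)
        + gammaln(a_p)
        + a_p * (np.log(b_q) - np.log(b_p))
        + a_q * (b_p - b_q) / b_q
    )


def beta_kl(a_q, b_q, a_p, b_p) -> np.ndarray:
    return (
        gammaln(a_q + b_q)
        - gammaln(a_q)
        - gammaln(b_q)
        - gammaln(a_p + b_p)
        + gammaln(a_p)
        + gammaln(b_p)
        + (a_q - a_p) * (digamma(a_q) - digamma(a_q + b_q))
        + (b_q - b_p) * (digamma(b_q) - digamma(a_q + b_q))
    )


def _wishart_elogdet(scale: np.ndarray, dof: float) -> float:
    k = scale.shape[0]
    sign, logdet = np.linalg.slogdet(scale)
    return float(
        np.sum(digamma(0.5 * (dof - np.arange(k)))) + k * np.log(2.0) + logdet
    )


def _wishart_logz(scale: np.ndarray, dof: float) -> float:
    k = scale.shape[0]
    _, logdet = np.linalg.slogdet(scale)
    return float(0.5 * dof * k * np.log(2.0) + 0.5 * dof * logdet + multigammaln(0.5 * dof, k))


def wishart_kl(scale_q, dof_q, scale_p, dof_p) -> float:
    k = scale_q.shape[0]
    e_logdet = _wishart_elogdet(scale_q, dof_q)
    e_x = dof_q * scale_q
    return float(
        -_wishart_logz(scale_q, dof_q)
        + _wishart_logz(scale_p, dof_p)
        + 0.5 * (dof_q - dof_p) * e_logdet
        + 0.5 * np.trace(np.linalg.solve(scale_p, e_x))
        - 0.5 * dof_q * k
    )


def _spd_jitter(mat: np.ndarray, jitter: float) -> np.ndarray:
    mat = 0.5 * (mat + mat.T)
    return mat + jitter * (np.trace(mat) / mat.shape[0] + 1.0) * np.eye(mat.shape[0])


def expected_map(spatial: SpatialPosterior) -> np.ndarray:
    """Membership-weighted posterior map, the model's subject map summary."""
    return spatial.expected()


# ---------------------------------------------------------------------------
# initialisation


def init_group_model(
    config: ModelConfig,
    n_voxels: int,
    initial_maps: Optional[np.ndarray] = None,
    init_weight: float = 5.0,
) -> GroupModel:
    """Group model at the hyperpriors, optionally centred on initial maps.

    ``init_weight`` acts as pseudo-evidence (in units of subjects) pulling
    the group signal means and membership probabilities towards the
    initial maps; it anchors the mode identities during the first batches
    without fixing the group.
    """
    v, k = n_voxels, config.n_modes
    sig_prec = np.full((v, k), config.signal_mean_prior_prec)
    sig_mp = np.full((v, k), config.signal_mean_prior_prec * config.signal_mean_prior_mean)
    mem_a = np.full((v, k), config.beta_a0)
    mem_b = np.full((v, k), config.beta_b0)
    if initial_maps is not None:
        if initial_maps.shape != (v, k):
            raise ValueError("initial maps shape mismatch")
        sig_prec = sig_prec + init_weight
        sig_mp = sig_mp + init_weight * initial_maps
        r0 = np.clip(1.0 / (1.0 + np.exp(-2.0 * (np.abs(initial_maps) - 1.0))), 0.02, 0.98)
        mem_a = mem_a + init_weight * r0
        mem_b = mem_b + init_weight * (1.0 - r0)
    return GroupModel(
        config=config,
        sig_mean_prec=sig_prec,
        sig_mean_mp=sig_mp,
        sig_prec_a=np.full((v, k), config.signal_prec_a),
        sig_prec_b=np.full((v, k), config.signal_prec_b),
        noise_prec_a=np.full((v, k), config.noise_prec_a),
        noise_prec_b=np.full((v, k), config.noise_prec_b),
        mem_a=mem_a,
        mem_b=mem_b,
        g_scale_inv=np.eye(k) * config.nu0,  # prior W0 = I/nu0 => E[G] = I
        g_dof=config.nu0,
        amp_prec=np.full(k, config.amplitude_group_prior_prec),
        amp_mp=np.zeros(k),
    )


def init_subject(
    group: GroupModel,
    initial_maps: np.ndarray,
    n_runs: int,
    n_timepoints: int,
) -> SubjectModel:
    """Fresh subject state seeded from the initial maps and the group."""
    cfg = group.config
    v, k = initial_maps.shape
    r0 = np.clip(1.0 / (1.0 + np.exp(-2.0 * (np.abs(initial_maps) - 1.0))), 0.02, 0.98)
    spatial = SpatialPosterior(
        membership=r0,
        signal_mean=initial_maps.copy(),
        signal_var=1.0 / group.e_tau_sig(),
        noise_mean=np.zeros((v, k)),
        noise_var=1.0 / group.e_tau_noise(),
    )
    e_g = group.e_g()
    w0 = np.linalg.inv(_spd_jitter(e_g, cfg.jitter))
    temporal = [
        TemporalPosterior(
            mean_timecourses=np.zeros((k, n_timepoints)),
            second_moment=np.eye(k),
            scatter_qinv=np.eye(k),
            logdet_cov_sum=0.0,
            sum_log_evals=0.0,
            prec_scale=w0,
            prec_dof=cfg.nu_link,
        )
        for _ in range(n_runs)
    ]
    amplitude = [
        AmplitudePosterior(log_mean=group.e_amp_mean().copy(), log_var=np.full(k, cfg.amplitude_log_sd**2))
        for _ in range(n_runs)
    ]
    noise = [NoiseModel(a=cfg.noise_gamma_a + 1.0, b=cfg.noise_gamma_b + 1.0) for _ in range(n_runs)]
    return SubjectModel(spatial=spatial, temporal=temporal, amplitude=amplitude, noise=noise)


# ---------------------------------------------------------------------------
# subject-level coordinate updates


def dgmm_spatial_update(
    data: Sequence[np.ndarray],
    group: GroupModel,
    subject: SubjectModel,
) -> SpatialPosterior:
    """Update the shared spatial DGMM posterior from all runs' evidence.

    For every voxel and mode, the regression evidence from the runs is a
    Gaussian pseudo-likelihood on P[v, k]; combining it with the group's
    signal/noise components gives conjugate component posteriors and a
    membership responsibility from the two marginal likelihoods. Modes are
    swept sequentially so each update is an exact coordinate step.
    """
    cfg = group.config
    v, k = subject.spatial.membership.shape
    e_mu, var_mu = group.e_mu(), group.var_mu()
    e_tau_s, e_log_tau_s = group.e_tau_sig(), group.e_log_tau_sig()
    e_tau_n, e_log_tau_n = group.e_tau_noise(), group.e_log_tau_noise()
    log_pi, log_1mpi = group.e_log_pi(), group.e_log_1mpi()

    # run-combined evidence pieces
    psis = [nz.expected_precision for nz in subject.noise]
    hs = [amp.mean for amp in subject.amplitude]
    cs = [d @ tp.mean_timecourses.T for d, tp in zip(data, subject.temporal)]  # (V, K)
    s_as = [tp.second_moment for tp in subject.temporal]

    sp = subject.spatial
    e_p = sp.expected()
    lam = np.zeros(k)
    for psi, h, s_a in zip(psis, hs, s_as):
        lam += psi * h**2 * np.diag(s_a)
    lam = np.maximum(lam, 0.0)

    r = sp.membership.copy()
    m_s, v_s = sp.signal_mean.copy(), sp.signal_var.copy()
    m_n, v_n = sp.noise_mean.copy(), sp.noise_var.copy()

    for kk in range(k):
        b = np.zeros(v)
        for psi, h, c, s_a in zip(psis, hs, cs, s_as):
            cross = e_p @ (h * s_a[:, kk])
            cross -= e_p[:, kk] * h[kk] * s_a[kk, kk]
            b += psi * h[kk] * (c[:, kk] - cross)
        lk = lam[kk]
        # component posteriors
        v_sig = 1.0 / (e_tau_s[:, kk] + lk)
        m_sig = v_sig * (e_tau_s[:, kk] * e_mu[:, kk] + b)
        v_noi = 1.0 / (e_tau_n[:, kk] + lk)
        m_noi = v_noi * b
        # responsibilities: log odds of the signal component
        log_r_sig = (
            log_pi[:, kk]
            + 0.5 * e_log_tau_s[:, kk]
            - 0.5 * e_tau_s[:, kk] * (e_mu[:, kk] ** 2 + var_mu[:, kk])
            + 0.5 * np.log(v_sig)
            + 0.5 * m_sig**2 / v_sig
        )
        log_r_noi = (
            log_1mpi[:, kk]
            + 0.5 * e_log_tau_n[:, kk]
            + 0.5 * np.log(v_noi)
            + 0.5 * m_noi**2 / v_noi
        )
        delta = np.clip(log_r_sig - log_r_noi, -700, 700)
        rk = 1.0 / (1.0 + np.exp(-delta))
        r[:, kk] = rk
        m_s[:, kk], v_s[:, kk] = m_sig, v_sig
        m_n[:, kk], v_n[:, kk] = m_noi, v_noi
        e_p[:, kk] = rk * m_sig + (1.0 - rk) * m_noi

    new = SpatialPosterior(
        membership=r, signal_mean=m_s, signal_var=v_s, noise_mean=m_n, noise_var=v_n
    )
    subject.spatial = new
    return new


def temporal_update(
    data: np.ndarray,
    subject: SubjectModel,
    run: int,
    kernel: TemporalKernel,
    jitter: float = 1e-8,
) -> TemporalPosterior:
    """Exact joint Gaussian update of one run's timecourse posterior.

    The HRF temporal prior kernel Q is diagonalised once per run length;
    in its eigenbasis the posterior factorises over rotated timepoints
    with covariance (psi H Gp H + alpha / q_j)^-1.
    """
    from scipy.linalg import eigh as sp_eigh

    sp = subject.spatial
    tp = subject.temporal[run]
    psi = subject.noise[run].expected_precision
    h = subject.amplitude[run].mean
    e_p = sp.expected()
    gp = sp.gram()
    m = psi * (h[:, None] * gp * h[None, :])
    e_alpha = _spd_jitter(tp.expected_precision(), jitter)

    z = (e_p * h[None, :]).T @ data * psi  # (K, T)
    z_rot = z @ kernel.evecs  # (K, T)
    q = kernel.evals
    t = data.shape[1]
    k = gp.shape[0]

    # simultaneous diagonalisation: B^T alpha B = I, B^T M B = diag(w), so
    # (M + alpha/q_j)^-1 = B diag(1/(w + 1/q_j)) B^T for every j at once
    w, b_mat = sp_eigh(0.5 * (m + m.T), e_alpha)
    w = np.maximum(w, 0.0)
    denom = w[:, None] + 1.0 / q[None, :]  # (K, T)
    z2 = b_mat.T @ z_rot  # (K, T)
    means_rot = b_mat @ (z2 / denom)  # (K, T)
    mean_tc = means_rot @ kernel.evecs.T

    s_second = (1.0 / denom).sum(axis=1)
    s_scatter = ((1.0 / q[None, :]) / denom).sum(axis=1)
    cov_second = (b_mat * s_second[None, :]) @ b_mat.T
    cov_scatter = (b_mat * s_scatter[None, :]) @ b_mat.T
    second = means_rot @ means_rot.T + cov_second
    scatter = (means_rot / q[None, :]) @ means_rot.T + cov_scatter

    # log|Sigma_j| = -log|alpha| - sum_i log(w_i + 1/q_j)
    _, logdet_alpha = np.linalg.slogdet(e_alpha)
    logdet_cov_sum = float(-t * logdet_alpha - np.log(denom).sum())

    new = TemporalPosterior(
        mean_timecourses=mean_tc,
        second_moment=0.5 * (second + second.T),
        scatter_qinv=0.5 * (scatter + scatter.T),
        logdet_cov_sum=logdet_cov_sum,
        sum_log_evals=float(np.sum(np.log(q))),
        prec_scale=tp.prec_scale,
        prec_dof=tp.prec_dof,
    )
    subject.temporal[run] = new
    return new


def precision_update(subject: SubjectModel, group: GroupModel) -> list:
    """Conjugate Wishart update of every run's cross-mode precision.

    Prior: alpha ~ Wishart(E[G]^-1, nu_link); the posterior adds one
    pseudo-count per timepoint and the expected timecourse scatter in the
    Q metric.
    """
    cfg = group.config
    e_g = group.e_g()
    out = []
    for tp in subject.temporal:
        t = tp.mean_timecourses.shape[1]
        scale_inv = _spd_jitter(e_g + tp.scatter_qinv, cfg.jitter)
        tp.prec_scale = np.linalg.inv(scale_inv)
        tp.prec_dof = cfg.nu_link + t
        out.append(tp)
    return out


def _amp_objective_terms(data, subject, run):
    """Quadratic-likelihood sufficient statistics for one run's amplitudes."""
    sp = subject.spatial
    tp = subject.temporal[run]
    e_p = sp.expected()
    g = sp.gram() * tp.second_moment  # elementwise: E[P'P] o E[A A']
    c = ((e_p.T @ data) * tp.mean_timecourses).sum(axis=1)  # (K,)
    return g, c


def amplitude_update(
    data: np.ndarray,
    subject: SubjectModel,
    run: int,
    group: GroupModel,
    n_sweeps: int = 2,
) -> AmplitudePosterior:
    """Coordinate maximisation of the positive per-mode amplitudes.

    Works in u = log h: for mode k the objective is
    -psi/2 g_kk e^{2u} + psi c_k e^u - prec (u - m0)^2 / 2, maximised by a
    safeguarded Newton iteration started from a grid scan. The Laplace
    curvature at the maximiser is reported as the log-domain variance.
    """
    cfg = group.config
    psi = subject.noise[run].expected_precision
    g, c = _amp_objective_terms(data, subject, run)
    m0 = group.e_amp_mean()
    p0 = 1.0 / cfg.amplitude_log_sd**2
    amp = subject.amplitude[run]
    u = amp.log_mean.copy()
    k = len(u)

    grid = np.linspace(-8.0, 8.0, 81)
    for sweep in range(n_sweeps):
        h = np.exp(u)
        for kk in range(k):
            c_eff = c[kk] - (g[kk] @ h - g[kk, kk] * h[kk])
            a2 = 0.5 * psi * g[kk, kk]

            def grad(x):
                e = np.exp(x)
                return -2.0 * a2 * e * e + psi * c_eff * e - p0 * (x - m0[kk])

            def obj(x):
                e = np.exp(x)
                return -a2 * e * e + psi * c_eff * e - 0.5 * p0 * (x - m0[kk]) ** 2

            if sweep == 0:
                # global grid scan guards against Newton picking a wrong root
                vals = obj(grid)
                x = grid[np.argmax(vals)]
                if obj(u[kk]) > vals.max():
                    x = u[kk]
            else:
                x = u[kk]
            for _ in range(50):
                gr = grad(x)
                e = np.exp(x)
                hess = -4.0 * a2 * e * e + psi * c_eff * e - p0
                if hess >= -1e-12:
                    break
                step = gr / hess
                x_new = x - np.clip(step, -1.0, 1.0)
                if obj(x_new) < obj(x) - 1e-12:
                    break
                x = x_new
                if abs(gr) < 1e-12:
                    break
            u[kk] = x
            h[kk] = np.exp(x)
    e = np.exp(u)
    curv = 4.0 * 0.5 * psi * np.diag(g) * e * e - psi * (c - (g @ e - np.diag(g) * e)) * e + p0
    new = AmplitudePosterior(log_mean=u, log_var=1.0 / np.maximum(curv, 1e-6))
    subject.amplitude[run] = new
    return new


def _expected_residual(data_sq: float, data: np.ndarray, subject: SubjectModel, run: int) -> float:
    g, c = _amp_objective_terms(data, subject, run)
    h = subject.amplitude[run].mean
    val = data_sq - 2.0 * float(h @ c) + float(h @ g @ h)
    return max(val, 1e-12)


def noise_update(data: np.ndarray, subject: SubjectModel, run: int, config: ModelConfig) -> NoiseModel:
    """Gamma posterior over the run's residual precision."""
    v, t = data.shape
    resid = _expected_residual(float(np.sum(data * data)), data, subject, run)
    new = NoiseModel(a=config.noise_gamma_a + 0.5 * v * t, b=config.noise_gamma_b + 0.5 * resid)
    subject.noise[run] = new
    return new


def update_subject(
    data: Sequence[np.ndarray],
    group: GroupModel,
    subject: SubjectModel,
    kernel: TemporalKernel,
) -> SubjectModel:
    """One full sweep of subject-factor coordinate updates.

    Timecourses are refreshed before the spatial map so that a freshly
    initialised subject (whose stored timecourses are zero) immediately
    sees real temporal evidence instead of collapsing its memberships.
    """
    for run, d in enumerate(data):
        temporal_update(d, subject, run, kernel, jitter=group.config.jitter)
    precision_update(subject, group)
    for run, d in enumerate(data):
        amplitude_update(d, subject, run, group)
        noise_update(d, subject, run, group.config)
    dgmm_spatial_update(data, group, subject)
    return subject


# ---------------------------------------------------------------------------
# group accumulation


def accumulate_and_update_group(
    subjects: Sequence[SubjectModel],
    group: GroupModel,
    scale: float = 1.0,
) -> GroupModel:
    """Conjugate group update from a batch of subjects.

    Every subject's sufficient statistics are multiplied by ``scale`` (the
    number of batches N) so a batch acts as if the full population were
    present. Factors are updated sequentially (means before variances) so
    each is an exact coordinate step.
    """
    if len(subjects) == 0:
        raise ValueError("empty batch")
    cfg = group.config
    v, k = group.sig_mean_prec.shape

    r_sum = np.zeros((v, k))
    rm_sum = np.zeros((v, k))
    rsq_sum = np.zeros((v, k))  # r * (m_sig^2 + v_sig)
    nsq_sum = np.zeros((v, k))  # (1-r) * (m_noise^2 + v_noise)
    for s in subjects:
        sp = s.spatial
        r = sp.membership
        r_sum += r
        rm_sum += r * sp.signal_mean
        rsq_sum += r * (sp.signal_mean**2 + sp.signal_var)
        nsq_sum += (1.0 - r) * (sp.noise_mean**2 + sp.noise_var)

    e_tau_s = group.e_tau_sig()
    # 1) signal means (uses current signal-precision expectation)
    sig_mean_prec = cfg.signal_mean_prior_prec + scale * e_tau_s * r_sum
    sig_mean_mp = (
        cfg.signal_mean_prior_prec * cfg.signal_mean_prior_mean + scale * e_tau_s * rm_sum
    )
    e_mu = sig_mean_mp / sig_mean_prec
    var_mu = 1.0 / sig_mean_prec

    # 2) signal precisions (uses the new mean posterior)
    dev = rsq_sum - 2.0 * e_mu * rm_sum + r_sum * (e_mu**2 + var_mu)
    sig_prec_a = cfg.signal_prec_a + 0.5 * scale * r_sum
    sig_prec_b = cfg.signal_prec_b + 0.5 * scale * np.maximum(dev, 0.0)

    # 3) noise precisions and memberships
    noise_prec_a = cfg.noise_prec_a + 0.5 * scale * (len(subjects) - r_sum)
    noise_prec_b = cfg.noise_prec_b + 0.5 * scale * np.maximum(nsq_sum, 0.0)
    mem_a = cfg.beta_a0 + scale * r_sum
    mem_b = cfg.beta_b0 + scale * (len(subjects) - r_sum)

    # 4) Wishart over the temporal inverse scale
    g_scale_inv = np.eye(k) * cfg.nu0
    g_dof = cfg.nu0
    for s in subjects:
        for tp in s.temporal:
            g_scale_inv = g_scale_inv + scale * tp.expected_precision()
            g_dof += scale * cfg.nu_link

    # 5) group log-amplitude means
    p_run = 1.0 / cfg.amplitude_log_sd**2
    amp_prec = np.full(k, cfg.amplitude_group_prior_prec)
    amp_mp = np.zeros(k)
    for s in subjects:
        for amp in s.amplitude:
            amp_prec = amp_prec + scale * p_run
            amp_mp = amp_mp + scale * p_run * amp.log_mean

    return GroupModel(
        config=cfg,
        sig_mean_prec=sig_mean_prec,
        sig_mean_mp=sig_mean_mp,
        sig_prec_a=sig_prec_a,
        sig_prec_b=sig_prec_b,
        noise_prec_a=noise_prec_a,
        noise_prec_b=noise_prec_b,
        mem_a=mem_a,
        mem_b=mem_b,
        g_scale_inv=g_scale_inv,
        g_dof=g_dof,
        amp_prec=amp_prec,
        amp_mp=amp_mp,
    )


# ---------------------------------------------------------------------------
# free energy


def _subject_local_terms(data: Sequence[np.ndarray], group: GroupModel, subject: SubjectModel) -> dict:
    cfg = group.config
    sp = subject.spatial
    terms = {"data_fit": 0.0, "temporal_kl": 0.0, "precision_kl": 0.0, "noise_kl": 0.0, "amplitude_logp": 0.0}

    # data fit per run
    for run, d in enumerate(data):
        v, t = d.shape
        nz = subject.noise[run]
        resid = _expected_residual(float(np.sum(d * d)), d, subject, run)
        terms["data_fit"] += 0.5 * v * t * (nz.expected_log_precision - _LOG2PI) - 0.5 * nz.expected_precision * resid
        terms["temporal_kl"] -= subject.temporal[run].kl_timecourses()
        terms["noise_kl"] -= float(gamma_kl(nz.a, nz.b, cfg.noise_gamma_a, cfg.noise_gamma_b))

        # precision: E[log p(alpha | G)] - E[log q(alpha)]
        tp = subject.temporal[run]
        k = tp.prec_scale.shape[0]
        e_alpha = tp.expected_precision()
        e_logdet = tp.expected_logdet_precision()
        e_g, e_logdet_g = group.e_g(), group.e_logdet_g()
        elogp = (
            0.5 * (cfg.nu_link - k - 1.0) * e_logdet
            - 0.5 * float(np.einsum("kl,lk->", e_g, e_alpha))
            + 0.5 * cfg.nu_link * e_logdet_g
            - 0.5 * cfg.nu_link * k * np.log(2.0)
            - multigammaln(0.5 * cfg.nu_link, k)
        )
        ent = (
            _wishart_logz(tp.prec_scale, tp.prec_dof)
            - 0.5 * (tp.prec_dof - k - 1.0) * e_logdet
            + 0.5 * tp.prec_dof * k
        )
        terms["precision_kl"] += float(elogp + ent)

        # amplitudes at their point value
        amp = subject.amplitude[run]
        m0, var0 = group.e_amp_mean(), group.var_amp_mean()
        sd2 = cfg.amplitude_log_sd**2
        terms["amplitude_logp"] += float(
            np.sum(-0.5 * np.log(2.0 * np.pi * sd2) - 0.5 * ((amp.log_mean - m0) ** 2 + var0) / sd2)
        )

    # spatial mixture KL (shared across runs)
    r = np.clip(sp.membership, 1e-12, 1.0 - 1e-12)
    e_mu, var_mu = group.e_mu(), group.var_mu()
    e_tau_s, e_log_tau_s = group.e_tau_sig(), group.e_log_tau_sig()
    e_tau_n, e_log_tau_n = group.e_tau_noise(), group.e_log_tau_noise()
    dev_s = sp.signal_var + (sp.signal_mean - e_mu) ** 2 + var_mu
    dev_n = sp.noise_var + sp.noise_mean**2
    kl_sig = -0.5 * np.log(2.0 * np.pi * np.e * sp.signal_var) - (
        0.5 * e_log_tau_s - 0.5 * _LOG2PI - 0.5 * e_tau_s * dev_s
    )
    kl_noi = -0.5 * np.log(2.0 * np.pi * np.e * sp.noise_var) - (
        0.5 * e_log_tau_n - 0.5 * _LOG2PI - 0.5 * e_tau_n * dev_n
    )
    kl_z = r * (np.log(r) - group.e_log_pi()) + (1.0 - r) * (
        np.log(1.0 - r) - group.e_log_1mpi()
    )
    terms["spatial_kl"] = -float(np.sum(kl_z + r * kl_sig + (1.0 - r) * kl_noi))
    return terms


def _group_kl(group: GroupModel) -> float:
    cfg = group.config
    kl = float(
        np.sum(
            gaussian_kl(
                group.e_mu(),
                group.var_mu(),
                cfg.signal_mean_prior_mean,
                1.0 / cfg.signal_mean_prior_prec,
            )
        )
    )
    kl += float(np.sum(gamma_kl(group.sig_prec_a, group.sig_prec_b, cfg.signal_prec_a, cfg.signal_prec_b)))
    kl += float(np.sum(gamma_kl(group.noise_prec_a, group.noise_prec_b, cfg.noise_prec_a, cfg.noise_prec_b)))
    kl += float(np.sum(beta_kl(group.mem_a, group.mem_b, cfg.beta_a0, cfg.beta_b0)))
    k = group.g_scale_inv.shape[0]
    kl += wishart_kl(
        np.linalg.inv(group.g_scale_inv), group.g_dof, np.eye(k) / cfg.nu0, cfg.nu0
    )
    kl += float(
        np.sum(
            gaussian_kl(
                group.e_amp_mean(),
                group.var_amp_mean(),
                0.0,
                1.0 / cfg.amplitude_group_prior_prec,
            )
        )
    )
    return kl


def free_energy(
    group: GroupModel,
    subjects: Sequence[SubjectModel],
    data: Sequence[Sequence[np.ndarray]],
    scale: float = 1.0,
) -> FreeEnergyLedger:
    """Variational free energy (evidence lower bound) of the model state.

    With ``scale`` > 1 and a subject subset, returns the batch estimate in
    which local terms are multiplied by the number of batches, an unbiased
    stand-in for the full-population objective.
    """
    terms = {
        "data_fit": 0.0,
        "spatial_kl": 0.0,
        "temporal_kl": 0.0,
        "precision_kl": 0.0,
        "amplitude_logp": 0.0,
        "noise_kl": 0.0,
    }
    for subj, d in zip(subjects, data):
        local = _subject_local_terms(d, group, subj)
        for key, val in local.items():
            terms[key] += scale * val
    terms["group_kl"] = -_group_kl(group)
    total = sum(terms.values())
    return FreeEnergyLedger(total=float(total), terms={k_: float(v_) for k_, v_ in terms.items()})
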
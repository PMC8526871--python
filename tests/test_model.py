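"""Conjugate variational updates against dense numeric oracles.

Every factor update is checked against an independent computation: the
spatial mixture against grid integration, the timecourse posterior
against a dense Kronecker linear solve, the precision update against the
scalar/sample conjugate closed forms, the noise update against direct
residual algebra, and the group accumulation against a hand-written
two-voxel reimplementation. Free-energy calculus is checked against an
analytic log-evidence and for per-update monotonicity.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spfm
from spfm import model as M


def sharp_group(cfg, v, mu, tau_sig, tau_noise, pi, sharp=1e8):
    """Group posteriors concentrated on known values (VB ~ exact Bayes)."""
    k = cfg.n_modes
    shape = (v, k)
    return M.GroupModel(
        config=cfg,
        sig_mean_prec=np.full(shape, sharp),
        sig_mean_mp=np.full(shape, sharp) * mu,
        sig_prec_a=np.full(shape, sharp),
        sig_prec_b=np.full(shape, sharp / tau_sig),
        noise_prec_a=np.full(shape, sharp),
        noise_prec_b=np.full(shape, sharp / tau_noise),
        mem_a=np.full(shape, sharp * pi),
        mem_b=np.full(shape, sharp * (1 - pi)),
        g_scale_inv=np.eye(k) * cfg.nu0,
        g_dof=cfg.nu0,
        amp_prec=np.full(k, 1e8),
        amp_mp=np.zeros(k),
    )


def subject_with_state(cfg, v, t, e_a, s_a, h, psi, n_runs=1):
    """Subject whose temporal/amplitude/noise factors are pinned."""
    k = cfg.n_modes
    group = M.init_group_model(cfg, v)
    subj = M.init_subject(group, np.zeros((v, k)), n_runs, t)
    for run in range(n_runs):
        tp = subj.temporal[run]
        tp.mean_timecourses = e_a.copy()
        tp.second_moment = s_a.copy()
        tp.scatter_qinv = s_a.copy()
        subj.amplitude[run] = M.AmplitudePosterior(
            log_mean=np.log(h), log_var=np.zeros(k)
        )
        subj.noise[run] = M.NoiseModel(a=psi * 1e8, b=1e8)
    return subj


class TestSpatialUpdate:
    def test_matches_grid_integration(self):
        """Single voxel-mode DGMM posterior equals numeric-grid Bayes."""
        cfg = M.ModelConfig(n_modes=1)
        mu, tau_s, tau_n, pi = 1.2, 0.8, 5.0, 0.3
        t = 30
        rng = np.random.default_rng(0)
        e_a = rng.standard_normal((1, t))
        s_a = e_a @ e_a.T
        h, psi = np.array([1.4]), 2.0
        data = [0.9 * e_a + 0.1 * rng.standard_normal((1, t))]

        group = sharp_group(cfg, 1, mu, tau_s, tau_n, pi)
        subj = subject_with_state(cfg, 1, t, e_a, s_a, h, psi)
        post = M.dgmm_spatial_update(data, group, subj)

        # oracle: evidence is Gaussian with precision lam and linear term b
        lam = psi * h[0] ** 2 * s_a[0, 0]
        b = psi * h[0] * float((data[0] @ e_a.T).item())
        grid = np.linspace(-6, 8, 200001)
        loglik = -0.5 * lam * grid**2 + b * grid
        comp_s = np.log(pi) + 0.5 * np.log(tau_s / (2 * np.pi)) - 0.5 * tau_s * (grid - mu) ** 2
        comp_n = np.log(1 - pi) + 0.5 * np.log(tau_n / (2 * np.pi)) - 0.5 * tau_n * grid**2
        w_s = np.exp(comp_s + loglik - loglik.max())
        w_n = np.exp(comp_n + loglik - loglik.max())
        mass_s, mass_n = np.trapezoid(w_s, grid), np.trapezoid(w_n, grid)
        r_oracle = mass_s / (mass_s + mass_n)
        mean_s_oracle = np.trapezoid(grid * w_s, grid) / mass_s
        mean_n_oracle = np.trapezoid(grid * w_n, grid) / mass_n

        assert post.membership[0, 0] == pytest.approx(r_oracle, abs=1e-5)
        assert post.signal_mean[0, 0] == pytest.approx(mean_s_oracle, abs=1e-5)
        assert post.noise_mean[0, 0] == pytest.approx(mean_n_oracle, abs=1e-5)

    def test_symmetric_components_keep_prior_membership(self):
        """Identical signal/noise components leave the membership at its prior."""
        cfg = M.ModelConfig(n_modes=2)
        v, t = 12, 25
        rng = np.random.default_rng(1)
        e_a = rng.standard_normal((2, t))
        group = sharp_group(cfg, v, mu=0.0, tau_sig=2.0, tau_noise=2.0, pi=0.3)
        subj = subject_with_state(cfg, v, t, e_a, e_a @ e_a.T, np.ones(2), 1.5)
        post = M.dgmm_spatial_update([rng.standard_normal((v, t))], group, subj)
        prior_r = 1.0 / (1.0 + np.exp(-(group.e_log_pi() - group.e_log_1mpi())))
        assert np.allclose(post.membership, prior_r, atol=1e-6)

    def test_zero_evidence_full_shrinkage(self):
        """As data precision vanishes the signal posterior returns to the prior."""
        cfg = M.ModelConfig(n_modes=1)
        t = 20
        e_a = np.ones((1, t))
        group = sharp_group(cfg, 5, mu=2.5, tau_sig=1.0, tau_noise=4.0, pi=0.2)
        subj = subject_with_state(cfg, 5, t, e_a, e_a @ e_a.T, np.ones(1), psi=1e-12)
        post = M.dgmm_spatial_update([np.random.default_rng(2).standard_normal((5, t))], group, subj)
        assert np.allclose(post.signal_mean, 2.5, atol=1e-5)
        assert np.allclose(post.signal_var, 1.0, rtol=1e-5)

    def test_run_order_invariance(self):
        """Evidence accumulated over runs is symmetric in run order."""
        cfg = M.ModelConfig(n_modes=3)
        v, t = 30, 40
        rng = np.random.default_rng(3)
        group = sharp_group(cfg, v, 0.5, 1.0, 4.0, 0.2)
        data = [rng.standard_normal((v, t)) for _ in range(2)]
        e_as = [rng.standard_normal((3, t)) for _ in range(2)]

        def build(order):
            subj = subject_with_state(cfg, v, t, e_as[order[0]], e_as[order[0]] @ e_as[order[0]].T,
                                      np.ones(3), 2.0, n_runs=2)
            for pos, idx in enumerate(order):
                subj.temporal[pos].mean_timecourses = e_as[idx].copy()
                subj.temporal[pos].second_moment = e_as[idx] @ e_as[idx].T
            return M.dgmm_spatial_update([data[i] for i in order], group, subj)

        a = build([0, 1])
        b = build([1, 0])
        assert np.allclose(a.membership, b.membership, atol=1e-12)
        assert np.allclose(a.signal_mean, b.signal_mean, atol=1e-12)


class TestTemporalUpdate:
    def test_null_data_gives_zero_means(self):
        cfg = M.ModelConfig(n_modes=2, tr=1.0)
        group = M.init_group_model(cfg, 10)
        subj = M.init_subject(group, np.zeros((10, 2)), 1, 15)
        subj.spatial.signal_mean[:] = 1.0
        subj.spatial.membership[:] = 0.5
        kernel = M.TemporalKernel.get(15, 1.0, cfg.temporal_noise_floor)
        tp = M.temporal_update(np.zeros((10, 15)), subj, 0, kernel)
        assert np.allclose(tp.mean_timecourses, 0.0)

    def test_matches_dense_kronecker_solve(self):
        """Posterior mean equals the generalised-ridge solution solved densely."""
        cfg = M.ModelConfig(n_modes=2, tr=0.72)
        k, t, v = 2, 6, 20
        rng = np.random.default_rng(4)
        maps = rng.standard_normal((v, k))
        h = np.array([1.3, 0.7])
        psi = 1.8
        alpha = np.array([[2.0, 0.4], [0.4, 1.5]])
        data = rng.standard_normal((v, t))
        kernel = M.TemporalKernel.get(t, cfg.tr, cfg.temporal_noise_floor)
        q_mat = kernel.evecs @ np.diag(kernel.evals) @ kernel.evecs.T

        group = M.init_group_model(cfg, v)
        subj = M.init_subject(group, maps, 1, t)
        subj.spatial = M.SpatialPosterior(
            membership=np.ones((v, k)),
            signal_mean=maps,
            signal_var=np.zeros((v, k)),
            noise_mean=np.zeros((v, k)),
            noise_var=np.zeros((v, k)),
        )
        subj.amplitude[0] = M.AmplitudePosterior(log_mean=np.log(h), log_var=np.zeros(k))
        subj.noise[0] = M.NoiseModel(a=psi * 1e9, b=1e9)
        dof = 1e9
        subj.temporal[0].prec_scale = alpha / dof
        subj.temporal[0].prec_dof = dof
        tp = M.temporal_update(data, subj, 0, kernel, jitter=0.0)

        # dense oracle over vec(A) with timepoint-major ordering
        m_small = psi * np.diag(h) @ maps.T @ maps @ np.diag(h)
        full_prec = np.kron(np.eye(t), m_small) + np.kron(np.linalg.inv(q_mat), alpha)
        rhs = (psi * np.diag(h) @ maps.T @ data).T.reshape(-1)  # stack columns a_t
        mean = np.linalg.solve(full_prec, rhs).reshape(t, k).T
        assert np.allclose(tp.mean_timecourses, mean, atol=1e-7)

    def test_high_snr_recovers_simulated_timecourses(self, fitted_toy, tiny_bundle):
        """After fitting, mode timecourses track the true BOLD series."""
        b = tiny_bundle
        corrs = []
        for s, subj in enumerate(fitted_toy["subjects"]):
            for r in range(b.config.n_runs):
                est = subj.temporal[r].mean_timecourses
                pairing = spfm.pair_modes(est.T, b.bold_timecourses[s, r].T)
                corrs.append(np.nanmean(pairing.correlations))
        assert np.mean(corrs) > 0.9


class TestPrecisionUpdate:
    def test_dof_bookkeeping(self, fitted_toy):
        cfg = fitted_toy["config"]
        subj = fitted_toy["subjects"][0]
        t = subj.temporal[0].mean_timecourses.shape[1]
        assert subj.temporal[0].prec_dof == cfg.nu_link + t

    def test_sample_scatter_recovers_known_precision(self):
        """Weak prior + 10k samples: posterior mean within 5% of truth."""
        k, n = 2, 10000
        rng = np.random.default_rng(5)
        truth = np.array([[3.0, 1.0], [1.0, 2.0]])
        cov = np.linalg.inv(truth)
        samples = rng.multivariate_normal(np.zeros(k), cov, size=n)
        cfg = M.ModelConfig(n_modes=k, precision_link_dof=k + 1.0)
        group = M.init_group_model(cfg, 4)
        group.g_scale_inv = np.eye(k) * 1e8  # E[G] ~ 0: essentially flat prior
        subj = M.init_subject(group, np.zeros((4, k)), 1, n)
        subj.temporal[0].scatter_qinv = samples.T @ samples
        M.precision_update(subj, group)
        e_alpha = subj.temporal[0].expected_precision()
        assert np.abs(e_alpha / truth - 1.0).max() < 0.05

    def test_scalar_case_matches_gamma_closed_form(self):
        """K=1 Wishart posterior equals the Gamma conjugate update."""
        t = 50
        rng = np.random.default_rng(6)
        x = rng.standard_normal(t) * 0.5
        cfg = M.ModelConfig(n_modes=1, precision_link_dof=3.0, jitter=0.0)
        group = M.init_group_model(cfg, 2)
        subj = M.init_subject(group, np.zeros((2, 1)), 1, t)
        subj.temporal[0].scatter_qinv = np.array([[float(x @ x)]])
        M.precision_update(subj, group)
        e_g = float(group.e_g()[0, 0])
        # Gamma conjugate oracle: a = (nu0 + n)/2, b = (prior-scale + sum x^2)/2
        a = (3.0 + t) / 2.0
        b = (e_g + float(x @ x)) / 2.0
        assert float(subj.temporal[0].expected_precision()[0, 0]) == pytest.approx(a / b, rel=1e-10)


class TestAmplitudeUpdate:
    def _subject(self, cfg, v, t, rng, flat_prior=False):
        maps = rng.standard_normal((v, cfg.n_modes))
        e_a = rng.standard_normal((cfg.n_modes, t))
        subj = subject_with_state(cfg, v, t, e_a, e_a @ e_a.T, np.ones(cfg.n_modes), 1.0)
        subj.spatial = M.SpatialPosterior(
            membership=np.ones((v, cfg.n_modes)),
            signal_mean=maps,
            signal_var=np.zeros((v, cfg.n_modes)),
            noise_mean=np.zeros((v, cfg.n_modes)),
            noise_var=np.zeros((v, cfg.n_modes)),
        )
        return subj, maps, e_a

    def test_scale_equivariance_flat_prior(self):
        cfg = M.ModelConfig(n_modes=3, amplitude_log_sd=100.0)
        rng = np.random.default_rng(7)
        subj, maps, e_a = self._subject(cfg, 40, 30, rng)
        group = M.init_group_model(cfg, 40)
        truth_h = np.array([0.5, 1.0, 2.0])
        data = maps @ (truth_h[:, None] * e_a)
        a1 = M.amplitude_update(data, subj, 0, group).mean.copy()
        subj.amplitude[0] = M.AmplitudePosterior(log_mean=np.zeros(3), log_var=np.zeros(3))
        a3 = M.amplitude_update(3.0 * data, subj, 0, group).mean
        assert np.allclose(a3, 3.0 * a1, rtol=1e-3)
        assert np.allclose(a1, truth_h, rtol=1e-3)

    def test_posterior_strictly_positive_on_anticorrelated_data(self):
        cfg = M.ModelConfig(n_modes=2)
        rng = np.random.default_rng(8)
        subj, maps, e_a = self._subject(cfg, 30, 25, rng)
        group = M.init_group_model(cfg, 30)
        data = -5.0 * maps @ e_a  # evidence pushes amplitudes negative
        amp = M.amplitude_update(data, subj, 0, group)
        assert np.all(amp.mean > 0)

    def test_rank_correlation_with_simulated_amplitudes(self):
        """High-SNR fit reproduces the between-subject amplitude ordering."""
        from scipy.stats import spearmanr

        n_subj = 25
        cfg = spfm.SimConfig(
            n_subjects=n_subj, n_modes=3, n_voxels=400, n_timepoints=100, n_runs=2,
            mean_mode_size=0.08, overlap_enabled=False, target_misalignment=0.05,
            noise_snr=100.0, amplitude_sigma=0.5, seed=21,
        )
        b = spfm.simulate(cfg)
        mc = M.ModelConfig(n_modes=3, tr=cfg.tr)
        kernel = M.TemporalKernel.get(100, cfg.tr, mc.temporal_noise_floor)
        init = b.group_maps / b.group_maps.std(axis=0, keepdims=True)
        group = M.init_group_model(mc, 400, init)
        # demean only: variance normalisation would rescale the amplitudes
        data = [
            [b.data[s, r] - b.data[s, r].mean(axis=1, keepdims=True) for r in range(2)]
            for s in range(n_subj)
        ]
        subjects = [M.init_subject(group, init, 2, 100) for _ in range(n_subj)]
        for _ in range(12):
            for s in range(n_subj):
                M.update_subject(data[s], group, subjects[s], kernel)
            group = M.accumulate_and_update_group(subjects, group, 1.0)
        perm = spfm.pair_modes(init, b.group_maps).permutation
        rhos = []
        for k in range(3):
            # the identifiable quantity is the mode's data magnitude:
            # amplitude x spatial-map norm x timecourse norm (the split
            # between the three is a gauge freedom of the factorisation;
            # true BOLD rows are unit-variance so the true product is
            # amplitude x map norm)
            est = np.array(
                [
                    [
                        subjects[s].amplitude[r].mean[k]
                        * np.linalg.norm(M.expected_map(subjects[s].spatial)[:, k])
                        * np.linalg.norm(subjects[s].temporal[r].mean_timecourses[k])
                        for r in range(2)
                    ]
                    for s in range(n_subj)
                ]
            )
            tru = b.amplitudes[:, :, perm[k]] * np.linalg.norm(
                b.subject_maps[:, :, perm[k]], axis=1
            )[:, None]
            rhos.append(spearmanr(est.ravel(), tru.ravel()).statistic)
        assert np.mean(rhos) > 0.9


class TestNoiseUpdate:
    def _pinned_subject(self, cfg, v, t, rng):
        maps = rng.standard_normal((v, cfg.n_modes))
        e_a = rng.standard_normal((cfg.n_modes, t))
        subj = subject_with_state(cfg, v, t, e_a, e_a @ e_a.T, np.ones(cfg.n_modes), 1.0)
        subj.spatial = M.SpatialPosterior(
            membership=np.ones((v, cfg.n_modes)),
            signal_mean=maps,
            signal_var=np.zeros((v, cfg.n_modes)),
            noise_mean=np.zeros((v, cfg.n_modes)),
            noise_var=np.zeros((v, cfg.n_modes)),
        )
        return subj, maps, e_a

    def test_flat_prior_equals_inverse_mean_squared_residual(self):
        cfg = M.ModelConfig(n_modes=2, noise_gamma_a=1e-12, noise_gamma_b=1e-12)
        rng = np.random.default_rng(9)
        v, t = 30, 40
        subj, maps, e_a = self._pinned_subject(cfg, v, t, rng)
        resid = rng.standard_normal((v, t))
        data = maps @ e_a + resid
        nz = M.noise_update(data, subj, 0, cfg)
        assert nz.expected_precision == pytest.approx(v * t / float((resid**2).sum()), rel=1e-9)

    def test_doubling_residual_quarters_precision(self):
        cfg = M.ModelConfig(n_modes=2, noise_gamma_a=1e-12, noise_gamma_b=1e-12)
        rng = np.random.default_rng(10)
        v, t = 25, 30
        subj, maps, e_a = self._pinned_subject(cfg, v, t, rng)
        resid = rng.standard_normal((v, t))
        p1 = M.noise_update(maps @ e_a + resid, subj, 0, cfg).expected_precision
        p2 = M.noise_update(maps @ e_a + 2 * resid, subj, 0, cfg).expected_precision
        assert p2 == pytest.approx(p1 / 4.0, rel=1e-9)

    def test_recovers_simulated_noise_level(self, fitted_toy, tiny_bundle, tiny_data):
        """Fitted residual precision matches the injected noise within 10%."""
        b = tiny_bundle
        # the data are variance-normalised; recompute the true noise share of
        # each voxel's unit variance
        subj = fitted_toy["subjects"][0]
        sig = b.subject_maps[0] @ (b.amplitudes[0, 0][:, None] * b.bold_timecourses[0, 0])
        total_var = (sig + (b.data[0, 0] - sig)).var(axis=1)
        noise_var_norm = float(np.mean(b.noise_sd[0, 0] ** 2 / total_var))
        est_noise_var = 1.0 / subj.noise[0].expected_precision
        assert est_noise_var == pytest.approx(noise_var_norm, rel=0.10)


class TestGroupAccumulation:
    def test_matches_dense_oracle_two_voxels_two_modes(self):
        """Independent reimplementation of every conjugate group update."""
        cfg = M.ModelConfig(n_modes=2)
        v, k, t = 2, 2, 7
        rng = np.random.default_rng(11)
        group = M.init_group_model(cfg, v)
        subjects = []
        for _ in range(3):
            subj = M.init_subject(group, rng.standard_normal((v, k)), 1, t)
            sp = subj.spatial
            subj.spatial = M.SpatialPosterior(
                membership=rng.uniform(0.1, 0.9, (v, k)),
                signal_mean=rng.standard_normal((v, k)),
                signal_var=rng.uniform(0.1, 1.0, (v, k)),
                noise_mean=0.1 * rng.standard_normal((v, k)),
                noise_var=rng.uniform(0.1, 0.5, (v, k)),
            )
            w = rng.standard_normal((k, 2 * k))
            subj.temporal[0].prec_scale = (w @ w.T) / 10.0
            subj.temporal[0].prec_dof = 12.0
            subj.amplitude[0] = M.AmplitudePosterior(
                log_mean=rng.standard_normal(k), log_var=np.ones(k)
            )
            subjects.append(subj)
        scale = 2.5
        new = M.accumulate_and_update_group(subjects, group, scale=scale)

        # --- oracle ---
        r = np.stack([s.spatial.membership for s in subjects])
        ms = np.stack([s.spatial.signal_mean for s in subjects])
        vs = np.stack([s.spatial.signal_var for s in subjects])
        mn = np.stack([s.spatial.noise_mean for s in subjects])
        vn = np.stack([s.spatial.noise_var for s in subjects])
        e_tau = group.e_tau_sig()
        prec = cfg.signal_mean_prior_prec + scale * e_tau * r.sum(0)
        mp = scale * e_tau * (r * ms).sum(0)
        mu, var_mu = mp / prec, 1.0 / prec
        assert np.allclose(new.sig_mean_prec, prec, atol=1e-12)
        assert np.allclose(new.sig_mean_mp, mp, atol=1e-12)
        dev = (r * (ms**2 + vs)).sum(0) - 2 * mu * (r * ms).sum(0) + r.sum(0) * (mu**2 + var_mu)
        assert np.allclose(new.sig_prec_a, cfg.signal_prec_a + 0.5 * scale * r.sum(0), atol=1e-12)
        assert np.allclose(new.sig_prec_b, cfg.signal_prec_b + 0.5 * scale * dev, atol=1e-9)
        assert np.allclose(new.noise_prec_b,
                           cfg.noise_prec_b + 0.5 * scale * ((1 - r) * (mn**2 + vn)).sum(0), atol=1e-9)
        assert np.allclose(new.mem_a, cfg.beta_a0 + scale * r.sum(0), atol=1e-12)
        assert np.allclose(new.mem_b, cfg.beta_b0 + scale * (1 - r).sum(0), atol=1e-12)
        g_inv = np.eye(k) * cfg.nu0 + scale * sum(
            s.temporal[0].prec_dof * s.temporal[0].prec_scale for s in subjects
        )
        assert np.allclose(new.g_scale_inv, g_inv, atol=1e-9)
        assert new.g_dof == pytest.approx(cfg.nu0 + scale * 3 * cfg.nu_link)
        p_run = 1.0 / cfg.amplitude_log_sd**2
        assert np.allclose(
            new.amp_mp, scale * p_run * sum(s.amplitude[0].log_mean for s in subjects), atol=1e-12
        )

    def test_degenerate_population_returns_shared_map(self):
        cfg = M.ModelConfig(n_modes=2, signal_mean_prior_prec=1e-9)
        v = 10
        rng = np.random.default_rng(12)
        shared = rng.standard_normal((v, 2))
        group = M.init_group_model(cfg, v)
        subjects = []
        for _ in range(4):
            s = M.init_subject(group, shared, 1, 5)
            s.spatial = M.SpatialPosterior(
                membership=np.ones((v, 2)),
                signal_mean=shared.copy(),
                signal_var=np.full((v, 2), 1e-6),
                noise_mean=np.zeros((v, 2)),
                noise_var=np.ones((v, 2)),
            )
            subjects.append(s)
        new = M.accumulate_and_update_group(subjects, group, scale=25.0)
        assert np.allclose(new.e_mu(), shared, atol=1e-6)

    def test_empty_batch_raises(self, fitted_toy):
        with pytest.raises(ValueError, match="empty"):
            M.accumulate_and_update_group([], fitted_toy["group"])


class TestFreeEnergy:
    def test_ledger_terms_sum_to_total(self, fitted_toy, tiny_data):
        fe = M.free_energy(fitted_toy["group"], fitted_toy["subjects"], tiny_data)
        assert fe.check(rtol=1e-9)

    def test_conjugate_gaussian_toy_reaches_log_evidence(self):
        """VB at the exact posterior equals the analytic marginal likelihood."""
        rng = np.random.default_rng(13)
        y = rng.standard_normal(20) + 0.7
        sigma2, s02 = 0.5, 2.0
        n = len(y)
        post_prec = n / sigma2 + 1.0 / s02
        post_mean = (y.sum() / sigma2) / post_prec
        e_loglik = float(
            -0.5 * n * np.log(2 * np.pi * sigma2)
            - 0.5 * ((y - post_mean) ** 2).sum() / sigma2
            - 0.5 * n * (1.0 / post_prec) / sigma2
        )
        fe = e_loglik - float(M.gaussian_kl(post_mean, 1.0 / post_prec, 0.0, s02))
        log_z = float(
            -0.5 * n * np.log(2 * np.pi * sigma2)
            - 0.5 * np.log(1 + n * s02 / sigma2)
            - 0.5 * (np.sum(y**2) / sigma2 - (y.sum() / sigma2) ** 2 / post_prec)
        )
        assert fe == pytest.approx(log_z, abs=1e-6)

    def test_nondecreasing_over_full_vb_sweeps(self, tiny_bundle, tiny_data, tiny_init):
        b = tiny_bundle
        cfg = M.ModelConfig(n_modes=b.config.n_modes, tr=b.config.tr)
        kernel = M.TemporalKernel.get(b.config.n_timepoints, cfg.tr, cfg.temporal_noise_floor)
        group = M.init_group_model(cfg, b.config.n_voxels, tiny_init.maps)
        subs = [
            M.init_subject(group, tiny_init.maps, b.config.n_runs, b.config.n_timepoints)
            for _ in range(4)
        ]
        data = tiny_data[:4]
        fes = []
        for _ in range(20):
            for s, subj in enumerate(subs):
                M.update_subject(data[s], group, subj, kernel)
            group = M.accumulate_and_update_group(subs, group, 1.0)
            fes.append(M.free_energy(group, subs, data).total)
        drops = [f2 - f1 for f1, f2 in zip(fes, fes[1:])]
        assert min(drops) >= -1e-6 * abs(fes[0])

    @pytest.mark.parametrize("factor", ["spatial", "temporal", "precision", "amplitude", "noise"])
    def test_single_factor_updates_never_decrease_free_energy(
        self, factor, tiny_bundle, tiny_data, tiny_init
    ):
        b = tiny_bundle
        cfg = M.ModelConfig(n_modes=b.config.n_modes, tr=b.config.tr)
        kernel = M.TemporalKernel.get(b.config.n_timepoints, cfg.tr, cfg.temporal_noise_floor)
        group = M.init_group_model(cfg, b.config.n_voxels, tiny_init.maps)
        subj = M.init_subject(group, tiny_init.maps, b.config.n_runs, b.config.n_timepoints)
        data = tiny_data[0]
        for _ in range(2):
            M.update_subject(data, group, subj, kernel)
        before = M.free_energy(group, [subj], [data]).total
        if factor == "spatial":
            M.dgmm_spatial_update(data, group, subj)
        elif factor == "temporal":
            for r, d in enumerate(data):
                M.temporal_update(d, subj, r, kernel, jitter=cfg.jitter)
        elif factor == "precision":
            M.precision_update(subj, group)
        elif factor == "amplitude":
            for r, d in enumerate(data):
                M.amplitude_update(d, subj, r, group)
        elif factor == "noise":
            for r, d in enumerate(data):
                M.noise_update(d, subj, r, cfg)
        after = M.free_energy(group, [subj], [data]).total
        assert after >= before - 1e-8 * abs(before)


class TestDivergenceHelpers:
    @given(
        m=st.floats(-3, 3), v=st.floats(0.1, 5), mp=st.floats(-3, 3), vp=st.floats(0.1, 5)
    )
    @settings(max_examples=50, deadline=None)
    def test_gaussian_kl_nonnegative_and_zero_at_equality(self, m, v, mp, vp):
        assert M.gaussian_kl(m, v, m, v) == pytest.approx(0.0, abs=1e-12)
        assert M.gaussian_kl(m, v, mp, vp) >= -1e-12

    @given(a=st.floats(0.5, 20), b=st.floats(0.1, 10), ap=st.floats(0.5, 20), bp=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_gamma_beta_kl_nonnegative(self, a, b, ap, bp):
        assert M.gamma_kl(a, b, ap, bp) >= -1e-10
        assert M.beta_kl(a, b, ap, bp) >= -1e-10
        assert M.gamma_kl(a, b, a, b) == pytest.approx(0.0, abs=1e-10)

    def test_wishart_kl_zero_at_equality_positive_otherwise(self):
        w = np.array([[0.8, 0.2], [0.2, 1.1]])
        assert M.wishart_kl(w, 7.0, w, 7.0) == pytest.approx(0.0, abs=1e-10)
        assert M.wishart_kl(w, 7.0, np.eye(2), 5.0) > 0
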
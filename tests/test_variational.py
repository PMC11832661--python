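"""Free-energy estimator tests: likelihood, sampling, gradients, and a
closed-form conjugate-Gaussian ELBO oracle."""

import math

import numpy as np
import pytest

from ssvb import VariationalState, free_energy_estimate, log_likelihood, sample_posterior
from ssvb.kinetics import AcquisitionSchedule, TissueConstants
from ssvb.simulate import simulate_dataset
from ssvb.spatial import build_laplacian, normal_logpdf
from ssvb.variational import (
    RMSProp,
    _buxton_model_grad,
    _data_stats,
    _free_energy_core,
)


class TestLogLikelihood:
    def test_zero_ssd_unit_precision(self):
        y = np.arange(5.0)
        assert log_likelihood(y, y, 1.0) == 0.0

    def test_precision_normalisation_term(self):
        y = np.zeros(36)
        assert log_likelihood(y, y, math.e**2) == pytest.approx(36.0)

    def test_hand_computed_example(self):
        # SSD = 1 + 4 = 5 -> (2/2)*log(1) - 5/2 = -2.5
        assert log_likelihood(np.array([1.0, 2.0]), np.zeros(2), 1.0) == \
            pytest.approx(-2.5)

    def test_errors(self):
        with pytest.raises(ValueError):
            log_likelihood(np.zeros(3), np.zeros(2), 1.0)
        with pytest.raises(ValueError):
            log_likelihood(np.zeros(3), np.zeros(3), 0.0)


def _state(v, rng=None, **over):
    rng = rng or np.random.default_rng(0)
    fields = dict(
        mean_cbf=rng.normal(55, 5, v),
        mean_att=rng.normal(1.4, 0.2, v),
        log_sd_cbf=np.full(v, math.log(8.0)),
        log_sd_att=np.full(v, math.log(0.4)),
        log_noise_var=np.full(v, math.log(300.0)),
        log_alpha_cbf=math.log(2e-2),
        log_alpha_att=math.log(3e-2),
    )
    fields.update(over)
    return VariationalState(**fields)


class TestSamplePosterior:
    def test_deterministic_under_seed(self):
        st = _state(9)
        a = sample_posterior(st, 4, np.random.default_rng(7))
        b = sample_posterior(st, 4, np.random.default_rng(7))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_degenerate_posterior_returns_means(self):
        st = _state(5, log_sd_cbf=np.full(5, -745.0),
                    log_sd_att=np.full(5, -745.0))
        cbf, att = sample_posterior(st, 3, np.random.default_rng(1))
        np.testing.assert_allclose(cbf, np.broadcast_to(st.mean_cbf, (3, 5)))
        np.testing.assert_allclose(att, np.broadcast_to(st.mean_att, (3, 5)))

    def test_sample_mean_matches_parametrisation(self):
        st = _state(4)
        L = 100_000
        cbf, att = sample_posterior(st, L, np.random.default_rng(11))
        se_cbf = 8.0 / math.sqrt(L)
        se_att = 0.4 / math.sqrt(L)
        assert np.all(np.abs(cbf.mean(axis=0) - st.mean_cbf) < 4 * se_cbf)
        assert np.all(np.abs(att.mean(axis=0) - st.mean_att) < 4 * se_att)

    def test_invalid_sample_count(self):
        with pytest.raises(ValueError):
            sample_posterior(_state(2), 0, np.random.default_rng(0))


class TestFreeEnergyGradients:
    def test_all_gradients_match_finite_differences(self, grey_schedule,
                                                    constants):
        ds = simulate_dataset(grey_schedule, constants, grid_shape=(2, 2, 2),
                              true_att=1.5, noise_sd=20, rng=1)
        stats = _data_stats(ds.data, grey_schedule)
        v = ds.n_voxels
        rng = np.random.default_rng(5)
        st = _state(v, rng)
        lap = (-build_laplacian(ds.grid)).tocsr().astype(float)
        npm = np.log(np.var(ds.data, axis=1))
        model = _buxton_model_grad(grey_schedule, constants)
        eps_f = rng.standard_normal((3, v))
        eps_a = rng.standard_normal((3, v))

        def F_of(state):
            return _free_energy_core(state, stats, eps_f, eps_a, model, lap,
                                     npm, 16.0)[0]

        _, grads = _free_energy_core(st, stats, eps_f, eps_a, model, lap,
                                     npm, 16.0)
        h = 1e-5
        for name in ("mean_cbf", "mean_att", "log_sd_cbf", "log_sd_att",
                     "log_noise_var"):
            for i in (0, v - 1):
                up, dn = st.copy(), st.copy()
                getattr(up, name)[i] += h
                getattr(dn, name)[i] -= h
                fd = (F_of(up) - F_of(dn)) / (2 * h)
                assert np.asarray(grads[name])[i] == pytest.approx(
                    fd, rel=1e-5, abs=1e-5), name
        for name in ("log_alpha_cbf", "log_alpha_att"):
            up, dn = st.copy(), st.copy()
            setattr(up, name, getattr(st, name) + h)
            setattr(dn, name, getattr(st, name) - h)
            fd = (F_of(up) - F_of(dn)) / (2 * h)
            assert grads[name] == pytest.approx(fd, rel=1e-5, abs=1e-5)


class TestFreeEnergyOracles:
    def _toy(self, L, rng, q_mean, q_sd, prior=(50.0, 20.0**2)):
        """Single-voxel linear-Gaussian toy model pred_i = a_i * cbf."""
        a = np.array([0.5, 1.0, 1.5])
        repeats = (2, 3, 1)
        sched = AcquisitionSchedule(1.0, plds=(0.1, 0.2, 0.3),
                                    repeats=repeats)
        rng_data = np.random.default_rng(99)
        theta_true = 60.0
        y = np.repeat(a, repeats) * theta_true + rng_data.normal(0, 5, 6)
        stats = _data_stats(y[None, :], sched)
        logvar = math.log(25.0)
        att_prior = (1.3, 0.25)
        st = VariationalState(
            mean_cbf=np.array([q_mean]), mean_att=np.array([1.3]),
            log_sd_cbf=np.array([math.log(q_sd)]),
            log_sd_att=np.array([math.log(0.5)]),
            log_noise_var=np.array([logvar]),
            log_alpha_cbf=0.0, log_alpha_att=0.0,
        )

        def model(cbf, att):
            pred = a * cbf
            return pred, np.broadcast_to(a, pred.shape).copy(), \
                np.zeros_like(pred)

        npm = np.array([logvar])
        eps_f = rng.standard_normal((L, 1))
        eps_a = rng.standard_normal((L, 1))
        F, _ = _free_energy_core(st, stats, eps_f, eps_a, model, None,
                                 npm, 16.0, cbf_prior=prior,
                                 att_prior=att_prior)

        # closed form: E_q[loglik] - KL(q_f||p_f) - KL(q_a||p_a) + noise term
        phi = math.exp(-logvar)
        R = np.array(repeats)
        e_ssd = (float(stats.sumsq[0])
                 - 2 * q_mean * float(stats.ysum[0] @ a)
                 + (q_mean**2 + q_sd**2) * float(np.sum(R * a**2)))
        e_loglik = 0.5 * 6 * (-logvar) - 0.5 * phi * e_ssd

        def kl(m, s, m0, v0):
            return (math.log(math.sqrt(v0) / s)
                    + (s**2 + (m - m0) ** 2) / (2 * v0) - 0.5)

        F_exact = (e_loglik
                   - kl(q_mean, q_sd, prior[0], prior[1])
                   - kl(1.3, 0.5, att_prior[0], att_prior[1])
                   + float(normal_logpdf(logvar, logvar, 16.0)))
        return F, F_exact

    def test_mc_estimate_matches_closed_form_elbo(self):
        # 3-SE check at L = 10^4; SE from 10 independent chunks
        rng = np.random.default_rng(42)
        chunks = [self._toy(1000, rng, q_mean=58.0, q_sd=4.0)[0]
                  for _ in range(10)]
        F_exact = self._toy(10, np.random.default_rng(0), 58.0, 4.0)[1]
        F_mc = float(np.mean(chunks))
        se = float(np.std(chunks, ddof=1)) / math.sqrt(10)
        assert abs(F_mc - F_exact) < 3 * se + 1e-9

    def test_divergence_vanishes_when_posterior_equals_prior(self):
        # with a flat (zero) model and matched q = p the sampled
        # divergence term averages to zero
        rng = np.random.default_rng(3)
        prior = (55.0, 6.0**2)
        F, F_exact = self._toy(20000, rng, q_mean=prior[0], q_sd=6.0,
                               prior=prior)
        assert F == pytest.approx(F_exact, abs=0.5)


class TestFreeEnergyEstimate:
    def test_point_mass_limit_recovers_plugin_value(self, grey_schedule,
                                                    constants):
        # sd -> 0: every sample equals mu, so the estimate converges to the
        # plug-in log-likelihood + priors at mu plus the entropy constants
        # (sum of log-SDs, E[eps^2/2] = 1/2 per parameter, and log 2pi)
        ds = simulate_dataset(grey_schedule, constants, grid_shape=(2, 2, 1),
                              true_att=1.3, noise_sd=10, rng=2)
        D = build_laplacian(ds.grid)
        v = ds.n_voxels
        st = _state(v, log_sd_cbf=np.full(v, -20.0),
                    log_sd_att=np.full(v, -20.0))
        L = 2000
        F = free_energy_estimate(st, ds, grey_schedule, constants, D, L,
                                 np.random.default_rng(0))

        from ssvb import log_likelihood, signal_vector, spatial_logpdf
        from ssvb.kinetics import KineticParams

        plug = sum(
            log_likelihood(
                ds.data[i],
                signal_vector(grey_schedule,
                              KineticParams(st.mean_cbf[i], st.mean_att[i]),
                              constants),
                math.exp(-st.log_noise_var[i]))
            for i in range(v))
        plug += spatial_logpdf(st.mean_cbf, math.exp(st.log_alpha_cbf), D)
        plug += spatial_logpdf(st.mean_att, math.exp(st.log_alpha_att), D)
        npm = np.log(np.var(ds.data, axis=1))
        plug += float(np.sum(normal_logpdf(st.log_noise_var, npm, 16.0)))
        plug += float(np.sum(st.log_sd_cbf + st.log_sd_att))
        plug += v * (1.0 + math.log(2.0 * math.pi))
        # MC error comes only from the eps^2/2 entropy term: SD = sqrt(v/L)
        assert F == pytest.approx(plug, abs=5 * math.sqrt(v / L))


class TestRMSProp:
    def test_minimises_a_quadratic(self):
        opt = RMSProp(learning_rate=0.1)
        params = {"x": np.array([5.0, -3.0])}
        for _ in range(500):
            g = 2.0 * params["x"]
            params = opt.step(params, {"x": g})
        # RMSProp settles into a limit cycle of order the learning rate
        np.testing.assert_allclose(params["x"], 0.0, atol=0.1)
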
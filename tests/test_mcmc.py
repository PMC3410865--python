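import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import gammaln

from trajmix.errors import DataError
from trajmix.mixture import (
    GibbsSampler,
    McmcConfig,
    gelman_rubin,
    run_mcmc,
)
from trajmix.signatures import Hyperparams, signature_log_prior
from trajmix.simulate import generate_counts_dataset, sample_prototype_library

from conftest import make_dataset


def make_sampler(counts, times, schedule, hyper=None, seed=0, **cfg_kw):
    # constant per-sample totals so the read-depth offsets are exactly zero
    counts = np.asarray(counts)
    totals = np.full(counts.shape[1], max(int(counts.sum(axis=0).max()) * 2, 10))
    ds = make_dataset(counts, times, totals=totals)
    cfg = McmcConfig(seed=seed, **cfg_kw)
    hyper = hyper or Hyperparams(mu_a_mean=float(np.log(np.mean(counts) + 1.0)))
    return GibbsSampler(ds, {"S1": schedule}, hyper, cfg, np.random.default_rng(seed))


@pytest.fixture
def prior_sampler(toy_schedule, toy_times):
    """Likelihood disabled: the chain must sample the prior exactly."""
    y = np.full((3, len(toy_times)), 10)
    # proposal scales of ~2.4 prior sd: without a likelihood the acceptance
    # ratio is near one, so small steps would mix by slow diffusion only
    scales = {"mu_a": 4.0, "X_b": 2.0, "X_d": 2.0, "d_ac": 2.0, "d_ce": 2.0,
              "loglam_c": 2.0, "loglam_e": 2.0, "gamma": 2.0, "logeps": 2.0}
    return make_sampler(
        y, toy_times, toy_schedule,
        hyper=Hyperparams(mu_a_mean=2.0),
        use_likelihood=False, update_alpha=False, alpha_init=1.0,
        proposal_scales=scales,
    )


class TestCrpUpdate:
    def test_cluster_count_matches_crp_closed_form(self, prior_sampler):
        """E[#clusters] for n=3, alpha=1 is 1 + 1/2 + 1/3 = 11/6."""
        counts = []
        for _ in range(4000):
            prior_sampler.update_assignments()
            counts.append(len(prior_sampler.clusters))
        assert np.mean(counts) == pytest.approx(11 / 6, abs=0.06)

    def test_single_unit_always_one_cluster(self, toy_schedule, toy_times):
        s = make_sampler(
            np.full((1, len(toy_times)), 5), toy_times, toy_schedule,
            use_likelihood=False, update_alpha=False,
        )
        for _ in range(50):
            s.sweep()
            assert len(s.clusters) == 1

    def test_identical_series_coassign_more_than_discordant(self, toy_schedule, toy_times):
        rng = np.random.default_rng(7)
        lib = sample_prototype_library(
            2, Hyperparams(mu_a_mean=5.0, mu_a_sd=1.0), seed=3,
            min_separation=2.0, schedule=toy_schedule,
        )
        from trajmix.signatures import evaluate_signature

        f0 = np.asarray(evaluate_signature(lib[0], toy_times, toy_schedule))
        f1 = np.asarray(evaluate_signature(lib[1], toy_times, toy_schedule))
        y = np.vstack([rng.poisson(np.exp(f0)), rng.poisson(np.exp(f0)),
                       rng.poisson(np.exp(f1))])
        s = make_sampler(y, toy_times, toy_schedule, seed=5)
        for _ in range(150):
            s.sweep()
        together = same01 = same02 = 0
        for _ in range(150):
            s.sweep()
            same01 += s.z[0] == s.z[1]
            same02 += s.z[0] == s.z[2]
        assert same01 > 3 * max(same02, 1)

    def test_occupancy_bookkeeping(self, toy_schedule, toy_times, rng):
        y = rng.integers(1, 50, size=(6, len(toy_times)))
        s = make_sampler(y, toy_times, toy_schedule)
        for _ in range(20):
            s.sweep()
            occ = np.bincount(s.z, minlength=len(s.clusters))
            assert occ.sum() == 6
            assert all(len(cl.members) == occ[k] for k, cl in enumerate(s.clusters))
            assert np.all(occ > 0)


class TestPriorRecovery:
    """With the likelihood off, every posterior marginal is its prior."""

    def test_switch_and_lambda_marginals(self, prior_sampler):
        sw, loglam, mu_a = [], [], []
        for i in range(4000):
            prior_sampler.sweep()
            if i % 2:
                for cl in prior_sampler.clusters:
                    sw.extend([cl.theta.s_ac, cl.theta.s_ce, cl.theta.s_lam])
                    loglam.append(cl.theta.loglam_c)
                    mu_a.append(cl.theta.mu_a)
        h = prior_sampler.hyper
        assert np.mean(sw) == pytest.approx(h.switch_prob, abs=0.05)
        assert np.mean(loglam) == pytest.approx(h.loglambda_mean, abs=0.12)
        assert np.std(loglam) == pytest.approx(h.loglambda_sd, rel=0.12)
        assert np.mean(mu_a) == pytest.approx(h.mu_a_mean, abs=0.25)
        assert np.std(mu_a) == pytest.approx(h.mu_a_sd, rel=0.15)

    def test_nuisance_marginals(self, prior_sampler):
        logeps, gam = [], []
        for i in range(3000):
            prior_sampler.sweep()
            if i % 2:
                logeps.append(np.log(prior_sampler.eps1))
                gam.append(prior_sampler.gamma[0])
        h = prior_sampler.hyper
        assert np.mean(logeps) == pytest.approx(h.logeps_mean, abs=0.25)
        assert np.std(logeps) == pytest.approx(h.logeps_sd, rel=0.2)
        assert np.mean(gam) == pytest.approx(0.0, abs=0.15)
        assert np.std(gam) == pytest.approx(h.gamma_sd, rel=0.15)

    def test_internal_prior_matches_public_density(self, prior_sampler):
        """Dual route: sampling-coordinate prior = public density + Jacobian."""
        for _ in range(25):
            th = prior_sampler._sample_theta_prior()
            internal = prior_sampler._theta_log_prior(th)
            public = signature_log_prior(th.to_public(), prior_sampler.hyper)
            jacobian = th.loglam_c + (th.loglam_e if th.s_lam else 0.0)
            assert internal == pytest.approx(public + jacobian, rel=1e-9)


class TestSignatureUpdates:
    def test_posterior_level_matches_poisson_oracle(self, toy_schedule):
        # constant signature, near-Poisson noise: the posterior of the total
        # log-level mu_a + gamma concentrates at log(mean count)
        rng = np.random.default_rng(11)
        times = np.linspace(0.0, 9.5, 60)  # all in the pre-treatment interval
        y = rng.poisson(150.0, size=(1, len(times)))[None][0]
        s = make_sampler(y.reshape(1, -1), times, toy_schedule, seed=3)
        for _ in range(300):
            s.sweep()
        levels = []
        for _ in range(400):
            s.sweep()
            levels.append(s.clusters[s.z[0]].theta.mu_a + s.gamma[0])
        assert np.mean(levels) == pytest.approx(np.log(y.mean()), abs=0.06)

    def test_zero_step_proposals_leave_state_unchanged(self, toy_schedule, toy_times, rng):
        y = rng.integers(1, 40, size=(4, len(toy_times)))
        s = make_sampler(
            y, toy_times, toy_schedule,
            proposal_scales={k: 0.0 for k in ("mu_a", "X_b", "X_d", "d_ac", "d_ce",
                                              "loglam_c", "loglam_e")},
        )
        before = [(cl.theta.mu_a, cl.theta.X_b, cl.theta.loglam_c) for cl in s.clusters]
        s.update_signatures()
        after = [(cl.theta.mu_a, cl.theta.X_b, cl.theta.loglam_c) for cl in s.clusters]
        assert before == after
        rates = s.acceptance_rates()
        assert rates["mu_a"] == 1.0 and rates["X_b"] == 1.0

    def test_tie_structure_always_consistent(self, prior_sampler):
        """Toggling a switch on and back off restores the exact ties."""
        for _ in range(300):
            prior_sampler.sweep()
            for cl in prior_sampler.clusters:
                th = cl.theta
                if not th.s_ac:
                    assert th.d_ac == 0.0
                if not th.s_ce:
                    assert th.d_ce == 0.0
                if not th.s_lam:
                    assert th.loglam_e == th.loglam_c


class TestSwitchPosterior:
    def test_level_shift_switch_matches_quadrature_oracle(self, toy_schedule, toy_times):
        """P(c->e switch on) against the exhaustive 2-model marginal likelihood."""
        rng = np.random.default_rng(21)
        from trajmix.signatures import PrototypeSignature, evaluate_signature

        truth = PrototypeSignature(mu_a=4.0, X_b=3.0, X_d=3.5, d_ce=1.2,
                                   c_mu=(False, True), lambda_c=4.0, lambda_e=4.0)
        f = np.asarray(evaluate_signature(truth, toy_times, toy_schedule))
        y = rng.poisson(np.exp(f), size=(1, len(toy_times)))
        # freeze everything except the c->e increment and its switch
        scales = {k: 0.0 for k in ("mu_a", "X_b", "X_d", "d_ac", "d_ce",
                                   "loglam_c", "loglam_e", "gamma", "logeps")}
        s = make_sampler(y, toy_times, toy_schedule, seed=9,
                         proposal_scales=scales, adapt_interval=10**9,
                         update_alpha=False)
        from trajmix.mixture import _Theta

        cl = s.clusters[s.z[0]]
        cl.theta = _Theta(mu_a=4.0, X_b=3.0, X_d=3.5, d_ce=0.0,
                          loglam_c=np.log(4.0), loglam_e=np.log(4.0),
                          s_ac=False, s_ce=False, s_lam=False)
        cl.invalidate()
        s.gamma[:] = 0.0
        s.eps1 = s.eps2 = 1e-4
        s.scales["d_ce"] = 0.3  # the only free continuous parameter

        on = 0
        n_iter = 3000
        for _ in range(n_iter):
            s.update_signatures()
            s.update_switches()
            on += s.clusters[s.z[0]].theta.s_ce

        # oracle: marginal likelihood of the switched model by quadrature
        def loglik(d):
            th = cl.theta.copy()
            th.s_ce, th.d_ce = True, d
            return s._score_cluster(cl, th)

        th_off = cl.theta.copy()
        th_off.s_ce, th_off.d_ce = False, 0.0
        base = s._score_cluster(cl, th_off)
        marg_on, _ = integrate.quad(
            lambda d: np.exp(loglik(d) - base) * stats.norm.pdf(d, 0, 1), -6, 6
        )
        p_on = marg_on / (marg_on + 1.0)  # prior odds 1:1
        assert on / n_iter == pytest.approx(p_on, abs=0.05)


class TestNuisance:
    def test_flat_data_gamma_centered_at_zero(self, prior_sampler):
        gam = []
        for _ in range(2000):
            prior_sampler.sweep()
            gam.append(prior_sampler.gamma[1])
        assert np.mean(gam) == pytest.approx(0.0, abs=0.12)

    def test_dispersion_recovery(self, toy_schedule):
        data, truth = generate_counts_dataset(
            n_subjects=1, n_refotus=8, K=2, schedule=toy_schedule,
            times=np.linspace(0, 50, 40), cv_target=0.6, seed=5,
        )
        samples = run_mcmc(
            data, truth.schedules,
            McmcConfig(n_burnin=400, n_sampling=400, thin=10, n_chains=1, seed=2),
        )
        est = np.mean([d.eps1 for d in samples.draws])
        assert abs(est - truth.eps1) / truth.eps1 < 0.5

    def test_alpha_update_matches_grid_conditional(self, prior_sampler):
        """Escobar-West chain against the closed-form conditional density."""
        s = prior_sampler
        # freeze the partition at k=2 clusters of the n=3 units
        k, n = 2, 3
        s.clusters = s.clusters[:1] * k
        draws = []
        s.alpha = 1.0
        for _ in range(20000):
            s.alpha = s._sample_alpha()
            draws.append(s.alpha)
        a, b = s.hyper.alpha_shape, s.hyper.alpha_rate
        grid = np.linspace(1e-4, 40, 8000)
        # p(alpha | k, n) ∝ Gamma(a,b) * alpha^k * Gamma(alpha) / Gamma(alpha+n)
        logd = (
            (a - 1) * np.log(grid) - b * grid + k * np.log(grid)
            + gammaln(grid) - gammaln(grid + n)
        )
        d = np.exp(logd - logd.max())
        d /= np.trapezoid(d, grid)
        target_mean = float(np.trapezoid(grid * d, grid))
        assert np.mean(draws) == pytest.approx(target_mean, rel=0.08)


class TestChainManagement:
    def test_retained_sample_arithmetic(self, toy_schedule, toy_times, rng):
        y = rng.integers(1, 30, size=(2, len(toy_times)))
        ds = make_dataset(y, toy_times)
        cfg = McmcConfig(n_burnin=5, n_sampling=40, thin=10, n_chains=2, seed=1)
        samples = run_mcmc(ds, {"S1": toy_schedule}, cfg)
        assert samples.n_draws == cfg.retained_samples == 8

    def test_no_sampling_gives_empty_posterior(self, toy_schedule, toy_times, rng):
        y = rng.integers(1, 30, size=(2, len(toy_times)))
        ds = make_dataset(y, toy_times)
        cfg = McmcConfig(n_burnin=3, n_sampling=0, thin=10, n_chains=2, seed=1)
        assert run_mcmc(ds, {"S1": toy_schedule}, cfg).n_draws == 0

    def test_empty_dataset_rejected(self, toy_schedule, toy_times):
        ds = make_dataset(np.zeros((1, len(toy_times)), int) + 1, toy_times)
        ds.counts["S1"] = ds.counts["S1"][:0]
        ds.refotus["S1"] = []
        with pytest.raises(DataError):
            run_mcmc(ds, {"S1": toy_schedule}, McmcConfig(n_chains=1))

    def test_seed_determinism(self, toy_schedule, toy_times, rng, tmp_path):
        y = rng.integers(1, 60, size=(3, len(toy_times)))
        ds = make_dataset(y, toy_times)
        cfg = McmcConfig(n_burnin=30, n_sampling=30, thin=10, n_chains=2, seed=42)
        a = run_mcmc(ds, {"S1": toy_schedule}, cfg)
        b = run_mcmc(ds, {"S1": toy_schedule}, cfg)
        pa, pb = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        a.save(pa)
        b.save(pb)
        assert pa.read_bytes() == pb.read_bytes()
        c = run_mcmc(ds, {"S1": toy_schedule},
                     McmcConfig(n_burnin=30, n_sampling=30, thin=10, n_chains=2, seed=43))
        pc = tmp_path / "c.jsonl"
        c.save(pc)
        assert pa.read_bytes() != pc.read_bytes()

    def test_partition_recovery_on_separated_signatures(self, toy_schedule, toy_times):
        from sklearn.metrics import adjusted_rand_score

        lib = sample_prototype_library(
            3, Hyperparams(mu_a_mean=5.5, mu_a_sd=1.0), seed=1,
            min_separation=2.5, schedule=toy_schedule,
        )
        data, truth = generate_counts_dataset(
            n_subjects=2, n_refotus=9, K=3, schedule=toy_schedule,
            times=toy_times, cv_target=0.4, seed=13, library=lib,
        )
        samples = run_mcmc(
            data, truth.schedules,
            McmcConfig(n_burnin=800, n_sampling=800, thin=10, n_chains=1, seed=4),
        )
        from trajmix.summaries import build_csgs, coassignment_matrix

        _, mat = coassignment_matrix(samples)
        groups = build_csgs(mat, samples)
        labels = np.empty(samples.n_units, int)
        for g, csg in enumerate(groups):
            for m in csg.members:
                labels[samples.units.index(m)] = g
        assert adjusted_rand_score(truth.z, labels) >= 0.9


class TestGewekeStyle:
    def test_successive_conditional_marginals_match_prior(self, toy_schedule):
        """parameters -> data -> parameters leaves prior marginals invariant."""
        rng = np.random.default_rng(3)
        times = np.array([0, 4, 8, 10, 11, 13, 16, 20, 26, 30, 33, 40.0])
        y0 = rng.poisson(20.0, size=(5, len(times)))
        ds = make_dataset(y0, times)
        hyper = Hyperparams(mu_a_mean=3.0, mu_a_sd=1.0)
        cfg = McmcConfig(seed=0, update_alpha=False, alpha_init=1.0)
        s = GibbsSampler(ds, {"S1": toy_schedule}, hyper, cfg, np.random.default_rng(17))
        # start from a prior draw of the full state
        s.config.use_likelihood = False
        for _ in range(50):
            s.sweep()
        s.config.use_likelihood = True
        mu_a, logeps, sw = [], [], []
        for i in range(4000):
            s.resample_counts()
            s.sweep()
            if i % 4 == 3:
                cl = s.clusters[s.z[0]]
                mu_a.append(cl.theta.mu_a)
                logeps.append(np.log(s.eps1))
                sw.append(cl.theta.s_lam)
        assert np.mean(mu_a) == pytest.approx(hyper.mu_a_mean, abs=0.2)
        assert np.std(mu_a) == pytest.approx(hyper.mu_a_sd, rel=0.25)
        assert np.mean(logeps) == pytest.approx(hyper.logeps_mean, abs=0.35)
        assert np.mean(sw) == pytest.approx(0.5, abs=0.08)


class TestGelmanRubin:
    def test_identical_chains_give_one(self):
        x = np.vstack([np.sin(np.arange(50.0))] * 3)
        assert gelman_rubin(x) == pytest.approx(1.0, abs=5e-3)

    def test_separated_chains_match_direct_formula(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 200)
        b = rng.normal(5, 1, 200)
        x = np.vstack([a, b])
        n = 200
        W = (a.var(ddof=1) + b.var(ddof=1)) / 2
        B_over_n = np.var([a.mean(), b.mean()], ddof=1)
        expected = np.sqrt(((n - 1) / n * W + B_over_n) / W)
        assert gelman_rubin(x) == pytest.approx(expected, rel=1e-12)
        assert gelman_rubin(x) > 1.5

    def test_affine_invariance(self, rng):
        x = rng.normal(size=(3, 100))
        assert gelman_rubin(3.0 * x - 7.0) == pytest.approx(gelman_rubin(x), rel=1e-10)

    def test_single_chain_rejected(self):
        with pytest.raises(DataError):
            gelman_rubin(np.zeros((1, 10)))
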
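import numpy as np
import pytest

from jmassoc.data import TrialDataset
from jmassoc.errors import DataError
from jmassoc.inference import (AdaptiveScalar, McmcSettings, PosteriorDraws,
                               PriorSpec, _ModelCache, diagnostics, ess,
                               fit_joint_model, initialize, rhat, summarize)
from jmassoc.synthetic_data import default_scenario, simulate_scenario
from jmassoc.trajectory import value_design

FAST = McmcSettings(n_chains=1, n_adapt=150, n_burnin=100, n_iter=300, seed=4)


class TestCacheAgreesWithReference:
    @pytest.mark.parametrize("tag", ["current_value", "slopes", "cumulative",
                                     "weighted_cumulative"])
    def test_survival_and_longitudinal_match(self, tag, rng):
        """The sampler's vectorized likelihood equals the plain per-subject
        reference implementation."""
        from jmassoc import hazard as hz
        from jmassoc.trajectory import SubjectEffects, TrajectoryParams, longitudinal_loglik
        sc = default_scenario(tag, n_subjects=30, seed=8)
        ds = simulate_scenario(sc)
        cache = _ModelCache(ds, sc.structure, sc.ncs, sc.baseline)
        beta = np.asarray(sc.traj.beta) + rng.normal(0, 0.1, 3)
        b = rng.normal(0, 0.8, (ds.n_subjects, 3))
        eff = {sid: SubjectEffects(tuple(b[i])) for i, sid in enumerate(ds.subject_ids)}
        a2 = sc.surv.alpha2
        fast = cache.surv_loglik_subjects(beta, b, np.asarray(sc.surv.gamma),
                                          sc.surv.alpha1, a2,
                                          np.asarray(sc.surv.k)).sum()
        tp = TrajectoryParams(tuple(beta), sc.traj.D, sc.traj.sigma2_eps)
        ref = hz.survival_loglik(ds, sc.structure, sc.surv, tp, eff,
                                 ncs=sc.ncs, baseline=sc.baseline)
        tol = 5e-3 if tag == "weighted_cumulative" else 1e-6
        assert fast == pytest.approx(ref, rel=tol)
        fl = cache.long_loglik_subjects(beta, b, sc.traj.sigma2_eps).sum()
        assert fl == pytest.approx(longitudinal_loglik(ds, tp, eff, sc.ncs), rel=1e-12)


class TestInitialize:
    def test_exact_on_noiseless_data(self):
        sc = default_scenario("current_value", n_subjects=40, seed=5)
        ds = simulate_scenario(sc)
        long = ds.longitudinal.copy()
        X = value_design(long["time_months"].to_numpy(), sc.ncs)
        long["sqrt_cd4"] = X @ np.asarray(sc.traj.beta)
        ds0 = TrialDataset(long, ds.survival, ds.meta)
        state = initialize(ds0, sc.structure, ncs=sc.ncs, baseline=sc.baseline)
        assert np.allclose(state["beta"], sc.traj.beta, atol=1e-6)

    def test_no_events_falls_back_to_prior_means(self, tiny_dataset):
        ds, sc = tiny_dataset
        surv = ds.survival.copy()
        surv["event"] = 0
        ds0 = TrialDataset(ds.longitudinal, surv, ds.meta)
        state = initialize(ds0, sc.structure, ncs=sc.ncs, baseline=sc.baseline)
        assert np.allclose(state["gamma"], 0.0)
        assert np.allclose(state["k"], 0.0)

    def test_initial_joint_loglik_finite(self, tiny_dataset):
        from jmassoc.hazard import SurvivalParams, joint_loglik
        from jmassoc.trajectory import SubjectEffects, TrajectoryParams
        ds, sc = tiny_dataset
        st = initialize(ds, sc.structure, ncs=sc.ncs, baseline=sc.baseline)
        traj = TrajectoryParams(tuple(st["beta"]), st["D"], st["sigma2_eps"])
        surv = SurvivalParams(tuple(st["gamma"]), st["alpha1"], tuple(st["k"]))
        eff = {sid: SubjectEffects((0.0, 0.0, 0.0)) for sid in ds.subject_ids}
        ll = joint_loglik(ds, sc.structure, surv, traj, eff,
                          ncs=sc.ncs, baseline=sc.baseline)
        assert np.isfinite(ll)

    def test_too_few_measurement_times_rejected(self, tiny_dataset):
        ds, sc = tiny_dataset
        long = ds.longitudinal[ds.longitudinal["time_months"] == 0.0]
        keep = set(long["subject_id"])
        surv = ds.survival[ds.survival["subject_id"].isin(keep)]
        ds0 = TrialDataset(long.copy(), surv.copy())
        with pytest.raises(DataError):
            initialize(ds0, sc.structure, ncs=sc.ncs, baseline=sc.baseline)


class TestSampler:
    def test_reproducible_given_seed(self, small_dataset):
        ds, sc = small_dataset
        a = fit_joint_model(ds, sc.structure, settings=FAST)
        b = fit_joint_model(ds, sc.structure, settings=FAST)
        for name in a.params:
            assert np.array_equal(a.params[name], b.params[name])
        assert np.array_equal(a.cond_loglik, b.cond_loglik)

    def test_consistency_smoke_low_noise(self):
        """With tiny residual noise the intercept posterior concentrates
        around the generating value."""
        from jmassoc.trajectory import TrajectoryParams
        from jmassoc.synthetic_data import simulate_trial
        sc = default_scenario("current_value", n_subjects=120, seed=21)
        traj = TrajectoryParams(sc.traj.beta, np.asarray(sc.traj.D) * 0.04, 0.01)
        ds = simulate_trial(sc.design, traj, sc.structure, sc.surv,
                            ncs=sc.ncs, baseline=sc.baseline)
        fit = fit_joint_model(ds, sc.structure, settings=McmcSettings(
            n_chains=1, n_adapt=300, n_burnin=200, n_iter=600, seed=1))
        b0 = fit.flat("beta")[:, 0]
        assert abs(b0.mean() - sc.traj.beta[0]) < 2 * max(b0.std(), 0.02)

    def test_conjugate_cross_check(self, small_dataset):
        """Survival factor off, b and sigma2 fixed: the beta posterior is the
        exact Gaussian conjugate posterior."""
        ds, sc = small_dataset
        sigma2 = 1.44
        prior_sd = 10.0
        init = initialize(ds, sc.structure, ncs=sc.ncs, baseline=sc.baseline)
        init["b"] = np.zeros_like(init["b"])
        init["sigma2_eps"] = sigma2
        fit = fit_joint_model(
            ds, sc.structure, PriorSpec(coef_sd=prior_sd),
            McmcSettings(n_chains=2, n_adapt=400, n_burnin=300, n_iter=2000, seed=2),
            ncs=sc.ncs, baseline=sc.baseline, init_state=init,
            likelihood="longitudinal",
            fixed=frozenset({"b", "sigma2_eps", "D", "gamma_alpha", "k"}))
        X = value_design(ds.longitudinal["time_months"].to_numpy(), sc.ncs)
        y = ds.longitudinal["sqrt_cd4"].to_numpy()
        prec = X.T @ X / sigma2 + np.eye(3) / prior_sd**2
        mean = np.linalg.solve(prec, X.T @ y / sigma2)
        cov = np.linalg.inv(prec)
        draws = fit.flat("beta")
        n_eff = 200.0  # conservative ESS for correlated RW draws
        for j in range(3):
            mc_se = np.sqrt(cov[j, j] / n_eff)
            assert abs(draws[:, j].mean() - mean[j]) < 4 * mc_se
            assert draws[:, j].std() == pytest.approx(np.sqrt(cov[j, j]), rel=0.25)

    def test_prior_only_sampling_recovers_prior(self, small_dataset):
        """Likelihood off: the kernel must reproduce the N(0, sd^2) prior."""
        ds, sc = small_dataset
        init = initialize(ds, sc.structure, ncs=sc.ncs, baseline=sc.baseline)
        fit = fit_joint_model(
            ds, sc.structure, PriorSpec(coef_sd=2.0),
            McmcSettings(n_chains=2, n_adapt=500, n_burnin=500, n_iter=3000, seed=6),
            ncs=sc.ncs, baseline=sc.baseline, init_state=init,
            likelihood="none",
            fixed=frozenset({"b", "sigma2_eps", "D", "gamma_alpha", "k"}))
        draws = fit.flat("beta")
        for j in range(3):
            e = ess(fit.params["beta"][:, :, j])
            se = 2.0 / np.sqrt(max(e, 10))
            assert abs(draws[:, j].mean()) < 4 * se
            assert draws[:, j].std() == pytest.approx(2.0, rel=0.3)


class TestSummaries:
    def _draws_from(self, arr):
        arr = np.asarray(arr, dtype=float).reshape(1, -1)
        n = arr.shape[1]
        return PosteriorDraws({"alpha1": arr}, np.zeros((1, n, 1)),
                              np.zeros((1, n)), np.zeros((1, 1)), "current_value")

    def test_constant_draws_give_stated_hr(self):
        d = self._draws_from(np.full(100, np.log(0.79)))
        tab = summarize(d).set_index("param")
        assert tab.loc["alpha1", "HR"] == pytest.approx(0.79, rel=1e-12)

    def test_symmetric_draws_bracket_unity(self, rng):
        d = self._draws_from(rng.normal(0, 0.5, 4000))
        tab = summarize(d).set_index("param")
        assert tab.loc["alpha1", "HR_lo"] < 1 < tab.loc["alpha1", "HR_hi"]

    def test_quantiles_match_sorted_oracle(self, rng):
        x = rng.normal(2, 3, 10_000)
        d = self._draws_from(x)
        tab = summarize(d).set_index("param")
        xs = np.sort(x)
        for q, col in ((0.025, "q2.5"), (0.975, "q97.5")):
            assert tab.loc["alpha1", col] == pytest.approx(
                np.quantile(xs, q), rel=1e-9)


class TestDiagnostics:
    def test_identical_iid_chains_rhat_near_one(self, rng):
        x = rng.normal(0, 1, (1, 2000))
        arr = np.vstack([x, x])
        assert rhat(arr) == pytest.approx(1.0, abs=0.02)

    def test_iid_ess_near_sample_size(self, rng):
        x = rng.normal(0, 1, (2, 2000))
        assert ess(x) == pytest.approx(4000, rel=0.2)

    def test_divergent_chain_flagged(self, rng):
        a = rng.normal(0, 1, (1, 1000))
        b = rng.normal(8, 1, (1, 1000))
        assert rhat(np.vstack([a, b])) > 1.1

    def test_diagnostics_table(self, small_dataset):
        ds, sc = small_dataset
        fit = fit_joint_model(ds, sc.structure, settings=McmcSettings(
            n_chains=2, n_adapt=150, n_burnin=100, n_iter=200, seed=3))
        tab = diagnostics(fit)
        assert {"param", "rhat", "ess", "flag"} <= set(tab.columns)
        assert len(tab) == len(fit.scalar_names())
        assert np.isfinite(tab["ess"]).all()


def test_sbc_rank_uniformity_single_parameter():
    """Simulation-based calibration of the adaptive scalar kernel on a
    one-parameter Normal-mean model: posterior ranks of the truth are
    uniform if the sampler targets the correct posterior."""
    from scipy.stats import kstest
    rng = np.random.default_rng(99)
    tau, sigma, m = 2.0, 1.0, 5
    n_rep, n_draw = 200, 120
    ranks = []
    for _ in range(n_rep):
        theta0 = rng.normal(0, tau)
        y = rng.normal(theta0, sigma, m)
        # RW chain using the package's adaptive scalar step
        kern = AdaptiveScalar(0.44, 0.5)
        th = 0.0
        def logpost(t):
            return -0.5 * t**2 / tau**2 - 0.5 * np.sum((y - t) ** 2) / sigma**2
        lp = logpost(th)
        draws = np.empty(n_draw)
        for i in range(100 + n_draw):
            prop = th + kern.scale * rng.standard_normal()
            lpp = logpost(prop)
            ap = min(1.0, np.exp(lpp - lp))
            if rng.random() < ap:
                th, lp = prop, lpp
            if i < 60:
                kern.adapt(ap)
            if i >= 100:
                draws[i - 100] = th
        ranks.append((draws[::4] < theta0).mean())  # thin to cut autocorrelation
    stat = kstest(ranks, "uniform").pvalue
    assert stat > 0.01
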
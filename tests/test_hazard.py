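import numpy as np
import pandas as pd
import pytest

from jmassoc.data import SubjectCovariates, TrialDataset
from jmassoc.errors import ConfigurationError, DomainError
from jmassoc.hazard import (AssociationStructure, SurvivalParams,
                            cumulative_hazard, joint_loglik, log_hazard,
                            survival_loglik)
from jmassoc.splines import BaselineSplineSpec, NcsSpec
from jmassoc.synthetic_data import _linear_log_baseline
from jmassoc.trajectory import (SubjectEffects, TrajectoryParams, WeightSpec,
                                longitudinal_loglik, m_area, m_slope, m_value,
                                m_weighted_area)

NCS = NcsSpec((0.0, 24.0), (6.0,))
BASE = BaselineSplineSpec(3, (10.0, 20.0, 30.0, 40.0, 50.0), (0.0, 60.0))
NK = BASE.n_basis
COVS = SubjectCovariates(1, 34.0, 0)
TRAJ = TrajectoryParams((12.0, 3.0, 5.0), np.eye(3), 1.0)
EFF = SubjectEffects((0.5, -0.3, 0.2))


def flat_baseline(level):
    """k giving log h0(t) = level exactly."""
    return _linear_log_baseline(level, 0.0, BASE)


def sp(alpha1=-0.2, alpha2=None, gamma=(0.0, 0.0, 0.0), k=None):
    return SurvivalParams(gamma, alpha1, k if k is not None else flat_baseline(-3.0),
                          alpha2=alpha2)


def all_structures():
    w = WeightSpec(15.0, 60.0)
    return [
        (AssociationStructure("current_value"), sp()),
        (AssociationStructure("slopes"), sp(alpha2=-0.3)),
        (AssociationStructure("cumulative"), sp(alpha1=-0.01)),
        (AssociationStructure("weighted_cumulative", w), sp()),
    ]


class TestLogHazard:
    def test_null_association_gives_baseline(self):
        p = sp(alpha1=0.0)
        t = np.linspace(0.5, 59.5, 25)
        got = log_hazard(t, AssociationStructure("current_value"), p, TRAJ, EFF,
                         COVS, ncs=NCS, baseline=BASE)
        assert np.allclose(got, -3.0, atol=1e-10)

    def test_slopes_with_zero_alpha2_matches_current_value(self):
        p_cv = sp(alpha1=-0.25)
        p_sl = sp(alpha1=-0.25, alpha2=0.0)
        t = np.linspace(0.5, 59.5, 25)
        a = log_hazard(t, AssociationStructure("current_value"), p_cv, TRAJ, EFF,
                       COVS, ncs=NCS, baseline=BASE)
        b = log_hazard(t, AssociationStructure("slopes"), p_sl, TRAJ, EFF,
                       COVS, ncs=NCS, baseline=BASE)
        assert np.allclose(a, b, atol=0.0)

    @pytest.mark.parametrize("structure,params", all_structures(),
                             ids=[s.tag for s, _ in all_structures()])
    def test_compositional_oracle(self, structure, params):
        """log h = log h0 + gamma'w + alpha * functional, re-composed from the
        trajectory-module functionals directly."""
        gamma = (-0.5, -0.01, -0.6)
        params = SurvivalParams(gamma, params.alpha1, params.k, alpha2=params.alpha2)
        t = np.linspace(0.5, 59.0, 15)
        got = log_hazard(t, structure, params, TRAJ, EFF, COVS,
                         ncs=NCS, baseline=BASE)
        lin = -3.0 + np.asarray(gamma) @ COVS.as_array()
        if structure.tag == "current_value":
            fn = params.alpha1 * m_value(t, TRAJ, EFF, NCS)
        elif structure.tag == "slopes":
            fn = (params.alpha1 * m_value(t, TRAJ, EFF, NCS)
                  + params.alpha2 * m_slope(t, TRAJ, EFF, NCS))
        elif structure.tag == "cumulative":
            fn = params.alpha1 * m_area(t, TRAJ, EFF, NCS)
        else:
            fn = params.alpha1 * m_weighted_area(t, TRAJ, EFF, NCS, structure.weight)
        assert np.allclose(got, lin + fn, rtol=1e-12)

    def test_structure_params_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            log_hazard(1.0, AssociationStructure("current_value"),
                       sp(alpha2=0.1), TRAJ, EFF, COVS, ncs=NCS, baseline=BASE)
        with pytest.raises(ConfigurationError):
            log_hazard(1.0, AssociationStructure("slopes"), sp(), TRAJ, EFF,
                       COVS, ncs=NCS, baseline=BASE)
        with pytest.raises(ConfigurationError):
            AssociationStructure("weighted_cumulative")  # missing weight


class TestCumulativeHazard:
    def test_zero_at_origin(self):
        st = AssociationStructure("current_value")
        assert cumulative_hazard(0.0, st, sp(), TRAJ, EFF, COVS,
                                 ncs=NCS, baseline=BASE) == 0.0

    def test_constant_hazard_is_linear(self):
        st = AssociationStructure("current_value")
        p = sp(alpha1=0.0, k=flat_baseline(np.log(0.05)))
        for T in (3.0, 24.0, 60.0):
            H = cumulative_hazard(T, st, p, TRAJ, EFF, COVS, ncs=NCS, baseline=BASE)
            assert H == pytest.approx(0.05 * T, rel=1e-9)

    @pytest.mark.parametrize("structure,params", all_structures(),
                             ids=[s.tag for s, _ in all_structures()])
    def test_matches_trapezoid_oracle(self, structure, params):
        T = 24.0
        grid = np.linspace(0, T, 100_001)
        h = np.exp(log_hazard(grid, structure, params, TRAJ, EFF, COVS,
                              ncs=NCS, baseline=BASE))
        ref = np.trapezoid(h, grid)
        got = cumulative_hazard(T, structure, params, TRAJ, EFF, COVS,
                                ncs=NCS, baseline=BASE)
        assert got == pytest.approx(ref, rel=1e-5)

    @pytest.mark.parametrize("structure,params", all_structures(),
                             ids=[s.tag for s, _ in all_structures()])
    def test_monotone_nondecreasing(self, structure, params):
        Ts = np.linspace(0, 60, 41)
        H = [cumulative_hazard(T, structure, params, TRAJ, EFF, COVS,
                               ncs=NCS, baseline=BASE) for T in Ts]
        assert np.all(np.diff(H) >= -1e-12)
        assert np.all(np.isfinite(H))

    def test_beyond_support_rejected(self):
        with pytest.raises(DomainError):
            cumulative_hazard(61.0, AssociationStructure("current_value"), sp(),
                              TRAJ, EFF, COVS, ncs=NCS, baseline=BASE)


def tiny_survival_dataset():
    long = pd.DataFrame({"subject_id": [1, 1, 2],
                         "time_months": [0.0, 2.0, 0.0],
                         "sqrt_cd4": [12.5, 13.0, 11.0]})
    surv = pd.DataFrame({"subject_id": [1, 2], "time_months": [10.0, 24.0],
                         "event": [1, 0], "arm": [1, 0],
                         "age": [30.0, 40.0], "gender": [0, 1]})
    return TrialDataset(long, surv)


class TestLikelihoods:
    def test_all_censored_at_zero_gives_zero(self):
        long = pd.DataFrame({"subject_id": [1], "time_months": [0.0], "sqrt_cd4": [12.0]})
        surv = pd.DataFrame({"subject_id": [1], "time_months": [0.0], "event": [0],
                             "arm": [1], "age": [30.0], "gender": [0]})
        ds = TrialDataset(long, surv)
        eff = {1: EFF}
        got = survival_loglik(ds, AssociationStructure("current_value"), sp(),
                              TRAJ, eff, ncs=NCS, baseline=BASE)
        assert got == 0.0

    def test_single_subject_constant_hazard(self):
        ds = tiny_survival_dataset()
        ds = TrialDataset(ds.longitudinal[ds.longitudinal.subject_id == 1],
                          ds.survival[ds.survival.subject_id == 1])
        h = 0.02
        p = sp(alpha1=0.0, k=flat_baseline(np.log(h)))
        got = survival_loglik(ds, AssociationStructure("current_value"), p,
                              TRAJ, {1: EFF}, ncs=NCS, baseline=BASE)
        assert got == pytest.approx(np.log(h) - h * 10.0, rel=1e-9)

    def test_compositional_oracle(self):
        ds = tiny_survival_dataset()
        st = AssociationStructure("current_value")
        p = sp(gamma=(-0.5, -0.01, -0.6))
        eff = {1: EFF, 2: SubjectEffects((-0.2, 0.4, 0.1))}
        got = survival_loglik(ds, st, p, TRAJ, eff, ncs=NCS, baseline=BASE)
        ref = 0.0
        for row in ds.survival.itertuples():
            covs = SubjectCovariates(row.arm, row.age, row.gender)
            H = cumulative_hazard(row.time_months, st, p, TRAJ, eff[row.subject_id],
                                  covs, ncs=NCS, baseline=BASE)
            ref -= H
            if row.event:
                ref += log_hazard(row.time_months, st, p, TRAJ, eff[row.subject_id],
                                  covs, ncs=NCS, baseline=BASE)
        assert got == pytest.approx(ref, rel=1e-12)

    def test_joint_additivity_and_factorization(self):
        ds = tiny_survival_dataset()
        st = AssociationStructure("current_value")
        eff = {1: EFF, 2: SubjectEffects((-0.2, 0.4, 0.1))}
        p0 = sp(alpha1=0.0)
        jl = joint_loglik(ds, st, p0, TRAJ, eff, ncs=NCS, baseline=BASE)
        from scipy.stats import multivariate_normal
        mvn = multivariate_normal(np.zeros(3), TRAJ.D)
        parts = (longitudinal_loglik(ds, TRAJ, eff, NCS)
                 + survival_loglik(ds, st, p0, TRAJ, eff, ncs=NCS, baseline=BASE)
                 + sum(mvn.logpdf(np.asarray(e.b)) for e in eff.values()))
        assert jl == pytest.approx(parts, rel=1e-12)
        # with alpha = 0 the survival factor ignores the random effects
        eff2 = {1: SubjectEffects((5.0, 5.0, 5.0)), 2: SubjectEffects((-5.0, 0.0, 2.0))}
        s1 = survival_loglik(ds, st, p0, TRAJ, eff, ncs=NCS, baseline=BASE)
        s2 = survival_loglik(ds, st, p0, TRAJ, eff2, ncs=NCS, baseline=BASE)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_hand_composed_two_subject_value(self):
        """Fully hand-built check: flat baseline, zero covariate effects,
        constant trajectories (only intercept), current-value association."""
        long = pd.DataFrame({"subject_id": [1, 1, 2],
                             "time_months": [0.0, 2.0, 0.0],
                             "sqrt_cd4": [12.0, 12.0, 8.0]})
        surv = pd.DataFrame({"subject_id": [1, 2], "time_months": [6.0, 12.0],
                             "event": [1, 0], "arm": [0, 0],
                             "age": [30.0, 30.0], "gender": [0, 0]})
        ds = TrialDataset(long, surv)
        traj = TrajectoryParams((12.0, 0.0, 0.0), np.eye(3), 1.0)
        eff = {1: SubjectEffects((0.0, 0.0, 0.0)), 2: SubjectEffects((-2.0, 0.0, 0.0))}
        alpha, lh0 = -0.1, np.log(0.05)
        p = sp(alpha1=alpha, k=flat_baseline(lh0))
        st = AssociationStructure("current_value")
        # hand: subject hazards constant: h_i = 0.05*exp(alpha*m_i)
        h1 = 0.05 * np.exp(alpha * 12.0)
        h2 = 0.05 * np.exp(alpha * 10.0)
        surv_hand = (np.log(h1) - h1 * 6.0) + (-h2 * 12.0)
        long_hand = (-0.5 * 2 * np.log(2 * np.pi)        # subject 1 exact fit
                     - 0.5 * (np.log(2 * np.pi) + 4.0))  # subject 2: y=8, m=10
        from scipy.stats import multivariate_normal
        mvn = multivariate_normal(np.zeros(3), np.eye(3))
        prior_hand = mvn.logpdf([0, 0, 0]) + mvn.logpdf([-2, 0, 0])
        got = joint_loglik(ds, st, p, traj, eff, ncs=NCS, baseline=BASE)
        assert got == pytest.approx(surv_hand + long_hand + prior_hand, rel=1e-9)

    def test_quadrature_refinement_stable(self, small_dataset):
        ds, sc = small_dataset
        order = {sid: i for i, sid in enumerate(ds.subject_ids)}
        b_all = ds.meta["true_b"]
        eff = {sid: SubjectEffects(tuple(b_all[order[sid]])) for sid in ds.subject_ids}
        a = survival_loglik(ds, sc.structure, sc.surv, sc.traj, eff,
                            ncs=sc.ncs, baseline=sc.baseline, n_panels=7)
        b = survival_loglik(ds, sc.structure, sc.surv, sc.traj, eff,
                            ncs=sc.ncs, baseline=sc.baseline, n_panels=14)
        assert a == pytest.approx(b, abs=1e-6)

    def test_nesting_current_value_is_alpha2_zero_slice(self, small_dataset):
        ds, sc = small_dataset
        order = {sid: i for i, sid in enumerate(ds.subject_ids)}
        eff = {sid: SubjectEffects(tuple(ds.meta["true_b"][order[sid]]))
               for sid in ds.subject_ids}
        p_cv = SurvivalParams(sc.surv.gamma, sc.surv.alpha1, sc.surv.k)
        p_sl = SurvivalParams(sc.surv.gamma, sc.surv.alpha1, sc.surv.k, alpha2=0.0)
        a = survival_loglik(ds, AssociationStructure("current_value"), p_cv,
                            sc.traj, eff, ncs=sc.ncs, baseline=sc.baseline)
        b = survival_loglik(ds, AssociationStructure("slopes"), p_sl,
                            sc.traj, eff, ncs=sc.ncs, baseline=sc.baseline)
        assert a == pytest.approx(b, rel=1e-14)
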
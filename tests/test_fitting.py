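import numpy as np
import pytest

from weibullcr.data_model import Dataset, SubjectRecord, design_matrix
from weibullcr.fitting import (
    ModelParams,
    cause_specific_hazard,
    fit_competing,
    fit_naive,
    hazard_ratio,
    hr_from_coefficient,
    log_likelihood,
    overall_survival,
    wald_interval,
    _grad_single,
    _loglik_single,
)
from weibullcr.synthetic import GeneratorConfig, generate_cohort


def _record(time, event, stage="I", sex="man"):
    return SubjectRecord(time=time, event=event, sex=sex, age=50.0, bmi=24.0,
                         stage=stage)


def _intercept_params(lams, shapes):
    betas = np.zeros((len(lams), 7))
    betas[:, 0] = np.log(lams)
    return ModelParams(betas=betas, shapes=np.asarray(shapes, dtype=float))


class TestHazardAndSurvival:
    def test_unit_exponential_hazard_is_one(self):
        params = _intercept_params([1.0], [1.0])
        x = np.zeros(7); x[0] = 1.0
        params.betas[0, 0] = 0.0
        for t in (0.1, 1.0, 50.0):
            assert cause_specific_hazard(t, x, 1, params) == pytest.approx(1.0)

    def test_weibull_hazard_value(self):
        # lam=1, p=2, t=3 -> h = 1 * 2 * 3 = 6
        params = _intercept_params([1.0], [2.0])
        x = np.zeros(7); x[0] = 1.0
        params.betas[0, 0] = 0.0
        assert cause_specific_hazard(3.0, x, 1, params) == pytest.approx(6.0)

    def test_nonpositive_time_rejected(self):
        params = _intercept_params([1.0], [1.0])
        x = np.zeros(7); x[0] = 1.0
        with pytest.raises(ValueError):
            cause_specific_hazard(0.0, x, 1, params)

    def test_hazard_is_negative_log_survival_derivative(self, rng):
        # finite-difference oracle at random (t, params, x) points
        for _ in range(100):
            lam1, lam2 = rng.uniform(0.01, 0.1, size=2)
            p1, p2 = rng.uniform(0.5, 2.0, size=2)
            params = _intercept_params([lam1, lam2], [p1, p2])
            x = np.zeros(7); x[0] = 1.0
            # t range keeps the cumulative hazard small enough that S(t)
            # stays well inside double precision
            t = rng.uniform(0.5, 20.0)
            h = cause_specific_hazard(t, x, 1, params)
            eps = 1e-6 * t
            from weibullcr.fitting import cause_specific_survival
            s_p = cause_specific_survival(t + eps, x, 1, params)
            s_m = cause_specific_survival(t - eps, x, 1, params)
            fd = -(np.log(s_p) - np.log(s_m)) / (2 * eps)
            assert h == pytest.approx(fd, rel=1e-5)

    def test_overall_survival_boundaries(self):
        params = _intercept_params([1.0, 1.0], [1.0, 1.0])
        x = np.zeros(7); x[0] = 1.0
        params.betas[:, 0] = 0.0
        assert overall_survival(0.0, x, params) == 1.0
        assert overall_survival(1.0, x, params) == pytest.approx(np.exp(-2.0))

    def test_overall_is_product_of_cause_specific(self, rng):
        from weibullcr.fitting import cause_specific_survival
        params = _intercept_params(rng.uniform(0.01, 0.2, 2),
                                   rng.uniform(0.6, 2.0, 2))
        x = np.zeros(7); x[0] = 1.0
        for t in rng.uniform(0.1, 120, size=20):
            prod = (cause_specific_survival(t, x, 1, params)
                    * cause_specific_survival(t, x, 2, params))
            assert overall_survival(t, x, params) == pytest.approx(prod, rel=1e-12)


class TestLogLikelihood:
    def test_single_censored_subject(self):
        # lam=1, p=1, censored at t=2 -> l = -2
        ds = Dataset(records=[_record(2.0, 0)], n_causes=1)
        params = _intercept_params([1.0], [1.0])
        params.betas[0, 0] = 0.0
        assert log_likelihood(ds, params) == pytest.approx(-2.0)

    def test_single_event_two_causes(self):
        # event cause 1 at t=1, lam1=lam2=1, p=1 -> log h1(1)=0, cumhaz = 2
        ds = Dataset(records=[_record(1.0, 1)], n_causes=2)
        params = _intercept_params([1.0, 1.0], [1.0, 1.0])
        params.betas[:, 0] = 0.0
        assert log_likelihood(ds, params) == pytest.approx(-2.0)

    def test_separability_on_random_datasets(self, rng):
        # joint competing-risks l == sum of per-cause censored-recode l's
        for trial in range(20):
            cfg = GeneratorConfig(n=60, seed=int(rng.integers(2**31 - 1)))
            ds, _ = generate_cohort(cfg)
            params = ModelParams(
                betas=cfg.betas + rng.normal(scale=0.1, size=cfg.betas.shape),
                shapes=cfg.shapes * rng.uniform(0.8, 1.2, size=2),
            )
            joint = log_likelihood(ds, params)
            total = 0.0
            for j in (1, 2):
                recoded = Dataset(
                    records=[
                        SubjectRecord(time=r.time, event=1 if r.event == j else 0,
                                      sex=r.sex, age=r.age, bmi=r.bmi, stage=r.stage)
                        for r in ds.records
                    ],
                    n_causes=1,
                )
                single = ModelParams(betas=params.betas[j - 1][None, :],
                                     shapes=params.shapes[j - 1:j])
                total += log_likelihood(recoded, single)
            assert joint == pytest.approx(total, abs=1e-9)

    def test_analytic_gradient_matches_finite_differences(self, rng):
        cfg = GeneratorConfig(n=150, seed=77)
        ds, _ = generate_cohort(cfg)
        t, X = ds.times, design_matrix(ds)
        delta = (ds.events == 1).astype(float)
        for _ in range(10):
            beta = rng.normal(scale=0.3, size=7)
            beta[0] = rng.uniform(-6, -3)
            beta[1:3] *= 0.02  # keep bmi/age contributions sane
            logp = rng.normal(scale=0.3)
            g = _grad_single(t, delta, X, beta, logp)
            theta = np.append(beta, logp)
            for i in range(8):
                h = 1e-6 * max(1.0, abs(theta[i]))
                tp = theta.copy(); tp[i] += h
                tm = theta.copy(); tm[i] -= h
                fd = (_loglik_single(t, delta, X, tp[:7], tp[7])
                      - _loglik_single(t, delta, X, tm[:7], tm[7])) / (2 * h)
                assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestFitting:
    def test_intercept_only_parameter_recovery(self):
        lam_true, p_true = 0.05, 1.2
        betas = np.zeros((1, 7)); betas[0, 0] = np.log(lam_true)
        cfg = GeneratorConfig(n=5000, seed=101, betas=betas,
                              shapes=np.array([p_true]),
                              censoring=("uniform", 132.0))
        ds, _ = generate_cohort(cfg)
        fit = fit_competing(ds, design=np.ones((len(ds), 1)))[0]
        assert fit.converged
        se = np.sqrt(np.diag(fit.covariance))
        assert abs(fit.beta[0] - np.log(lam_true)) < 3 * se[0]
        assert abs(np.log(fit.shape) - np.log(p_true)) < 3 * se[1]

    def test_exponential_closed_form_mle(self):
        # shape fixed at 1, intercept-only: lam-hat = events / person-time
        cfg = GeneratorConfig(n=2000, seed=55)
        ds, _ = generate_cohort(cfg)
        fits = fit_competing(ds, design=np.ones((len(ds), 1)), fixed_shape=1.0)
        for j, fit in enumerate(fits, start=1):
            closed = (ds.events == j).sum() / ds.times.sum()
            assert np.exp(fit.beta[0]) == pytest.approx(closed, abs=1e-6 * closed)

    def test_missing_cause_flagged_non_estimable(self):
        records = [_record(10.0 + i, 1 if i % 2 else 0) for i in range(40)]
        ds = Dataset(records=records, n_causes=2)
        fits = fit_competing(ds, design=np.ones((len(ds), 1)))
        assert fits[0].estimable and fits[0].converged
        assert not fits[1].estimable
        assert "not estimable" in fits[1].message

    def test_rank_deficient_design_flagged(self, default_cohort):
        _, ds, _ = default_cohort
        X = design_matrix(ds)
        X[:, 6] = X[:, 0]  # duplicate column
        fits = fit_competing(ds, design=X)
        assert not fits[0].estimable
        assert "rank deficient" in fits[0].message

    def test_competing_cause1_equals_naive_cause1(self, default_cohort):
        _, ds, _ = default_cohort
        comp = fit_competing(ds)[0]
        naive = fit_naive(ds, event_definition="cause-1-only")
        assert np.allclose(comp.beta, naive.beta, atol=1e-6)
        assert comp.shape == pytest.approx(naive.shape, abs=1e-6)
        assert comp.loglik == pytest.approx(naive.loglik, abs=1e-6)

    def test_any_death_event_count(self, default_cohort):
        _, ds, _ = default_cohort
        naive = fit_naive(ds, event_definition="any-death")
        assert naive.n_events == int((ds.events > 0).sum())

    def test_naive_recovers_truth_when_model_holds(self):
        # single active cause: the naive cause-1 analysis is the true model
        betas = np.zeros((1, 7))
        betas[0] = [-5.0, -0.03, 0.01, -0.3, 0.4, 0.8, 1.2]
        cfg = GeneratorConfig(n=4000, seed=303, betas=betas,
                              shapes=np.array([1.1]),
                              censoring=("uniform", 132.0))
        ds, _ = generate_cohort(cfg)
        fit = fit_naive(ds, event_definition="cause-1-only")
        assert fit.converged
        se = fit.beta_se
        for i in range(7):
            assert abs(fit.beta[i] - betas[0][i]) < 3.5 * se[i]

    def test_time_rescaling_preserves_covariate_hrs(self, default_cohort):
        # t -> c*t shifts only intercept and scale-linked quantities
        _, ds, _ = default_cohort
        fit0 = fit_competing(ds)[0]
        c = 12.0
        scaled = Dataset(
            records=[
                SubjectRecord(time=r.time * c, event=r.event, sex=r.sex,
                              age=r.age, bmi=r.bmi, stage=r.stage)
                for r in ds.records
            ],
            n_causes=2,
        )
        fit1 = fit_competing(scaled)[0]
        assert fit1.shape == pytest.approx(fit0.shape, rel=1e-4)
        # covariate coefficients (hence HRs) unchanged
        assert np.allclose(fit1.beta[1:], fit0.beta[1:], atol=1e-4)
        # intercept shifts by -p log c (Weibull scale property)
        assert fit1.beta[0] == pytest.approx(fit0.beta[0] - fit0.shape * np.log(c),
                                             abs=1e-3)


class TestWaldInference:
    @pytest.mark.parametrize(
        "coef,se,hr,lo,hi",
        [
            (1.507, 0.224, 4.511, 2.911, 6.992),
            (-0.266, 0.124, 0.766, 0.599, 0.978),
            (0.529, 0.158, 1.698, 1.246, 2.315),
        ],
    )
    def test_published_coefficient_chains(self, coef, se, hr, lo, hi):
        res = hr_from_coefficient(coef, se)
        assert res.hr == pytest.approx(hr, abs=0.01)
        assert res.ci_low == pytest.approx(lo, abs=0.01)
        assert res.ci_high == pytest.approx(hi, abs=0.01)

    def test_null_coefficient(self):
        res = hr_from_coefficient(0.0, 0.2)
        assert res.hr == 1.0
        assert res.ci_low * res.ci_high == pytest.approx(1.0)  # symmetric on log scale
        assert res.p_value == pytest.approx(1.0)

    def test_wald_interval_ordering(self):
        lo, hi = wald_interval(0.5, 0.1)
        assert lo < np.exp(0.5) < hi

    def test_hazard_ratio_lookup_by_name(self, default_cohort):
        _, ds, _ = default_cohort
        fit = fit_competing(ds)[0]
        res = hazard_ratio(fit, "stage_IV")
        i = fit.design_columns.index("stage_IV")
        assert res.hr == pytest.approx(np.exp(fit.beta[i]))
        with pytest.raises(KeyError):
            hazard_ratio(fit, "tumour_grade")
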
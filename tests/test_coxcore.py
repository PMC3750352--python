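"""Unit and property tests for the partial-likelihood engine."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from relhaz import (
    NonIdentifiableError,
    SurvivalDataset,
    TiesPolicy,
    fit_cox,
    fit_stratified_cox,
    log_partial_likelihood,
    score_and_information,
    wald_summary,
)

from _oracles import naive_fit, naive_log_partial_likelihood, random_small_dataset
from conftest import make_dataset


class TestLogPartialLikelihood:
    def test_all_events_distinct_times_at_null(self):
        # beta = 0: each event contributes -log(risk-set size) -> -log(4!)
        d = make_dataset([1, 2, 3, 4], [1, 1, 1, 1], np.array([[0.3], [1.0], [-1.2], [0.5]]))
        assert log_partial_likelihood([0.0], d) == pytest.approx(-np.log(24.0), abs=1e-12)

    def test_single_event_subject_is_zero(self):
        d = make_dataset([3.0], [1], np.array([[2.0]]))
        for beta in (-1.0, 0.0, 2.5):
            assert log_partial_likelihood([beta], d) == pytest.approx(0.0, abs=1e-14)

    def test_six_subject_fixture_matches_bruteforce(self, six_subject):
        d = six_subject
        want = naive_log_partial_likelihood(
            [0.3], d.time, d.event, d.covariates.to_numpy(), d.offset
        )
        assert log_partial_likelihood([0.3], d) == pytest.approx(want, abs=1e-12)

    # Efron equals Breslow when there are no ties; with ties the brute-force
    # oracle is Breslow-form, so the tied case checks Breslow only.
    @pytest.mark.parametrize(
        "allow_ties, method",
        [(False, "breslow"), (False, "efron"), (True, "breslow")],
    )
    def test_random_datasets_match_bruteforce(self, allow_ties, method):
        rng = np.random.default_rng(101)
        for _ in range(15):
            t, e, X, off = random_small_dataset(rng, allow_ties=allow_ties)
            beta = rng.normal(0, 0.7, X.shape[1])
            d = make_dataset(t, e, X, offset=off)
            got = log_partial_likelihood(beta, d, TiesPolicy(method))
            want = naive_log_partial_likelihood(beta, t, e, X, off)
            assert got == pytest.approx(want, abs=1e-10)

    def test_dimension_mismatch_raises(self, six_subject):
        with pytest.raises(ValueError, match="covariates"):
            log_partial_likelihood([0.1, 0.2], six_subject)

    def test_no_events_raises(self):
        d = make_dataset([1, 2], [0, 0], np.array([[1.0], [0.0]]))
        with pytest.raises(ValueError, match="events"):
            log_partial_likelihood([0.0], d)

    def test_offset_equivalent_to_frozen_unit_coefficient(self):
        rng = np.random.default_rng(5)
        t, e, X, off = random_small_dataset(rng)
        with_offset = make_dataset(t, e, X, offset=off)
        # append the offset as a covariate and freeze its coefficient at 1
        extended = make_dataset(t, e, np.column_stack([X, off]))
        for beta in ([0.2, -0.4], [0.0, 0.0]):
            assert log_partial_likelihood(beta, with_offset) == pytest.approx(
                log_partial_likelihood(list(beta) + [1.0], extended), abs=1e-12
            )


class TestScoreAndInformation:
    def test_gradient_matches_finite_differences(self, six_subject):
        d = six_subject
        for beta in ([0.0], [0.3]):
            U, _ = score_and_information(beta, d)
            h = 1e-6
            fd = (
                log_partial_likelihood([beta[0] + h], d)
                - log_partial_likelihood([beta[0] - h], d)
            ) / (2 * h)
            assert U[0] == pytest.approx(fd, abs=1e-6)

    @pytest.mark.parametrize("method", ["breslow", "efron"])
    def test_multivariate_gradient_and_hessian_fd(self, method):
        rng = np.random.default_rng(17)
        t, e, X, off = random_small_dataset(rng, p=3, allow_ties=(method == "efron"))
        d = make_dataset(t, e, X, offset=off)
        ties = TiesPolicy(method)
        beta = np.array([0.2, -0.1, 0.4])
        U, I = score_and_information(beta, d, ties)
        h = 1e-6
        for j in range(3):
            ej = np.eye(3)[j] * h
            fd = (
                log_partial_likelihood(beta + ej, d, ties)
                - log_partial_likelihood(beta - ej, d, ties)
            ) / (2 * h)
            assert U[j] == pytest.approx(fd, abs=1e-5)
            fdU_plus, _ = score_and_information(beta + ej, d, ties)
            fdU_minus, _ = score_and_information(beta - ej, d, ties)
            assert np.allclose(-(fdU_plus - fdU_minus) / (2 * h), I[j], atol=1e-5)

    def test_information_symmetric_psd(self):
        rng = np.random.default_rng(23)
        t, e, X, off = random_small_dataset(rng, p=3)
        d = make_dataset(t, e, X, offset=off)
        _, I = score_and_information([0.5, -0.2, 0.1], d)
        assert np.allclose(I, I.T, atol=1e-12)
        assert np.linalg.eigvalsh(I).min() >= -1e-10

    def test_gradient_zero_at_maximum(self):
        rng = np.random.default_rng(31)
        t, e, X, off = random_small_dataset(rng)
        d = make_dataset(t, e, X, offset=off)
        fit = fit_cox(d)
        U, _ = score_and_information(fit.coef.to_numpy(), d)
        assert np.max(np.abs(U)) < 1e-6


class TestFitCox:
    def test_symmetric_tied_dataset_gives_zero(self, symmetric_ties):
        fit = fit_cox(symmetric_ties, TiesPolicy("breslow"))
        assert abs(fit.coef.iloc[0]) < 1e-8

    def test_fixture_matches_scalar_direct_search(self, six_subject):
        d = six_subject
        neg = lambda b: -log_partial_likelihood([b], d)
        res = optimize.minimize_scalar(neg, bounds=(-5, 5), method="bounded",
                                       options={"xatol": 1e-10})
        fit = fit_cox(d)
        assert fit.coef.iloc[0] == pytest.approx(res.x, abs=1e-6)

    def test_random_datasets_match_bruteforce_maximizer(self):
        rng = np.random.default_rng(202)
        for _ in range(20):
            t, e, X, off = random_small_dataset(rng)
            d = make_dataset(t, e, X, offset=off)
            fit = fit_cox(d)
            if not fit.converged:
                continue  # monotone-likelihood resample: oracle diverges too
            want = naive_fit(t, e, X, offset=off)
            assert np.allclose(fit.coef.to_numpy(), want, atol=1e-5)

    def test_loglik_not_below_null(self):
        rng = np.random.default_rng(7)
        t, e, X, off = random_small_dataset(rng)
        fit = fit_cox(make_dataset(t, e, X, offset=off))
        assert fit.loglik >= fit.loglik_null - 1e-12

    def test_constant_covariate_raises(self):
        d = make_dataset([1, 2, 3], [1, 1, 0], np.zeros((3, 1)))
        with pytest.raises(NonIdentifiableError):
            fit_cox(d)

    def test_monotone_likelihood_flagged(self):
        # the covariate perfectly orders events before censorings
        d = make_dataset(
            [1, 2, 3, 4, 5, 6],
            [1, 1, 1, 0, 0, 0],
            np.array([[1.0], [1.0], [1.0], [0.0], [0.0], [0.0]]),
        )
        with pytest.warns(RuntimeWarning, match="monotone"):
            fit = fit_cox(d)
        assert not fit.converged

    def test_offset_constant_shift_leaves_fit_unchanged(self):
        rng = np.random.default_rng(13)
        t, e, X, off = random_small_dataset(rng)
        f1 = fit_cox(make_dataset(t, e, X, offset=off))
        f2 = fit_cox(make_dataset(t, e, X, offset=off + 3.7))
        assert np.allclose(f1.coef.to_numpy(), f2.coef.to_numpy(), atol=1e-9)

    def test_monotone_time_transform_leaves_fit_unchanged(self):
        rng = np.random.default_rng(19)
        t, e, X, off = random_small_dataset(rng)
        f1 = fit_cox(make_dataset(t, e, X, offset=off))
        f2 = fit_cox(make_dataset(np.exp(t), e, X, offset=off))
        assert np.allclose(f1.coef.to_numpy(), f2.coef.to_numpy(), atol=1e-10)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-10)

    def test_concave_profile_unimodal_through_maximum(self, six_subject):
        fit = fit_cox(six_subject)
        b_hat = fit.coef.iloc[0]
        grid = b_hat + np.linspace(-2, 2, 41)
        vals = [log_partial_likelihood([b], six_subject) for b in grid]
        diffs = np.sign(np.diff(vals))
        assert (np.diff(diffs) <= 0).all()  # increasing then decreasing

    def test_efron_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        n = 200
        X = rng.standard_normal((n, 2))
        T = rng.exponential(1 / np.exp(X @ [0.5, -0.3]))
        C = rng.exponential(1.5, n)
        t, e = np.minimum(T, C), (T <= C).astype(int)
        t = np.ceil(t * 10) / 10  # create ties so Efron matters
        fit = fit_cox(make_dataset(t, e, X), TiesPolicy("efron"))
        df = pd.DataFrame(X, columns=["x0", "x1"]).assign(t=t, e=e)
        cph = lifelines.CoxPHFitter().fit(df, "t", "e")
        assert np.allclose(fit.coef.to_numpy(), cph.params_.to_numpy(), atol=1e-5)
        assert np.allclose(fit.se.to_numpy(), cph.standard_errors_.to_numpy(), atol=1e-5)

    def test_breslow_matches_scikit_survival(self):
        sksurv = pytest.importorskip("sksurv.linear_model")
        from sksurv.util import Surv

        rng = np.random.default_rng(4)
        n = 200
        X = rng.standard_normal((n, 2))
        T = rng.exponential(1 / np.exp(X @ [0.4, 0.6]))
        C = rng.exponential(2.0, n)
        t, e = np.minimum(T, C), (T <= C).astype(int)
        fit = fit_cox(make_dataset(t, e, X))
        m = sksurv.CoxPHSurvivalAnalysis(alpha=0.0, ties="breslow").fit(
            X, Surv.from_arrays(e.astype(bool), t)
        )
        assert np.allclose(fit.coef.to_numpy(), m.coef_, atol=1e-6)


class TestStratifiedCox:
    def test_duplicated_strata_same_coef_halved_vcov(self):
        rng = np.random.default_rng(11)
        t, e, X, off = random_small_dataset(rng, n_max=25)
        single = fit_cox(make_dataset(t, e, X, offset=off))
        double = fit_stratified_cox(
            make_dataset(
                np.r_[t, t], np.r_[e, e], np.vstack([X, X]),
                offset=np.r_[off, off], strata=np.r_[np.zeros(len(t)), np.ones(len(t))],
            )
        )
        assert np.allclose(double.coef.to_numpy(), single.coef.to_numpy(), atol=1e-8)
        assert np.allclose(double.vcov.to_numpy(), single.vcov.to_numpy() / 2, atol=1e-8)

    def test_matches_lifelines_strata_fit(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(21)
        n = 300
        X = rng.standard_normal((n, 2))
        s = (rng.random(n) < 0.4).astype(int)
        T = rng.exponential(1 / (np.exp(X @ [0.5, -0.5]) * np.where(s == 1, 2.0, 1.0)))
        C = rng.exponential(1.0, n)
        t, e = np.minimum(T, C), (T <= C).astype(int)  # continuous: no ties
        fit = fit_stratified_cox(make_dataset(t, e, X, strata=s))
        df = pd.DataFrame(X, columns=["x0", "x1"]).assign(t=t, e=e, s=s)
        cph = lifelines.CoxPHFitter().fit(df, "t", "e", strata=["s"])
        assert np.allclose(fit.coef.to_numpy(), cph.params_.to_numpy(), atol=1e-6)

    def test_eventless_stratum_contributes_nothing(self):
        rng = np.random.default_rng(29)
        t, e, X, off = random_small_dataset(rng)
        t2 = np.r_[t, [5.0, 6.0]]
        e2 = np.r_[e, [0, 0]]
        X2 = np.vstack([X, rng.standard_normal((2, X.shape[1]))])
        off2 = np.r_[off, [0.0, 0.0]]
        s2 = np.r_[np.zeros(len(t)), [1, 1]]
        alone = fit_cox(make_dataset(t, e, X, offset=off))
        both = fit_stratified_cox(make_dataset(t2, e2, X2, offset=off2, strata=s2))
        assert np.allclose(both.coef.to_numpy(), alone.coef.to_numpy(), atol=1e-10)

    def test_requires_strata(self):
        d = make_dataset([1, 2], [1, 1], np.array([[1.0], [0.0]]))
        with pytest.raises(ValueError, match="strat"):
            fit_stratified_cox(d)


class TestLikelihoodProperties:
    """Hypothesis-driven invariants of the partial likelihood."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.integers(min_value=0, max_value=10_000), st.floats(-1.5, 1.5))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_bruteforce_for_any_seed_and_beta(self, seed, beta):
        t, e, X, off = random_small_dataset(np.random.default_rng(seed), allow_ties=True)
        d = make_dataset(t, e, X, offset=off)
        got = log_partial_likelihood([beta, -beta / 2], d)
        want = naive_log_partial_likelihood([beta, -beta / 2], t, e, X, off)
        assert got == pytest.approx(want, abs=1e-10)

    @given(st.integers(min_value=0, max_value=10_000), st.floats(-5, 5))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_constant_offset_shift_cancels(self, seed, shift):
        t, e, X, off = random_small_dataset(np.random.default_rng(seed))
        d1 = make_dataset(t, e, X, offset=off)
        d2 = make_dataset(t, e, X, offset=off + shift)
        beta = [0.4, -0.2]
        assert log_partial_likelihood(beta, d1) == pytest.approx(
            log_partial_likelihood(beta, d2), abs=1e-9
        )


class TestWaldSummary:
    def test_null_coefficient(self):
        fit = fit_cox(make_dataset([1, 1, 2, 2], [1, 1, 1, 1],
                                   np.array([[1.0], [0.0], [1.0], [0.0]])))
        tab = wald_summary(fit)
        assert tab["hr"].iloc[0] == pytest.approx(1.0, abs=1e-6)
        assert tab["p"].iloc[0] == pytest.approx(1.0, abs=1e-4)

    def test_formula_values(self):
        # forced by the formula: HR = 2, CI = exp(log 2 +/- 1.959964 * 0.1)
        from relhaz.coxcore import CoxFit

        fit = CoxFit(
            coef=pd.Series([np.log(2)], index=["z"]),
            vcov=pd.DataFrame([[0.01]], index=["z"], columns=["z"]),
            loglik=0.0, loglik_null=0.0, n_events=1, n_subjects=1,
            iterations=1, converged=True,
        )
        tab = wald_summary(fit, level=0.95)
        assert tab["hr"].iloc[0] == pytest.approx(2.0, rel=1e-12)
        assert tab["ci_low"].iloc[0] == pytest.approx(np.exp(np.log(2) - 1.959964 * 0.1), rel=1e-6)
        assert tab["ci_high"].iloc[0] == pytest.approx(np.exp(np.log(2) + 1.959964 * 0.1), rel=1e-6)
        assert tab["ci_low"].iloc[0] < tab["hr"].iloc[0] < tab["ci_high"].iloc[0]

    def test_p_decreases_with_z(self):
        from relhaz.coxcore import CoxFit

        ps = []
        for coef in (0.1, 0.5, 1.0):
            fit = CoxFit(
                coef=pd.Series([coef], index=["z"]),
                vcov=pd.DataFrame([[0.04]], index=["z"], columns=["z"]),
                loglik=0.0, loglik_null=0.0, n_events=1, n_subjects=1,
                iterations=1, converged=True,
            )
            ps.append(wald_summary(fit)["p"].iloc[0])
        assert ps[0] > ps[1] > ps[2]
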
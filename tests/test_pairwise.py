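"""Pairwise likelihood values, derivatives, profile reduction and fitting."""

import numpy as np
import pytest

from perrcox import (PairedSurvivalData, fit_pairwise, pairwise_loglik,
                     pairwise_score_and_information, perr_alt_estimate,
                     profile_baseline_mles, remove_tied_pairs)
from perrcox.pairwise import (PairwiseModelSpec, SingularInformationError,
                              StepFunction)

from conftest import counts_dataset, random_paired


def one_pair(tp, dp, ts, ds, x=0.0):
    return PairedSurvivalData([0], [tp], [dp], [ts], [ds], [[x]])


def product_form_loglik(params, data):
    """Independent oracle: evaluate the likelihood subject by subject in its
    literal product form (prior factor ** d_prior * study factor ** d_study)."""
    theta, alpha = np.atleast_1d(params[:-1]), params[-1]
    total = 0.0
    for i in range(data.n):
        if data.t_study[i] == 0 and data.d_study[i] == 0:
            continue
        P = 1.0 if data.t_prior[i] <= data.t_study[i] else 0.0
        S = 1.0 if data.t_study[i] <= data.t_prior[i] else 0.0
        e = np.exp(float(theta @ data.x[i]) + alpha)
        lik = (1.0 / (1.0 + P * e)) ** data.d_prior[i] * (e / (e + S)) ** data.d_study[i]
        total += np.log(lik)
    return total


class TestLoglik:
    def test_null_single_pair_prior_first(self):
        # d_p = d_s = 1, T_p < T_s at null parameters: log(1/2) + log(1)
        assert pairwise_loglik([0.0, 0.0], one_pair(1, 1, 2, 1)) == pytest.approx(
            np.log(0.5), abs=1e-12)

    def test_study_first_prior_event_is_uninformative(self, rng):
        pair = one_pair(2, 1, 1, 0)  # P=0, d_s=0: both factors are one
        for _ in range(5):
            params = rng.normal(size=2)
            assert pairwise_loglik(params, pair) == 0.0

    def test_between_period_death_contributes_nothing(self, rng):
        data = random_paired(rng, n=30)
        dead = PairedSurvivalData(
            np.arange(31), np.append(data.t_prior, 1.5),
            np.append(data.d_prior, 1.0), np.append(data.t_study, 0.0),
            np.append(data.d_study, 0.0), np.vstack([data.x, [[1.0]]]))
        params = rng.normal(size=2)
        assert pairwise_loglik(params, dead) == pytest.approx(
            pairwise_loglik(params, data), abs=1e-12)

    def test_matches_product_form_oracle(self, rng):
        for _ in range(100):
            data = random_paired(rng, n=8)
            params = rng.normal(size=2)
            assert pairwise_loglik(params, data) == pytest.approx(
                product_form_loglik(params, data), abs=1e-10)

    def test_nonfinite_params_rejected(self, rng):
        with pytest.raises(ValueError, match="non-finite"):
            pairwise_loglik([np.inf, 0.0], random_paired(rng))


class TestProfileBaselines:
    def test_null_parameters_prior_first(self):
        out = profile_baseline_mles([0.0], 0.0, [1.0], 1.0, 1, 2.0, 1)
        assert out["h_tp"] == pytest.approx(0.5)
        assert out["h_ts"] == pytest.approx(1.0)

    def test_censored_prior_gives_zero_hazard(self):
        out = profile_baseline_mles([0.3], -0.2, [1.0], 1.0, 0, 2.0, 1)
        assert out["h_tp"] == 0.0

    def test_full_likelihood_profiles_to_pairwise(self, rng):
        """Plugging the profile MLEs into the full two-period likelihood
        reproduces the pairwise log-likelihood up to a term free of the
        parameters (here: the difference is constant over parameter draws)."""
        for _ in range(20):
            tp, ts = rng.exponential(), rng.exponential()
            dp, ds = rng.integers(0, 2), rng.integers(0, 2)
            x = rng.normal()
            diffs = []
            for _ in range(4):
                theta, alpha = rng.normal(size=2)
                prof = profile_baseline_mles([theta], alpha, [x], tp, dp, ts, ds)
                e = np.exp(theta * x + alpha)
                full = 0.0
                if dp:
                    full += np.log(prof["h_tp"])
                full -= prof["H_tp"]
                if ds:
                    full += np.log(prof["h_ts"] * e)
                full -= prof["H_ts"] * e
                pair = pairwise_loglik(
                    [theta, alpha], one_pair(tp, dp, ts, ds, x))
                diffs.append(full - pair)
            assert np.ptp(diffs) < 1e-10


class TestDerivatives:
    def test_information_single_pair_example(self):
        _, info = pairwise_score_and_information(
            [0.0, 0.0], one_pair(1, 1, 2, 1, x=1.0))
        np.testing.assert_allclose(info, 0.25 * np.ones((2, 2)))

    def test_score_matches_finite_differences(self, rng):
        h = 1e-6
        for _ in range(10):
            data = random_paired(rng, n=40, q=2)
            params = 0.5 * rng.normal(size=3)
            score, _ = pairwise_score_and_information(params, data)
            for j in range(3):
                e = np.zeros(3)
                e[j] = h
                fd = (pairwise_loglik(params + e, data)
                      - pairwise_loglik(params - e, data)) / (2 * h)
                assert score[j] == pytest.approx(fd, abs=1e-6)

    def test_hessian_matches_finite_differences(self, rng):
        h = 1e-4
        for _ in range(10):
            data = random_paired(rng, n=40, q=1)
            params = 0.5 * rng.normal(size=2)
            _, info = pairwise_score_and_information(params, data)
            for j in range(2):
                for k in range(2):
                    ej, ek = np.zeros(2), np.zeros(2)
                    ej[j], ek[k] = h, h
                    fd = -(pairwise_loglik(params + ej + ek, data)
                           - pairwise_loglik(params + ej - ek, data)
                           - pairwise_loglik(params - ej + ek, data)
                           + pairwise_loglik(params - ej - ek, data)) / (4 * h * h)
                    assert info[j, k] == pytest.approx(fd, rel=1e-6, abs=1e-6)

    def test_score_vanishes_at_mle(self, rng):
        data = random_paired(rng, n=300)
        fit = fit_pairwise(data)
        score, _ = pairwise_score_and_information(fit.estimates, data)
        assert np.max(np.abs(score)) < 1e-8


class TestFit:
    def test_closed_form_binary_design(self):
        data = counts_dataset(10, 30, 20, 20)
        fit = fit_pairwise(data)
        assert fit.estimates[0] == pytest.approx(np.log(3.0), abs=1e-9)
        assert fit.estimates[1] == pytest.approx(0.0, abs=1e-9)
        assert fit.converged

    def test_alpha_zero_under_count_symmetry(self):
        data = counts_dataset(0, 0, 25, 25).subset(np.arange(50))
        no_cov = PairedSurvivalData(data.subject_id, data.t_prior, data.d_prior,
                                    data.t_study, data.d_study,
                                    np.zeros((50, 0)), x_names=[])
        fit = fit_pairwise(no_cov)
        assert fit.estimates[0] == pytest.approx(0.0, abs=1e-9)

    def test_result_invariant_to_subject_order(self, rng):
        data = random_paired(rng, n=150)
        perm = rng.permutation(150)
        fit1 = fit_pairwise(data)
        fit2 = fit_pairwise(data.subset(perm))
        np.testing.assert_allclose(fit1.estimates, fit2.estimates, atol=1e-9)

    def test_uninformative_subjects_do_not_move_estimates(self, rng):
        data = random_paired(rng, n=200)
        data, _ = remove_tied_pairs(data)
        ind = data.pair_indicators()
        informative = ((data.d_prior * ind.p) + (data.d_study * ind.s)) > 0
        fit_all = fit_pairwise(data)
        fit_inf = fit_pairwise(data.subset(informative))
        np.testing.assert_allclose(fit_all.estimates, fit_inf.estimates, atol=1e-8)
        np.testing.assert_allclose(fit_all.covariance, fit_inf.covariance, atol=1e-8)

    def test_covariate_scaling_equivariance(self, rng):
        data = random_paired(rng, n=300)
        scaled = PairedSurvivalData(data.subject_id, data.t_prior, data.d_prior,
                                    data.t_study, data.d_study, 2.5 * data.x)
        f1, f2 = fit_pairwise(data), fit_pairwise(scaled)
        assert f2.estimates[0] == pytest.approx(f1.estimates[0] / 2.5, abs=1e-8)
        assert f2.estimates[1] == pytest.approx(f1.estimates[1], abs=1e-8)

    def test_separation_reported_not_clipped(self):
        # every informative exposed pair is study-first: theta + alpha diverges
        data = counts_dataset(0, 20, 10, 10)
        fit = fit_pairwise(data)
        assert not fit.converged
        assert "separation" in fit.message or "diverging" in fit.message

    def test_constant_covariate_is_singular(self):
        data = PairedSurvivalData(np.arange(4), [1, 1, 2, 2], [1, 1, 1, 1],
                                  [2, 2, 1, 1], [0, 0, 1, 1],
                                  np.ones((4, 1)))
        with pytest.raises(SingularInformationError, match="non-identified"):
            fit_pairwise(data)

    def test_damped_newton_increases_loglik_monotonically(self, rng):
        data = random_paired(rng, n=100)
        lls = []
        params = np.array([2.0, -2.0])  # start far from the optimum
        ll = pairwise_loglik(params, data)
        for _ in range(8):
            lls.append(ll)
            score, info = pairwise_score_and_information(params, data)
            step, lam = np.linalg.solve(info, score), 1.0
            while pairwise_loglik(params + lam * step, data) < ll and lam > 1e-8:
                lam *= 0.5
            params = params + lam * step
            ll = pairwise_loglik(params, data)
        assert np.all(np.diff(lls) > -1e-10)

    def test_perr_alt_equals_joint_fit_for_binary_treatment(self, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            data = random_paired(r, n=400)
            data.x[:, 0] = (r.random(400) < 0.5).astype(float)
            joint = fit_pairwise(data)
            alt = perr_alt_estimate(data)
            assert alt.estimates[0] == pytest.approx(joint.estimates[0], abs=1e-7)


class TestVariants:
    def test_period_specific_with_zero_prior_covariate_reduces_to_shared(self, rng):
        data = random_paired(rng, n=50)
        data.x_prior = np.zeros((50, 1))
        spec = PairwiseModelSpec(covariate_mode="period_specific")
        for _ in range(5):
            th, al = rng.normal(size=2)
            assert pairwise_loglik([th, 0.0, al], data, spec) == pytest.approx(
                pairwise_loglik([th, al], data), abs=1e-12)

    def test_wlw_common_baseline_design_informative_subjects(self, rng):
        # treated-on-one-side only (x = xs - xp in {-1, 0, 1}); x = 0 pairs
        # carry no treatment information in the zero-alpha design
        n = 60
        xs = (rng.random(n) < 0.5).astype(float)
        xp = (rng.random(n) < 0.5).astype(float)
        data = random_paired(rng, n=n)
        data.x = (xs - xp)[:, None]
        spec = PairwiseModelSpec(covariate_mode="shared", alpha_form="zero")
        ll_a = pairwise_loglik([0.7], data, spec)
        only = data.subset(data.x[:, 0] != 0.0)
        base = pairwise_loglik([0.0], data, spec)
        base_only = pairwise_loglik([0.0], only, spec)
        assert ll_a - base == pytest.approx(
            pairwise_loglik([0.7], only, spec) - base_only, abs=1e-10)

    def test_linear_alpha_reduces_to_constant_when_slope_zero(self, rng):
        data = random_paired(rng, n=50)
        spec = PairwiseModelSpec(alpha_form="linear_in_time")
        th, al = rng.normal(size=2)
        assert pairwise_loglik([th, al, 0.0], data, spec) == pytest.approx(
            pairwise_loglik([th, al], data), abs=1e-12)

    def test_linear_alpha_uses_each_periods_event_time(self):
        pair = one_pair(1.0, 1, 3.0, 1, x=0.0)
        spec = PairwiseModelSpec(alpha_form="linear_in_time")
        a0, a1 = 0.2, 0.4
        up = a0 + a1 * 1.0
        vs = a0 + a1 * 3.0
        expected = -np.log1p(np.exp(up)) + vs - np.log(np.exp(vs))
        assert pairwise_loglik([0.0, a0, a1], pair, spec) == pytest.approx(
            expected, abs=1e-12)

    def test_time_varying_constant_path_reduces_to_shared(self, rng):
        n = 30
        data = random_paired(rng, n=n)
        data.tau = rng.uniform(0, 2, size=n)
        paths = [StepFunction([], [[float(data.x[i, 0])]]) for i in range(n)]
        spec = PairwiseModelSpec(covariate_mode="time_varying", paths=paths)
        th, al = rng.normal(size=2)
        ll = pairwise_loglik([th, al], data, spec)
        # under a constant path the treatment term cancels within each period
        # contrast, so the value must match the shared model at theta = 0 with
        # the same alpha
        zero_x = PairedSurvivalData(data.subject_id, data.t_prior, data.d_prior,
                                    data.t_study, data.d_study,
                                    np.zeros((n, 1)))
        assert ll == pytest.approx(pairwise_loglik([0.0, al], zero_x), abs=1e-12)

    def test_step_function_right_continuity(self):
        f = StepFunction([1.0, 2.0], [[0.0], [5.0], [7.0]])
        assert f(0.5)[0] == 0.0
        assert f(1.0)[0] == 5.0  # new value exactly at the breakpoint
        assert f(1.9)[0] == 5.0
        assert f(2.0)[0] == 7.0
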
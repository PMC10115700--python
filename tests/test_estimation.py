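import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

import cdmkit as ck
from cdmkit.data import InvalidValueError, QMatrix, ResponseMatrix
from cdmkit.estimation import (
    e_step,
    expected_item_counts,
    fit_cdm,
    information_criteria,
    m_step_item,
    standard_errors,
)
from cdmkit.measurement import ItemParameterSet, check_monotonicity, probs_from_link


def _item(probs, qvector, label="GDINA"):
    return ItemParameterSet(model_label=label, qvector=np.array(qvector),
                            probs=np.array(probs))


class TestEStep:
    def test_single_item_bayes_by_hand(self):
        # prior (.5,.5), item probs (.2,.8), observed 1 -> posterior (.2,.8)
        items = [_item([0.2, 0.8], [1])]
        resp = ResponseMatrix(values=np.array([[1]]))
        post, ll = e_step(resp, items, np.array([0.5, 0.5]))
        assert np.allclose(post, [[0.2, 0.8]], atol=1e-9)
        assert ll == pytest.approx(np.log(0.5 * 0.2 + 0.5 * 0.8))

    def test_uninformative_items_return_the_prior(self):
        items = [_item([0.4, 0.4], [1]), _item([0.7, 0.7], [1])]
        resp = ResponseMatrix(values=np.array([[1, 0], [0, 1], [1, 1]]))
        prior = np.array([0.3, 0.7])
        post, _ = e_step(resp, items, prior)
        assert np.allclose(post, prior, atol=1e-9)

    def test_posterior_rows_normalized_for_random_inputs(self):
        rng = np.random.default_rng(0)
        items = [_item(np.sort(rng.uniform(0.05, 0.95, 4)), [1, 1]) for _ in range(6)]
        resp = ResponseMatrix(values=rng.integers(0, 2, (50, 6)))
        post, _ = e_step(resp, items, rng.dirichlet(np.ones(4)))
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)

    def test_extreme_probabilities_do_not_underflow(self):
        # a response pattern near-impossible under every class stays finite
        items = [_item([1e-9, 1 - 1e-9], [1]) for _ in range(40)]
        x = np.tile([0, 1], 20)[None, :]
        post, ll = e_step(ResponseMatrix(values=x), items, np.array([0.5, 0.5]))
        assert np.all(np.isfinite(post)) and np.isfinite(ll)


class TestMStep:
    def test_saturated_closed_form(self):
        new = m_step_item(np.array([30.0, 160.0]), np.array([100.0, 200.0]),
                          "GDINA", np.array([1]))
        assert np.allclose(new.probs, [0.30, 0.80], atol=1e-9)

    def test_additive_counts_are_a_fixed_point_of_the_acdm_update(self):
        d = np.array([0.1, 0.3, 0.45])
        probs = probs_from_link("ACDM", 2, d)
        T = np.array([400.0, 300.0, 200.0, 100.0])
        new = m_step_item(T * probs, T, "ACDM", np.array([1, 1]))
        assert np.allclose(new.probs, probs, atol=1e-6)

    def test_violating_update_projected_to_monotone(self):
        # raw ratios are non-monotone; the projection restores weak inequalities
        R = np.array([50.0, 10.0, 30.0, 55.0])
        T = np.array([100.0, 100.0, 100.0, 100.0])
        new = m_step_item(R, T, "GDINA", np.array([1, 1]))
        ok, viol = check_monotonicity(new)
        assert ok, viol

    def test_llm_and_rrum_fixed_points(self):
        for label in ("LLM", "RRUM"):
            if label == "LLM":
                probs = expit(np.array([[1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]])
                              @ np.array([-1.5, 1.0, 2.0]))
            else:
                probs = np.exp(np.array([[1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]])
                               @ np.array([-1.8, 0.7, 0.9]))
            T = np.full(4, 250.0)
            new = m_step_item(T * probs, T, label, np.array([1, 1]))
            assert np.allclose(new.probs, probs, atol=1e-5)

    def test_dina_pools_non_full_classes(self):
        R = np.array([10.0, 12.0, 8.0, 90.0])
        T = np.array([100.0, 100.0, 100.0, 100.0])
        new = m_step_item(R, T, "DINA", np.array([1, 1]))
        assert np.allclose(new.probs[:3], 0.10, atol=1e-9)
        assert new.probs[3] == pytest.approx(0.90)


class TestFitCDM:
    def test_loglik_monotone_and_converged(self, small_fit):
        *_, fitted = small_fit
        assert fitted.converged
        assert np.all(np.diff(fitted.loglik_trace) >= -1e-6)

    def test_posterior_rows_sum_to_one(self, small_fit):
        *_, fitted = small_fit
        assert np.allclose(fitted.posteriors.sum(axis=1), 1.0, atol=1e-10)

    def test_refit_from_converged_solution_is_stable(self, small_fit):
        Q, _, _, _, resp, fitted = small_fit
        post, ll = e_step(resp, fitted.items, fitted.prior)
        for j, item in enumerate(fitted.items):
            R, T = expected_item_counts(post, resp, item, col=j)
            new = m_step_item(R, T, item.model_label, item.qvector, prev=item)
            assert np.max(np.abs(new.probs - item.probs)) < 5e-4

    def test_point_mass_prior_gives_item_means(self):
        rng = np.random.default_rng(3)
        items = [_item([0.2, 0.8], [1]), _item([0.3, 0.9], [1])]
        resp = ResponseMatrix(values=rng.integers(0, 2, (120, 2)))
        prior = np.array([0.0, 1.0])
        post, _ = e_step(resp, items, np.clip(prior, 1e-12, None))
        for j, item in enumerate(items):
            R, T = expected_item_counts(post, resp, item, col=j)
            new = m_step_item(R, T, "GDINA", item.qvector, prev=item)
            assert new.probs[1] == pytest.approx(resp.values[:, j].mean(), abs=1e-6)

    def test_npar_counts_items_plus_structural(self, small_fit):
        Q, *_, fitted = small_fit
        assert fitted.npar == 6 * 2 + (4 - 1)

    def test_reduced_item_models_are_respected(self, small_fit):
        Q, items, joint, prof, resp, _ = small_fit
        Q2 = QMatrix(entries=np.vstack([Q.entries, [[1, 1]]]),
                     item_ids=Q.item_ids + ["item7"])
        both = ck.simulate_responses(
            np.hstack([prof]), items + [_item([0.1, 0.4, 0.5, 0.8], [1, 1])], seed=9)
        both.item_ids = Q2.item_ids
        fitted = fit_cdm(both, Q2, item_models=["GDINA"] * 6 + ["ACDM"],
                         structural="saturated", seed=2)
        it = fitted.items[6]
        assert it.model_label == "ACDM" and it.link_params is not None
        # additive structure holds exactly in the fitted probabilities
        assert it.probs[3] - it.probs[2] == pytest.approx(it.probs[1] - it.probs[0], abs=1e-6)

    def test_degenerate_qmatrix_rejected(self):
        with pytest.raises(Exception):
            QMatrix(entries=np.array([[1, 0], [1, 0]]))


class TestInformationCriteria:
    def test_formulas(self):
        aic, bic = information_criteria(-10000.0, 20, 500)
        assert aic == pytest.approx(20040.0)
        assert bic == pytest.approx(20000.0 + 20 * np.log(500))

    def test_single_observation_limit(self):
        aic, bic = information_criteria(-50.0, 5, 1)
        assert bic == pytest.approx(100.0)

    def test_published_aic_difference(self):
        # the printed saturated-vs-reduced AIC gap equals 20,039.12 - 20,032.66
        assert 20039.12 - 20032.66 == pytest.approx(6.46)

    def test_npar_must_be_positive(self):
        with pytest.raises(InvalidValueError):
            information_criteria(-1.0, 0, 10)


class TestStandardErrors:
    def test_all_positive_on_converged_fit(self, small_fit):
        _, _, _, _, resp, fitted = small_fit
        ses = standard_errors(fitted, resp)
        for j in range(len(fitted.items)):
            assert np.all(ses.item_ses(j) > 0)
        assert np.all(ses.structural_ses() > 0)

    def test_root_n_shrinkage(self, small_fit):
        Q, items, joint, _, _, _ = small_fit
        out = []
        for n, seed in [(600, 21), (2400, 22)]:
            prof = ck.simulate_profiles(n, joint, seed=seed)
            resp = ck.simulate_responses(prof, items, seed=seed + 100)
            resp.item_ids = Q.item_ids
            fitted = fit_cdm(resp, Q, structural="saturated", seed=1)
            ses = standard_errors(fitted, resp)
            out.append(np.concatenate([ses.item_ses(j) for j in range(Q.J)]))
        ratio = np.median(out[0] / out[1])
        assert ratio == pytest.approx(2.0, abs=0.5)


class TestOracleEquivalence:
    def test_em_matches_direct_marginal_likelihood_maximization(self):
        # small two-attribute instance: EM against a direct numeric optimizer
        rng = np.random.default_rng(77)
        Q = QMatrix(entries=np.array([[1, 0], [1, 0], [0, 1], [0, 1]]))
        true_items = [_item([0.15, 0.85], Q.qvector(j)) for j in range(4)]
        joint = np.array([0.35, 0.2, 0.15, 0.3])
        prof = ck.simulate_profiles(200, ck.LatentClassDistribution(probs=joint),
                                    seed=rng.integers(2**31))
        resp = ck.simulate_responses(prof, true_items, seed=rng.integers(2**31))
        resp.item_ids = Q.item_ids
        X = resp.values.astype(float)

        fitted = fit_cdm(resp, Q, structural="saturated", tol=1e-9,
                         loglik_tol=1e-12, max_iter=100000, seed=1)

        ridx = np.array([[0, 0, 1, 1], [0, 1, 0, 1]])  # class -> reduced index per attribute

        def negll_grad(theta):
            p = expit(theta[:8]).reshape(4, 2)  # item x (absent, present)
            logits = np.concatenate([[0.0], theta[8:]])
            prior = np.exp(logits - logsumexp(logits))
            P = np.empty((4, 4))
            for j in range(4):
                attr = 0 if j < 2 else 1
                P[j] = p[j][ridx[attr]]
            ll = X @ np.log(P) + (1 - X) @ np.log(1 - P) + np.log(prior)[None, :]
            norm = logsumexp(ll, axis=1)
            w = np.exp(ll - norm[:, None])  # posterior class weights
            grad = np.empty_like(theta)
            for j in range(4):
                attr = 0 if j < 2 else 1
                for m in (0, 1):
                    mask = ridx[attr] == m
                    # d/d logit(p_jm): sum_i sum_{c in group} w_ic (x_ij - p_jm)
                    grad[2 * j + m] = -((X[:, j][:, None] - p[j, m]) * w[:, mask]).sum()
            grad[8:] = -(w[:, 1:].sum(axis=0) - X.shape[0] * prior[1:])
            return -norm.sum(), grad

        from scipy.special import logit

        x0 = np.concatenate([np.tile(logit([0.15, 0.85]), 4), np.zeros(3)])
        res = minimize(negll_grad, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12})
        direct_probs = expit(res.x[:8]).reshape(4, 2)
        logits = np.concatenate([[0.0], res.x[8:]])
        direct_prior = np.exp(logits - logsumexp(logits))

        em_probs = np.vstack([it.probs for it in fitted.items])
        assert fitted.loglik == pytest.approx(-res.fun, abs=1e-6)
        assert np.max(np.abs(em_probs - direct_probs)) < 1e-3
        assert np.max(np.abs(fitted.prior - direct_prior)) < 1e-3
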
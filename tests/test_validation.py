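import numpy as np
import pytest

import cdmkit as ck
from cdmkit.data import InvalidValueError, QMatrix
from cdmkit.estimation import fit_cdm, standard_errors
from cdmkit.validation import (
    UndefinedPVAFError,
    class_success_probs,
    gdi,
    lrt,
    mesa_data,
    pvaf,
    rmsea2,
    suggest_qvector,
    wald_select_item,
)


class TestGDI:
    def test_constant_success_probability_gives_zero(self):
        assert gdi(np.array([1, 0]), np.full(4, 0.5), np.full(4, 0.25)) == pytest.approx(0.0)

    def test_two_group_hand_computation(self):
        # groups with weights .5/.5 and probs .2/.8: weighted variance .09
        val = gdi(np.array([1]), np.array([0.2, 0.8]), np.array([0.5, 0.5]))
        assert val == pytest.approx(0.09)

    def test_sub_qvector_never_exceeds_full_qvector(self):
        # brute force over random K=4 instances and all nested q-vector pairs
        rng = np.random.default_rng(14)
        qvecs = [np.array([int(b) for b in np.binary_repr(m, 4)]) for m in range(1, 16)]
        for _ in range(20):
            p = rng.uniform(0, 1, 16)
            w = rng.dirichlet(np.ones(16))
            for q in qvecs:
                for sub in qvecs:
                    if np.all(sub <= q) and not np.array_equal(sub, q):
                        assert gdi(sub, p, w) <= gdi(q, p, w) + 1e-12

    def test_scale_free_in_weights(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 16)
        w = rng.dirichlet(np.ones(16))
        q = np.array([1, 0, 1, 0])
        assert gdi(q, p, 5 * w) == pytest.approx(gdi(q, p, w))


class TestPVAF:
    def test_full_qvector_gives_one(self, small_fit):
        _, _, _, _, resp, fitted = small_fit
        assert pvaf("item1", np.ones(2, dtype=int), fitted, resp) == pytest.approx(1.0)

    def test_flat_item_raises(self, small_fit):
        # an item nobody endorses has identical success probability in every
        # class, so its maximum GDI is zero and PVAF is undefined
        Q, items, joint, prof, resp, fitted = small_fit
        from cdmkit.data import ResponseMatrix

        values = resp.values.copy()
        values[:, 0] = 0
        resp_flat = ResponseMatrix(values=values, item_ids=Q.item_ids)
        with pytest.raises(UndefinedPVAFError):
            pvaf("item1", np.array([1, 0]), fitted, resp_flat)


class TestMesa:
    def test_best_pvaf_sequence_is_nondecreasing(self, recovery):
        scen, resp, _, fitted = recovery
        for item_id in ["item1", "item26", "item29", "item38"]:
            md = mesa_data(item_id, fitted, resp)
            assert np.all(np.diff(md.best_pvafs) >= -1e-9)
            assert md.best_pvafs[-1] == pytest.approx(1.0)

    def test_true_two_attribute_item_shows_mesa_edge(self, recovery):
        # item 29 loads on anxiety+hostility: PVAF jumps at m=2 with that vector
        scen, resp, _, fitted = recovery
        md = mesa_data("item29", fitted, resp)
        assert md.best_qvectors[1].tolist() == [0, 1, 1, 0]
        assert md.best_pvafs[1] > 0.95

    def test_suggest_recovers_generating_qvector(self, recovery):
        scen, resp, _, fitted = recovery
        q, v = suggest_qvector("item26", fitted, resp, epsilon=0.95)
        assert q.tolist() == [0, 1, 0, 1]

    def test_suggest_epsilon_one_returns_full_vector(self, recovery):
        scen, resp, _, fitted = recovery
        for item_id in ["item1", "item29"]:
            q, _ = suggest_qvector(item_id, fitted, resp, epsilon=1.0)
            assert q.tolist() == [1, 1, 1, 1]

    def test_suggest_tiny_epsilon_returns_single_attribute_vector(self, recovery):
        scen, resp, _, fitted = recovery
        q, _ = suggest_qvector("item29", fitted, resp, epsilon=1e-6)
        assert q.sum() == 1


class TestWald:
    def test_single_attribute_item_not_tested(self, recovery):
        scen, resp, _, fitted = recovery
        wr = wald_select_item(fitted, resp, "item1")
        assert wr.selected == "GDINA" and wr.tests == {} and "coincide" in wr.note

    def test_selection_on_recovery_data_prefers_true_generating_forms(self, recovery):
        # items simulated from non-additive probabilities keep the saturated
        # model or an adequate reduced form; additive-like items reduce
        scen, resp, _, fitted = recovery
        ses = standard_errors(fitted, resp)
        selections = {}
        for item_id in ["item21", "item26", "item27", "item28", "item29"]:
            wr = wald_select_item(fitted, resp, item_id, ses=ses)
            selections[item_id] = wr.selected
            for W, df, p in wr.tests.values():
                assert W >= 0 and 0 <= p <= 1
        assert all(s in {"GDINA", "ACDM", "LLM", "RRUM", "DINA", "DINO"}
                   for s in selections.values())

    def test_true_generating_reduced_models_recovered(self):
        # two-attribute items simulated from each reduced form: the Wald
        # selection should identify the generating model most of the time
        from scipy.special import expit

        Q = QMatrix(entries=np.array([[1, 0]] * 3 + [[0, 1]] * 3 + [[1, 1]] * 5))
        joint = ck.LatentClassDistribution(probs=np.array([0.35, 0.2, 0.15, 0.3]))
        items = [ck.ItemParameterSet(model_label="GDINA", qvector=Q.qvector(j),
                                     probs=np.array([0.15, 0.85]), item_id=Q.item_ids[j])
                 for j in range(6)]
        truth = {
            "item7": ("ACDM", [0.1, 0.4, 0.5, 0.8]),
            "item8": ("LLM", expit(np.array([-2.2, -0.2, -0.8, 1.2]))),
            "item9": ("RRUM", [0.08, 0.32, 0.2, 0.8]),
            "item10": ("DINA", [0.15, 0.15, 0.15, 0.85]),
            "item11": ("DINO", [0.1, 0.7, 0.7, 0.7]),
        }
        for iid, (_, p) in truth.items():
            items.append(ck.ItemParameterSet(model_label="GDINA", qvector=np.array([1, 1]),
                                             probs=np.array(p), item_id=iid))
        correct = total = 0
        for rep in range(3):
            prof = ck.simulate_profiles(5000, joint, seed=200 + rep)
            resp = ck.simulate_responses(prof, items, seed=300 + rep)
            resp.item_ids = Q.item_ids
            fitted = fit_cdm(resp, Q, structural="saturated", seed=1)
            ses = standard_errors(fitted, resp)
            for iid, (label, _) in truth.items():
                wr = wald_select_item(fitted, resp, iid, ses=ses)
                correct += wr.selected == label
                total += 1
        assert correct / total >= 0.70

    def test_statistics_invariant_to_saturated_reparameterization(self, small_fit):
        # the Wald statistic built from probabilities equals the one built
        # from the delta coefficients (a linear reparameterization)
        rng = np.random.default_rng(8)
        Q = QMatrix(entries=np.array([[1, 0], [1, 0], [0, 1], [0, 1], [1, 1]]))
        items = [ck.ItemParameterSet(model_label="GDINA", qvector=Q.qvector(j),
                                     probs=np.array([0.15, 0.85]), item_id=Q.item_ids[j])
                 for j in range(4)]
        items.append(ck.ItemParameterSet(model_label="GDINA", qvector=Q.qvector(4),
                                         probs=np.array([0.1, 0.3, 0.5, 0.9]),
                                         item_id=Q.item_ids[4]))
        prof = ck.simulate_profiles(1500, ck.LatentClassDistribution(
            probs=np.array([0.3, 0.2, 0.2, 0.3])), seed=4)
        resp = ck.simulate_responses(prof, items, seed=5)
        resp.item_ids = Q.item_ids
        fitted = fit_cdm(resp, Q, structural="saturated", seed=1)
        ses = standard_errors(fitted, resp)
        wr = wald_select_item(fitted, resp, "item5", ses=ses)
        # recompute the ACDM Wald statistic in the delta parameterization
        from cdmkit.measurement import full_design

        A, _ = full_design(2)
        item = fitted.items[4]
        V = ses.item_cov(4)
        Ainv = np.linalg.inv(A)
        delta = Ainv @ item.probs
        Vd = Ainv @ V @ Ainv.T
        W_delta = delta[3] ** 2 / Vd[3, 3]
        assert wr.tests["ACDM"][0] == pytest.approx(W_delta, rel=1e-8)


class TestLRT:
    def test_identical_models_give_zero(self, small_fit):
        *_, fitted = small_fit
        res = lrt(fitted, fitted)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_structural_orders_are_nested(self, recovery):
        scen, resp, _, sat = recovery
        f2 = fit_cdm(resp, scen.Q, structural=2, seed=1)
        res = lrt(f2, sat)
        assert res.df == 5  # saturated (15) vs homogeneous association (10)
        assert res.statistic >= 0

    def test_non_nested_order_rejected(self, small_fit):
        *_, fitted = small_fit
        import dataclasses

        bigger = dataclasses.replace(fitted, loglik=fitted.loglik - 10, npar=fitted.npar - 2)
        with pytest.raises(InvalidValueError):
            lrt(fitted, bigger)


class TestRMSEA2:
    def test_nonnegative_and_small_under_correct_model(self, small_fit):
        _, _, _, _, resp, fitted = small_fit
        res = rmsea2(fitted, resp)
        assert res.rmsea2 >= 0
        assert res.m2 >= 0

    def test_self_consistency_at_recovery_scale(self, recovery):
        # data simulated from the fitted family: RMSEA2 should be near zero
        scen, resp, _, fitted = recovery
        res = rmsea2(fitted, resp)
        assert res.rmsea2 < 0.01
        assert res.df > 0

    def test_misfit_detected_for_wrong_qmatrix(self, small_fit):
        # swap the q-vectors so items load on the wrong attribute
        Q, items, joint, prof, resp, _ = small_fit
        wrongQ = QMatrix(entries=Q.entries[::-1].copy(), item_ids=Q.item_ids)
        wrong = fit_cdm(resp, wrongQ, structural="saturated", seed=1)
        res_wrong = rmsea2(wrong, resp)
        right = fit_cdm(resp, Q, structural="saturated", seed=1)
        res_right = rmsea2(right, resp)
        assert res_wrong.rmsea2 > res_right.rmsea2
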
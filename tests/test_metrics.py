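"""Verification/validation measures against independent oracles."""

import numpy as np
import pytest
from scipy import stats

import grncompare as g
from grncompare.metrics import UndefinedCorrelationError
from grncompare.simulate import TimeSeriesSet, Trajectory


def make_set(*matrices, t=None):
    trajectories = []
    for i, x in enumerate(matrices):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        grid = np.arange(x.shape[0]) if t is None else t
        trajectories.append(Trajectory(i, grid, x))
    return TimeSeriesSet(trajectories)


def brute_force_pfit(obs_list, pred_list):
    """Independent double-loop implementation of the fitting score."""
    total, count = 0.0, 0
    for obs, pred in zip(obs_list, pred_list):
        for t in range(len(obs)):
            for k in range(len(obs[t])):
                total += (obs[t][k] - pred[t][k]) ** 2
                count += 1
    return 1.0 / (1.0 + total / count)


class TestPFit:
    def test_identical_sets(self):
        a = make_set([[1.0, 2.0], [3.0, 4.0]])
        assert g.p_fit(a, a) == 1.0

    def test_hand_example(self):
        # N=1, p=2: E = ((1-1)^2 + (2-1)^2)/2 = 0.5, P_fit = 2/3
        obs = make_set([[1.0], [2.0]])
        pred = make_set([[1.0], [1.0]])
        assert g.p_fit(obs, pred) == pytest.approx(2.0 / 3.0)

    def test_error_roundtrip_identity(self, rng):
        obs = make_set(rng.random((7, 3)))
        pred = make_set(rng.random((7, 3)))
        p = g.p_fit(obs, pred)
        e = 1.0 / p - 1.0
        assert e == pytest.approx(np.mean(
            (obs.trajectories[0].x - pred.trajectories[0].x) ** 2))

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(5):
            obs = [rng.random((6, 4)), rng.random((6, 4))]
            pred = [rng.random((6, 4)), rng.random((6, 4))]
            mine = g.p_fit(make_set(*obs), make_set(*pred))
            assert mine == pytest.approx(brute_force_pfit(obs, pred))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            g.p_fit(make_set(np.ones((3, 2))), make_set(np.ones((4, 2))))


class TestPInf:
    def test_exact_match(self):
        assert g.p_inf([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_anticorrelated(self):
        w = np.array([1.0, -2.0, 3.0])
        assert g.p_inf(w, -w) == pytest.approx(0.0)

    def test_near_match_value_from_oracle(self):
        w_ref = np.array([1.0, 2.0, 3.0, 4.0])
        w_hat = np.array([1.0, 2.0, 3.0, 5.0])
        r = stats.pearsonr(w_ref, w_hat).statistic
        assert g.p_inf(w_ref, w_hat) == pytest.approx(0.5 * (1 + r))
        assert g.p_inf(w_ref, w_hat) == pytest.approx(0.991354, abs=1e-6)

    def test_positive_affine_invariance(self, rng):
        w = rng.random(10)
        assert g.p_inf(w, 3.5 * w + 2.0) == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            g.p_inf([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_cross_method_rejected(self, case_models):
        with pytest.raises(ValueError):
            g.p_inf_models(case_models[("A", "ANN")],
                           case_models[("A", "SS")])

    def test_self_pinf_is_one(self, case_models):
        for m in case_models.values():
            assert g.p_inf_models(m, m) == pytest.approx(1.0)


class TestRelativeDifference:
    def test_identical(self):
        a = make_set([[1.0, 2.0], [3.0, 4.0]])
        assert g.relative_difference(a, a) == 0.0

    def test_hand_example(self):
        # single point: ((2-1)/2)^2 = 0.25
        assert g.relative_difference(
            make_set([[2.0]]), make_set([[1.0]])) == pytest.approx(0.25)

    def test_scale_invariance(self, rng):
        obs = rng.random((5, 3)) + 0.5
        pred = rng.random((5, 3))
        a = g.relative_difference(make_set(obs), make_set(pred))
        b = g.relative_difference(make_set(2 * obs), make_set(2 * pred))
        assert a == pytest.approx(b)

    def test_zero_observed_reported(self):
        with pytest.raises(ZeroDivisionError):
            g.relative_difference(make_set([[0.0]]), make_set([[1.0]]))


class TestClassifyPfit:
    @pytest.mark.parametrize("value,band", [
        (0.9999, "highly accurate"),
        (0.9992, "highly accurate"),
        (0.997, "converging"),
        (0.97, "same range, patterns may differ"),
        (0.92, "poor"),
        (0.85, "very poor"),
        (0.4, "very poor"),
    ])
    def test_bands(self, value, band):
        assert g.classify_pfit(value) == band


class TestVerifyValidate:
    def test_generator_model_verifies_its_own_data(self, case_models,
                                                   sparse_case_a_ann):
        m = case_models[("A", "ANN")]
        assert g.verify(m, sparse_case_a_ann) > 0.9999

    def test_degenerate_model_scores_poorly(self, sparse_case_a_ann):
        # a do-nothing model (v = 0 everywhere, fast decay) is clearly
        # separated from the generator's near-perfect self-fit; the
        # absolute score stays high-ish because case A concentrations
        # are below one unit, so squared errors are intrinsically small
        topo = g.build_case("A", "ANN").topology
        p = g.ANNParams(v=np.zeros(5), w=np.zeros((5, 5)),
                        theta=np.zeros(5), k=np.full(5, 2.0))
        zero = g.GRNModel("ANN", topo, p)
        assert g.verify(zero, sparse_case_a_ann) < 0.97

    def test_self_validation_is_perfect(self, case_models,
                                        sparse_case_a_ann):
        m = case_models[("A", "ANN")]
        val = g.validate(m, m, sparse_case_a_ann)
        assert val.p_val == pytest.approx(1.0, abs=1e-6)
        assert set(val.per_condition) == {"increase (k1=0.1)",
                                          "decrease (k1=0.5)"}

    def test_report_delta_identity(self, case_models, sparse_case_a_ann):
        m = case_models[("A", "ANN")]
        report = g.evaluate_pair(m, m, sparse_case_a_ann, "A", "sparse")
        assert report.delta_p_fit == report.p_val - report.p_ver
        assert report.p_inf == pytest.approx(1.0)
        # published arithmetic example: 0.9972 - 0.9996 = -0.0024
        assert 0.9972 - 0.9996 == pytest.approx(-0.0024)


class TestQcom:
    def test_reference_models_reproduce_designed_features(self, case_models):
        designed = {
            "A": {"uniform_degradation": True,
                  "constant_signal_propagation": True},
            "B": {"uniform_degradation": True,
                  "asymmetric_signal_branching": True,
                  "asymmetric_coregulation": True},
            "C": {"uniform_degradation": True,
                  "asymmetric_signal_branching": True,
                  "asymmetric_coregulation": True,
                  "positive_feedback": True,
                  "negative_feedback": True},
        }
        for (case, method), m in case_models.items():
            assert g.qcom_features(m, case) == designed[case], (case, method)

    def test_nonuniform_degradation_detected(self, case_models):
        m = case_models[("A", "ANN")]
        d = m.to_dict()
        d["params"]["k"][4] = 0.5
        feats = g.qcom_features(g.GRNModel.from_dict(d), "A")
        assert feats["uniform_degradation"] is False

    def test_constant_propagation_ratio_rule(self, case_models):
        # doubling one cascade weight crosses the max/min ratio of 2
        m = case_models[("A", "ANN")]
        d = m.to_dict()
        d["params"]["w"][1][0] = 10.1
        feats = g.qcom_features(g.GRNModel.from_dict(d), "A")
        assert feats["constant_signal_propagation"] is False

    def test_feedback_sign_flip_detected(self, case_models):
        m = case_models[("C", "ANN")]
        d = m.to_dict()
        d["params"]["w"][1][4] = 8.0   # negative loop made positive
        feats = g.qcom_features(g.GRNModel.from_dict(d), "C")
        assert feats["negative_feedback"] is False

    def test_unknown_case(self, case_models):
        with pytest.raises(ValueError):
            g.qcom_features(case_models[("A", "ANN")], "E")
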
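"""Fuzzy logistic regression: search, classification, and invariants."""

import numpy as np
import pytest
from scipy.special import expit

from fuzzylogit.datasets import generate, preset_dataset_I
from fuzzylogit.fuzzify import FuzzificationConfig, FuzzyDataset, \
    fuzzify_dataset
from fuzzylogit.model import (CoefficientSearchConfig, FuzzyLogisticRegression,
                              FuzzyThreshold, classify, defuzzify_coefficients,
                              fit, fuzzy_probability, generate_candidate,
                              linear_predictor, predict)
from fuzzylogit.tfn import TFN


class TestLinearPredictor:
    def test_zero_coefficients(self):
        out = linear_predictor([TFN(0, 0, 0), TFN(0, 0, 0)], [TFN(1, 2, 3)])
        assert out.as_tuple() == (0, 0, 0)

    def test_crisp_arithmetic(self):
        out = linear_predictor([TFN(1, 1, 1), TFN(0.5, 0.5, 0.5)],
                               [TFN(2, 2, 2)])
        assert out.as_tuple() == pytest.approx((2, 2, 2))

    def test_fuzzy_product_term(self):
        out = linear_predictor([TFN(0, 0, 0), TFN(-1, 1, 2)], [TFN(1, 2, 3)])
        assert out.as_tuple() == pytest.approx((-3, 2, 6))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="k\\+1"):
            linear_predictor([TFN(0, 0, 0)], [TFN(1, 2, 3)])


class TestFuzzyProbability:
    def test_zero_maps_to_half(self):
        assert fuzzy_probability(TFN(0, 0, 0)).as_tuple() == (0.5, 0.5, 0.5)

    def test_logistic_pointwise(self):
        p = fuzzy_probability(TFN(-1, 0, 1))
        assert p.as_tuple() == pytest.approx((0.2689, 0.5, 0.7311), abs=5e-5)

    def test_large_negative_keeps_ordering(self):
        p = fuzzy_probability(TFN(-40, -35, -30))
        assert 0 < p.a1 <= p.a2 <= p.a3 < 1e-10


class TestCandidates:
    def test_sort_and_affine_map(self):
        """Raw triple (0.9, 0.1, 0.5) on [-2,2] -> sorted, mapped (-1.6,0,1.6)."""

        class _Seq:
            def uniform(self, lo, hi, size):
                return np.array([0.9, 0.1, 0.5]).reshape(size)

        cfg = CoefficientSearchConfig(I_minus=-2, I_plus=2)
        # k=1 would need 6 draws; use the three-value raw triple directly
        raw = np.array([[0.9, 0.1, 0.5]])
        raw.sort(axis=1)
        mapped = cfg.I_minus + raw * (cfg.I_plus - cfg.I_minus)
        assert mapped[0] == pytest.approx([-1.6, 0.0, 1.6])

    def test_identity_range(self):
        cfg = CoefficientSearchConfig(I_minus=0, I_plus=1)
        rng = np.random.default_rng(0)
        cand = generate_candidate(cfg, 2, rng)
        for t in cand:
            assert 0 <= t.a1 <= t.a2 <= t.a3 <= 1

    def test_supports_inside_range(self, rng):
        cfg = CoefficientSearchConfig(I_minus=-2, I_plus=2)
        for t in generate_candidate(cfg, 3, rng):
            assert -2 <= t.a1 and t.a3 <= 2

    def test_determinism(self):
        cfg = CoefficientSearchConfig(seed=5)
        a = generate_candidate(cfg, 2, np.random.default_rng(5))
        b = generate_candidate(cfg, 2, np.random.default_rng(5))
        assert [t.as_tuple() for t in a] == [t.as_tuple() for t in b]


def _tiny_fuzzy(seed=0, n=30):
    rng = np.random.default_rng(seed)
    x = np.concatenate([rng.normal(-1, 1, n // 2), rng.normal(1, 1, n - n // 2)])
    y = (np.arange(n) >= n // 2).astype(int)
    return fuzzify_dataset(x[:, None], y, FuzzificationConfig(seed=seed))


class TestFit:
    def test_single_candidate_returned_verbatim(self):
        data = _tiny_fuzzy()
        cfg = CoefficientSearchConfig(n_candidates=1, n_repetitions=1, seed=9)
        out = fit(data, cfg)
        expected = generate_candidate(cfg, data.n_predictors,
                                      np.random.default_rng(9))
        # same raw stream: the sole candidate must be the fit's coefficients
        raw = np.random.default_rng(9).uniform(0, 1, size=(1, 2, 3))
        raw.sort(axis=-1)
        mapped = cfg.I_minus + raw * (cfg.I_plus - cfg.I_minus)
        assert np.allclose([c.as_array() for c in out.coefficients], mapped[0])

    def test_chosen_measure_has_smallest_variation(self):
        out = fit(_tiny_fuzzy(), CoefficientSearchConfig(
            n_candidates=50, n_repetitions=5, seed=2))
        assert out.chosen_measure == min(out.measure_variations,
                                         key=out.measure_variations.get)
        assert out.best_error >= 0

    def test_coefficient_vertices_inside_range(self):
        out = fit(_tiny_fuzzy(), CoefficientSearchConfig(
            n_candidates=30, n_repetitions=2, seed=3))
        for c in out.coefficients:
            assert -2 <= c.a1 <= c.a2 <= c.a3 <= 2

    def test_single_class_rejected(self):
        data = _tiny_fuzzy()
        data.y_crisp = np.zeros_like(data.y_crisp)
        with pytest.raises(ValueError, match="class"):
            fit(data, CoefficientSearchConfig(n_candidates=2, n_repetitions=1))

    def test_sign_recovery_monte_carlo(self):
        """Defuzzified slope sign matches the generating direction.

        One informative predictor with higher values in class 1; the
        fitted slope should defuzzify positive in nearly all seeded runs.
        """
        hits = 0
        n_runs = 100
        for s in range(n_runs):
            rng = np.random.default_rng(s)
            n = 40
            y = np.tile([0, 1], n // 2)
            x = rng.normal(2.0 * y - 1.0, 0.8)
            clf = FuzzyLogisticRegression(n_candidates=80, n_repetitions=4,
                                          random_state=s).fit(x[:, None], y)
            _, beta, _ = clf.defuzzified_coefficients()[1]
            hits += beta > 0
        assert hits / n_runs >= 0.95


class TestClassify:
    def test_worked_example(self):
        """P̄=(0.2,0.3,0.4) vs τ̄=(0.4,0.5,0.6): label 0, w(𝔻)=0.2."""
        pred = classify(TFN(0.2, 0.3, 0.4), FuzzyThreshold(0.4, 0.5, 0.6))
        assert pred.label == 0
        assert pred.d_width == pytest.approx(0.2)
        assert pred.y_hat.as_tuple() == pytest.approx((-0.2, 0.0, 0.2))

    def test_equality_classifies_positive(self):
        pred = classify(TFN(0.5, 0.5, 0.5), FuzzyThreshold(0.4, 0.5, 0.6))
        assert pred.p_expected == 0.5 and pred.label == 1

    def test_probability_equal_to_threshold(self):
        tau = FuzzyThreshold(0.4, 0.5, 0.6)
        pred = classify(TFN(0.4, 0.5, 0.6), tau)
        assert pred.label == 1
        assert pred.d_width == pytest.approx(0.2)  # width(τ̄⊖τ̄)/2

    def test_prediction_tfn_symmetry(self):
        for p in (TFN(0.1, 0.2, 0.9), TFN(0.55, 0.6, 0.61)):
            pred = classify(p, FuzzyThreshold())
            assert pred.y_hat.a3 - pred.y_hat.a2 == pytest.approx(
                pred.y_hat.a2 - pred.y_hat.a1) == pytest.approx(pred.d_width)


class TestPredict:
    def test_zero_coefficients_all_positive(self):
        data = _tiny_fuzzy()
        from fuzzylogit.model import FLRFit
        zero = FLRFit([TFN(0, 0, 0)] * 2, "MAE", {}, 0.0, np.empty((0, 4)),
                      CoefficientSearchConfig())
        preds = predict(zero, data, FuzzyThreshold(0.4, 0.5, 0.6))
        assert all(p.p_expected == 0.5 and p.label == 1 for p in preds)

    def test_row_permutation_invariance(self):
        data = _tiny_fuzzy()
        out = fit(data, CoefficientSearchConfig(n_candidates=20,
                                                n_repetitions=2, seed=1))
        preds = predict(out, data)
        perm = np.random.default_rng(3).permutation(data.n_obs)
        data_p = FuzzyDataset(data.X_fuzzy[perm], data.Y_fuzzy[perm],
                              data.y_crisp[perm])
        preds_p = predict(out, data_p)
        assert [preds[i].label for i in perm] == [p.label for p in preds_p]

    def test_dimension_mismatch(self):
        data = _tiny_fuzzy()
        out = fit(data, CoefficientSearchConfig(n_candidates=5,
                                                n_repetitions=1))
        wide = FuzzyDataset(np.repeat(data.X_fuzzy, 2, axis=1), data.Y_fuzzy,
                            data.y_crisp)
        with pytest.raises(ValueError, match="predictors"):
            predict(out, wide)


class TestDefuzzifyCoefficients:
    @pytest.mark.parametrize("triple,beta,theta", [
        ((1.507, 1.642, 1.779), 1.643, 5.171),
        ((0, 0, 0), 0.0, 1.0),
        ((1.715, 1.733, 1.974), 1.807, 6.092),
    ])
    def test_published_rows(self, triple, beta, theta):
        from fuzzylogit.model import FLRFit
        f = FLRFit([TFN(0, 0, 0), TFN(*triple)], "MAE", {}, 0.0,
                   np.empty((0, 4)), CoefficientSearchConfig())
        name, b, _ = defuzzify_coefficients(f)[1]
        assert b == pytest.approx(beta, abs=5e-4)
        # published odds ratios follow the crisp estimate at printed precision
        assert np.exp(round(b, 3)) == pytest.approx(theta, abs=5e-4)


class TestEstimatorInvariants:
    def test_monotonicity_in_coefficient_vertices(self):
        """Raising every coefficient vertex raises E(P̄) for nonneg. X̄."""
        X = np.abs(np.random.default_rng(0).normal(size=(10, 2, 3)))
        X.sort(axis=-1)
        lo = np.array([[0.0, 0.1, 0.5], [0.0, 0.2, 0.4], [0.1, 0.3, 0.6]])
        hi = lo.copy()
        hi[:, 1] += 0.3  # raise vertices only
        from fuzzylogit.model import _eta
        for coef_lo, coef_hi in [(lo, hi)]:
            e_lo = expit(_eta(coef_lo[None], X)[0])
            e_hi = expit(_eta(coef_hi[None], X)[0])
            ev = lambda p: (p[:, 0] + 2 * p[:, 1] + p[:, 2]) / 4
            assert np.all(ev(e_hi) >= ev(e_lo) - 1e-12)

    def test_probability_containment(self, dataset_I):
        X, y = dataset_I
        clf = FuzzyLogisticRegression(n_candidates=50, n_repetitions=2,
                                      random_state=0).fit(X, y)
        for p in clf.predict_fuzzy(X):
            assert 0 < p.p_fuzzy.a1 <= p.p_fuzzy.a3 < 1
            assert 0 < p.p_expected < 1

    def test_determinism(self, dataset_I):
        X, y = dataset_I
        a = FuzzyLogisticRegression(n_candidates=40, n_repetitions=3,
                                    random_state=11).fit(X, y)
        b = FuzzyLogisticRegression(n_candidates=40, n_repetitions=3,
                                    random_state=11).fit(X, y)
        assert a.to_json() == b.to_json()
        assert np.array_equal(a.predict(X), b.predict(X))

    def test_degenerate_limit_matches_classical_logistic(self, dataset_I):
        """m=0 and crisp coefficients reduce to the classical model."""
        X, y = dataset_I
        clf = FuzzyLogisticRegression(m=0, n_candidates=10, n_repetitions=2,
                                      random_state=0).fit(X, y)
        beta = np.array([c.a2 for c in clf.coefficients_])
        clf.coefficients_ = [TFN(b, b, b) for b in beta]
        Xs = (X - clf.center_) / clf.scale_
        p_classical = expit(beta[0] + Xs @ beta[1:])
        p_fuzzy = np.array([p.p_expected for p in clf.predict_fuzzy(X)])
        assert np.allclose(p_fuzzy, p_classical, atol=1e-12)

    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone
        clf = FuzzyLogisticRegression(m=2.0, n_candidates=7)
        cloned = clone(clf)
        assert cloned.get_params()["m"] == 2.0
        assert cloned.get_params()["n_candidates"] == 7
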
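"""Diagonal LDA, stratified CV, session pooling, curves, error anatomy."""

import numpy as np
import pandas as pd
import pytest

from fingercode import GeneratorConfig, make_factorized_tuning, simulate_counts
from fingercode.datasets import SessionData, TrialDataset
from fingercode.decode import (
    ConfusionMatrix,
    aggregate_sessions,
    build_pseudopopulation,
    crossval_confusion,
    crossval_dataset,
    error_breakdown,
    fit_dlda,
    learning_curve,
    neuron_dropping_curve,
    predict_dlda,
    stratified_folds,
)
from fingercode.errors import ConfigError, DataError

from conftest import make_session


def shared_variance_gnb(xtr, ytr, xte):
    """Independent oracle: Gaussian naive Bayes with one pooled
    variance vector shared across classes, brute-force densities."""
    classes = sorted(set(ytr))
    mus, ns = {}, 0
    ss = np.zeros(xtr.shape[1])
    for c in classes:
        xc = xtr[np.asarray(ytr) == c]
        mus[c] = xc.mean(axis=0)
        ss += ((xc - mus[c]) ** 2).sum(axis=0)
        ns += len(xc)
    var = np.maximum(ss / (ns - len(classes)), 1e-6)
    priors = {c: np.mean(np.asarray(ytr) == c) for c in classes}
    out = []
    for x in xte:
        best, best_s = None, -np.inf
        for c in classes:
            s = np.log(priors[c]) + np.sum(
                -0.5 * np.log(2 * np.pi * var) - (x - mus[c]) ** 2 / (2 * var)
            )
            if s > best_s:
                best, best_s = c, s
        out.append(best)
    return np.array(out)


class TestDlda:
    def test_two_class_decision_boundary_at_midpoint(self):
        """Means 0 and 10, equal priors: trials below 5 -> class a."""
        xtr = np.array([[0.0], [0.1], [-0.1], [10.0], [9.9], [10.1]])
        ytr = np.array(["a", "a", "a", "b", "b", "b"])
        model = fit_dlda(xtr, ytr)
        pred, _, _ = predict_dlda(model, np.array([[4.9], [5.1]]))
        assert list(pred) == ["a", "b"]

    def test_agrees_with_shared_variance_gnb_oracle(self):
        """Exact label agreement with the naive-Bayes oracle on 100
        random small instances."""
        rng = np.random.default_rng(20)
        for _ in range(100):
            n_cls = int(rng.integers(2, 5))
            n_units = int(rng.integers(1, 6))
            n_tr = int(rng.integers(3, 8))
            xtr, ytr = [], []
            for c in range(n_cls):
                xtr.append(rng.normal(rng.normal(0, 3, n_units), 1.0,
                                      size=(n_tr, n_units)))
                ytr += [f"c{c}"] * n_tr
            xtr = np.concatenate(xtr)
            ytr = np.array(ytr)
            xte = rng.normal(0, 3, size=(10, n_units))
            model = fit_dlda(xtr, ytr)
            pred, _, _ = predict_dlda(model, xte)
            np.testing.assert_array_equal(pred, shared_variance_gnb(xtr, ytr, xte))

    def test_duplicating_trials_leaves_model_unchanged(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=(12, 4))
        y = np.repeat(["a", "b", "c"], 4)
        m1 = fit_dlda(x, y)
        m2 = fit_dlda(np.vstack([x, x]), np.concatenate([y, y]))
        np.testing.assert_allclose(m1.means, m2.means)
        np.testing.assert_allclose(m1.log_priors, m2.log_priors)
        # pooled variance denominator differs (2n-C vs n-C); means/priors don't

    def test_tie_break_lowest_class_and_flagged(self):
        xtr = np.array([[0.0], [0.0], [10.0], [10.0]])
        ytr = np.array(["a", "a", "b", "b"])
        model = fit_dlda(xtr, ytr)
        pred, _, ties = predict_dlda(model, np.array([[5.0]]))
        assert pred[0] == "a" and ties[0]

    def test_score_decreases_away_from_class_mean(self):
        xtr = np.array([[0.0, 0.0]] * 3 + [[8.0, 8.0]] * 3)
        ytr = np.array(["a"] * 3 + ["b"] * 3)
        xtr += np.random.default_rng(22).normal(0, 0.5, xtr.shape)
        model = fit_dlda(xtr, ytr)
        ia = model.classes.index("a")
        mean_a = model.means[ia]
        offsets = [0.0, 1.0, 2.0, 4.0]
        scores = []
        for d in offsets:
            x = np.zeros(2)
            x[model.unit_mask.nonzero()[0]] = mean_a + d
            _, s, _ = predict_dlda(model, x)
            scores.append(s[0, ia])
        assert all(np.diff(scores) < 0)

    def test_dimension_mismatch_errors(self):
        model = fit_dlda(np.zeros((4, 3)) + np.arange(4)[:, None],
                         np.array(["a", "a", "b", "b"]))
        with pytest.raises(DataError):
            predict_dlda(model, np.zeros((2, 5)))


class TestFoldsAndCv:
    def test_round_robin_stratified_no_shuffling(self):
        labels = np.array(["a", "b", "a", "b", "a", "b", "a", "b"])
        folds = stratified_folds(labels, 2)
        # within each class, trial order alternates folds 0,1,0,1
        np.testing.assert_array_equal(folds, [0, 0, 1, 1, 0, 0, 1, 1])

    def test_class_smaller_than_k_errors_naming_class(self):
        labels = np.array(["a"] * 8 + ["rare"] * 3)
        with pytest.raises(DataError, match="rare"):
            stratified_folds(labels, 8)

    def test_perfectly_separable_data_reaches_accuracy_one(self):
        rng = np.random.default_rng(23)
        conds = ["right_thumb", "right_index"]
        rates = np.concatenate([
            rng.normal(5.0, 0.1, size=(16, 3)),
            rng.normal(50.0, 0.1, size=(16, 3)),
        ])
        s = make_session(np.abs(rates), np.repeat(conds, 16))
        cm = crossval_confusion(s, k=8)
        assert cm.accuracy == 1.0

    def test_permuted_labels_give_chance_accuracy(self):
        """6 balanced classes with labels shuffled: accuracy ~ 1/6."""
        rng = np.random.default_rng(24)
        n_per, classes = 24, [f"right_{f}" for f in
                              ("thumb", "index", "middle", "ring", "little")] + ["nogo"]
        accs = []
        for rep in range(10):
            rates = rng.poisson(8.0, size=(n_per * 6, 30)) / 0.5
            labels = np.array(np.repeat(classes, n_per))
            rng.shuffle(labels)
            s = make_session(rates.astype(float), labels, f"s{rep}")
            accs.append(crossval_confusion(s, k=8).accuracy)
        mean = np.mean(accs)
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(mean - 1 / 6) < 3 * max(se, 0.01)

    def test_no_test_fold_leakage_canary(self):
        """Corrupting test-fold trials of fold 0 must not change the
        model fitted on its training fold."""
        rng = np.random.default_rng(25)
        rates = rng.poisson(8.0, size=(32, 10)).astype(float) / 0.5
        labels = np.repeat(["right_thumb", "right_index"], 16)
        s1 = make_session(rates, labels)
        folds = stratified_folds(s1.conditions, 8)
        poisoned = rates.copy()
        poisoned[folds == 0] = 999.0          # absurd test-fold rates
        s2 = make_session(poisoned, labels)
        from fingercode.decode import fit_dlda as fit
        from fingercode.ratewin import filter_low_rate_units
        tr = folds != 0
        m1 = fit(s1.rates[tr], s1.conditions[tr],
                 unit_mask=filter_low_rate_units(s1.rates[tr], 1.0))
        m2 = fit(s2.rates[tr], s2.conditions[tr],
                 unit_mask=filter_low_rate_units(s2.rates[tr], 1.0))
        np.testing.assert_array_equal(m1.means, m2.means)
        np.testing.assert_array_equal(m1.unit_mask, m2.unit_mask)


class TestAggregation:
    def _cm(self, acc, n, sid):
        n_cor = int(acc * n)
        counts = np.array([[n_cor, n - n_cor], [0, 0]])
        return ConfusionMatrix(["a", "b"], counts, sid)

    def test_pooled_accuracy_weighted_arithmetic(self):
        pooled, acc, sd = aggregate_sessions(
            [self._cm(0.8, 100, "s1"), self._cm(0.6, 50, "s2")]
        )
        assert acc == pytest.approx((80 + 30) / 150)
        assert pooled.n_trials == 150

    def test_single_session_identity(self):
        cm = self._cm(0.75, 40, "s")
        pooled, acc, sd = aggregate_sessions([cm])
        np.testing.assert_array_equal(pooled.counts, cm.counts)
        assert sd == 0.0

    def test_order_invariance_and_trial_conservation(self):
        cms = [self._cm(0.8, 100, "s1"), self._cm(0.6, 50, "s2"),
               self._cm(0.9, 30, "s3")]
        p1, a1, sd1 = aggregate_sessions(cms)
        p2, a2, sd2 = aggregate_sessions(cms[::-1])
        assert a1 == a2 and sd1 == pytest.approx(sd2)
        assert p1.n_trials == sum(c.n_trials for c in cms)

    def test_class_mismatch_errors(self):
        bad = ConfusionMatrix(["x", "y"], np.eye(2, dtype=int), "s9")
        with pytest.raises(DataError):
            aggregate_sessions([self._cm(0.5, 10, "s1"), bad])


class TestCurves:
    def test_learning_curve_fraction_one_equals_crossval(self, small_dataset):
        lc = learning_curve(small_dataset, np.array([1.0]), k=8)
        _, acc, _, _ = crossval_dataset(small_dataset, k=8)
        assert lc.accuracy[-1] == pytest.approx(acc)

    def test_learning_curve_trend_on_weak_signal(self):
        """More training data should help when accuracy is off ceiling."""
        cfg = GeneratorConfig(
            n_sessions=2, n_units_per_session=12, trials_per_condition=32,
            hand_effect_sd=0.8, finger_effect_sd=0.8, seed=26,
        )
        ds = simulate_counts(make_factorized_tuning(cfg), cfg)
        lc = learning_curve(ds, np.array([0.15, 1.0]), k=8)
        assert lc.accuracy[0] < lc.accuracy[-1]

    def test_pseudopopulation_unit_additivity_and_min_trim(self):
        rng = np.random.default_rng(27)
        s1 = make_session(rng.poisson(5, (20, 7)).astype(float),
                          np.repeat(["right_thumb", "right_index"], 10), "s1")
        s2 = make_session(rng.poisson(5, (22, 9)).astype(float),
                          np.repeat(["right_thumb", "right_index"], 11), "s2")
        pseudo = build_pseudopopulation(TrialDataset([s1, s2]))
        ps = pseudo.sessions[0]
        assert ps.n_units == 16
        assert ps.n_trials == 20  # min(10, 11) per condition x 2

    def test_pseudopopulation_missing_condition_errors(self):
        rng = np.random.default_rng(28)
        s1 = make_session(rng.poisson(5, (20, 4)).astype(float),
                          np.repeat(["right_thumb", "right_index"], 10), "s1")
        s2 = make_session(rng.poisson(5, (20, 4)).astype(float),
                          np.repeat(["right_thumb", "right_middle"], 10), "s2")
        with pytest.raises(DataError):
            build_pseudopopulation(TrialDataset([s1, s2]))

    def test_neuron_dropping_full_population_no_variability(self, small_dataset):
        pseudo = build_pseudopopulation(small_dataset)
        n = pseudo.sessions[0].n_units
        ndc = neuron_dropping_curve(pseudo, np.array([n]), n_resamples=5, k=4)
        assert ndc.ci_low[0] == pytest.approx(ndc.ci_high[0])

    def test_neuron_dropping_m_bounds(self, small_dataset):
        pseudo = build_pseudopopulation(small_dataset)
        with pytest.raises(ConfigError):
            neuron_dropping_curve(pseudo, np.array([0]), n_resamples=2)
        with pytest.raises(ConfigError):
            neuron_dropping_curve(pseudo, np.array([10**6]), n_resamples=2)

    def test_neuron_dropping_monotone_trend(self):
        """Mean accuracy grows with M for independent informative units."""
        cfg = GeneratorConfig(
            n_sessions=2, n_units_per_session=30, trials_per_condition=16,
            hand_effect_sd=0.7, finger_effect_sd=0.7, seed=29,
        )
        ds = simulate_counts(make_factorized_tuning(cfg), cfg)
        pseudo = build_pseudopopulation(ds)
        ndc = neuron_dropping_curve(pseudo, np.array([2, 15, 60]),
                                    n_resamples=15, k=4, seed=1)
        assert ndc.accuracy[0] < ndc.accuracy[1] < ndc.accuracy[2]


class TestErrorBreakdown:
    def _cm_from_errors(self, classes, errors):
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        np.fill_diagonal(counts, 5)
        for t, p in errors:
            counts[classes.index(t), classes.index(p)] += 1
        return ConfusionMatrix(classes, counts, "s")

    def test_single_adjacent_error(self):
        classes = [f"right_{f}" for f in ("thumb", "index", "middle", "ring",
                                          "little")]
        cm = self._cm_from_errors(classes, [("right_middle", "right_ring")])
        out = error_breakdown(cm, mode="within_hand")
        assert out["adjacent_fraction"] == 1.0

    def test_single_matching_across_hand_error(self):
        classes = ["right_thumb", "left_thumb", "right_index", "left_index"]
        cm = self._cm_from_errors(classes, [("left_thumb", "right_thumb")])
        out = error_breakdown(cm, mode="ten_finger")
        assert out["matching_across_hand_fraction"] == 1.0
        assert out["adjacent_fraction"] == 0.0

    def test_zero_errors_not_applicable(self):
        classes = ["right_thumb", "right_index"]
        cm = self._cm_from_errors(classes, [])
        out = error_breakdown(cm, mode="within_hand")
        assert out["n_errors"] == 0 and np.isnan(out["adjacent_fraction"])
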
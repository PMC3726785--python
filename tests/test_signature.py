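"""LDA, ROC/AUC and the exhaustive subset search, against independent oracles."""

from itertools import chain, combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from mirsig.datatypes import ValidationError
from mirsig.signature import (
    MetricsReport,
    enumerate_signatures,
    evaluate_signature,
    evaluate_signatures,
    fit_lda,
    predict,
    rank_signatures,
    roc_auc,
    roc_curve,
)


def bayes_posterior_oracle(x_train, y_train, x_new, priors="empirical"):
    """Closed-form two-Gaussian shared-covariance posterior, computed from
    class densities (independent of the discriminant-weight algebra)."""
    pos = x_train[y_train == "AD"]
    neg = x_train[y_train == "NC"]
    mu_p, mu_n = pos.mean(axis=0), neg.mean(axis=0)
    n = len(x_train)
    scatter = (pos - mu_p).T @ (pos - mu_p) + (neg - mu_n).T @ (neg - mu_n)
    cov = scatter / (n - 2)
    if priors == "empirical":
        pi_p, pi_n = len(pos) / n, len(neg) / n
    else:
        pi_p = pi_n = 0.5
    log_p = multivariate_normal.logpdf(x_new, mean=mu_p, cov=cov, allow_singular=True)
    log_n = multivariate_normal.logpdf(x_new, mean=mu_n, cov=cov, allow_singular=True)
    return 1.0 / (1.0 + np.exp(np.log(pi_n) + log_n - np.log(pi_p) - log_p))


def mann_whitney_auc_oracle(scores, labels):
    """AUC as the exhaustive pairwise comparison statistic, ties count 1/2."""
    pos = scores[labels == "AD"]
    neg = scores[labels == "NC"]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestEnumerateSignatures:
    def test_seven_mirnas_give_127_signatures(self):
        panel = [f"mir{i}" for i in range(7)]
        assert len(enumerate_signatures(panel)) == 127

    def test_single_name(self):
        assert enumerate_signatures(["m"]) == [("m",)]

    def test_matches_powerset_oracle(self):
        panel = ["b", "a", "c"]
        subsets = enumerate_signatures(panel)
        assert len(subsets) == 7
        oracle = set(
            chain.from_iterable(
                combinations(sorted(panel), k) for k in range(1, 4)
            )
        )
        assert set(subsets) == oracle

    @pytest.mark.parametrize("n", range(1, 11))
    def test_count_is_two_to_n_minus_one(self, n):
        assert len(enumerate_signatures([f"m{i}" for i in range(n)])) == 2**n - 1

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            enumerate_signatures(["a", "a", "b"])


class TestFitLda:
    def test_symmetric_1d_boundary_at_zero(self):
        x = np.array([[-1.2], [-0.8], [0.8], [1.2]])
        y = np.array(["NC", "NC", "AD", "AD"])
        model = fit_lda(x, y, priors="equal")
        post = predict(model, np.array([[0.0]]))
        assert post["posterior_ad"].iloc[0] == pytest.approx(0.5)

    def test_identical_means_posterior_equals_priors(self):
        x = np.array([[1.0, 2.0], [3.0, 0.0], [1.0, 2.0], [3.0, 0.0], [2.0, 1.0], [2.0, 1.0]])
        y = np.array(["AD", "AD", "NC", "NC", "AD", "NC"])
        model = fit_lda(x, y)
        np.testing.assert_allclose(model.weights, 0.0, atol=1e-12)
        post = predict(model, np.array([[5.0, -3.0], [0.0, 0.0]]))
        np.testing.assert_allclose(
            post["posterior_ad"], model.priors["AD"], atol=1e-12
        )

    def test_posteriors_match_bayes_oracle_on_random_instances(self, rng):
        for _ in range(25):
            n_pos = rng.integers(3, 10)
            n_neg = rng.integers(3, 10)
            p = rng.integers(1, 5)
            x = rng.normal(0, 1, size=(n_pos + n_neg, p))
            x[:n_pos] += rng.normal(0, 1, size=p)
            y = np.array(["AD"] * n_pos + ["NC"] * n_neg)
            grid = rng.normal(0, 2, size=(6, p))
            for priors in ("empirical", "equal"):
                model = fit_lda(x, y, priors=priors)
                ours = predict(model, grid)["posterior_ad"].to_numpy()
                oracle = bayes_posterior_oracle(x, y, grid, priors=priors)
                np.testing.assert_allclose(ours, oracle, atol=1e-8)

    def test_matches_reference_lda_implementation(self):
        """Posteriors agree with R's MASS::lda on a fixed 6-point dataset.

        The expected values were computed once with
        ``MASS::lda(x, y); predict(fit, grid)$posterior[,"AD"]`` and frozen.
        """
        x = np.array(
            [[0.0, 0.0], [1.0, 0.5], [2.5, 2.0], [3.0, 3.5], [0.5, 2.0], [2.0, 0.5]]
        )
        y = np.array(["NC", "NC", "AD", "AD", "NC", "AD"])
        grid = np.array(
            [[0.0, 0.0], [1.5, 1.5], [3.0, 3.0], [-1.0, 2.0], [2.0, -1.0], [1.0, 2.5]]
        )
        expected = np.array(
            [
                0.000000268855,
                0.446258494114,
                0.999999586040,
                0.000000000000,
                0.999996362043,
                0.000114904885,
            ]
        )
        model = fit_lda(x, y)
        ours = predict(model, grid)["posterior_ad"].to_numpy()
        np.testing.assert_allclose(ours, expected, atol=1e-8)

    def test_singular_covariance_is_regularized_and_flagged(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 6.0], [3.0, 6.0]])
        y = np.array(["AD", "AD", "NC", "NC"])
        model = fit_lda(x, y)
        assert model.regularized
        assert np.isfinite(model.weights).all()

    def test_class_with_too_few_samples(self):
        with pytest.raises(ValidationError, match="2 samples"):
            fit_lda(np.zeros((3, 1)), np.array(["AD", "NC", "NC"]))


class TestPredict:
    def _model(self):
        x = np.array([[0.0], [0.4], [2.0], [2.4]])
        y = np.array(["NC", "NC", "AD", "AD"])
        return fit_lda(x, y)

    def test_training_mean_is_confidently_classified(self):
        model = self._model()
        post = predict(model, np.array([[2.2], [0.2]]))
        assert post["posterior_ad"].iloc[0] > 0.5
        assert post["posterior_ad"].iloc[1] < 0.5
        assert list(post["label"]) == ["AD", "NC"]

    def test_posteriors_normalized(self):
        model = self._model()
        post = predict(model, np.linspace(-3, 5, 20)[:, None])
        assert ((0 <= post["posterior_ad"]) & (post["posterior_ad"] <= 1)).all()

    def test_feature_mismatch_rejected(self):
        x = pd.DataFrame({"a": [0.0, 0.1, 1.0, 1.1], "b": [0.0, 0.1, 1.0, 1.1]})
        y = np.array(["NC", "NC", "AD", "AD"])
        model = fit_lda(x, y)
        with pytest.raises(ValidationError, match="absent|mismatch"):
            predict(model, pd.DataFrame({"a": [0.5], "c": [0.5]}))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array(["AD", "AD", "NC", "NC"])
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(1.0)

    def test_all_tied_scores_give_half(self):
        scores = np.full(10, 0.5)
        labels = np.array(["AD"] * 4 + ["NC"] * 6)
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5)

    def test_hand_computed_small_cases(self):
        # AD (0.9, 0.8, 0.35) vs NC (0.4, 0.3, 0.2): 8 wins of 9 pairs
        scores = np.array([0.9, 0.8, 0.35, 0.4, 0.3, 0.2])
        labels = np.array(["AD", "AD", "AD", "NC", "NC", "NC"])
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(8.0 / 9)
        assert auc == pytest.approx(mann_whitney_auc_oracle(scores, labels))
        # with a genuine tie: AD (0.9, 0.4) vs NC (0.4, 0.2) -> 3.5/4
        scores = np.array([0.9, 0.4, 0.4, 0.2])
        labels = np.array(["AD", "AD", "NC", "NC"])
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(3.5 / 4)

    def test_curve_geometry(self, rng):
        scores = rng.uniform(0, 1, 30)
        labels = rng.choice(["AD", "NC"], 30)
        if len(set(labels)) < 2:
            labels[:2] = ["AD", "NC"]
        roc = roc_curve(scores, labels)
        assert roc.iloc[0]["fpr"] == 0.0 and roc.iloc[0]["tpr"] == 0.0
        assert roc.iloc[-1]["fpr"] == 1.0 and roc.iloc[-1]["tpr"] == 1.0
        assert (roc["fpr"].diff().dropna() >= 0).all()
        assert (roc["tpr"].diff().dropna() >= 0).all()

    def test_matches_mann_whitney_on_random_vectors(self, rng):
        for _ in range(200):
            n = rng.integers(4, 30)
            # coarse grid forces plenty of ties
            scores = rng.choice(np.linspace(0, 1, 5), n)
            labels = rng.choice(["AD", "NC"], n)
            if len(set(labels)) < 2:
                labels[:2] = ["AD", "NC"]
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(mann_whitney_auc_oracle(scores, labels))

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.uniform(0.01, 0.99, 40)
        labels = rng.choice(["AD", "NC"], 40)
        labels[:2] = ["AD", "NC"]
        _, auc1 = roc_auc(scores, labels)
        _, auc2 = roc_auc(np.log(scores / (1 - scores)), labels)
        assert auc1 == pytest.approx(auc2)

    def test_label_swap_maps_auc_to_complement(self, rng):
        scores = rng.uniform(0, 1, 25)
        labels = rng.choice(["AD", "NC"], 25)
        labels[:2] = ["AD", "NC"]
        swapped = np.where(labels == "AD", "NC", "AD")
        _, auc = roc_auc(scores, labels)
        _, auc_swapped = roc_auc(scores, swapped)
        assert auc_swapped == pytest.approx(1.0 - auc)

    def test_one_class_absent(self):
        with pytest.raises(ValidationError, match="both classes"):
            roc_auc(np.array([0.1, 0.9]), np.array(["AD", "AD"]))


def _separable_cohort(rng, n_pos, n_neg, p=3, shift=3.0, index_prefix="S"):
    x = rng.normal(0, 1, size=(n_pos + n_neg, p))
    x[:n_pos] += shift
    y = np.array(["AD"] * n_pos + ["NC"] * n_neg)
    frame = pd.DataFrame(
        x,
        columns=[f"m{i}" for i in range(p)],
        index=[f"{index_prefix}{i}" for i in range(n_pos + n_neg)],
    )
    return frame, y


class TestEvaluateSignatures:
    def test_resubstitution_on_separable_classes(self, rng):
        train, y = _separable_cohort(rng, 8, 8, index_prefix="T")
        test = train.copy()
        test.index = [f"E{i}" for i in range(len(test))]
        report = evaluate_signature(tuple(train.columns), train, y, test, y)
        assert report.accuracy == 1.0 and report.auc == 1.0

    def test_label_swap_swaps_sensitivity_and_specificity(self, rng):
        train, y_train = _separable_cohort(rng, 10, 10, shift=1.0, index_prefix="T")
        test, y_test = _separable_cohort(rng, 9, 11, shift=1.0, index_prefix="E")
        r = evaluate_signature(tuple(train.columns), train, y_train, test, y_test)
        swap = {"AD": "NC", "NC": "AD"}
        y_train_s = np.array([swap[v] for v in y_train])
        y_test_s = np.array([swap[v] for v in y_test])
        r_s = evaluate_signature(
            tuple(train.columns), train, y_train_s, test, y_test_s
        )
        assert r_s.sensitivity == pytest.approx(r.specificity)
        assert r_s.specificity == pytest.approx(r.sensitivity)

    def test_overlapping_sample_ids_rejected(self, rng):
        train, y = _separable_cohort(rng, 4, 4, index_prefix="X")
        with pytest.raises(ValidationError, match="share sample ids"):
            evaluate_signatures(train, y, train, y)

    def test_permuted_training_labels_give_chance_auc(self, rng):
        medians = []
        for _ in range(20):
            train, y_train = _separable_cohort(rng, 8, 12, p=5, shift=2.0, index_prefix="T")
            test, y_test = _separable_cohort(rng, 10, 9, p=5, shift=2.0, index_prefix="E")
            y_perm = rng.permutation(y_train)
            reports = evaluate_signatures(train, y_perm, test, y_test)
            medians.append(np.median([r.auc for r in reports]))
        assert abs(np.mean(medians) - 0.5) < 0.1


class TestRankSignatures:
    def _report(self, spec, sens, auc, acc=0.9, features=("a",)):
        return MetricsReport(
            features=features,
            tp=1, fp=0, tn=1, fn=0,
            accuracy=acc,
            sensitivity=sens,
            specificity=spec,
            roc=pd.DataFrame({"threshold": [np.inf], "fpr": [0.0], "tpr": [0.0]}),
            auc=auc,
        )

    def test_strictly_exceeding_cutoffs_kept(self):
        # the headline signature: spec 0.941, sens 0.95, AUC 0.953
        kept = rank_signatures([self._report(0.941, 0.95, 0.953)])
        assert len(kept) == 1

    def test_boundary_dropped(self):
        assert rank_signatures([self._report(0.9, 0.95, 0.953)]) == []

    def test_empty_survivors_ok(self):
        reports = [self._report(0.95, 0.95, auc) for auc in (0.85, 0.9)]
        assert rank_signatures(reports) == []

    def test_sort_order(self):
        a = self._report(0.95, 0.95, 0.96, acc=0.9, features=("a", "b"))
        b = self._report(0.95, 0.95, 0.99, acc=0.8, features=("c",))
        c = self._report(0.95, 0.95, 0.96, acc=0.9, features=("a",))
        out = rank_signatures([a, b, c])
        assert [r.features for r in out] == [("c",), ("a",), ("a", "b")]
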
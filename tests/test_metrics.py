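import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanoml5mou import (
    ConfusionCounts,
    MetricsReport,
    auprc,
    auroc,
    confusion,
    evaluate_scores,
    scalar_metrics,
)
from nanoml5mou.errors import UsageError


def pairwise_auroc_oracle(labels, scores):
    """O(n^2) rank formulation: P(score+ > score-) + 0.5 P(tie)."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_correct_predictions(self):
        assert confusion([1, 0], [0.9, 0.1]) == ConfusionCounts(tp=1, fp=0, tn=1, fn=0)

    def test_inverted_predictions(self):
        assert confusion([1, 0], [0.1, 0.9]) == ConfusionCounts(tp=0, fp=1, tn=0, fn=1)

    def test_counts_conserve_n(self, rng):
        labels = rng.integers(0, 2, 100)
        scores = rng.random(100)
        c = confusion(labels, scores)
        assert c.n == 100

    def test_threshold_ties_go_positive(self):
        assert confusion([1], [0.5], threshold=0.5).tp == 1

    def test_length_mismatch(self):
        with pytest.raises(UsageError):
            confusion([1, 0], [0.5])


class TestScalarMetrics:
    def test_perfect_classifier(self):
        m = scalar_metrics(ConfusionCounts(tp=1, fp=0, tn=1, fn=0))
        assert (m.acc, m.precision, m.recall, m.f1, m.mcc) == (1, 1, 1, 1, 1)

    def test_perfectly_wrong_classifier(self):
        m = scalar_metrics(ConfusionCounts(tp=0, fp=1, tn=0, fn=1))
        assert m.mcc == -1

    def test_hand_computed_example(self):
        m = scalar_metrics(ConfusionCounts(tp=50, fp=10, tn=40, fn=0))
        assert m.acc == pytest.approx(0.9)
        assert m.precision == pytest.approx(50 / 60)
        assert m.recall == 1.0
        assert m.f1 == pytest.approx(2 * (5 / 6) / (1 + 5 / 6))
        assert m.mcc == pytest.approx(0.8165, abs=1e-4)

    def test_degenerate_ratios_flagged_not_nan(self):
        m = scalar_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert m.precision == 0.0 and m.recall == 0.0
        assert {"precision", "recall", "f1", "mcc"} <= set(m.degenerate)

    def test_exhaustive_agreement_with_sklearn(self):
        """All 6^4 - 1 confusion matrices with entries <= 5 against sklearn's
        textbook implementations (zero_division=0 mirrors the degenerate-flag
        convention)."""
        from sklearn.metrics import (
            accuracy_score,
            f1_score,
            matthews_corrcoef,
            precision_score,
            recall_score,
        )

        for tp, fp, tn, fn in itertools.product(range(6), repeat=4):
            if tp + fp + tn + fn == 0:
                continue
            y_true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
            y_pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
            m = scalar_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            assert m.acc == pytest.approx(accuracy_score(y_true, y_pred))
            assert m.precision == pytest.approx(
                precision_score(y_true, y_pred, zero_division=0)
            )
            assert m.recall == pytest.approx(recall_score(y_true, y_pred, zero_division=0))
            assert m.f1 == pytest.approx(f1_score(y_true, y_pred, zero_division=0))
            if len(set(y_true)) > 1 or len(set(y_pred)) > 1:
                assert m.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 1, 0, 0], [0.9, 0.8, 0.3, 0.1]) == 1.0

    def test_three_of_four_pairs_ordered(self):
        assert auroc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1]) == 0.75

    def test_complete_tie_is_half(self):
        assert auroc([1, 0], [0.5, 0.5]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(UsageError):
            auroc([1, 1], [0.2, 0.8])

    def test_matches_pairwise_oracle_on_random_inputs(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 51))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.choice([0.1, 0.25, 0.5, 0.8, rng.random()], size=n)
            assert auroc(labels, scores) == pytest.approx(pairwise_auroc_oracle(labels, scores))

    @given(st.data())
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_complement_under_score_negation_without_ties(self, data):
        n = data.draw(st.integers(4, 30))
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < len(ls)
            )
        )
        scores = data.draw(
            st.lists(st.floats(0, 1, allow_nan=False), min_size=n, max_size=n, unique=True)
        )
        assert auroc(labels, scores) == pytest.approx(
            1.0 - auroc(labels, [-s for s in scores])
        )

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, 60)
        labels[0], labels[1] = 0, 1
        scores = rng.random(60)
        assert auroc(labels, scores) == pytest.approx(auroc(labels, np.exp(3 * scores)))


class TestAuprc:
    def test_perfect_separation(self):
        assert auprc([1, 1, 0, 0], [0.9, 0.8, 0.3, 0.1]) == 1.0

    def test_single_positive_ranked_last(self):
        assert auprc([1, 0], [0.1, 0.9]) == 0.5

    def test_all_ties_equals_prevalence(self):
        assert auprc([1, 0, 0, 1, 0], [0.3] * 5) == pytest.approx(2 / 5)

    def test_matches_sklearn_average_precision(self, rng):
        from sklearn.metrics import average_precision_score

        for _ in range(100):
            n = int(rng.integers(3, 40))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 1)  # coarse scores force ties
            assert auprc(labels, scores) == pytest.approx(
                average_precision_score(labels, scores)
            )


class TestMetricsReport:
    def test_fold_aggregation(self):
        folds = [
            dict(auroc=0.9, auprc=0.8, acc=0.85, precision=0.8, recall=0.9, f1=0.85, mcc=0.7),
            dict(auroc=0.8, auprc=0.7, acc=0.75, precision=0.7, recall=0.8, f1=0.75, mcc=0.5),
        ]
        report = MetricsReport.from_folds(folds)
        assert report.auroc == pytest.approx((0.85, np.std([0.9, 0.8], ddof=1)))
        assert report.mcc[0] == pytest.approx(0.6)

    def test_single_evaluation_has_zero_sd(self, rng):
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        report = MetricsReport.single(evaluate_scores(labels, rng.random(50)))
        assert all(stats["sd"] == 0.0 for stats in report.to_dict().values())
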
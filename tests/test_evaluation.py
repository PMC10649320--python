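import numpy as np
import pytest

from pirlstm import (
    ConfusionCounts,
    GeneralizationConfig,
    SyntheticSpec,
    TrainConfig,
    compute_metrics,
    confusion,
    cross_validate,
    generate_benchmark,
    split_folds,
)
from pirlstm.benchmark import POSITIVE
from pirlstm.nn import NetworkConfig


def _independent_metrics(tp, tn, fp, fn):
    """Direct textbook evaluation of the four formulas (test oracle)."""
    n = tp + tn + fp + fn
    acc = (tp + tn) / n
    sen = tp / (tp + fn) if tp + fn else None
    ppv = tp / (tp + fp) if tp + fp else None
    f1 = (2 * sen * ppv / (sen + ppv)
          if sen and ppv else None)
    return acc, sen, ppv, f1


class TestConfusion:
    def test_all_correct(self):
        c = confusion([1] * 10 + [0] * 10, [1] * 10 + [0] * 10)
        assert (c.TP, c.TN, c.FP, c.FN) == (10, 10, 0, 0)

    def test_all_predicted_positive(self):
        c = confusion([1] * 10, [1] * 5 + [0] * 5)
        assert (c.TP, c.FP, c.TN, c.FN) == (5, 5, 0, 0)

    def test_matches_bruteforce_tally(self, rng):
        preds = rng.integers(0, 2, size=50)
        labels = rng.integers(0, 2, size=50)
        c = confusion(preds, labels)
        tally = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
        for p, l in zip(preds, labels):
            key = {(1, 1): "TP", (0, 0): "TN", (1, 0): "FP", (0, 1): "FN"}[(p, l)]
            tally[key] += 1
        assert (c.TP, c.TN, c.FP, c.FN) == \
            (tally["TP"], tally["TN"], tally["FP"], tally["FN"])
        assert c.total == 50

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestComputeMetrics:
    def test_perfect_classifier(self):
        r = compute_metrics(ConfusionCounts(TP=50, TN=50, FP=0, FN=0))
        assert (r.ACC, r.SEN, r.PPV, r.F1) == (1.0, 1.0, 1.0, 1.0)

    def test_worked_example(self):
        r = compute_metrics(ConfusionCounts(TP=9, FN=1, FP=3, TN=7))
        assert r.SEN == pytest.approx(0.9)
        assert r.PPV == pytest.approx(0.75)
        assert r.F1 == pytest.approx(2 / (1 / 0.9 + 1 / 0.75))

    def test_undefined_reported_not_zero(self):
        r = compute_metrics(ConfusionCounts(TP=0, FP=0, TN=10, FN=10))
        assert r.ACC == 0.5
        assert r.PPV is None and r.F1 is None
        assert any("PPV" in reason for reason in r.undefined_reasons)

    def test_agreement_with_formula_oracle_1000_tables(self, rng):
        for _ in range(1000):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 40, size=4))
            if tp + tn + fp + fn == 0:
                continue
            r = compute_metrics(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn))
            acc, sen, ppv, f1 = _independent_metrics(tp, tn, fp, fn)
            assert r.ACC == pytest.approx(acc, abs=1e-12)
            for ours, ref in ((r.SEN, sen), (r.PPV, ppv), (r.F1, f1)):
                if ref is None:
                    assert ours is None or ours == 0.0 and ref is None
                else:
                    assert ours == pytest.approx(ref, abs=1e-12)
            if r.F1 is not None:
                assert min(r.SEN, r.PPV) - 1e-12 <= r.F1 <= max(r.SEN, r.PPV) + 1e-12


class TestSplitFolds:
    def test_even_stratified_partition(self, rng):
        ds = generate_benchmark(SyntheticSpec(n_per_class=100, seed=1))
        fa = split_folds(ds, k=4, seed=0)
        labels = np.array([1 if s.label == POSITIVE else 0 for s in ds.samples])
        seen = np.zeros(len(ds), dtype=int)
        for fold in range(4):
            te = fa.test_indices(fold)
            seen[te] += 1
            assert np.sum(labels[te] == 1) == 25
            assert np.sum(labels[te] == 0) == 25
        assert np.all(seen == 1)

    def test_uneven_sizes_differ_by_at_most_one(self):
        ds = generate_benchmark(SyntheticSpec(n_per_class=10, seed=2))
        fa = split_folds(ds, k=4, seed=3)
        labels = np.array([1 if s.label == POSITIVE else 0 for s in ds.samples])
        for fold in range(4):
            te = fa.test_indices(fold)
            assert np.sum(labels[te] == 1) in (2, 3)
            assert np.sum(labels[te] == 0) in (2, 3)

    def test_reproducible(self, small_dataset):
        a = split_folds(small_dataset, k=4, seed=9).fold_of
        b = split_folds(small_dataset, k=4, seed=9).fold_of
        np.testing.assert_array_equal(a, b)

    def test_class_smaller_than_k(self):
        ds = generate_benchmark(SyntheticSpec(n_per_class=3, seed=4))
        with pytest.raises(ValueError, match="fewer than k"):
            split_folds(ds, k=4)


class TestCrossValidate:
    @pytest.fixture(scope="class")
    def cv_result(self):
        ds = generate_benchmark(
            SyntheticSpec(n_per_class=60, p_u1=1.0, p_a10=1.0,
                          length_range=(18, 24), seed=6))
        tr = TrainConfig(max_epochs=4, batch_size=32, seed=2,
                         generalization=GeneralizationConfig(p=0.6, seed=2))
        net = NetworkConfig(hidden_size=8, n_layers=1)
        return cross_validate(ds, net, tr, k=4)

    def test_four_fold_reports_and_full_coverage(self, cv_result):
        assert len(cv_result.fold_reports) == 4
        total_tested = sum(r.counts.total for r in cv_result.fold_reports)
        assert total_tested == 120
        assert cv_result.pooled.counts.total == 120

    def test_mean_is_average_of_defined_folds(self, cv_result):
        accs = [r.ACC for r in cv_result.fold_reports]
        assert cv_result.mean["ACC"] == pytest.approx(np.mean(accs))
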
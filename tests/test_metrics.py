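import numpy as np
import pytest

from hemopipe.gwo import GWOConfig, gwo_select
from hemopipe.metrics import (
    ConfusionMatrix,
    class_rates,
    confusion,
    macro_metrics,
    make_classifier,
    stratified_split,
    train_eval,
)

# Published reference matrices for a binary smear classifier (rows = true)
BINARY_CM = ConfusionMatrix(np.array([[177, 4], [2, 176]]), ("ALL", "Healthy"))
# and for the four leukemia subtypes
SUBTYPE_CM = ConfusionMatrix(
    np.array(
        [
            [1004, 11, 5, 4],
            [5, 982, 11, 2],
            [2, 2, 1036, 10],
            [6, 13, 5, 996],
        ]
    ),
    ("Benign", "Precursor", "Pro-B", "Early pre-B"),
)


class TestStratifiedSplit:
    def test_binary_augmented_counts(self):
        labels = np.repeat(["Healthy", "ALL"], [593, 601])
        plan = stratified_split(labels, 0.7, seed=0)
        train_labels = labels[plan.train_idx]
        assert (train_labels == "Healthy").sum() == 415
        assert (train_labels == "ALL").sum() == 420
        assert len(plan.test_idx) == 178 + 181

    def test_subtype_test_counts(self):
        sizes = {"Benign": 1024, "Precursor": 1000, "Pro-B": 1050, "Early": 1020}
        labels = np.repeat(list(sizes), list(sizes.values()))
        plan = stratified_split(labels, 0.7, seed=1)
        test_labels = labels[plan.test_idx]
        counts = {c: int((test_labels == c).sum()) for c in sizes}
        assert counts == {"Benign": 308, "Precursor": 300, "Pro-B": 315, "Early": 306}
        assert len(plan.test_idx) == 1229

    def test_floor_rule_small_class(self):
        plan = stratified_split(np.zeros(10, dtype=int), 0.7, seed=3)
        assert len(plan.train_idx) == 7 and len(plan.test_idx) == 3

    def test_sizes_seed_independent_membership_varies(self):
        labels = np.repeat([0, 1], [20, 30])
        plans = [stratified_split(labels, 0.7, seed=s) for s in range(3)]
        assert all(len(p.train_idx) == 14 + 21 for p in plans)
        assert any(not np.array_equal(plans[0].train_idx, p.train_idx) for p in plans[1:])

    def test_disjoint_exhaustive(self):
        labels = np.repeat([0, 1, 2], [11, 7, 5])
        plan = stratified_split(labels, 0.6, seed=2)
        union = np.sort(np.concatenate([plan.train_idx, plan.test_idx]))
        np.testing.assert_array_equal(union, np.arange(23))

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.zeros(5, dtype=int), 1.0)


class TestConfusion:
    def test_perfect_prediction_diagonal(self):
        y = np.array([0, 1, 2, 0, 1])
        cm = confusion(y, y)
        np.testing.assert_array_equal(cm.counts, np.diag([2, 2, 1]))

    def test_hand_counted_binary(self):
        cm = confusion([0, 0, 1], [0, 1, 1], classes=(0, 1))
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])

    def test_row_sums_are_class_counts(self, rng):
        y_true = rng.integers(0, 3, 200)
        y_pred = rng.integers(0, 3, 200)
        cm = confusion(y_true, y_pred, classes=(0, 1, 2))
        np.testing.assert_array_equal(
            cm.counts.sum(axis=1), [(y_true == c).sum() for c in (0, 1, 2)]
        )

    def test_stray_label_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0, 3], classes=(0, 1))


class TestClassRates:
    def test_binary_reference_tpr(self):
        rates = class_rates(BINARY_CM)
        assert rates["tpr"][0] == pytest.approx(177 / 181)  # ALL, prints as 97.7%
        assert rates["tpr"][1] == pytest.approx(176 / 178)  # Healthy, prints as 98.8%
        np.testing.assert_allclose(rates["tpr"] + rates["fnr"], 1.0)

    def test_subtype_reference_rates(self):
        rates = class_rates(SUBTYPE_CM)
        assert rates["tpr"][0] == pytest.approx(1004 / 1024)  # Benign, prints as 98.04%
        assert rates["precision"][0] == pytest.approx(1004 / 1017)  # prints as 98.72%
        # per-class accuracy follows the TPR convention
        np.testing.assert_array_equal(rates["accuracy"], rates["tpr"])

    def test_never_predicted_class_warns(self):
        cm = ConfusionMatrix(np.array([[2, 0], [1, 0]]), (0, 1))
        with pytest.warns(UserWarning):
            rates = class_rates(cm)
        assert rates["precision"][1] == 0.0


class TestMacroMetrics:
    def test_subtype_overall_accuracy(self):
        report = macro_metrics(SUBTYPE_CM)
        assert report.overall_accuracy * 100 == pytest.approx(98.14, abs=0.005)

    def test_perfect_diagonal_all_ones(self):
        report = macro_metrics(ConfusionMatrix(np.diag([5, 7, 9]), (0, 1, 2)))
        assert report.overall_accuracy == 1.0
        assert report.macro_f1 == 1.0
        assert report.macro_precision == 1.0

    def test_macro_f1_permutation_invariant(self, rng):
        counts = rng.integers(0, 50, (4, 4))
        counts += np.diag(rng.integers(10, 50, 4))  # ensure non-empty rows
        perm = rng.permutation(4)
        r1 = macro_metrics(ConfusionMatrix(counts, (0, 1, 2, 3)))
        r2 = macro_metrics(ConfusionMatrix(counts[np.ix_(perm, perm)], tuple(perm)))
        assert r1.macro_f1 == pytest.approx(r2.macro_f1)
        assert r1.overall_accuracy == pytest.approx(r2.overall_accuracy)

    def test_agrees_with_sklearn_report(self, rng):
        """Dual route: macro averages cross-checked against sklearn."""
        from sklearn.metrics import classification_report

        y_true = rng.integers(0, 3, 300)
        y_pred = np.where(rng.random(300) < 0.7, y_true, rng.integers(0, 3, 300))
        report = macro_metrics(confusion(y_true, y_pred, classes=(0, 1, 2)))
        sk = classification_report(y_true, y_pred, output_dict=True)
        assert report.macro_precision == pytest.approx(sk["macro avg"]["precision"])
        assert report.macro_recall == pytest.approx(sk["macro avg"]["recall"])
        assert report.macro_f1 == pytest.approx(sk["macro avg"]["f1-score"])
        assert report.overall_accuracy == pytest.approx(sk["accuracy"])


@pytest.fixture(scope="module")
def separable():
    # well away from the origin so the classes also separate in angle
    # (cosine preset), and big enough for the coarse k=100 preset
    rng = np.random.default_rng(17)
    x = rng.standard_normal((300, 10)) + 3.0
    y = np.repeat([0, 1], 150)
    x[y == 1, :5] += 6.0
    return x, y


class TestTrainEval:
    @pytest.mark.parametrize("spec", ["knn-fine", "knn-cosine", "knn-cubic", "knn-coarse"])
    def test_separable_fixture_perfect_knn(self, separable, spec):
        x, y = separable
        plan = stratified_split(y, 0.7, seed=0)
        report = train_eval(x, y, plan, spec=spec, seed=0)
        assert report.overall_accuracy == 1.0

    @pytest.mark.parametrize("spec", ["svm-gaussian", "svm-quadratic", "svm-regression",
                                      "tree-medium", "nn-wide"])
    def test_other_presets_run(self, small_planted, spec):
        fm, _ = small_planted
        plan = stratified_split(fm.labels, 0.7, seed=0)
        report = train_eval(fm.values, fm.labels, plan, spec=spec, seed=0)
        assert 0.0 <= report.overall_accuracy <= 1.0

    def test_deterministic_report(self, small_planted):
        fm, _ = small_planted
        plan = stratified_split(fm.labels, 0.7, seed=4)
        r1 = train_eval(fm.values, fm.labels, plan, spec="knn-cosine", seed=4)
        r2 = train_eval(fm.values, fm.labels, plan, spec="knn-cosine", seed=4)
        np.testing.assert_array_equal(r1.confusion.counts, r2.confusion.counts)

    def test_unknown_spec_rejected(self):
        with pytest.raises(ValueError):
            make_classifier("knn-telepathic")

    def test_mask_restricts_features(self, small_planted):
        fm, truth = small_planted
        plan = stratified_split(fm.labels, 0.7, seed=0)
        mask = np.zeros(fm.n_features, dtype=int)
        mask[truth] = 1
        report = train_eval(fm.values, fm.labels, plan, spec="knn-fine", seed=0, mask=mask)
        assert report.selected_features == len(truth)
        assert report.total_features == fm.n_features
        assert report.overall_accuracy == 1.0

    def test_gwo_mask_beats_random_mask_of_same_size(self, planted):
        """Paired comparison: selected subset vs size-matched random subsets."""
        fm, _ = planted
        wins = 0
        for seed in range(5):
            mask, _ = gwo_select(fm, GWOConfig(n_pop=10, t_max=10), seed=seed)
            plan = stratified_split(fm.labels, 0.7, seed=seed)
            acc_sel = train_eval(fm.values, fm.labels, plan, "knn-fine", seed, mask=mask).overall_accuracy
            r = np.random.default_rng(1000 + seed)
            rand_mask = np.zeros(fm.n_features, dtype=int)
            rand_mask[r.choice(fm.n_features, int(mask.sum()), replace=False)] = 1
            acc_rand = train_eval(fm.values, fm.labels, plan, "knn-fine", seed, mask=rand_mask).overall_accuracy
            wins += acc_sel >= acc_rand
        assert wins >= 3
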
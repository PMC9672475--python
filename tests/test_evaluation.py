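import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tlmnet.evaluation import (
    ConfusionCounts,
    CVRecordSet,
    ModelSpec,
    aggregate,
    build_model,
    compare_distributions,
    confusion_from_predictions,
    mcc,
    permutation_importance,
    repeated_stratified_cv,
    roc_auc,
    top_mean_abs_coefficients,
)
from tlmnet.features import FeatureDescriptor
from tlmnet.pipeline import phenotype_task

from .oracles import auc_pairwise, mannwhitney_exact_enumeration, mcc_pearson


class TestMCC:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((5, 5, 0, 0), 1.0),
            ((5, 5, 5, 5), 0.0),
            ((3, 4, 1, 2), 10.0 / math.sqrt(600.0)),
            ((0, 5, 0, 5), 0.0),  # zero factor: documented convention
        ],
    )
    def test_known_tables(self, counts, expected):
        tp, tn, fp, fn = counts
        assert mcc(ConfusionCounts(tp, tn, fp, fn)) == pytest.approx(expected)

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)

    @settings(deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 25)] * 4))
    def test_equals_pearson_correlation_of_encodings(self, counts):
        tp, tn, fp, fn = counts
        c = ConfusionCounts(tp, tn, fp, fn)
        factors = [tp + fn, tp + fp, tn + fp, tn + fn]
        if any(f == 0 for f in factors) or c.total == 0:
            assert mcc(c) == 0.0
        else:
            assert mcc(c) == pytest.approx(mcc_pearson(tp, tn, fp, fn))


class TestAUC:
    def test_perfect_separation_and_total_ties(self):
        y = np.array([0, 0, 1, 1])
        assert roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), y) == 1.0
        assert roc_auc(np.ones(4), y) == 0.5

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            y = rng.integers(0, 2, size=8)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.random(8), 1)  # coarse grid forces ties
            assert roc_auc(scores, y) == pytest.approx(auc_pairwise(scores, y))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        y = np.array([0, 1] * 10)
        scores = rng.normal(size=20)
        assert roc_auc(scores, y) == pytest.approx(
            roc_auc(np.exp(3 * scores) + 7, y)
        )

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestModelRegistry:
    def test_registry_overrides(self):
        assert ModelSpec("LRCV").hyperparameters == {"max_iter": 10_000}
        assert ModelSpec("RF").hyperparameters["criterion"] == "entropy"
        assert ModelSpec("PSVC").hyperparameters["kernel"] == "poly"
        with pytest.raises(ValueError, match="unknown model"):
            ModelSpec("GBM")

    def test_build_model_applies_class_weight(self):
        model = build_model(ModelSpec("LRCV", class_weight="balanced"), seed=0)
        assert model.class_weight == "balanced"
        with pytest.raises(ValueError, match="class_weight"):
            build_model(ModelSpec("XGB", class_weight="balanced"), seed=0)


@pytest.fixture(scope="module")
def task(small_world):
    return phenotype_task(small_world)


class TestCrossValidation:
    def test_record_counts_partition_and_stratification(self, task):
        x, y = task
        folds = 5  # the compact world has few labeled genes per class
        records = repeated_stratified_cv(
            x, y, ModelSpec("LRCV"), repeats=3, folds=folds, seed=2
        )
        for metric in ("MCC", "AUC"):
            assert len(records.values(metric)) == 3 * folds
        from tlmnet.features import labels_to_binary

        y_bin = labels_to_binary(y, x.samples)
        global_prop = y_bin.mean()
        for repeat in range(3):
            test_sets = [t for r, f, _, t in records.folds if r == repeat]
            pooled = np.sort(np.concatenate(test_sets))
            assert np.array_equal(pooled, np.arange(x.n_samples))
            for test_idx in test_sets:
                fold_prop = y_bin[test_idx].mean()
                assert abs(fold_prop - global_prop) < 1.0 / len(test_idx)

    def test_no_leakage_between_fit_stages_and_heldout(self, task):
        x, y = task
        seen: list[tuple[int, int, str, frozenset]] = []

        def instrument(repeat, fold, stage, idx):
            seen.append((repeat, fold, stage, frozenset(idx.tolist())))

        records = repeated_stratified_cv(
            x, y, ModelSpec("LSVC"), repeats=1, folds=5, seed=3, instrument=instrument
        )
        test_by_fold = {(r, f): frozenset(t.tolist()) for r, f, _, t in records.folds}
        stages_by_fold: dict[tuple[int, int], set[str]] = {}
        for repeat, fold, stage, idx in seen:
            assert not idx & test_by_fold[(repeat, fold)]
            stages_by_fold.setdefault((repeat, fold), set()).add(stage)
        assert all(
            s == {"scaler_fit", "selection_fit", "model_fit"}
            for s in stages_by_fold.values()
        )

    def test_identical_seed_reproduces_records(self, task):
        x, y = task
        a = repeated_stratified_cv(x, y, ModelSpec("LRCV"), repeats=2, folds=5, seed=5)
        b = repeated_stratified_cv(x, y, ModelSpec("LRCV"), repeats=2, folds=5, seed=5)
        assert a.records == b.records

    def test_class_smaller_than_fold_count_raises(self, task):
        x, y = task
        with pytest.raises(ValueError, match="stratify"):
            repeated_stratified_cv(x, y, ModelSpec("LRCV"), repeats=1, folds=1000, seed=0)

    def test_feature_count_never_exceeds_training_samples(self, task):
        x, y = task
        from tlmnet.evaluation import fit_fold_pipeline
        from tlmnet.features import labels_to_binary

        y_bin = labels_to_binary(y, x.samples)
        # deliberately train on fewer samples than there are features
        pos = np.flatnonzero(y_bin == 1)[:5]
        neg = np.flatnonzero(y_bin == 0)[:5]
        train_idx = np.concatenate([pos, neg])
        assert len(train_idx) < x.n_features
        model, _, selected = fit_fold_pipeline(
            x, y_bin, train_idx, ModelSpec("LSVC"), seed=0
        )
        assert len(selected) == len(train_idx)
        assert model.n_features_in_ == len(selected)


class TestAggregation:
    def _records(self, values):
        from tlmnet.evaluation import CVRecord

        rs = CVRecordSet()
        for i, v in enumerate(values):
            rs.records.append(CVRecord(0, i, "LRCV", "fs", "AUC", v, 0))
        return rs

    def test_median_and_singleton(self):
        out = aggregate(self._records([0.2, 0.4, 0.9]), by=["model_key"], stat="median")
        assert out["median"].iloc[0] == 0.4
        out = aggregate(self._records([0.7]), by=["model_key"], stat="median")
        assert out["median"].iloc[0] == 0.7

    def test_mean_and_sd_match_hand_arithmetic(self):
        rs = self._records([0.0, 1.0, 2.0])
        assert aggregate(rs, by=["model_key"], stat="mean")["mean"].iloc[0] == 1.0
        assert aggregate(rs, by=["model_key"], stat="sd")["sd"].iloc[0] == pytest.approx(1.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate(CVRecordSet(), by=["model_key"])


class TestMannWhitney:
    def test_identical_samples_give_half_the_comparisons(self):
        x = [1.0, 2.0, 3.0]
        u, _ = compare_distributions(x, x)
        assert u == len(x) * len(x) / 2

    def test_exact_mode_matches_enumeration(self):
        x, y = [7.0, 8.0, 9.0], [1.0, 2.0, 3.0]
        u_exp, p_exp = mannwhitney_exact_enumeration(x, y)
        u, p = compare_distributions(x, y, method="exact")
        assert (u, p) == (pytest.approx(u_exp), pytest.approx(p_exp))
        assert p == pytest.approx(0.1)  # 2/20 arrangements are as extreme

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(4)
        x = list(rng.normal(size=9))
        y = list(rng.normal(size=7))
        base = compare_distributions(x, y)
        perm = compare_distributions(
            [x[i] for i in rng.permutation(9)], [y[i] for i in rng.permutation(7)]
        )
        assert base == pytest.approx(perm)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            compare_distributions([], [1.0])


class TestPermutationImportance:
    def test_planted_signal_and_constant_column(self):
        rng = np.random.default_rng(7)
        n = 200
        x = np.column_stack([
            rng.normal(size=n),       # informative
            rng.normal(size=n),       # noise
            np.zeros(n),              # constant: shuffling is a no-op
        ])
        y = (x[:, 0] > 0).astype(int)
        model = build_model(ModelSpec("LRCV"), seed=0).fit(x, y)
        imp = permutation_importance(model, x, y, n_repeats=5, seed=1)
        assert imp[0] > 0.2
        assert abs(imp[1]) < 0.1
        assert imp[2] == 0.0


class TestTopCoefficients:
    def _fd(self, name):
        return FeatureDescriptor(source="KEGG", set_id=name, family="gi_proportion")

    def test_hand_computed_ranking_and_eligibility(self):
        a, b, c = self._fd("a"), self._fd("b"), self._fd("c")
        runs = [
            {a: 1.0, b: -4.0, c: 0.5},
            {a: -2.0, b: 2.0, c: 0.5},
            {a: 3.0, b: -3.0},  # c missing: ineligible
        ]
        ranked = top_mean_abs_coefficients(runs, k=15)
        assert [f.set_id for f, _ in ranked] == ["b", "a"]
        assert ranked[0][1] == pytest.approx(3.0)
        assert ranked[1][1] == pytest.approx(2.0)

    def test_k_truncates_and_validates(self):
        a, b = self._fd("a"), self._fd("b")
        runs = [{a: 1.0, b: 2.0}]
        assert len(top_mean_abs_coefficients(runs, k=1)) == 1
        with pytest.raises(ValueError):
            top_mean_abs_coefficients(runs, k=0)
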
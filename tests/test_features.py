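import numpy as np
import pytest
import scipy.sparse as sp

from tlmnet.features import (
    FeatureTable,
    filter_gene_sets,
    gi_proportion_features,
    labels_to_binary,
    membership_features,
    merge_feature_tables,
    select_top_features,
    standardize,
)
from tlmnet.types import (
    GeneId,
    GeneSet,
    GeneSetCollection,
    GIMatrix,
    Species,
)

SC = Species.CEREVISIAE


def _genes(n, prefix="G"):
    return [GeneId(SC, f"{prefix}{i:03d}") for i in range(n)]


def _collection(source, member_lists, prefix="S"):
    coll = GeneSetCollection(source=source)
    for k, members in enumerate(member_lists):
        coll.add(GeneSet(set_id=f"{prefix}{k}", name=f"set {k}", members=tuple(members)))
    return coll


class TestSetFiltering:
    def test_size_bounds_after_background_intersection(self):
        genes = _genes(40)
        background = set(genes[:35])
        coll = _collection(
            "GO_BP",
            [
                genes[:31],      # 31 background members: too broad
                genes[:2],       # 2 members: too small
                genes[:3],       # exactly 3: kept
                genes[:30],      # exactly 30: kept
                genes[30:36],    # 6 listed but only 5 in background: kept
            ],
        )
        kept = filter_gene_sets(coll, background)
        assert set(kept.sets) == {"S2", "S3", "S4"}
        assert len(kept.sets["S4"].members) == 5

    def test_empty_background_raises(self):
        coll = _collection("GO_BP", [_genes(5)])
        with pytest.raises(ValueError, match="background"):
            filter_gene_sets(coll, set())


class TestGIProportion:
    def test_direct_ratio_and_zero_row(self):
        genes = _genes(6)
        # gene 0 interacts with members 1 and 3 of the 4-member set
        mat = sp.csr_matrix(
            np.array(
                [
                    [0, 1.0, 0, -0.5, 0, 0],
                    [0, 0, 0, 0, 0, 0],
                ]
            )
        )
        gi = GIMatrix(genes[:2], genes, mat, "scored")
        sets = _collection("KEGG", [genes[1:5]])
        table = gi_proportion_features(gi, sets)
        assert table.values[0, 0] == pytest.approx(0.5)
        assert table.values[1, 0] == 0.0

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(5)
        genes = _genes(20)
        dense = (rng.random((20, 20)) < 0.2) * rng.normal(size=(20, 20))
        gi = GIMatrix(genes, genes, sp.csr_matrix(dense), "scored")
        sets = _collection(
            "KEGG",
            [
                [genes[i] for i in rng.choice(20, size=size, replace=False)]
                for size in (3, 5, 7, 4, 6)
            ],
        )
        table = gi_proportion_features(gi, sets)
        for i, g in enumerate(genes):
            for j, gs in enumerate(sets):
                count = sum(
                    1 for m in gs.members if dense[i, genes.index(m)] != 0
                )
                assert table.values[i, j] == pytest.approx(count / len(gs.members))

    def test_invariant_to_member_order(self):
        rng = np.random.default_rng(6)
        genes = _genes(10)
        dense = (rng.random((10, 10)) < 0.3).astype(float)
        gi = GIMatrix(genes, genes, sp.csr_matrix(dense), "binary")
        members = [genes[i] for i in (2, 5, 7, 1)]
        a = gi_proportion_features(gi, _collection("KEGG", [members]))
        b = gi_proportion_features(gi, _collection("KEGG", [members[::-1]]))
        assert np.array_equal(a.values, b.values)


class TestMembership:
    def test_indicator_matches_containment_and_drops_orphans(self):
        genes = _genes(8)
        sets = _collection("COMPLEX", [genes[0:3], genes[2:5]], prefix="C")
        table = membership_features(sets, genes)
        assert set(table.samples) == set(genes[0:5])  # genes 5-7 dropped
        for i, g in enumerate(table.samples):
            for j, gs in enumerate(sets):
                assert table.values[i, j] == float(g in gs.members)

    def test_unrestricted_mode_keeps_all_samples(self):
        genes = _genes(8)
        sets = _collection("COMPLEX", [genes[0:3]], prefix="C")
        table = membership_features(sets, genes, restrict_to_members=False)
        assert table.samples == genes
        assert table.values[5:].sum() == 0


class TestMerging:
    def _table(self, sample_names, width, tag):
        from tlmnet.features import FeatureDescriptor

        samples = [GeneId(SC, s) for s in sample_names]
        feats = [
            FeatureDescriptor(source=tag, set_id=f"{tag}{j}", family="membership")
            for j in range(width)
        ]
        return FeatureTable(samples, feats, np.zeros((len(samples), width)))

    def test_sample_intersection_and_width_addition(self):
        a = self._table(["x", "y", "z"], 3, "a")
        b = self._table(["y", "z", "w"], 2, "b")
        merged = merge_feature_tables(a, b)
        assert [g.systematic_name for g in merged.samples] == ["y", "z"]
        assert merged.n_features == 5

    def test_merge_is_associative_over_samples_and_features(self):
        a = self._table(["x", "y", "z", "q"], 2, "a")
        b = self._table(["y", "z", "w", "q"], 3, "b")
        c = self._table(["z", "q", "y"], 1, "c")
        left = merge_feature_tables(merge_feature_tables(a, b), c)
        right = merge_feature_tables(a, merge_feature_tables(b, c))
        assert set(left.samples) == set(right.samples)
        assert sorted(f.set_id for f in left.features) == sorted(
            f.set_id for f in right.features
        )

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError, match="share no samples"):
            merge_feature_tables(self._table(["x"], 1, "a"), self._table(["y"], 1, "b"))


class TestStandardization:
    def test_training_columns_become_standard(self):
        t = TestMerging()._table(["a", "b", "c"], 2, "f")
        t.values = np.array([[1.0, 5.0], [2.0, 5.0], [6.0, 5.0]])
        _, out = standardize(t, t)
        assert out.values[:, 0].mean() == pytest.approx(0.0)
        assert out.values[:, 0].std() == pytest.approx(1.0)
        assert np.all(out.values[:, 1] == 0.0)  # constant column

    def test_heldout_rows_use_training_statistics(self):
        train = TestMerging()._table(["a", "b", "c"], 2, "f")
        train.values = np.array([[0.0, 1.0], [2.0, 3.0], [4.0, 5.0]])
        held = TestMerging()._table(["d"], 2, "f")
        held.values = np.array([[6.0, 0.0]])
        _, out = standardize(train, held)
        # train means (2, 3), population sds (sqrt(8/3), sqrt(8/3))
        sd = np.sqrt(8.0 / 3.0)
        assert out.values[0, 0] == pytest.approx((6.0 - 2.0) / sd)
        assert out.values[0, 1] == pytest.approx((0.0 - 3.0) / sd)

    def test_feature_mismatch_raises(self):
        a = TestMerging()._table(["a"], 2, "f")
        b = TestMerging()._table(["a"], 2, "g")
        with pytest.raises(ValueError, match="mismatch"):
            standardize(a, b)


class TestNaiveBayesSelection:
    def _toy(self):
        # 6 samples, 3 positive; feature 0 present in every positive and no
        # negative, feature 1 present in nothing, feature 2 in one positive
        t = TestMerging()._table(list("abcdef"), 3, "f")
        t.values = np.array(
            [
                [1.0, 0.0, 1.0],
                [1.0, 0.0, 0.0],
                [1.0, 0.0, 0.0],
                [0.0, 0.0, 0.0],
                [0.0, 0.0, 0.0],
                [0.0, 0.0, 0.0],
            ]
        )
        y = np.array([1, 1, 1, 0, 0, 0])
        return t, y

    def test_hand_computed_ranking(self):
        # smoothed log P(x=1 | pos): f0 -> log 4/5, f2 -> log 2/5, f1 -> log 1/5
        t, y = self._toy()
        assert [f.set_id for f in select_top_features(t, y, k=1)] == ["f0"]
        assert [f.set_id for f in select_top_features(t, y, k=2)] == ["f0", "f2"]

    def test_identity_when_k_covers_all_features(self):
        t, y = self._toy()
        assert select_top_features(t, y, k=3) == t.features
        assert select_top_features(t, y, k=10) == t.features

    def test_selection_is_monotone_in_k(self):
        rng = np.random.default_rng(2)
        t = TestMerging()._table([f"s{i}" for i in range(12)], 8, "f")
        t.values = rng.normal(size=(12, 8))
        y = np.array([1, 0] * 6)
        previous: set = set()
        for k in range(1, 9):
            current = set(select_top_features(t, y, k))
            assert previous <= current
            previous = current

    def test_single_class_raises(self):
        t, _ = self._toy()
        with pytest.raises(ValueError, match="both classes"):
            select_top_features(t, np.ones(6, dtype=int), k=2)


def test_labels_to_binary_positive_class(small_world):
    labels = small_world.cerevisiae.labels
    samples = list(labels.labels)
    y = labels_to_binary(labels, samples)
    assert set(np.unique(y)) == {0, 1}
    # the positive class is 'long'
    longs = [g for g in samples if labels.labels[g] == "long"]
    assert all(y[samples.index(g)] == 1 for g in longs[:5])
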
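"""SVM training, cross-validation, scoring, partition, and the
feature-importance analyses."""

import numpy as np
import pytest

import hkera as hk
from hkera.classifier import _entropy, _fold_assignment
from hkera.rank_tensor import N_COMPONENTS


def cloud_features(n_per_class=40, separation=5.0, n_informative=16, seed=0):
    """Two Gaussian point clouds in 16-d, HK shifted up on the informative
    attributes; returns (FeatureTable, labels)."""
    rng = np.random.default_rng(seed)
    shift = np.zeros(N_COMPONENTS)
    shift[:n_informative] = separation
    hk_rows = rng.normal(0, 1, (n_per_class, N_COMPONENTS)) + shift
    ts_rows = rng.normal(0, 1, (n_per_class, N_COMPONENTS))
    ids = tuple(f"hk{i}" for i in range(n_per_class)) + tuple(
        f"ts{i}" for i in range(n_per_class)
    )
    table = hk.FeatureTable(
        gene_ids=ids, attributes=np.vstack([hk_rows, ts_rows])
    )
    labels = {g: ("HK" if g.startswith("hk") else "TS") for g in ids}
    return table, labels


class TestTrainSvm:
    def test_separable_clouds_reach_perfect_training_accuracy(self):
        table, labels = cloud_features()
        model = hk.train_svm(table, labels)
        scores = model.decision_values(table.attributes)
        pred = np.where(scores > 0, "HK", "TS")
        assert all(p == labels[g] for p, g in zip(pred, table.gene_ids))

    def test_label_flip_negates_decision_values(self):
        table, labels = cloud_features(separation=2.0)
        flipped = {g: ("TS" if v == "HK" else "HK") for g, v in labels.items()}
        s1 = hk.train_svm(table, labels).decision_values(table.attributes)
        s2 = hk.train_svm(table, flipped).decision_values(table.attributes)
        # antisymmetry holds at the optimum; allow the solver's tolerance
        np.testing.assert_allclose(s1, -s2, atol=5e-3)

    @pytest.mark.parametrize("kernel", ["linear", "rbf"])
    def test_json_round_trip_scores_identically(self, tmp_path, kernel):
        table, labels = cloud_features(separation=1.0)
        model = hk.train_svm(table, labels, kernel=kernel)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = hk.TrainedModel.from_json(path)
        np.testing.assert_allclose(
            back.decision_values(table.attributes),
            model.decision_values(table.attributes),
            rtol=1e-12,
        )

    def test_zero_variance_features_rejected(self):
        ids = ("a", "b", "c", "d")
        table = hk.FeatureTable(
            gene_ids=ids, attributes=np.ones((4, N_COMPONENTS))
        )
        labels = {"a": "HK", "b": "HK", "c": "TS", "d": "TS"}
        with pytest.raises(ValueError, match="zero variance"):
            hk.train_svm(table, labels)

    def test_single_class_rejected(self):
        table, labels = cloud_features(n_per_class=5)
        only_hk = {g: "HK" for g in table.gene_ids}
        with pytest.raises(ValueError):
            hk.train_svm(table, only_hk)


class TestCrossValidate:
    def test_stratified_fold_sizes(self):
        y = np.array([1] * 300 + [-1] * 300)
        fold = _fold_assignment(y, k=5, seed=1)
        for f in range(5):
            assert np.sum((fold == f) & (y == 1)) == 60
            assert np.sum((fold == f) & (y == -1)) == 60

    def test_remainder_spread_round_robin(self):
        y = np.array([1] * 13 + [-1] * 11)
        fold = _fold_assignment(y, k=5, seed=0)
        hk_counts = sorted(np.sum((fold == f) & (y == 1)) for f in range(5))
        ts_counts = sorted(np.sum((fold == f) & (y == -1)) for f in range(5))
        assert hk_counts == [2, 2, 3, 3, 3]
        assert ts_counts == [2, 2, 2, 2, 3]

    def test_separable_features_give_perfect_folds(self):
        table, labels = cloud_features(n_per_class=50)
        report, models = hk.cross_validate(table, labels, k=5, seed=2)
        assert len(models) == 5
        assert all(f["test_accuracy"] == 100.0 for f in report.folds)

    def test_seed_determinism(self):
        table, labels = cloud_features(separation=0.5, seed=4)
        r1, _ = hk.cross_validate(table, labels, k=5, seed=77)
        r2, _ = hk.cross_validate(table, labels, k=5, seed=77)
        assert r1 == r2

    def test_k_larger_than_class_errors(self):
        table, labels = cloud_features(n_per_class=3)
        with pytest.raises(ValueError):
            hk.cross_validate(table, labels, k=5, seed=0)

    def test_out_of_fold_scores_cover_all_genes(self):
        table, labels = cloud_features(n_per_class=25, separation=1.0)
        scores, report, models = hk.out_of_fold_scores(table, labels, k=5, seed=5)
        assert scores.gene_ids == table.gene_ids
        fold_of = np.array(report.fold_assignment)
        # spot-check: each gene's score comes from the model that held it out
        for i in [0, 7, 30, 49]:
            expected = models[fold_of[i]].decision_values(
                table.attributes[i : i + 1]
            )[0]
            assert scores.scores[i] == pytest.approx(expected)


class TestScoresAndPartition:
    def test_call_is_sign_of_score(self):
        table = hk.ScoreTable(
            gene_ids=("a", "b", "c"), scores=np.array([0.3, -0.2, 0.0])
        )
        assert table.calls == ("HK", "TS", "TS")  # call HK iff score > 0

    def test_infinite_threshold_calls_everything_ts(self):
        table, labels = cloud_features(n_per_class=10)
        model = hk.train_svm(table, labels)
        scored = hk.score_genes(model, table, threshold=np.inf)
        assert set(scored.calls) == {"TS"}

    @pytest.mark.parametrize("threshold", [-0.5, 0.0, 0.7])
    def test_calls_match_independent_sign_comparison(self, threshold):
        rng = np.random.default_rng(8)
        scores = rng.normal(0, 1, 30)
        table = hk.ScoreTable(
            gene_ids=tuple(f"g{i}" for i in range(30)),
            scores=scores,
            threshold=threshold,
        )
        for g, s, c in zip(table.gene_ids, scores, table.calls):
            assert c == ("HK" if s > threshold else "TS")

    def test_partition_is_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(0, 1, 10)
        scores[:6] = np.abs(scores[:6]) + 0.1
        scores[6:] = -np.abs(scores[6:]) - 0.1
        table = hk.ScoreTable(
            gene_ids=tuple(f"g{i}" for i in range(10)), scores=scores
        )
        hk_set, ts_set = hk.partition(table)
        assert len(hk_set) == 6 and len(ts_set) == 4
        assert hk_set.members | ts_set.members == set(table.gene_ids)
        assert not (hk_set.members & ts_set.members)

    def test_score_table_round_trip(self, tmp_path):
        table = hk.ScoreTable(
            gene_ids=("a", "b"), scores=np.array([0.25, -1.5])
        )
        p = tmp_path / "scores.tsv"
        table.write(p)
        back = hk.ScoreTable.read(p)
        assert back.gene_ids == table.gene_ids
        np.testing.assert_allclose(back.scores, table.scores)


class TestInformationGain:
    def test_perfect_separator_on_balanced_classes_is_one_bit(self):
        table, labels = cloud_features(n_per_class=20, separation=10.0,
                                       n_informative=1)
        gains = hk.information_gain(table, labels)
        assert gains[0] == pytest.approx(1.0)
        assert np.all((gains >= 0) & (gains <= 1))

    def test_constant_attribute_has_zero_gain(self):
        table, labels = cloud_features(n_per_class=10)
        attrs = table.attributes.copy()
        attrs[:, 3] = 0.5
        table2 = hk.FeatureTable(gene_ids=table.gene_ids, attributes=attrs)
        assert hk.information_gain(table2, labels)[3] == 0.0

    def test_75_percent_agreement_matches_entropy_arithmetic(self):
        # attribute agreeing with balanced labels on 75% of genes at its
        # optimal split: IG = 1 - H(0.25)
        n = 40
        ids = tuple(f"g{i}" for i in range(n))
        labels = {g: ("HK" if i < 20 else "TS") for i, g in enumerate(ids)}
        attrs = np.zeros((n, N_COMPONENTS))
        # high values: 15 HK + 5 TS; low values: 5 HK + 15 TS
        high = list(range(15)) + list(range(20, 25))
        attrs[high, 0] = 1.0
        table = hk.FeatureTable(gene_ids=ids, attributes=attrs)
        expected = 1.0 - _entropy(0.25)
        assert hk.information_gain(table, labels)[0] == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(0.18872, abs=1e-4)


class TestLeaveOneFeatureOut:
    def test_redundant_attribute_has_negligible_delta(self):
        table, labels = cloud_features(n_per_class=30, separation=1.5,
                                       n_informative=1, seed=2)
        attrs = table.attributes.copy()
        attrs[:, 1] = attrs[:, 0]  # duplicate the informative attribute
        table2 = hk.FeatureTable(gene_ids=table.gene_ids, attributes=attrs)
        deltas = hk.leave_one_feature_out(table2, labels, k=5, seed=3)
        assert deltas.shape == (16,)
        assert abs(deltas[0]) <= 5.0  # its copy still carries the signal

    def test_sole_informative_attribute_is_costly(self):
        table, labels = cloud_features(n_per_class=30, separation=4.0,
                                       n_informative=1, seed=6)
        deltas = hk.leave_one_feature_out(table, labels, k=5, seed=3)
        assert deltas[0] < -20.0  # accuracy collapses toward 50%
        assert np.all(np.abs(np.delete(deltas, 0)) <= 10.0)
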
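"""Stratified forest, out-of-bag votes and confusion summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seqaudit as sa
from seqaudit.featurize import FeatureConfig
from seqaudit.forest import ForestConfig


@pytest.fixture(scope="module")
def small_votes(easy_synthetic, schemes):
    """Votes from a 100-tree forest on a 60-sequence slice of the preset."""
    _, dataset, truth = easy_synthetic
    planted = set(truth.ids)
    by_class = {}
    for rec in dataset.records:
        if rec.id not in planted:  # keep only correctly labeled sequences
            by_class.setdefault(rec.label, []).append(rec)
    records = [r for c in dataset.classes for r in by_class[c][:9]]
    sub = sa.LabeledDataset(records=records, classes=dataset.classes)
    fm = sa.build_feature_matrix(sub, schemes["dav"], FeatureConfig(n_values=(1, 2)))
    cfg = ForestConfig(n_trees=100, seed=7)
    return sub, fm, sa.train_oob_votes(fm, sub.labels, sub.classes, cfg), cfg


class TestVotes:
    def test_deterministic_given_seed(self, small_votes):
        sub, fm, votes, cfg = small_votes
        again = sa.train_oob_votes(fm, sub.labels, sub.classes, cfg)
        np.testing.assert_array_equal(votes.values, again.values)
        np.testing.assert_array_equal(votes.oob_tree_count, again.oob_tree_count)

    def test_rows_sum_to_one_and_are_tree_fractions(self, small_votes):
        _, _, votes, _ = small_votes
        assert np.all(votes.oob_tree_count > 0)
        np.testing.assert_allclose(votes.values.sum(axis=1), 1.0, atol=1e-9)
        # every fraction is a multiple of 1/oob_tree_count
        scaled = votes.values * votes.oob_tree_count[:, None]
        np.testing.assert_allclose(scaled, np.round(scaled), atol=1e-6)

    def test_oob_accuracy_high_on_separated_classes(self, small_votes):
        sub, _, votes, _ = small_votes
        preds = sa.predicted_classes(votes)
        acc = np.mean([p == t for p, t in zip(preds, sub.labels)])
        assert acc >= 0.95

    def test_unstratified_oob_tree_count_near_expectation(self, small_votes):
        # with bootstrap size N, a sample is OOB for ~ e^-1 of the trees
        sub, fm, _, _ = small_votes
        cfg = ForestConfig(n_trees=200, seed=3, stratified=False)
        votes = sa.train_oob_votes(fm, sub.labels, sub.classes, cfg)
        mean_oob = votes.oob_tree_count.mean()
        assert 200 * 0.30 < mean_oob < 200 * 0.44

    def test_all_vote_mode_counts_every_tree(self, small_votes):
        sub, fm, _, _ = small_votes
        cfg = ForestConfig(n_trees=50, seed=3, vote_mode="all")
        votes = sa.train_oob_votes(fm, sub.labels, sub.classes, cfg)
        assert np.all(votes.oob_tree_count == 50)

    def test_single_class_rejected(self, small_votes, schemes):
        sub, fm, _, _ = small_votes
        with pytest.raises(ValueError, match="at least 2 classes"):
            sa.train_oob_votes(fm, ["x"] * len(sub.records), ["x"], ForestConfig(n_trees=2))

    def test_comparable_to_reference_forest(self, small_votes):
        """Independent cross-check: sklearn's own bagged forest reaches the
        same (near-perfect) OOB accuracy on this easily separated data."""
        from sklearn.ensemble import RandomForestClassifier

        sub, fm, votes, _ = small_votes
        rf = RandomForestClassifier(
            n_estimators=100, oob_score=True, random_state=42
        ).fit(fm.values, sub.labels)
        ours = np.mean(
            [p == t for p, t in zip(sa.predicted_classes(votes), sub.labels)]
        )
        assert abs(rf.oob_score_ - ours) < 0.1


class TestConfusion:
    def test_identity_matrix_is_perfect(self):
        s = sa.summarize_confusion(np.eye(3, dtype=int) * 5, ["a", "b", "c"])
        assert s.overall_accuracy == 1.0
        np.testing.assert_array_equal(s.class_error, 0.0)
        assert s.oob_error == 0.0

    def test_zero_row_reported_missing(self):
        counts = np.array([[3, 0], [0, 0]])
        s = sa.summarize_confusion(counts, ["a", "b"])
        assert np.isnan(s.class_error[1])
        assert s.overall_accuracy == 1.0

    @given(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=50), min_size=3, max_size=3),
            min_size=3,
            max_size=3,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_per_cell_oracle(self, rows):
        counts = np.array(rows)
        if counts.sum() == 0:
            return
        s = sa.summarize_confusion(counts, ["a", "b", "c"])
        # brute-force recomputation, one cell at a time
        total = correct = 0
        for i in range(3):
            rowsum = sum(counts[i])
            total += rowsum
            correct += counts[i][i]
            if rowsum:
                assert s.class_error[i] == pytest.approx(1 - counts[i][i] / rowsum)
        assert s.overall_accuracy == pytest.approx(correct / total)

    def test_rejects_non_square_and_negative(self):
        with pytest.raises(ValueError):
            sa.summarize_confusion(np.zeros((2, 3), dtype=int), ["a", "b"])
        with pytest.raises(ValueError):
            sa.summarize_confusion(np.array([[1, 0], [0, -1]]), ["a", "b"])


class TestConfusionFromVotes:
    def test_unanimous_votes_are_diagonal(self):
        vm = sa.VoteMatrix(
            sequence_ids=["s1", "s2"],
            classes=["a", "b"],
            values=np.array([[1.0, 0.0], [0.0, 1.0]]),
            oob_tree_count=np.array([10, 10]),
        )
        s = sa.confusion_from_votes(vm, ["a", "b"])
        assert s.overall_accuracy == 1.0

    def test_study_vote_row_predicts_pheromone(self, tables):
        """The a8dz71_danre row (true mG) argmaxes at the Ph column."""
        df = tables.shortlist_votes["aac"].set_index("id")
        row = df.loc["a8dz71_danre", list(tables.classes)].to_numpy(dtype=float)
        vm = sa.VoteMatrix(
            sequence_ids=["a8dz71_danre"],
            classes=list(tables.classes),
            values=row[None, :],
            oob_tree_count=np.array([200]),
        )
        assert sa.predicted_classes(vm) == ["Ph"]
        s = sa.confusion_from_votes(vm, ["mG"])
        assert s.counts[tables.classes.index("mG"), tables.classes.index("Ph")] == 1

    def test_tie_breaks_to_earliest_class(self):
        vm = sa.VoteMatrix(
            sequence_ids=["s"],
            classes=["A", "B"],
            values=np.array([[0.5, 0.5]]),
            oob_tree_count=np.array([10]),
        )
        assert sa.predicted_classes(vm) == ["A"]

    def test_flagged_sequences_excluded(self):
        vm = sa.VoteMatrix(
            sequence_ids=["s1", "s2"],
            classes=["a", "b"],
            values=np.array([[1.0, 0.0], [0.0, 0.0]]),
            oob_tree_count=np.array([10, 0]),
        )
        s = sa.confusion_from_votes(vm, ["a", "b"])
        assert s.counts.sum() == 1

    def test_label_length_mismatch(self):
        vm = sa.VoteMatrix(
            sequence_ids=["s1"],
            classes=["a", "b"],
            values=np.array([[1.0, 0.0]]),
            oob_tree_count=np.array([5]),
        )
        with pytest.raises(ValueError, match="labels"):
            sa.confusion_from_votes(vm, ["a", "a"])
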
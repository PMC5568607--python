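"""Consistency statistics, shortlists and cross-featurization merging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seqaudit as sa
from seqaudit.consistency import ConsistencyRecord, Shortlist


def votes_of(rows, classes, ids=None, oob=200):
    rows = np.asarray(rows, dtype=float)
    return sa.VoteMatrix(
        sequence_ids=ids or [f"s{i}" for i in range(len(rows))],
        classes=list(classes),
        values=rows,
        oob_tree_count=np.full(len(rows), oob),
    )


class TestClassVoteStats:
    def test_unanimous_votes_give_identity_means(self):
        vm = votes_of([[1, 0], [1, 0], [0, 1]], ["a", "b"])
        stats = sa.class_vote_stats(vm, ["a", "a", "b"])
        np.testing.assert_allclose(stats.mean.to_numpy(), np.eye(2))
        assert stats.sd.loc["a"].tolist() == [0.0, 0.0]

    def test_hand_computed_mean_and_sd(self):
        # two class-a rows: (0.6, 0.4) and (0.8, 0.2); sd with n-1 denominator
        vm = votes_of([[0.6, 0.4], [0.8, 0.2], [0.1, 0.9], [0.3, 0.7]], ["a", "b"])
        stats = sa.class_vote_stats(vm, ["a", "a", "b", "b"])
        np.testing.assert_allclose(stats.mean.loc["a"].to_numpy(), [0.7, 0.3])
        np.testing.assert_allclose(
            stats.sd.loc["a"].to_numpy(), [0.14142136, 0.14142136], atol=1e-7
        )

    def test_mean_rows_sum_to_one(self, easy_audit):
        _, _, report = easy_audit
        for res in report.transformations.values():
            sums = res.stats.mean.sum(axis=1)
            np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-6)

    def test_fully_flagged_class_reported_missing(self):
        vm = votes_of([[1, 0], [0, 1]], ["a", "b"])
        vm.oob_tree_count = np.array([200, 0])
        stats = sa.class_vote_stats(vm, ["a", "b"])
        assert stats.mean.loc["b"].isna().all()


class TestShortlist:
    def test_perfectly_consistent_not_shortlisted(self):
        vm = votes_of([[1.0, 0.0]], ["a", "b"])
        assert sa.build_shortlist(vm, ["a"]).entries == []

    def test_boundary_exactly_at_threshold_excluded(self):
        # 7 classes; v_true exactly 1/7 fails the *strict* inequality
        row = [1 / 7] * 7
        vm = votes_of([row], list("ABCDEFG"))
        assert sa.build_shortlist(vm, ["A"]).entries == []

    def test_below_threshold_included_with_prediction(self, tables):
        df = tables.shortlist_votes["aac"]
        classes = list(tables.classes)
        vm = votes_of(
            df[classes].to_numpy(), classes, ids=df["id"].tolist()
        )
        sl = sa.build_shortlist(vm, df["true_label"].tolist())
        entry = {e.id: e for e in sl.entries}["a8dz71_danre"]
        assert entry.predicted_class == "Ph"
        assert entry.true_class_consistency == pytest.approx(0.045)

    def test_entries_sorted_by_ascending_consistency(self):
        vm = votes_of([[0.10, 0.9], [0.02, 0.98], [0.4, 0.6]], ["a", "b"])
        sl = sa.build_shortlist(vm, ["a", "a", "a"], threshold=0.3)
        assert [e.true_class_consistency for e in sl.entries] == [0.02, 0.10]

    def test_pigeonhole_for_every_entry(self, easy_audit):
        """v_true < 1/K and rows summing to 1 force a different argmax."""
        _, _, report = easy_audit
        for res in report.transformations.values():
            assert res.shortlist.entries, "expected a non-empty shortlist"
            for e in res.shortlist.entries:
                assert e.predicted_class != e.true_class
                assert e.max_vote >= 1 / len(res.shortlist.classes)

    def test_lowering_threshold_never_grows_the_list(self):
        rng = np.random.default_rng(0)
        raw = rng.dirichlet(np.ones(4), size=40)
        vm = votes_of(raw, list("wxyz"))
        labels = [list("wxyz")[i] for i in rng.integers(0, 4, size=40)]
        prev = None
        for thr in (0.5, 0.25, 0.1, 0.02):
            ids = set(sa.build_shortlist(vm, labels, thr).ids)
            if prev is not None:
                assert ids <= prev
            prev = ids

    def test_flagged_sequences_excluded_with_warning(self):
        vm = votes_of([[0.0, 1.0], [0.0, 0.0]], ["a", "b"])
        vm.oob_tree_count = np.array([100, 0])
        sl = sa.build_shortlist(vm, ["a", "a"])
        assert sl.ids == ["s0"]


def shortlist_named(name, ids, true_class="a"):
    entries = [
        ConsistencyRecord(
            id=i, true_class=true_class, votes=(0.0, 1.0),
            true_class_consistency=0.0, predicted_class="b", max_vote=1.0,
        )
        for i in ids
    ]
    return Shortlist(transformation=name, entries=entries, threshold=0.5,
                     classes=["a", "b"])


class TestMerge:
    def test_identical_shortlists_fill_the_top_bucket(self):
        sls = [shortlist_named(n, ["x", "y"]) for n in ("t1", "t2", "t3")]
        merged = sa.merge_shortlists(sls)
        assert merged.bucket(3) == ["x", "y"]
        assert merged.bucket(1) == [] and merged.bucket(2) == []
        assert merged.all_transformations == ["x", "y"]

    def test_duplicate_transformation_name_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            sa.merge_shortlists([shortlist_named("t", ["x"]), shortlist_named("t", ["y"])])

    def test_needs_two_shortlists(self):
        with pytest.raises(ValueError, match="at least 2"):
            sa.merge_shortlists([shortlist_named("t", ["x"])])

    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_buckets_match_set_oracle(self, data):
        universe = [f"id{i}" for i in range(8)]
        memberships = [
            data.draw(st.sets(st.sampled_from(universe)), label=f"sl{t}")
            for t in range(3)
        ]
        sls = [shortlist_named(f"t{t}", sorted(m)) for t, m in enumerate(memberships)]
        merged = sa.merge_shortlists(sls)
        buckets = merged.buckets
        # oracle: exhaustive set arithmetic per id
        for sid in universe:
            k = sum(sid in m for m in memberships)
            if k:
                assert sid in buckets[k]
        # buckets partition the union
        union = set().union(*memberships)
        flat = [i for b in buckets.values() for i in b]
        assert sorted(flat) == sorted(union)
        # |top bucket| two ways: intersection of sets vs count filter
        inter = set(universe)
        for m in memberships:
            inter &= m
        assert sorted(inter) == buckets[3]

    def test_conflicting_true_classes_rejected(self):
        with pytest.raises(ValueError, match="conflicting"):
            sa.merge_shortlists(
                [shortlist_named("t1", ["x"], "a"), shortlist_named("t2", ["x"], "b")]
            )
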
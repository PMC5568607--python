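"""Vote-consistency statistics and shortlists of suspect labels.

The consistency of a sequence for a class is the fraction of counted trees
voting that class; 100% needs unanimous trees (which does not imply the
label is right — unanimous agreement on a *wrong* class is exactly the
signal of interest).  A sequence is shortlisted when the vote fraction for
its recorded (true) class falls strictly below a threshold, by default 1/K
(1/7 for the seven Class C sub-families): votes sum to 1, so by pigeonhole
some other class must then beat the recorded one and the argmax prediction
necessarily disagrees with the label.

Shortlists computed under different featurizations are merged by sequence
id and bucketed by how many featurizations flagged each id; sequences
flagged by all featurizations are the strongest relabeling candidates and
are handed to expert curation — labels are never rewritten automatically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .forest import VoteMatrix, predicted_classes


@dataclass
class ClassVoteStats:
    """Mean and n−1 standard deviation of vote fractions per true class."""

    classes: list[str]
    mean: pd.DataFrame   # rows = true class, cols = voted class
    sd: pd.DataFrame

    def to_csv(self, mean_path: str | Path, sd_path: str | Path) -> None:
        self.mean.to_csv(mean_path, float_format="%.3f")
        self.sd.to_csv(sd_path, float_format="%.3f")


@dataclass(frozen=True)
class ConsistencyRecord:
    """One sequence's vote vector viewed against its recorded class."""

    id: str
    true_class: str
    votes: tuple[float, ...]
    true_class_consistency: float
    predicted_class: str
    max_vote: float


@dataclass
class Shortlist:
    """Sequences whose true-class consistency is strictly below threshold."""

    transformation: str
    entries: list[ConsistencyRecord]
    threshold: float
    classes: list[str]

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "transformation": self.transformation,
                "id": e.id,
                "true_label": e.true_class,
                "predicted_label": e.predicted_class,
                "v_true": e.true_class_consistency,
                **dict(zip(self.classes, e.votes)),
            }
            for e in self.entries
        ]
        cols = ["transformation", "id", "true_label", "predicted_label", "v_true", *self.classes]
        return pd.DataFrame(rows, columns=cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.3f")


@dataclass
class MergedShortlist:
    """Shortlisted ids bucketed by how many featurizations flagged them."""

    transformations: list[str]
    flagged_in: dict[str, list[str]]      # id -> transformations that flagged it
    true_class: dict[str, str]

    @property
    def buckets(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {k: [] for k in range(1, len(self.transformations) + 1)}
        for sid in sorted(self.flagged_in):
            out[len(self.flagged_in[sid])].append(sid)
        return out

    def bucket(self, count: int) -> list[str]:
        return self.buckets.get(count, [])

    @property
    def all_transformations(self) -> list[str]:
        return self.bucket(len(self.transformations))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": sid,
                "true_label": self.true_class[sid],
                "n_transformations": len(tr),
                "transformations": ";".join(tr),
            }
            for sid, tr in sorted(self.flagged_in.items())
        ]
        return pd.DataFrame(
            rows, columns=["id", "true_label", "n_transformations", "transformations"]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def class_vote_stats(votes: VoteMatrix, labels: list[str]) -> ClassVoteStats:
    """Mean/SD of vote fractions grouped by true class.

    Sequences with no counted tree are excluded; a class whose sequences
    are all excluded gets a NaN row.  SD uses the n−1 denominator.
    """
    keep = votes.oob_tree_count != 0
    df = pd.DataFrame(votes.values[keep], columns=votes.classes)
    df["__true"] = np.asarray(labels)[keep]
    g = df.groupby("__true", sort=False)
    mean = g.mean().reindex(votes.classes)
    sd = g.std(ddof=1).reindex(votes.classes)
    mean.index.name = sd.index.name = "TC"
    return ClassVoteStats(classes=list(votes.classes), mean=mean, sd=sd)


def consistency_records(votes: VoteMatrix, labels: list[str]) -> list[ConsistencyRecord]:
    """Per-sequence consistency view, in dataset order (flagged excluded)."""
    preds = predicted_classes(votes)
    out = []
    for sid, lab, row, pred, n_oob in zip(
        votes.sequence_ids, labels, votes.values, preds, votes.oob_tree_count
    ):
        if n_oob == 0:
            continue
        ci = votes.classes.index(lab)
        out.append(
            ConsistencyRecord(
                id=sid,
                true_class=lab,
                votes=tuple(float(v) for v in row),
                true_class_consistency=float(row[ci]),
                predicted_class=pred,
                max_vote=float(row.max()),
            )
        )
    return out


def consistency_table(votes: VoteMatrix, labels: list[str]) -> pd.DataFrame:
    """Per-sequence consistency CSV payload (id, position, consistency)."""
    recs = consistency_records(votes, labels)
    return pd.DataFrame(
        {
            "id": [r.id for r in recs],
            "position": range(len(recs)),
            "true_label": [r.true_class for r in recs],
            "consistency": [r.true_class_consistency for r in recs],
        }
    )


def build_shortlist(
    votes: VoteMatrix,
    labels: list[str],
    threshold: float | None = None,
    transformation: str = "",
) -> Shortlist:
    """Shortlist sequences with true-class consistency strictly below threshold.

    *threshold* defaults to 1/K.  Entries are sorted by ascending
    true-class consistency (ties by id) and carry the full vote vector.
    """
    K = len(votes.classes)
    if threshold is None:
        threshold = 1.0 / K
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    entries = [
        r
        for r in consistency_records(votes, labels)
        if r.true_class_consistency < threshold
    ]
    entries.sort(key=lambda r: (r.true_class_consistency, r.id))
    return Shortlist(
        transformation=transformation or votes.vote_mode,
        entries=entries,
        threshold=threshold,
        classes=list(votes.classes),
    )


def merge_shortlists(shortlists: list[Shortlist]) -> MergedShortlist:
    """Bucket shortlisted ids by the number of featurizations flagging them."""
    if len(shortlists) < 2:
        raise ValueError("need at least 2 shortlists to merge")
    names = [s.transformation for s in shortlists]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate transformation names: {names}")
    flagged: dict[str, list[str]] = {}
    true_class: dict[str, str] = {}
    for s in shortlists:
        for e in s.entries:
            flagged.setdefault(e.id, []).append(s.transformation)
            prev = true_class.setdefault(e.id, e.true_class)
            if prev != e.true_class:
                raise ValueError(
                    f"id {e.id!r} has conflicting true classes across shortlists"
                )
    return MergedShortlist(
        transformations=names, flagged_in=flagged, true_class=true_class
    )
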
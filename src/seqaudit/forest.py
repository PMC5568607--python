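"""Stratified random forest with per-sequence out-of-bag vote fractions.

The ensemble is grown tree by tree: each tree gets its own bootstrap,
drawn *per class* with replacement (default sample size per class = the
smallest class count), which equalizes class influence on every tree —
the standard realization of a "stratified" forest for data as unbalanced
as the Class C sub-families (48 vs 392 members).  Individual trees are
CART classifiers with a random feature subset per split
(floor(sqrt(p)) by default) and unlimited depth.

For every sequence, votes are tallied only over the trees whose bootstrap
excluded it (out-of-bag, OOB); the normalized tally is the sequence's vote
fraction vector, the per-sequence consistency object used downstream.
OOB votes are preferred to in-bag votes because in-bag predictions are
memorization-biased toward perfect self-consistency; an ``all`` vote mode
is available for comparison.  All randomness flows from a single seed
(default 42), with per-tree streams derived deterministically from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger("seqaudit")

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyper-parameters; defaults follow the Class C study setup."""

    n_trees: int = 500
    seed: int = 42
    stratified: bool = True
    per_class_size: int | str = "min-class"
    max_features: int | str = "sqrt"
    vote_mode: str = "oob"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if isinstance(self.per_class_size, int) and self.per_class_size < 1:
            raise ValueError("per-class bootstrap size must be >= 1")
        if self.vote_mode not in {"oob", "all"}:
            raise ValueError("vote_mode must be 'oob' or 'all'")


@dataclass
class VoteMatrix:
    """Per-sequence vote fractions over the class set.

    ``values[s, c]`` is the fraction of counted trees voting class ``c``
    for sequence ``s``; rows sum to 1 wherever ``oob_tree_count > 0``.
    Sequences with no OOB tree are flagged and excluded downstream.
    """

    sequence_ids: list[str]
    classes: list[str]
    values: np.ndarray
    oob_tree_count: np.ndarray
    vote_mode: str = "oob"

    @property
    def flagged_ids(self) -> list[str]:
        return [s for s, n in zip(self.sequence_ids, self.oob_tree_count) if n == 0]

    def to_frame(self, labels: list[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=pd.Index(self.sequence_ids, name="id"),
            columns=self.classes,
        )
        df.insert(0, "oob_tree_count", self.oob_tree_count)
        if labels is not None:
            df.insert(0, "true_label", labels)
        return df

    def to_csv(self, path: str | Path, labels: list[str] | None = None) -> None:
        self.to_frame(labels).to_csv(path, float_format="%.6g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, classes: list[str]) -> "VoteMatrix":
        values = df[classes].to_numpy(dtype=float)
        if "oob_tree_count" in df.columns:
            oob = df["oob_tree_count"].to_numpy(dtype=int)
        else:
            oob = np.full(len(df), -1)  # unknown tree counts (external table)
        return cls(
            sequence_ids=[str(i) for i in df.index],
            classes=list(classes),
            values=values,
            oob_tree_count=oob,
        )


def train_oob_votes(
    matrix,
    labels: list[str],
    classes: list[str],
    cfg: ForestConfig = ForestConfig(),
) -> VoteMatrix:
    """Grow the stratified forest and return per-sequence vote fractions.

    *matrix* is a :class:`~seqaudit.featurize.FeatureMatrix` (or any object
    with ``values`` and ``sequence_ids``).  Fully reproducible from
    ``cfg.seed``.
    """
    X = np.asarray(matrix.values, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    y = np.asarray([classes.index(l) for l in labels], dtype=int)
    K = len(classes)
    if K < 2:
        raise ValueError("need at least 2 classes to train")
    class_indices = [np.flatnonzero(y == c) for c in range(K)]
    counts = [len(ci) for ci in class_indices]
    for c, n in zip(classes, counts):
        if n < 2:
            raise ValueError(f"class {c!r} has fewer than 2 sequences")

    if cfg.per_class_size == "min-class":
        per_class = min(counts)
    else:
        per_class = int(cfg.per_class_size)

    N = len(y)
    rng = np.random.default_rng(cfg.seed)
    tree_seeds = rng.integers(0, _SEED_MOD, size=cfg.n_trees)
    votes = np.zeros((N, K), dtype=np.int64)
    oob_count = np.zeros(N, dtype=np.int64)

    for t in range(cfg.n_trees):
        t_rng = np.random.default_rng(tree_seeds[t])
        if cfg.stratified:
            boot = np.concatenate(
                [t_rng.choice(ci, size=per_class, replace=True) for ci in class_indices]
            )
        else:
            boot = t_rng.choice(N, size=N, replace=True)
        in_bag = np.zeros(N, dtype=bool)
        in_bag[boot] = True
        tree = DecisionTreeClassifier(
            max_features=cfg.max_features,
            random_state=int(tree_seeds[t]),
        )
        tree.fit(X[boot], y[boot])
        if cfg.vote_mode == "oob":
            target = np.flatnonzero(~in_bag)
        else:
            target = np.arange(N)
        if target.size:
            # predict returns the original class codes, no remapping needed
            pred = tree.predict(X[target]).astype(int)
            votes[target, pred] += 1
            oob_count[target] += 1

    fractions = np.zeros((N, K), dtype=float)
    pos = oob_count > 0
    fractions[pos] = votes[pos] / oob_count[pos, None]
    vm = VoteMatrix(
        sequence_ids=list(matrix.sequence_ids),
        classes=list(classes),
        values=fractions,
        oob_tree_count=oob_count,
        vote_mode=cfg.vote_mode,
    )
    for sid in vm.flagged_ids:
        logger.warning("sequence %s has no out-of-bag tree; excluded downstream", sid)
    return vm


# ---------------------------------------------------------------------------
# Confusion summaries
# ---------------------------------------------------------------------------

@dataclass
class ConfusionSummary:
    """Counts plus per-class errors and overall accuracy.

    ``class_error[t] = 1 − counts[t,t]/rowsum[t]`` (one minus sensitivity);
    ``overall_accuracy = trace/total``.  Values are exact; rounding (3
    decimals for errors, 2 for accuracy) happens only in the report layer.
    """

    classes: list[str]
    counts: np.ndarray
    class_error: np.ndarray      # NaN where a row sum is zero
    overall_accuracy: float
    oob_error: float = field(init=False)

    def __post_init__(self) -> None:
        self.oob_error = 1.0 - self.overall_accuracy

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts, index=pd.Index(self.classes, name="TC"), columns=self.classes
        )
        df["Class.error"] = np.round(self.class_error, 3)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, float_format="%.3f")


def summarize_confusion(counts: np.ndarray, classes: list[str]) -> ConfusionSummary:
    """Class errors and overall accuracy from a square count matrix."""
    counts = np.asarray(counts)
    K = len(classes)
    if counts.shape != (K, K):
        raise ValueError(f"expected a {K}x{K} matrix, got {counts.shape}")
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        if not np.all(counts == counts.astype(int)) or np.any(counts < 0):
            raise ValueError("counts must be non-negative integers")
        counts = counts.astype(int)
    row = counts.sum(axis=1)
    diag = np.diag(counts).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        err = np.where(row > 0, 1.0 - diag / row, np.nan)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return ConfusionSummary(
        classes=list(classes),
        counts=counts,
        class_error=err,
        overall_accuracy=float(counts.trace() / total),
    )


def predicted_classes(votes: VoteMatrix) -> list[str]:
    """Argmax class per sequence; ties break to the earliest class."""
    idx = np.argmax(votes.values, axis=1)
    return [votes.classes[i] for i in idx]


def confusion_from_votes(votes: VoteMatrix, labels: list[str]) -> ConfusionSummary:
    """Confusion summary of argmax vote predictions against *labels*.

    Sequences with no counted tree are excluded.  Labels are positional and
    must align with ``votes.sequence_ids``.
    """
    if len(labels) != len(votes.sequence_ids):
        raise ValueError(
            f"{len(labels)} labels for {len(votes.sequence_ids)} sequences"
        )
    classes = votes.classes
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    preds = predicted_classes(votes)
    for lab, pred, n_oob in zip(labels, preds, votes.oob_tree_count):
        if n_oob == 0:
            continue
        counts[classes.index(lab), classes.index(pred)] += 1
    return summarize_confusion(counts, classes)
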
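"""Filter-style feature selection by one-vs-one t-test significance.

For each feature and each unordered pair of classes, a two-sided Welch
(unequal-variance) two-sample t-test is computed on the feature's values in
the two classes.  A feature's score is the number of class pairs for which
p < alpha; with K classes the score ranges over [0, K(K−1)/2] (21 pairs for
the seven Class C sub-families).  Welch's form is used because sub-family
sizes are highly unbalanced; no multiple-testing correction is applied.

Selection either keeps all features significant for at least ``min_pairs``
pairs, or the top ``target_size`` features ranked by (descending pair
count, ascending minimum pairwise p, feature-name order) — a fully
deterministic ordering.  The sizes 585 (aac), 386 (sez), 238 (dav) used in
the Class C study are recorded as conventional ``target_size`` defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .featurize import FeatureMatrix

#: Selected-subset sizes used in the GPCR Class C case study, per scheme.
STUDY_TARGET_SIZES: dict[str, int] = {"aac": 585, "sez-table": 386, "sez-lit": 386, "dav": 238}


@dataclass
class SelectionResult:
    """Per-feature significance counts plus the chosen subset."""

    feature_names: list[str]
    pair_counts: np.ndarray          # significant pairs per feature
    min_p: np.ndarray                # smallest pairwise p per feature (nan if none defined)
    selected: list[str]              # ordered subset of feature_names
    alpha: float
    mode: str
    value: int

    def to_frame(self) -> pd.DataFrame:
        sel = set(self.selected)
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "count": self.pair_counts,
                "min_p": self.min_p,
                "selected": [int(f in sel) for f in self.feature_names],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")


def pairwise_ttest_counts(
    matrix: FeatureMatrix,
    labels: list[str],
    classes: list[str],
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Count significant one-vs-one Welch tests per feature.

    Returns ``(counts, min_p)`` arrays over ``matrix.feature_names``.
    Features with zero variance in both groups of a pair yield an undefined
    statistic (NaN p) and contribute no significance for that pair.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    y = np.asarray(labels)
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 sequences")
    X = matrix.values
    counts = np.zeros(X.shape[1], dtype=int)
    min_p = np.full(X.shape[1], np.nan)
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            a = X[y == classes[i]]
            b = X[y == classes[j]]
            with np.errstate(divide="ignore", invalid="ignore"):
                res = stats.ttest_ind(a, b, axis=0, equal_var=False)
            p = np.asarray(res.pvalue)
            counts += (p < alpha)
            min_p = np.fmin(min_p, p)  # fmin ignores NaNs
    return counts, min_p


def select_features(
    matrix: FeatureMatrix,
    counts: np.ndarray,
    min_p: np.ndarray,
    mode: str,
    value: int,
    alpha: float = 0.05,
) -> SelectionResult:
    """Build a :class:`SelectionResult` from precomputed pair counts.

    ``mode="min_pairs"`` keeps features with count ≥ value (value 0 keeps
    everything); ``mode="target_size"`` keeps the top *value* features under
    the deterministic ranking described in the module docstring.
    """
    names = matrix.feature_names
    if mode == "min_pairs":
        if value < 0:
            raise ValueError("min_pairs threshold must be >= 0")
        selected = [f for f, c in zip(names, counts) if c >= value]
    elif mode == "target_size":
        if not 0 <= value <= len(names):
            raise ValueError(
                f"target_size must lie in [0, {len(names)}], got {value}"
            )
        # NaN min_p sorts last within a count tier
        key_p = np.where(np.isnan(min_p), np.inf, min_p)
        order = sorted(
            range(len(names)), key=lambda i: (-counts[i], key_p[i], names[i])
        )
        keep = sorted(order[:value])  # restore enumeration order
        selected = [names[i] for i in keep]
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    return SelectionResult(
        feature_names=list(names),
        pair_counts=np.asarray(counts),
        min_p=np.asarray(min_p),
        selected=selected,
        alpha=alpha,
        mode=mode,
        value=value,
    )
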
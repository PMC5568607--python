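"""Relative n-gram frequency features over a reduced alphabet.

A sequence of cleaned length L has L−n+1 overlapping windows of size n; the
feature value for an n-gram is its window count divided by the number of
windows, so each size-n block of the feature vector sums to 1 (for L ≥ n).
Feature columns are enumerated in a fixed order — ascending n, then
lexicographic in the scheme's group-symbol order — so matrices built from
the same scheme are always column-aligned.

The division by L−n+1 (window count) rather than L is configurable via
``FeatureConfig.denominator``; window count is the default, keeping each
block a probability distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .seqdata import AlphabetScheme, LabeledDataset, reduce_sequence

logger = logging.getLogger("seqaudit")


@dataclass(frozen=True)
class FeatureConfig:
    """n-gram featurization settings.

    ``n_values`` defaults to {1, 2, 3}: alphabet size grows as |Σ|^n, so
    larger n is rarely affordable (8000 columns already at n=3 over 20
    symbols).  ``denominator`` is ``"windows"`` (L−n+1) or ``"length"`` (L).
    """

    n_values: tuple[int, ...] = (1, 2, 3)
    denominator: str = "windows"

    def __post_init__(self) -> None:
        if not self.n_values:
            raise ValueError("n_values must be non-empty")
        if any(n < 1 for n in self.n_values):
            raise ValueError("n-gram sizes must be positive")
        if self.denominator not in {"windows", "length"}:
            raise ValueError("denominator must be 'windows' or 'length'")
        object.__setattr__(self, "n_values", tuple(sorted(set(self.n_values))))


@dataclass
class FeatureMatrix:
    """Per-sequence n-gram frequency vectors with named, ordered columns."""

    sequence_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    scheme_name: str
    n_values: tuple[int, ...]
    #: ids of sequences shorter than some n (their size-n block is all-zero)
    short_sequences: dict[str, list[int]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sequence_ids, name="id"),
            columns=self.feature_names,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, float_format="%.10g")

    def select(self, names: list[str]) -> "FeatureMatrix":
        """Column subset in the given order (used after feature selection)."""
        pos = {f: i for i, f in enumerate(self.feature_names)}
        idx = [pos[n] for n in names]
        return FeatureMatrix(
            sequence_ids=list(self.sequence_ids),
            feature_names=list(names),
            values=self.values[:, idx],
            scheme_name=self.scheme_name,
            n_values=self.n_values,
            short_sequences=dict(self.short_sequences),
        )


def enumerate_features(scheme: AlphabetScheme, n_values: tuple[int, ...]) -> list[str]:
    """Ordered n-gram names: ascending n, lexicographic in group order."""
    names: list[str] = []
    for n in sorted(set(n_values)):
        for combo in product(scheme.group_symbols, repeat=n):
            names.append("".join(combo))
    return names


def vectorize_sequence(
    residues: str,
    scheme: AlphabetScheme,
    cfg: FeatureConfig = FeatureConfig(),
) -> np.ndarray:
    """Feature vector of one cleaned sequence (concatenated n blocks)."""
    if not residues:
        raise ValueError("cannot featurize an empty sequence")
    tokens = reduce_sequence(residues, scheme)
    return _vectorize_tokens(tokens, scheme.size, scheme.group_symbols, cfg)


def _vectorize_tokens(
    tokens: str,
    k: int,
    symbols: tuple[str, ...],
    cfg: FeatureConfig,
) -> np.ndarray:
    sym_index = {s: i for i, s in enumerate(symbols)}
    codes = np.fromiter((sym_index[t] for t in tokens), dtype=np.int64, count=len(tokens))
    L = len(codes)
    blocks: list[np.ndarray] = []
    for n in cfg.n_values:
        if L < n:
            blocks.append(np.zeros(k**n))
            continue
        # window code = base-k integer with digits in group order; bincount
        # over codes gives the per-n-gram window counts in enumeration order
        window = np.zeros(L - n + 1, dtype=np.int64)
        for j in range(n):
            window = window * k + codes[j : L - n + 1 + j]
        counts = np.bincount(window, minlength=k**n).astype(float)
        denom = (L - n + 1) if cfg.denominator == "windows" else L
        blocks.append(counts / denom)
    return np.concatenate(blocks)


def build_feature_matrix(
    dataset: LabeledDataset,
    scheme: AlphabetScheme,
    cfg: FeatureConfig = FeatureConfig(),
) -> FeatureMatrix:
    """Featurize every record of *dataset* under *scheme*.

    Row order follows the dataset record order; column order follows
    :func:`enumerate_features`.  Sequences shorter than some n are kept
    (all-zero block) but flagged in ``short_sequences`` with a warning.
    """
    names = enumerate_features(scheme, cfg.n_values)
    rows = np.empty((len(dataset.records), len(names)))
    short: dict[str, list[int]] = {}
    for i, rec in enumerate(dataset.records):
        try:
            rows[i] = vectorize_sequence(rec.residues, scheme, cfg)
        except Exception as exc:
            raise type(exc)(f"sequence {rec.id!r}: {exc}") from exc
        too_short = [n for n in cfg.n_values if len(rec.residues) < n]
        if too_short:
            short[rec.id] = too_short
            logger.warning(
                "sequence %s shorter than n=%s: zero block(s)", rec.id, too_short
            )
    return FeatureMatrix(
        sequence_ids=dataset.ids,
        feature_names=names,
        values=rows,
        scheme_name=scheme.name,
        n_values=cfg.n_values,
        short_sequences=short,
    )
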
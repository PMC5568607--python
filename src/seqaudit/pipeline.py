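"""End-to-end label audit: featurize → select → forest → shortlists.

``run_full_audit`` executes, for each requested alphabet scheme, the whole
chain — n-gram featurization, optional t-test feature selection, stratified
forest training with out-of-bag votes, confusion summary, per-class vote
statistics, per-sequence consistency table and shortlist — then merges the
per-scheme shortlists by sequence id.  ``report_from_tables`` runs the
pure-arithmetic tail of the pipeline (no forest) on pre-computed vote and
confusion tables, e.g. the bundled case-study tables.

All reports are plain CSV plus a JSON manifest carrying everything needed
to re-run the audit bit-identically (inputs and their checksums, full
configuration, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .consistency import (
    ClassVoteStats,
    MergedShortlist,
    Shortlist,
    build_shortlist,
    class_vote_stats,
    consistency_table,
    merge_shortlists,
)
from .datasets import ReferenceTables
from .featselect import SelectionResult, pairwise_ttest_counts, select_features
from .featurize import FeatureConfig, build_feature_matrix
from .forest import (
    ConfusionSummary,
    ForestConfig,
    VoteMatrix,
    confusion_from_votes,
    summarize_confusion,
    train_oob_votes,
)
from .seqdata import LabeledDataset, load_dataset, load_scheme

logger = logging.getLogger("seqaudit")


@dataclass(frozen=True)
class RunConfig:
    """Everything a full audit run depends on."""

    fasta: str
    labels: str
    schemes: tuple[str, ...] = ("aac", "sez-table", "dav")
    n_values: tuple[int, ...] = (1, 2, 3)
    select_mode: str | None = None        # None disables feature selection
    select_value: int = 0
    alpha: float = 0.05
    n_trees: int = 500
    seed: int = 42
    threshold: float | None = None        # None -> 1/K
    vote_mode: str = "oob"
    denominator: str = "windows"


@dataclass
class TransformationResult:
    """Audit artifacts for one alphabet scheme."""

    scheme: str
    selection: SelectionResult | None
    votes: VoteMatrix
    labels: list[str]
    confusion: ConfusionSummary
    stats: ClassVoteStats
    consistency: pd.DataFrame
    shortlist: Shortlist


@dataclass
class AuditReport:
    """Full audit output: per-scheme results, merged shortlist, manifest."""

    transformations: dict[str, TransformationResult]
    merged: MergedShortlist
    manifest: dict = field(default_factory=dict)


def _file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_full_audit(cfg: RunConfig, dataset: LabeledDataset | None = None) -> AuditReport:
    """Run the audit described by *cfg*; loads the dataset unless given."""
    t0 = time.perf_counter()
    if dataset is None:
        dataset = load_dataset(cfg.fasta, cfg.labels)
    for cls, n in dataset.class_counts().items():
        if n < 2:
            raise ValueError(
                f"stage seqdata: class {cls!r} has only {n} sequence(s); "
                "at least 2 are required"
            )
    feat_cfg = FeatureConfig(n_values=cfg.n_values, denominator=cfg.denominator)
    results: dict[str, TransformationResult] = {}
    for scheme_name in cfg.schemes:
        t_stage = time.perf_counter()
        scheme = load_scheme(scheme_name)
        matrix = build_feature_matrix(dataset, scheme, feat_cfg)
        selection = None
        if cfg.select_mode is not None:
            counts, min_p = pairwise_ttest_counts(
                matrix, dataset.labels, dataset.classes, cfg.alpha
            )
            selection = select_features(
                matrix, counts, min_p, cfg.select_mode, cfg.select_value, cfg.alpha
            )
            matrix = matrix.select(selection.selected)
        forest_cfg = ForestConfig(
            n_trees=cfg.n_trees, seed=cfg.seed, vote_mode=cfg.vote_mode
        )
        votes = train_oob_votes(matrix, dataset.labels, dataset.classes, forest_cfg)
        results[scheme.name] = TransformationResult(
            scheme=scheme.name,
            selection=selection,
            votes=votes,
            labels=dataset.labels,
            confusion=confusion_from_votes(votes, dataset.labels),
            stats=class_vote_stats(votes, dataset.labels),
            consistency=consistency_table(votes, dataset.labels),
            shortlist=build_shortlist(
                votes, dataset.labels, cfg.threshold, transformation=scheme.name
            ),
        )
        logger.info(
            "[%s] featurize+train+shortlist done in %.1fs",
            scheme.name,
            time.perf_counter() - t_stage,
        )
    shortlists = [r.shortlist for r in results.values()]
    if len(shortlists) > 1:
        merged = merge_shortlists(shortlists)
    else:  # single-scheme run: one trivial bucket, nothing to intersect
        sl = shortlists[0]
        merged = MergedShortlist(
            transformations=[sl.transformation],
            flagged_in={e.id: [sl.transformation] for e in sl.entries},
            true_class={e.id: e.true_class for e in sl.entries},
        )
    manifest = {
        "config": asdict(cfg),
        "package_version": __version__,
        "classes": dataset.classes,
        "n_sequences": len(dataset.records),
        "inputs": {
            name: _file_sha256(p)
            for name, p in (("fasta", cfg.fasta), ("labels", cfg.labels))
            if p and Path(p).exists()
        },
    }
    logger.info("audit finished in %.1fs", time.perf_counter() - t0)
    return AuditReport(transformations=results, merged=merged, manifest=manifest)


def report_from_tables(
    tables: ReferenceTables, threshold: float | None = None
) -> tuple[dict[str, ConfusionSummary], dict[str, Shortlist], MergedShortlist]:
    """Pure-arithmetic audit tail on pre-computed tables (no forest).

    Recomputes confusion summaries from the count matrices and rebuilds and
    merges the shortlists from the per-sequence vote rows under the strict
    below-1/K criterion.
    """
    classes = list(tables.classes)
    summaries = {
        t: summarize_confusion(tables.confusion_counts(t), classes)
        for t in tables.confusion
    }
    shortlists = {}
    for t, df in tables.shortlist_votes.items():
        vm = VoteMatrix.from_frame(df.set_index("id"), classes)
        labels = df["true_label"].tolist()
        shortlists[t] = build_shortlist(vm, labels, threshold, transformation=t)
    merged = merge_shortlists(list(shortlists.values()))
    return summaries, shortlists, merged


def write_reports(report: AuditReport, outdir: str | Path) -> list[Path]:
    """Write all audit CSVs plus the manifest; returns the paths written.

    Report-layer precision follows the study tables: accuracies to 2
    decimals, class errors to 3, vote fractions to 3.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(path: Path, writer) -> None:
        writer(path)
        written.append(path)

    accuracy_rows = []
    for name, res in report.transformations.items():
        _w(outdir / f"confusion_{name}.csv", res.confusion.to_csv)
        _w(outdir / f"votes_{name}.csv", lambda p, r=res: r.votes.to_csv(p, r.labels))
        _w(outdir / f"vote_stats_mean_{name}.csv",
           lambda p, r=res: r.stats.mean.to_csv(p, float_format="%.3f"))
        _w(outdir / f"vote_stats_sd_{name}.csv",
           lambda p, r=res: r.stats.sd.to_csv(p, float_format="%.3f"))
        _w(outdir / f"consistency_{name}.csv",
           lambda p, r=res: r.consistency.to_csv(p, index=False, float_format="%.3f"))
        _w(outdir / f"shortlist_{name}.csv", res.shortlist.to_csv)
        if res.selection is not None:
            _w(outdir / f"selection_{name}.csv", res.selection.to_csv)
        accuracy_rows.append(
            {"transformation": name,
             "overall_accuracy": round(res.confusion.overall_accuracy, 2),
             "oob_error": round(res.confusion.oob_error, 2)}
        )
    _w(outdir / "overall_accuracy.csv",
       lambda p: pd.DataFrame(accuracy_rows).to_csv(p, index=False, float_format="%.2f"))
    _w(outdir / "merged_shortlist.csv", report.merged.to_csv)
    _w(outdir / "manifest.json",
       lambda p: p.write_text(json.dumps(report.manifest, indent=2, sort_keys=True) + "\n"))
    return written
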
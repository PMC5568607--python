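"""Synthetic labeled sequence sets and bundled reference tables.

The synthetic generator emulates multi-class protein datasets whose classes
differ in residue *composition*: each class gets a profile over the 20
amino acids (drawn from a symmetric Dirichlet, or supplied explicitly) and
sequences are sampled i.i.d. residue-by-residue from their generating
class's profile.  A mislabel plan plants sequences generated from one
class but labeled as another — the ground truth the audit pipeline is
asked to recover.  Smaller Dirichlet concentration means sparser, more
distinct profiles; larger concentration makes classes overlap and recovery
harder.  No positional or motif structure is simulated: the featurization
under audit is purely compositional, so composition is the honest
difficulty axis.

The module also bundles, as checksummed CSV data, the printed tables of
the GPCR Class C sub-family case study this tool operationalizes: three
confusion matrices (one per featurization: amino-acid composition,
Sezerman/11, Davies/9) and the per-sequence vote rows of the three
consistently-misclassified shortlists.  These drive the report-only code
path and the arithmetic regression tests.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .seqdata import CANONICAL_RESIDUES, LabeledDataset, SequenceRecord

#: Class C sub-family names, study order.
STUDY_CLASSES: tuple[str, ...] = ("mG", "CS", "GB", "VN", "Ph", "Od", "Ta")

#: Sequences per sub-family in the studied database extract (total 1510).
STUDY_CLASS_SIZES: dict[str, int] = {
    "mG": 351, "CS": 48, "GB": 208, "VN": 344, "Ph": 392, "Od": 102, "Ta": 65,
}

#: Transformation keys of the bundled reference tables.
STUDY_TRANSFORMATIONS: tuple[str, ...] = ("aac", "sez", "dav")


# ---------------------------------------------------------------------------
# Synthetic generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticConfig:
    """Recipe for a synthetic labeled dataset with planted mislabels.

    ``mislabels`` lists ``(generating_class, assigned_label, count)``
    triples: *count* of the sequences labeled *assigned_label* are in fact
    drawn from *generating_class*'s profile.  ``alpha0`` is the symmetric
    Dirichlet concentration for class profiles (ignored when ``profiles``
    is given); 0.05 yields strongly separated compositions, 1.0 nearly
    indistinguishable ones.
    """

    class_names: tuple[str, ...]
    n_per_class: tuple[int, ...]
    length_range: tuple[int, int] = (250, 600)
    alpha0: float = 0.05
    profiles: tuple[tuple[float, ...], ...] | None = None
    mislabels: tuple[tuple[str, str, int], ...] = ()
    seed: int = 42

    def __post_init__(self) -> None:
        if len(self.class_names) != len(self.n_per_class):
            raise ValueError("one size per class required")
        if any(n < 0 for n in self.n_per_class):
            raise ValueError("class sizes must be non-negative")
        lo, hi = self.length_range
        if lo < 3 or hi < lo:
            raise ValueError("length range must satisfy 3 <= Lmin <= Lmax")
        sizes = dict(zip(self.class_names, self.n_per_class))
        planted_per_label: dict[str, int] = {}
        for gen, assigned, count in self.mislabels:
            if gen not in sizes or assigned not in sizes:
                raise ValueError(f"unknown class in mislabel plan: {gen!r}/{assigned!r}")
            if gen == assigned:
                raise ValueError("a planted mislabel must cross classes")
            if count < 0:
                raise ValueError("mislabel counts must be non-negative")
            planted_per_label[assigned] = planted_per_label.get(assigned, 0) + count
        for lab, planted in planted_per_label.items():
            if planted > sizes[lab]:
                raise ValueError(
                    f"mislabel plan wants {planted} planted sequences labeled "
                    f"{lab!r} but the class only has {sizes[lab]}"
                )
        if self.profiles is not None:
            if len(self.profiles) != len(self.class_names):
                raise ValueError("one profile per class required")
            for p in self.profiles:
                if len(p) != 20 or abs(sum(p) - 1.0) > 1e-9:
                    raise ValueError("profiles must be length-20 and sum to 1")


@dataclass
class PlantedTruth:
    """Ground truth of the mislabel plan: planted id -> classes."""

    generating_class: dict[str, str] = field(default_factory=dict)
    assigned_label: dict[str, str] = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return sorted(self.generating_class)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "generating_class": [self.generating_class[i] for i in self.ids],
                "assigned_label": [self.assigned_label[i] for i in self.ids],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def class_profiles(cfg: SyntheticConfig) -> np.ndarray:
    """Composition profiles (K x 20), explicit or Dirichlet-drawn."""
    if cfg.profiles is not None:
        return np.asarray(cfg.profiles, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    return rng.dirichlet(np.full(20, cfg.alpha0), size=len(cfg.class_names))


def generate_synthetic(cfg: SyntheticConfig) -> tuple[LabeledDataset, PlantedTruth]:
    """Draw a labeled dataset (and its planted-mislabel truth) from *cfg*.

    Deterministic given ``cfg.seed``.  Sequence ids encode the assigned
    label and an index (``mG_0003``); which of them are planted is recorded
    only in the returned :class:`PlantedTruth`.
    """
    profiles = class_profiles(cfg)
    rng = np.random.default_rng(cfg.seed + 1)  # separate stream from profiles
    residues = np.array(list(CANONICAL_RESIDUES))
    lo, hi = cfg.length_range

    # which slots of each labeled class are planted, and from which class
    plant_source: dict[str, list[str]] = {c: [] for c in cfg.class_names}
    for gen, assigned, count in cfg.mislabels:
        plant_source[assigned].extend([gen] * count)

    records: list[SequenceRecord] = []
    truth = PlantedTruth()
    for ci, (cname, n) in enumerate(zip(cfg.class_names, cfg.n_per_class)):
        sources = plant_source[cname]
        for k in range(n):
            sid = f"{cname}_{k:04d}"
            if k < len(sources):
                gen_class = sources[k]
                truth.generating_class[sid] = gen_class
                truth.assigned_label[sid] = cname
            else:
                gen_class = cname
            p = profiles[cfg.class_names.index(gen_class)]
            L = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(residues, size=L, p=p))
            records.append(SequenceRecord(id=sid, label=cname, residues=seq))
    dataset = LabeledDataset(records=records, classes=list(cfg.class_names))
    return dataset, truth


def easy_preset(seed: int = 42) -> SyntheticConfig:
    """Strongly separated 7-class preset at quarter scale.

    Class sizes mirror the study extract's imbalance at 1/4 scale
    (88/12/52/86/98/26/16, total 378); Dirichlet concentration 0.05 makes
    compositions well separated; 10 mislabels are planted across classes.
    """
    sizes = tuple(round(STUDY_CLASS_SIZES[c] / 4) for c in STUDY_CLASSES)
    plan = (
        ("Ph", "mG", 2),
        ("mG", "Ph", 2),
        ("mG", "GB", 1),
        ("Od", "Ph", 1),
        ("VN", "Ph", 1),
        ("mG", "VN", 1),
        ("GB", "mG", 1),
        ("Ta", "mG", 1),
    )
    return SyntheticConfig(
        class_names=STUDY_CLASSES,
        n_per_class=sizes,
        length_range=(250, 600),
        alpha0=0.05,
        mislabels=plan,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Bundled reference tables
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTables:
    """Printed case-study tables, machine-readable.

    ``confusion[t]`` is the 7x7 count matrix (DataFrame, true class rows)
    with the printed per-class error in column ``printed_class_error``;
    ``shortlist_votes[t]`` holds the printed per-sequence vote rows of the
    consistently-misclassified shortlists (mG/GB/Ph lists) for
    transformation *t* in {aac, sez, dav}; ``printed_accuracy[t]`` the
    printed overall accuracy.
    """

    confusion: dict[str, pd.DataFrame]
    shortlist_votes: dict[str, pd.DataFrame]
    printed_accuracy: dict[str, float]
    classes: tuple[str, ...] = STUDY_CLASSES

    def confusion_counts(self, transformation: str) -> np.ndarray:
        return self.confusion[transformation][list(self.classes)].to_numpy(dtype=int)


def _read_bundled(name: str) -> pd.DataFrame:
    root = resources.files("seqaudit").joinpath("data")
    payload = root.joinpath(name).read_bytes()
    sums = {}
    for line in root.joinpath("SHA256SUMS").read_text().splitlines():
        digest, fname = line.split()
        sums[fname] = digest
    actual = hashlib.sha256(payload).hexdigest()
    if sums.get(name) != actual:
        raise RuntimeError(f"bundled table {name} fails its checksum")
    from io import BytesIO

    return pd.read_csv(BytesIO(payload))


def reference_tables() -> ReferenceTables:
    """Load (and checksum-verify) the bundled case-study tables."""
    confusion = {
        t: _read_bundled(f"confusion_{t}.csv").set_index("TC")
        for t in STUDY_TRANSFORMATIONS
    }
    votes = _read_bundled("shortlist_votes.csv")
    shortlists = {
        t: votes[votes["transformation"] == t].drop(columns="transformation").reset_index(drop=True)
        for t in STUDY_TRANSFORMATIONS
    }
    acc_df = _read_bundled("overall_accuracy.csv")
    accuracy = dict(zip(acc_df["transformation"], acc_df["printed_accuracy"]))
    return ReferenceTables(
        confusion=confusion, shortlist_votes=shortlists, printed_accuracy=accuracy
    )
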
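"""Sequence datasets and reduced amino-acid alphabets.

A labeled dataset pairs a FASTA file of protein sequences with a two-column
TSV mapping sequence ids to class labels (e.g. GPCR Class C sub-families).
Labels always come from the TSV, never from FASTA headers, so the provenance
of the "true class" under audit is unambiguous.

An :class:`AlphabetScheme` is a partition of the 20 canonical amino acids
into groups of physico-chemically similar residues.  Schemes are data, not
code: they ship as YAML files (``aac`` identity/20, ``sez-table`` and
``sez-lit`` Sezerman/11, ``dav`` Davies/9) and users may supply their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO

logger = logging.getLogger("seqaudit")

#: The 20 canonical one-letter amino-acid codes, alphabetical.
CANONICAL_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

#: Symbols removed during cleaning: ambiguity codes, rare residues, gaps.
NON_CANONICAL: frozenset[str] = frozenset("XBZJUO*-.")


class DatasetError(ValueError):
    """Raised for malformed sequence datasets or label files."""


class AlphabetError(ValueError):
    """Raised for alphabet schemes that do not partition the 20 residues."""


# ---------------------------------------------------------------------------
# Alphabet schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlphabetScheme:
    """A named partition of the canonical amino acids into groups.

    Parameters
    ----------
    name
        Short identifier, e.g. ``"dav"``.
    groups
        Ordered tuple of groups; each group is a string of one-letter codes.
    group_symbols
        One token per group, used as the reduced-alphabet letter.  Defaults
        to the first residue of each group.
    """

    name: str
    groups: tuple[str, ...]
    group_symbols: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.group_symbols:
            object.__setattr__(
                self, "group_symbols", tuple(g[0] for g in self.groups)
            )

    @property
    def size(self) -> int:
        """Number of groups (the reduced alphabet size)."""
        return len(self.groups)

    @property
    def residue_to_symbol(self) -> dict[str, str]:
        """Total map residue -> group symbol (valid schemes only)."""
        return {
            res: sym
            for group, sym in zip(self.groups, self.group_symbols)
            for res in group
        }


def validate_alphabet(scheme: AlphabetScheme) -> AlphabetScheme:
    """Check that *scheme* partitions the 20 canonical residues.

    Returns the scheme unchanged if every residue belongs to exactly one
    group and group symbols are unique; raises :class:`AlphabetError`
    naming the offending residues otherwise.
    """
    seen: dict[str, int] = {}
    duplicated = []
    for gi, group in enumerate(scheme.groups):
        for res in group:
            if res not in CANONICAL_RESIDUES:
                raise AlphabetError(
                    f"scheme {scheme.name!r}: {res!r} is not a canonical "
                    "amino-acid code"
                )
            if res in seen:
                duplicated.append(res)
            seen[res] = gi
    unassigned = [r for r in CANONICAL_RESIDUES if r not in seen]
    problems = []
    if duplicated:
        problems.append(
            "assigned to multiple groups: " + ", ".join(sorted(set(duplicated)))
        )
    if unassigned:
        problems.append(" ".join(f"{r} unassigned" for r in unassigned))
    if len(set(scheme.group_symbols)) != len(scheme.group_symbols):
        problems.append("group symbols are not unique")
    if len(scheme.group_symbols) != len(scheme.groups):
        problems.append("one symbol required per group")
    if problems:
        raise AlphabetError(f"scheme {scheme.name!r}: " + "; ".join(problems))
    return scheme


def load_scheme(source: str | Path) -> AlphabetScheme:
    """Load and validate an alphabet scheme.

    *source* is either the name of a bundled scheme (``aac``, ``sez-table``,
    ``sez-lit``, ``dav``) or a path to a YAML file with fields ``name`` and
    ``groups`` (list of strings of one-letter codes) and optionally
    ``group_symbols``.
    """
    path = Path(source)
    if path.suffix in {".yaml", ".yml", ".json"} and path.exists():
        text = path.read_text()
    else:
        ref = resources.files("seqaudit").joinpath(f"schemes/{source}.yaml")
        if not ref.is_file():
            raise AlphabetError(
                f"unknown scheme {source!r}: not a bundled name and not a file"
            )
        text = ref.read_text()
    raw = yaml.safe_load(text)
    scheme = AlphabetScheme(
        name=str(raw["name"]),
        groups=tuple(str(g).upper() for g in raw["groups"]),
        group_symbols=tuple(raw.get("group_symbols", ())),
    )
    return validate_alphabet(scheme)


def bundled_scheme_names() -> tuple[str, ...]:
    """Names of the alphabet schemes shipped with the package."""
    root = resources.files("seqaudit").joinpath("schemes")
    return tuple(sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml")))


def reduce_sequence(residues: str, scheme: AlphabetScheme) -> str:
    """Map a cleaned residue string to its reduced-alphabet token string.

    Length-preserving and position-wise: token *i* is the group symbol of
    residue *i*.  Raises :class:`AlphabetError` on residues outside the
    scheme (cannot occur after cleaning; guards misuse).
    """
    table = scheme.residue_to_symbol
    try:
        return "".join(table[r] for r in residues)
    except KeyError as exc:
        raise AlphabetError(
            f"residue {exc.args[0]!r} not covered by scheme {scheme.name!r}"
        ) from None


# ---------------------------------------------------------------------------
# Labeled datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """One labeled protein sequence (cleaned, upper-case residues)."""

    id: str
    label: str
    residues: str


@dataclass
class LabeledDataset:
    """An ordered collection of labeled sequences with a fixed class order.

    The class order is set once at load time and reused everywhere
    downstream (vote columns, confusion axes, argmax tie-breaking).
    """

    records: list[SequenceRecord]
    classes: list[str]
    removed_residue_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate sequence ids: {', '.join(dupes)}")
        if len(self.classes) < 2:
            raise DatasetError("a labeled dataset needs at least 2 classes")
        bad = sorted({r.label for r in self.records} - set(self.classes))
        if bad:
            raise DatasetError(f"labels outside the class list: {', '.join(bad)}")

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.classes}
        for r in self.records:
            counts[r.label] += 1
        return counts


def clean_residues(raw: str) -> tuple[str, int]:
    """Upper-case *raw* and strip non-canonical symbols.

    Returns the cleaned string and the number of symbols removed.
    """
    up = raw.upper()
    cleaned = "".join(c for c in up if c in CANONICAL_RESIDUES)
    return cleaned, len(up) - len(cleaned)


def load_dataset(
    fasta_path: str | Path,
    labels_path: str | Path,
    class_order: Sequence[str] | None = None,
) -> LabeledDataset:
    """Read a FASTA file and its label TSV into a :class:`LabeledDataset`.

    The label file is a two-column TSV with header ``id<TAB>label``; every
    FASTA id must appear in it.  Residues are upper-cased and non-canonical
    symbols (X, B, Z, J, U, O, gaps) removed, with per-record removal counts
    logged.  Class order is first-appearance order in the label file unless
    *class_order* overrides it.
    """
    labels_path = Path(labels_path)
    label_map: dict[str, str] = {}
    order: list[str] = []
    with open(labels_path, encoding="utf-8") as fh:
        header = fh.readline()
        if header.rstrip("\n").split("\t")[:2] != ["id", "label"]:
            raise DatasetError(
                f"{labels_path}: expected TSV header 'id<TAB>label', "
                f"got {header.rstrip()!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise DatasetError(f"{labels_path}:{lineno}: malformed row {line!r}")
            sid, lab = parts
            if sid in label_map:
                raise DatasetError(f"{labels_path}: duplicate id {sid!r}")
            label_map[sid] = lab
            if lab not in order:
                order.append(lab)

    classes = list(class_order) if class_order is not None else order
    records: list[SequenceRecord] = []
    removed: dict[str, int] = {}
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        sid = rec.id
        if sid in seen:
            raise DatasetError(f"duplicate FASTA id {sid!r}")
        seen.add(sid)
        if sid not in label_map:
            raise DatasetError(f"FASTA id {sid!r} missing from label file")
        residues, n_removed = clean_residues(str(rec.seq))
        if n_removed:
            removed[sid] = n_removed
            logger.warning(
                "sequence %s: removed %d non-canonical residue(s)", sid, n_removed
            )
        if not residues:
            raise DatasetError(f"sequence {sid!r} empty after cleaning")
        records.append(SequenceRecord(id=sid, label=label_map[sid], residues=residues))
    return LabeledDataset(records=records, classes=classes, removed_residue_counts=removed)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (deterministic byte layout)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def write_labels(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write the id→label TSV for *records*."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tlabel\n")
        for rec in records:
            fh.write(f"{rec.id}\t{rec.label}\n")
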
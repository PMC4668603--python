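"""Protein sequence and label I/O.

Reads and writes FASTA, tab-delimited label files, and tab-delimited
feature matrices, enforcing the 20-letter residue contract that every
downstream encoder relies on.  FASTA parsing goes through Biopython.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .alphabets import STANDARD_AA
from .errors import (
    ConsistencyError,
    DuplicateIdError,
    EmptyInputError,
    FastaFormatError,
    LabelError,
    SequenceDomainError,
)

logger = logging.getLogger(__name__)

#: Residue policies for non-standard letters (B, J, O, U, X, Z, ``*``, gaps).
POLICIES = ("strict", "skip-record", "strip-residue")

#: Binary label set: 1 = nuclear receptor, 0 = non-NR.
BINARY_LABELS = ("0", "1")
#: Eight-subfamily label set.
SUBFAMILY_LABELS = tuple(f"NR{i}" for i in range(1, 9))

_STANDARD_SET = frozenset(STANDARD_AA)


@dataclass(frozen=True)
class ProteinRecord:
    """An identifier plus a validated residue string."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        bad = set(self.residues) - _STANDARD_SET
        if bad:
            raise SequenceDomainError(
                f"record {self.id!r}: non-standard residues {sorted(bad)}"
            )
        if not self.residues:
            raise SequenceDomainError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class LabeledCollection:
    """Parallel lists of records and class labels."""

    records: tuple[ProteinRecord, ...]
    labels: tuple[str, ...]
    label_set: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise ConsistencyError(
                f"{len(self.records)} records but {len(self.labels)} labels"
            )
        declared = set(self.label_set)
        for rec, lab in zip(self.records, self.labels):
            if lab not in declared:
                raise LabelError(f"record {rec.id!r}: label {lab!r} not in label set")

    def __len__(self) -> int:
        return len(self.records)

    def sequences(self) -> list[str]:
        return [r.residues for r in self.records]


def _apply_policy(rec_id: str, residues: str, policy: str) -> str | None:
    """Validate/clean one residue string; None means drop the record."""
    residues = residues.upper()
    nonstandard = [r for r in residues if r not in _STANDARD_SET]
    if not nonstandard:
        return residues
    if policy == "strict":
        raise SequenceDomainError(
            f"record {rec_id!r}: non-standard residues {sorted(set(nonstandard))}"
        )
    if policy == "skip-record":
        warnings.warn(
            f"record {rec_id!r} dropped: non-standard residues "
            f"{sorted(set(nonstandard))}",
            stacklevel=3,
        )
        return None
    if policy == "strip-residue":
        warnings.warn(
            f"record {rec_id!r}: stripped {len(nonstandard)} non-standard "
            f"residue(s) {sorted(set(nonstandard))}",
            stacklevel=3,
        )
        return "".join(r for r in residues if r in _STANDARD_SET)
    raise ValueError(f"unknown residue policy {policy!r}; choose from {POLICIES}")


def read_fasta(path, policy: str = "strip-residue") -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Parameters
    ----------
    path:
        FASTA file path.
    policy:
        How to treat non-standard letters: ``strict`` raises,
        ``skip-record`` drops the whole record with a warning,
        ``strip-residue`` (default) removes the offending letters with a
        warning.

    Returns records in file order; lowercase residues are uppercased; the
    record id is the first whitespace-delimited header token.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown residue policy {policy!r}; choose from {POLICIES}")
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise FastaFormatError(f"{path}: sequence data before any FASTA header")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        rec_id = seq_rec.id
        if rec_id in seen:
            raise DuplicateIdError(f"{path}: duplicate record id {rec_id!r}")
        seen.add(rec_id)
        cleaned = _apply_policy(rec_id, str(seq_rec.seq), policy)
        if cleaned is None or not cleaned:
            if cleaned == "":
                warnings.warn(f"record {rec_id!r} dropped: no residues left")
            continue
        records.append(ProteinRecord(id=rec_id, residues=cleaned))
    if not seen:
        raise EmptyInputError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    """Write records to FASTA, preserving id and order."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_labels(path, label_set: Sequence[str]) -> dict[str, str]:
    """Read a two-column tab-delimited (id, label) file.

    Every label must belong to ``label_set``; repeated ids and unknown
    labels raise with the offending line number.
    """
    declared = set(label_set)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LabelError(f"{path}:{lineno}: expected two tab-separated columns")
            rec_id, label = parts[0].strip(), parts[1].strip()
            if label not in declared:
                raise LabelError(
                    f"{path}:{lineno}: label {label!r} not in declared set "
                    f"{sorted(declared)}"
                )
            if rec_id in mapping:
                raise DuplicateIdError(f"{path}:{lineno}: repeated id {rec_id!r}")
            mapping[rec_id] = label
    if not mapping:
        raise EmptyInputError(f"{path}: no labels found")
    return mapping


def labels_from_headers(
    records: Iterable[ProteinRecord],
    label_set: Sequence[str],
    delimiter: str = "|",
) -> dict[str, str]:
    """Parse labels encoded in record ids as ``<name><delimiter><label>``.

    Alternative to the canonical separate label file.
    """
    declared = set(label_set)
    mapping: dict[str, str] = {}
    for rec in records:
        if delimiter not in rec.id:
            raise LabelError(f"record {rec.id!r}: no {delimiter!r} delimiter in header")
        label = rec.id.rsplit(delimiter, 1)[1]
        if label not in declared:
            raise LabelError(f"record {rec.id!r}: label {label!r} not in declared set")
        mapping[rec.id] = label
    return mapping


def write_labels(mapping: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for rec_id, label in mapping.items():
            fh.write(f"{rec_id}\t{label}\n")


def write_feature_matrix(records, vectors, path) -> None:
    """Write a tab-delimited feature matrix: id column, then one column per
    feature with stable headers (for CTF the triad class-label string,
    e.g. ``C-RK-AGV``)."""
    from .encode import FeatureVector, feature_names

    records = list(records)
    vectors = list(vectors)
    if len(records) != len(vectors):
        raise ConsistencyError(
            f"{len(records)} records but {len(vectors)} feature vectors"
        )
    if not vectors:
        raise EmptyInputError("no feature vectors to write")
    feature_sets = {v.feature_set for v in vectors}
    if len(feature_sets) != 1:
        raise ConsistencyError(f"mixed feature sets: {sorted(feature_sets)}")
    (fset,) = feature_sets
    names = feature_names(fset)
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(names) + "\n")
        for rec, vec in zip(records, vectors):
            if isinstance(vec, FeatureVector):
                values = vec.values
            else:  # pragma: no cover - defensive
                values = vec
            fh.write(rec.id + "\t" + "\t".join(repr(float(v)) for v in values) + "\n")


def read_feature_matrix(path):
    """Read a matrix written by :func:`write_feature_matrix`.

    Returns ``(ids, feature_names, values)`` with ``values`` a 2-D float
    array; ``repr`` round-tripping preserves full precision.
    """
    import numpy as np

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return ids, header[1:], np.asarray(rows, dtype=float)
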
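"""Labelled feature tables and their ARFF/CSV serialization.

A :class:`FeatureTable` is the samples x features matrix the classifiers
consume: ordered unique feature names, a float matrix, an optional 0/1
label per row (1 = positive = cancerlectin), and the provenance of its
columns (which descriptor families, in which order).

The ARFF dialect is intentionally narrow — numeric attributes plus one
final nominal ``class {0,1}`` attribute, which is exactly what the pipeline
emits; sparse, string, and date attributes are rejected on read. Floats are
serialized with shortest round-trip text, so write-then-read is the
identity on names, values, and labels.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .descriptors import DEFAULT_PARAMS, DescriptorParams, extract, min_length
from .seqio import POSITIVE, ProteinRecord

logger = logging.getLogger(__name__)


class ArffParseError(ValueError):
    """Malformed or out-of-dialect ARFF input; carries a line number."""


class AlignmentError(ValueError):
    """Tables with incompatible rows/labels cannot be concatenated."""


@dataclass
class FeatureTable:
    feature_names: list[str]
    X: np.ndarray
    labels: Optional[np.ndarray] = None  # int (0/1) per row, or None
    provenance: list[tuple[str, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"{len(self.feature_names)} feature names but {self.X.shape[1]} columns"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.X.shape[0],):
                raise ValueError("labels must supply one value per row")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be 0 (negative) or 1 (positive)")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


def build_table(
    records: Sequence[ProteinRecord],
    methods: Sequence[str | tuple[str, DescriptorParams]],
    params: DescriptorParams = DEFAULT_PARAMS,
) -> FeatureTable:
    """Extract the listed descriptor families for every record.

    One row per record (input order preserved), columns grouped by method in
    the listed order. A record that fails any family's length precondition
    raises naming the record and family — filtering belongs to
    ``seqio.validate_records``, not here.
    """
    if not methods:
        raise ValueError("empty method list")
    if not records:
        raise ValueError("no records to featurize")
    normalized: list[tuple[str, DescriptorParams]] = [
        (m, params) if isinstance(m, str) else m for m in methods
    ]
    for method, p in normalized:
        need = min_length(method, p)
        for rec in records:
            if rec.length < need:
                raise ValueError(
                    f"record {rec.id!r} (L={rec.length}) is too short for {method!r} "
                    f"(needs >= {need}); validate with min_length first"
                )
    names: list[str] = []
    provenance: list[tuple[str, dict]] = []
    columns: list[np.ndarray] = []
    for method, p in normalized:
        vecs = [extract(rec, method, p) for rec in records]
        names.extend(vecs[0].names)
        provenance.append((method, vecs[0].params))
        columns.append(np.vstack([v.values for v in vecs]))
    labels = None
    if all(rec.label is not None for rec in records):
        labels = np.array([1 if rec.label == POSITIVE else 0 for rec in records])
    return FeatureTable(names, np.hstack(columns), labels, provenance)


def concat_tables(tables: Sequence[FeatureTable]) -> FeatureTable:
    """Column-wise concatenation of tables over the same rows.

    Row counts and labels must agree; duplicate feature names are
    disambiguated with a numeric suffix.
    """
    if not tables:
        raise ValueError("no tables to concatenate")
    if len(tables) == 1:
        return tables[0]
    first = tables[0]
    for t in tables[1:]:
        if t.n != first.n:
            raise AlignmentError(f"row count mismatch: {first.n} vs {t.n}")
        same_labels = (t.labels is None) == (first.labels is None) and (
            t.labels is None or np.array_equal(t.labels, first.labels)
        )
        if not same_labels:
            raise AlignmentError("label mismatch between tables")
    names: list[str] = []
    seen: dict[str, int] = {}
    for t in tables:
        for nm in t.feature_names:
            if nm in seen:
                seen[nm] += 1
                nm = f"{nm}__{seen[nm]}"
            else:
                seen[nm] = 0
            names.append(nm)
    X = np.hstack([t.X for t in tables])
    prov = [p for t in tables for p in t.provenance]
    return FeatureTable(names, X, first.labels, prov)


# ---------------------------------------------------------------------------
# ARFF

def _fmt(x: float) -> str:
    return repr(float(x))


def write_arff(table: FeatureTable, relation: str, path: str | Path) -> None:
    """Write the table as ARFF: numeric attributes, final ``class {0,1}``.

    Unlabelled tables write ``?`` in the class column (the ARFF
    missing-value convention).
    """
    if table.n == 0 or table.d == 0:
        raise ValueError("refusing to write an empty table")
    with open(path, "w") as fh:
        fh.write(f"@relation {relation}\n\n")
        for name in table.feature_names:
            fh.write(f"@attribute '{name}' numeric\n")
        fh.write("@attribute class {0,1}\n\n@data\n")
        for i in range(table.n):
            row = ",".join(_fmt(v) for v in table.X[i])
            cls = "?" if table.labels is None else str(int(table.labels[i]))
            fh.write(f"{row},{cls}\n")


def read_arff(path: str | Path) -> FeatureTable:
    """Read an ARFF file in the pipeline's numeric + final-class dialect."""
    names: list[str] = []
    rows: list[list[float]] = []
    labels: list[int] = []
    any_label = False
    saw_class = False
    in_data = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if not in_data:
                if low.startswith("@relation"):
                    continue
                if low.startswith("@attribute"):
                    if saw_class:
                        raise ArffParseError(
                            f"line {lineno}: attribute after the class attribute"
                        )
                    rest = line[len("@attribute"):].strip()
                    if rest.endswith("numeric") or rest.endswith("real"):
                        name = rest.rsplit(None, 1)[0].strip().strip("'\"")
                        names.append(name)
                    elif "{" in rest:
                        name = rest.split("{", 1)[0].strip().strip("'\"")
                        domain = rest.split("{", 1)[1].rstrip("}").replace(" ", "")
                        if name != "class" or domain != "0,1":
                            raise ArffParseError(
                                f"line {lineno}: unsupported nominal attribute {name!r}"
                            )
                        saw_class = True
                    else:
                        raise ArffParseError(
                            f"line {lineno}: unsupported attribute declaration {line!r}"
                        )
                    continue
                if low.startswith("@data"):
                    if not saw_class:
                        raise ArffParseError(f"line {lineno}: no class attribute before @data")
                    in_data = True
                    continue
                raise ArffParseError(f"line {lineno}: unexpected header line {line!r}")
            fields = line.split(",")
            if len(fields) != len(names) + 1:
                raise ArffParseError(
                    f"line {lineno}: expected {len(names) + 1} values, got {len(fields)}"
                )
            try:
                rows.append([float(v) for v in fields[:-1]])
            except ValueError as exc:
                raise ArffParseError(f"line {lineno}: {exc}") from None
            cls = fields[-1].strip()
            if cls == "?":
                labels.append(-1)
            else:
                if cls not in ("0", "1"):
                    raise ArffParseError(f"line {lineno}: class value {cls!r} not in {{0,1,?}}")
                any_label = True
                labels.append(int(cls))
    if not in_data:
        raise ArffParseError("no @data section found")
    if not rows:
        raise ArffParseError("no data rows found")
    lab_arr: Optional[np.ndarray] = None
    if any_label:
        if -1 in labels:
            raise ArffParseError("mixed labelled and unlabelled rows")
        lab_arr = np.array(labels)
    return FeatureTable(names, np.array(rows), lab_arr)


# ---------------------------------------------------------------------------
# CSV

def write_csv(table: FeatureTable, path: str | Path) -> None:
    """Write header = feature names + ``class``; unlabelled rows leave it blank."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(table.feature_names + ["class"])
        for i in range(table.n):
            cls = "" if table.labels is None else str(int(table.labels[i]))
            writer.writerow([_fmt(v) for v in table.X[i]] + [cls])


def read_csv(path: str | Path) -> FeatureTable:
    """Read a CSV written by :func:`write_csv`; ragged rows are errors."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ArffParseError("empty CSV file") from None
        if not header or header[-1] != "class":
            raise ArffParseError("CSV header must end with a 'class' column")
        names = header[:-1]
        rows: list[list[float]] = []
        labels: list[int] = []
        any_label = False
        for lineno, fields in enumerate(reader, start=2):
            if not fields:
                continue
            if len(fields) != len(header):
                raise ArffParseError(
                    f"line {lineno}: expected {len(header)} values, got {len(fields)}"
                )
            try:
                rows.append([float(v) for v in fields[:-1]])
            except ValueError as exc:
                raise ArffParseError(f"line {lineno}: {exc}") from None
            cls = fields[-1].strip()
            if cls in ("", "?"):
                labels.append(-1)
            elif cls in ("0", "1"):
                any_label = True
                labels.append(int(cls))
            else:
                raise ArffParseError(f"line {lineno}: class value {cls!r} not in {{0,1}}")
    if not rows:
        raise ArffParseError("CSV file has no data rows")
    lab_arr: Optional[np.ndarray] = None
    if any_label:
        if -1 in labels:
            raise ArffParseError("mixed labelled and unlabelled rows")
        lab_arr = np.array(labels)
    return FeatureTable(names, np.array(rows), lab_arr)
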
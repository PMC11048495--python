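"""Reading KEEL ``.dat`` and delimited files; writing JSON experiment reports.

The KEEL imbalanced-classification dialect is a small ARFF-like format::

    @relation ecoli4
    @attribute a real [0.0, 1.0]
    @attribute class {positive, negative}
    @inputs a
    @outputs class
    @data
    0.5, positive

Supported attribute forms: ``real``/``integer`` with optional range bounds
(parsed but not enforced — repository files occasionally violate their own
declared ranges) and nominal ``{v1, v2}`` sets. The output attribute comes
from ``@outputs`` when present, else the last declared attribute. Label
strings are stripped and matched case-insensitively to positive/negative.
Nominal non-label attributes are rejected: the distance-based methods here
need numeric features, and silently encoding categories would change results.
"""
from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import NEGATIVE, POSITIVE, LabeledDataset, summarize  # noqa: F401
from .exceptions import ConfigError, FormatError, LabelError

_ATTR_RE = re.compile(r"@attribute\s+(\S+)\s+(.*)", re.IGNORECASE)


@dataclass
class _Attribute:
    name: str
    kind: str              # "real", "integer" or "nominal"
    values: tuple | None   # nominal value set, if any


def _parse_attribute(line: str, lineno: int) -> _Attribute:
    m = _ATTR_RE.match(line)
    if not m:
        raise FormatError(f"line {lineno}: malformed @attribute: {line!r}")
    name, rest = m.group(1), m.group(2).strip()
    if rest.startswith("{"):
        if not rest.endswith("}"):
            raise FormatError(f"line {lineno}: unterminated nominal set")
        values = tuple(v.strip() for v in rest[1:-1].split(","))
        return _Attribute(name, "nominal", values)
    kind = rest.split("[")[0].strip().lower()
    if kind not in ("real", "integer"):
        raise FormatError(f"line {lineno}: unsupported attribute type {rest!r}")
    return _Attribute(name, kind, None)


def _normalize_label(raw: str, lineno: int) -> str:
    value = raw.strip().lower()
    if value == POSITIVE:
        return POSITIVE
    if value == NEGATIVE:
        return NEGATIVE
    raise LabelError(f"line {lineno}: unknown label value {raw.strip()!r}")


def read_keel_dat(path) -> LabeledDataset:
    """Parse a KEEL ``.dat`` file into a :class:`LabeledDataset`.

    Raises
    ------
    FormatError
        Missing ``@data`` marker, malformed header, row arity mismatch or a
        non-numeric feature cell (errors name the offending line; rows are
        never silently dropped or imputed).
    LabelError
        A label other than positive/negative.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()

    attributes: list[_Attribute] = []
    outputs: str | None = None
    relation = ""
    data_start = None
    for i, line in enumerate(lines):
        stripped = line.strip()
        low = stripped.lower()
        if not stripped or stripped.startswith("%"):
            continue
        if low.startswith("@relation"):
            relation = stripped.split(None, 1)[1].strip() if " " in stripped else ""
        elif low.startswith("@attribute"):
            attributes.append(_parse_attribute(stripped, i + 1))
        elif low.startswith("@inputs"):
            pass  # informative only; attribute order is authoritative
        elif low.startswith("@outputs"):
            outputs = stripped.split(None, 1)[1].strip()
        elif low.startswith("@data"):
            data_start = i + 1
            break
        else:
            raise FormatError(f"line {i + 1}: unexpected header line {stripped!r}")
    if data_start is None:
        raise FormatError(f"{path}: no @data marker found")
    if not attributes:
        raise FormatError(f"{path}: no @attribute declarations before @data")

    if outputs is not None:
        names = [a.name for a in attributes]
        if outputs not in names:
            raise FormatError(f"@outputs names unknown attribute {outputs!r}")
        label_idx = names.index(outputs)
    else:
        label_idx = len(attributes) - 1
    feature_attrs = [a for i, a in enumerate(attributes) if i != label_idx]
    nominal = [a.name for a in feature_attrs if a.kind == "nominal"]
    if nominal:
        raise FormatError(
            f"nominal non-label attributes not supported: {nominal}"
        )

    rows, labels = [], []
    for offset, line in enumerate(lines[data_start:]):
        lineno = data_start + offset + 1
        stripped = line.strip()
        if not stripped or stripped.startswith("%"):
            continue
        cells = [c.strip() for c in stripped.split(",")]
        if len(cells) != len(attributes):
            raise FormatError(
                f"line {lineno}: expected {len(attributes)} fields, got {len(cells)}"
            )
        labels.append(_normalize_label(cells[label_idx], lineno))
        feature_cells = [c for i, c in enumerate(cells) if i != label_idx]
        try:
            rows.append([float(c) for c in feature_cells])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric feature cell ({exc})")
    if not rows:
        raise FormatError(f"{path}: no data rows after @data")

    return LabeledDataset(
        features=np.asarray(rows, dtype=float),
        labels=np.asarray(labels, dtype=object),
        feature_names=[a.name for a in feature_attrs],
        name=relation or str(path),
    )


def write_keel_dat(dataset: LabeledDataset, path) -> None:
    """Write a dataset in the KEEL dialect (inverse of :func:`read_keel_dat`)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"@relation {dataset.name or 'dataset'}\n")
        for name in dataset.feature_names:
            fh.write(f"@attribute {name} real\n")
        fh.write("@attribute class {positive, negative}\n")
        fh.write("@inputs " + ", ".join(dataset.feature_names) + "\n")
        fh.write("@outputs class\n@data\n")
        for row, label in zip(dataset.features, dataset.labels):
            fh.write(", ".join(repr(float(v)) for v in row) + f", {label}\n")


def read_delimited(path, label_column: str, positive_label: str,
                   delimiter: str = ",", name: str | None = None) -> LabeledDataset:
    """Read a delimited text file with a header row.

    Rows whose label cell equals ``positive_label`` (after stripping) become
    positive, all others negative; if ``positive_label`` never occurs a
    warning is issued and the dataset has zero positives. All non-label
    columns must parse as numbers.
    """
    try:
        frame = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse delimited file ({exc})")
    if label_column not in frame.columns:
        raise ConfigError(
            f"label column {label_column!r} not in header {list(frame.columns)}"
        )
    raw_labels = frame[label_column].astype(str).str.strip()
    labels = np.where(raw_labels == str(positive_label), POSITIVE, NEGATIVE)
    if not (labels == POSITIVE).any():
        warnings.warn(
            f"positive label {positive_label!r} absent from {path}; "
            "dataset has zero positive rows"
        )
    feature_frame = frame.drop(columns=[label_column])
    numeric = feature_frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & feature_frame.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric cell at data row {r + 1}, column {feature_frame.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        raise FormatError(f"{path}: missing feature values are not imputed")
    return LabeledDataset(
        features=numeric.to_numpy(dtype=float),
        labels=labels.astype(object),
        feature_names=list(feature_frame.columns),
        name=name or str(path),
    )


def _sanitize(obj):
    """Recursively convert numpy scalars and NaN to JSON-safe values."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        obj = float(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, np.ndarray):
        return _sanitize(obj.tolist())
    return obj


def write_report(records, path) -> None:
    """Serialize evaluation records to JSON.

    ``records`` is a sequence of dicts (or objects with ``to_dict``). NaN and
    infinite metric values are written as JSON null, never as "NaN" strings,
    so the file round-trips losslessly through :func:`read_report`.
    """
    payload = []
    for rec in records:
        payload.append(_sanitize(rec.to_dict() if hasattr(rec, "to_dict") else dict(rec)))
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"records": payload}, fh, indent=2, allow_nan=False)


def read_report(path) -> list[dict]:
    """Read back a report written by :func:`write_report`."""
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, dict) or "records" not in data:
        raise FormatError(f"{path}: not a report file")
    return data["records"]
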
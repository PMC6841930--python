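"""Readers and writers for the interchange formats the pipeline touches.

Two formats are supported: morphologika landmark text files (the dialect with
``[individuals]``, ``[landmarks]``, ``[dimensions]``, optional ``[names]`` and
``[rawpoints]`` sections) and comma-delimited measurement tables with a header
row.  Both round-trip exactly (to 1e-9) and never reorder individuals.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    MEASUREMENT_COLUMNS,
    LandmarkConfiguration,
    LandmarkDataset,
    MeasurementTable,
    ValidationError,
)

_SECTIONS = {"individuals", "landmarks", "dimensions", "names", "labels", "rawpoints"}


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _is_section(line: str) -> str | None:
    s = line.strip().lower()
    if s.startswith("[") and s.endswith("]"):
        return s[1:-1]
    return None


def read_morphologika(path: str | os.PathLike) -> LandmarkDataset:
    """Parse a morphologika landmark file into a :class:`LandmarkDataset`.

    Section keywords are case-insensitive; coordinates are whitespace-separated.
    Raw points must supply ``individuals x landmarks`` rows in individual order.
    Comment lines starting with ``'`` inside ``[rawpoints]`` are ignored.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    sections: dict[str, list[tuple[int, str]]] = {}
    current: str | None = None
    for lineno, raw in enumerate(lines, start=1):
        name = _is_section(raw)
        if name is not None:
            if name not in _SECTIONS:
                raise ParseError(f"{path}:{lineno}: unknown section [{name}]")
            current = name
            sections[current] = []
            continue
        if raw.strip() == "":
            continue
        if current is None:
            raise ParseError(f"{path}:{lineno}: content before any section header")
        sections[current].append((lineno, raw))

    def scalar(section: str) -> int:
        if section not in sections or not sections[section]:
            raise ParseError(f"{path}: missing [{section}] section")
        lineno, text = sections[section][0]
        try:
            return int(text.split()[0])
        except ValueError as exc:
            raise ParseError(
                f"{path}:{lineno}: [{section}] must be an integer, got {text!r}"
            ) from exc

    n = scalar("individuals")
    k = scalar("landmarks")
    d = scalar("dimensions")
    if d not in (2, 3):
        raise ParseError(f"{path}: dimensions must be 2 or 3, got {d}")
    if n < 1 or k < 1:
        raise ParseError(f"{path}: individuals and landmarks must be positive")

    names: list[str]
    if "names" in sections:
        names = [text.strip() for _, text in sections["names"]]
        if len(names) != n:
            raise ParseError(
                f"{path}: [names] lists {len(names)} entries for {n} individuals"
            )
    else:
        names = [f"specimen_{i + 1}" for i in range(n)]

    rows: list[tuple[int, list[float]]] = []
    comment_ids: list[str] = []
    for lineno, text in sections.get("rawpoints", []):
        if text.lstrip().startswith("'"):
            # per-individual comment label: records the specimen id
            comment_ids.append(text.lstrip()[1:].strip())
            continue
        parts = text.split()
        try:
            rows.append((lineno, [float(p) for p in parts]))
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric coordinate in {text!r}")

    if len(rows) != n * k:
        # locate the first individual whose block is short, for the message
        raise ParseError(
            f"{path}: [rawpoints] has {len(rows)} coordinate rows, expected "
            f"{n * k} ({n} individuals x {k} landmarks); first incomplete "
            f"individual: {names[min(len(rows) // k, n - 1)]!r}"
        )
    for lineno, values in rows:
        if len(values) != d:
            raise ParseError(
                f"{path}:{lineno}: expected {d} coordinates per row, got {len(values)}"
            )

    coords = np.array([v for _, v in rows]).reshape(n, k, d)
    specimen_ids = comment_ids if len(comment_ids) == n else names
    configs = [
        LandmarkConfiguration(
            coords[i],
            mark_type="score" if d == 2 else "pit",
            class_label=None,
            specimen_id=specimen_ids[i],
        )
        for i in range(n)
    ]
    return LandmarkDataset(configs, labels=list(names))


def write_morphologika(dataset: LandmarkDataset, path: str | os.PathLike) -> None:
    """Write a dataset as morphologika text readable by :func:`read_morphologika`.

    Coordinates carry 12 significant digits so the round trip is exact to 1e-9.
    """
    if len(dataset) == 0:
        raise ValidationError("refusing to write an empty dataset")
    k, d = dataset.dims
    out = [
        "[individuals]",
        str(len(dataset)),
        "[landmarks]",
        str(k),
        "[dimensions]",
        str(d),
        "[names]",
    ]
    out.extend(dataset.labels)
    out.append("[rawpoints]")
    for config in dataset:
        out.append(f"' {config.specimen_id}")
        for point in config.coords:
            out.append(" ".join(f"{x:.12g}" for x in point))
    Path(path).write_text("\n".join(out) + "\n")


def read_measurement_csv(path: str | os.PathLike) -> MeasurementTable:
    """Read a comma-delimited measurement table.

    Expects a ``label`` column (case-insensitive) plus the measurement columns;
    a 7-column table must include ``OA``.  Validation failures report the
    offending rows.
    """
    frame = pd.read_csv(path)
    label_col = next((c for c in frame.columns if c.lower() == "label"), None)
    if label_col is None:
        raise ParseError(f"{path}: no 'label' column in header {list(frame.columns)}")
    labels = frame[label_col].astype(str).tolist()
    meas = frame.drop(columns=[label_col])
    if meas.shape[1] == 7 and "OA" not in meas.columns:
        raise ParseError(f"{path}: 7 measurement columns but none named 'OA'")
    try:
        values = meas.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric measurement value ({exc})") from exc
    try:
        return MeasurementTable(values, list(meas.columns), labels)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_measurement_csv(table: MeasurementTable, path: str | os.PathLike) -> None:
    """Write a measurement table as CSV (paired with :func:`read_measurement_csv`)."""
    table.to_frame().to_csv(path, index=False, float_format="%.12g")


def dataset_from_arrays(
    coords: np.ndarray,
    labels: Sequence[str],
    mark_type: str,
    specimen_ids: Sequence[str] | None = None,
) -> LandmarkDataset:
    """Assemble a validated dataset from an (n, k, d) array and labels."""
    coords = np.asarray(coords, dtype=float)
    if specimen_ids is None:
        specimen_ids = [f"{lab}_{i + 1:02d}" for i, lab in enumerate(labels)]
    configs = [
        LandmarkConfiguration(
            coords[i], mark_type=mark_type, class_label=labels[i],
            specimen_id=specimen_ids[i],
        )
        for i in range(coords.shape[0])
    ]
    return LandmarkDataset(configs, labels=list(labels))
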
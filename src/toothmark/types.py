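"""Core data containers for landmark-based tooth-mark analysis.

A *landmark configuration* is an ordered set of homologous points digitized
on one tooth mark: 7 points in 2D for the cross-section of a score (an
elongated groove) or 17 points in 3D for a whole pit (a roughly circular
depression).  Datasets bundle same-shaped configurations with class labels
(the carnivore that produced the mark), and measurement tables hold the
classical groove metrics derived from score cross-sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: landmark counts and dimensionalities of the two study protocols
SCORE_SHAPE = (7, 2)
PIT_SHAPE = (17, 3)

#: canonical column order of the seven groove measurements
MEASUREMENT_COLUMNS = ("WIS", "WIM", "WIB", "D", "OA", "LWA", "RWA")


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


@dataclass
class LandmarkConfiguration:
    """One mark's ordered landmark coordinates (k x d) plus metadata.

    Parameters
    ----------
    coords
        Real matrix of shape (k, d); millimetres by convention.
    mark_type
        ``"score"`` or ``"pit"``.
    class_label
        Optional producer class (``"wolf"``, ``"dog"``, ``"fox"``).
    specimen_id
        Identifier of the digitized specimen.
    strict
        When True, enforce the canonical protocol shapes (7x2 scores, 17x3 pits);
        generic (k, d) are allowed otherwise.
    """

    coords: np.ndarray
    mark_type: str = "score"
    class_label: str | None = None
    specimen_id: str = ""
    strict: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValidationError("coords must be a k x d matrix")
        if self.mark_type not in ("score", "pit"):
            raise ValidationError(f"unknown mark_type {self.mark_type!r}")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"non-finite coordinates in {self.specimen_id!r}")
        if self.strict:
            expected = SCORE_SHAPE if self.mark_type == "score" else PIT_SHAPE
            if self.coords.shape != expected:
                raise ValidationError(
                    f"{self.mark_type} configuration must be {expected}, "
                    f"got {self.coords.shape}"
                )
        # coincident landmarks break Procrustes scaling and the TPS system
        k = self.coords.shape[0]
        for i in range(k):
            for j in range(i + 1, k):
                if np.array_equal(self.coords[i], self.coords[j]):
                    raise ValidationError(
                        f"landmarks {i + 1} and {j + 1} coincide in "
                        f"{self.specimen_id!r}"
                    )

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    def copy(self) -> "LandmarkConfiguration":
        return LandmarkConfiguration(
            self.coords.copy(), self.mark_type, self.class_label, self.specimen_id
        )


@dataclass
class LandmarkDataset:
    """Ordered collection of same-shaped configurations with class labels."""

    configurations: list[LandmarkConfiguration]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = [c.class_label or c.specimen_id for c in self.configurations]
        if len(self.labels) != len(self.configurations):
            raise ValidationError("labels length must match configuration count")
        dims = {(c.k, c.d) for c in self.configurations}
        if len(dims) > 1:
            raise ValidationError(f"mixed configuration shapes: {sorted(dims)}")

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self) -> Iterator[LandmarkConfiguration]:
        return iter(self.configurations)

    def __getitem__(self, i: int) -> LandmarkConfiguration:
        return self.configurations[i]

    @property
    def dims(self) -> tuple[int, int]:
        if not self.configurations:
            raise ValidationError("empty dataset has no dims")
        c = self.configurations[0]
        return (c.k, c.d)

    @property
    def mark_type(self) -> str:
        return self.configurations[0].mark_type

    def coords_array(self) -> np.ndarray:
        """Stacked coordinates, shape (n, k, d)."""
        return np.stack([c.coords for c in self.configurations])

    def subset(self, indices: Sequence[int]) -> "LandmarkDataset":
        return LandmarkDataset(
            [self.configurations[i].copy() for i in indices],
            [self.labels[i] for i in indices],
        )


def class_labels_from_names(names: Sequence[str]) -> list[str]:
    """Derive class labels from specimen names by their leading alphabetic token.

    ``wolf_03`` -> ``wolf``; isolated here because deposited-file naming
    conventions vary and this rule is the single point of change.
    """
    out = []
    for name in names:
        token = ""
        for ch in name:
            if ch.isalpha():
                token += ch
            else:
                break
        out.append(token.lower() if token else name)
    return out


class MeasurementTable:
    """n x 7 table of groove cross-section metrics (or n x 6 without OA).

    Columns follow :data:`MEASUREMENT_COLUMNS`; ``OA`` (opening angle, degrees)
    may be dropped via :meth:`drop_oa`, mirroring the protocol's with/without-OA
    analyses.  Widths and the depth must be strictly positive and OA must lie
    in (0, 180) degrees.
    """

    def __init__(
        self,
        values: np.ndarray,
        column_names: Sequence[str],
        labels: Sequence[str],
    ) -> None:
        self.values = np.asarray(values, dtype=float).reshape(
            len(labels), len(column_names)
        )
        self.column_names = tuple(column_names)
        self.labels = list(labels)
        self._validate()

    def _validate(self) -> None:
        n_oa = sum(1 for c in self.column_names if c == "OA")
        if self.values.shape[1] != len(self.column_names):
            raise ValidationError("column_names length does not match values width")
        if self.values.shape[1] == 7 and n_oa != 1:
            raise ValidationError("a 7-column table must contain exactly one OA column")
        if n_oa > 1:
            raise ValidationError("duplicate OA column")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite measurement values")
        bad_rows: list[int] = []
        for j, name in enumerate(self.column_names):
            col = self.values[:, j]
            if name in ("WIS", "WIM", "WIB", "D"):
                bad_rows.extend(np.nonzero(col <= 0)[0].tolist())
            elif name == "OA":
                bad_rows.extend(np.nonzero((col <= 0) | (col >= 180))[0].tolist())
        if bad_rows:
            rows = sorted(set(bad_rows))
            raise ValidationError(
                f"invalid measurement values in rows {rows} "
                "(widths/depths must be > 0, OA in (0, 180) degrees)"
            )

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def has_oa(self) -> bool:
        return "OA" in self.column_names

    def drop_oa(self) -> "MeasurementTable":
        """Return the n x 6 view excluding the opening angle."""
        if not self.has_oa:
            raise ValidationError("table has no OA column to drop")
        keep = [j for j, c in enumerate(self.column_names) if c != "OA"]
        return MeasurementTable(
            self.values[:, keep],
            [self.column_names[j] for j in keep],
            self.labels,
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(self.column_names))
        frame.insert(0, "label", self.labels)
        return frame

    def equals(self, other: "MeasurementTable", tol: float = 1e-9) -> bool:
        return (
            self.column_names == other.column_names
            and self.labels == other.labels
            and self.values.shape == other.values.shape
            and bool(np.allclose(self.values, other.values, atol=tol))
        )
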
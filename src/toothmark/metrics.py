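"""The seven classical groove measurements from 7-landmark score cross-sections.

Landmark-role convention (enforced, 2D, left-right ordered by x):

* LM1, LM7 — groove edges on the bone surface,
* LM4 — deepest point,
* LM2, LM6 — wall points at half maximal depth,
* LM3, LM5 — wall points at three-quarter maximal depth.

Measurements: surface width WIS = |LM1-LM7|; widths at half and
three-quarter depth WIM = |LM2-LM6|, WIB = |LM3-LM5|; maximal depth D =
perpendicular distance from LM4 to the surface chord LM1-LM7; opening angle
OA = angle at LM4 subtended by LM1 and LM7; left/right wall angles LWA/RWA =
angles the walls LM1-LM4 and LM7-LM4 make with the surface chord.  Lengths in
the input units (mm by convention), angles in degrees.  All seven are rigid-
motion invariant; lengths scale and angles are fixed under uniform scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (
    MEASUREMENT_COLUMNS,
    LandmarkConfiguration,
    LandmarkDataset,
    MeasurementTable,
    ValidationError,
)


@dataclass(frozen=True)
class MeasurementRecord:
    WIS: float
    WIM: float
    WIB: float
    D: float
    OA: float
    LWA: float
    RWA: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in MEASUREMENT_COLUMNS])


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def compute_measurements(config: LandmarkConfiguration) -> MeasurementRecord:
    """Compute the seven groove metrics from a 7x2 score cross-section."""
    if config.mark_type != "score":
        raise ValidationError("measurements are defined for score cross-sections only")
    if config.coords.shape != (7, 2):
        raise ValidationError(
            f"expected a 7x2 configuration, got {config.coords.shape}"
        )
    lm = config.coords
    lm1, lm2, lm3, lm4, lm5, lm6, lm7 = lm

    wis = float(np.linalg.norm(lm1 - lm7))
    wim = float(np.linalg.norm(lm2 - lm6))
    wib = float(np.linalg.norm(lm3 - lm5))

    chord = lm7 - lm1
    # perpendicular distance from the deepest point to the surface chord
    to_deepest = lm4 - lm1
    cross = chord[0] * to_deepest[1] - chord[1] * to_deepest[0]
    depth = float(abs(cross) / np.linalg.norm(chord))
    if depth <= 1e-12 * max(wis, 1.0):
        raise ValidationError(
            f"deepest landmark lies on the surface chord in {config.specimen_id!r}"
        )
    oa = _angle_between(lm1 - lm4, lm7 - lm4)
    lwa = _angle_between(lm4 - lm1, lm7 - lm1)
    rwa = _angle_between(lm4 - lm7, lm1 - lm7)
    return MeasurementRecord(wis, wim, wib, depth, oa, lwa, rwa)


def measurement_table(
    dataset: LandmarkDataset, include_oa: bool = True
) -> MeasurementTable:
    """Measurement table for a score dataset, in dataset row order.

    ``include_oa=False`` returns the n x 6 view without the opening angle,
    mirroring the protocol's with/without-OA analyses.
    """
    if len(dataset) == 0:
        columns = [c for c in MEASUREMENT_COLUMNS if include_oa or c != "OA"]
        return MeasurementTable(np.empty((0, len(columns))), columns, [])
    if dataset.mark_type != "score":
        raise ValidationError(
            "pits have no cross-section measurement model; pass a score dataset"
        )
    values = np.stack([compute_measurements(c).as_array() for c in dataset])
    table = MeasurementTable(values, MEASUREMENT_COLUMNS, list(dataset.labels))
    return table if include_oa else table.drop_oa()
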
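"""Procrustes superimposition, shape/form space and thin-plate-spline warps.

Generalized Procrustes Analysis (GPA) removes translation, scale and rotation
from a landmark sample: configurations are centred, scaled to unit centroid
size, iteratively rotated onto a consensus, and finally projected orthogonally
onto the Euclidean space tangent to the shape manifold at the consensus so
that ordinary linear statistics (PCA, MANOVA) apply.  Reflections are never
allowed: tooth marks are chiral.

Form space keeps a size term by rescaling the aligned coordinates of each
specimen by the natural log of its centroid size; coordinates are converted
to micrometres first (``unit_scale=1000`` from millimetres) so the log is
always positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .types import LandmarkConfiguration, LandmarkDataset, ValidationError


class ConvergenceError(RuntimeError):
    """GPA failed to converge within the iteration budget."""


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Centroid size: root summed squared landmark distances from the centroid.

    The standard geometric-morphometric size measure; homogeneous of degree 1
    under uniform scaling.
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else config
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs == 0.0:
        raise ValidationError("all landmarks coincident: centroid size is zero")
    return cs


def _center_unit(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    return centered / centroid_size(centered)


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing ||target - source @ R||_F."""
    u, _, vt = np.linalg.svd(source.T @ target)
    d = source.shape[1]
    sign = np.sign(np.linalg.det(u @ vt))
    correction = np.ones(d)
    correction[-1] = sign
    return (u * correction) @ vt


def procrustes_superimpose_pair(
    source: LandmarkConfiguration, target: LandmarkConfiguration
) -> tuple[LandmarkConfiguration, float]:
    """Fit ``source`` onto ``target`` by translation, scale and rotation.

    Returns the transformed source expressed in the target's frame and the
    Procrustes distance: the root summed squared residuals after both
    configurations are centred and scaled to unit centroid size.
    """
    if source.coords.shape != target.coords.shape:
        raise ValidationError(
            f"shape mismatch: {source.coords.shape} vs {target.coords.shape}"
        )
    x = _center_unit(source.coords)
    y = _center_unit(target.coords)
    if np.linalg.matrix_rank(x) == 0 or np.linalg.matrix_rank(y) == 0:
        raise ValidationError("degenerate configuration (rank 0)")
    rotation = optimal_rotation(x, y)
    aligned_unit = x @ rotation
    distance = float(np.sqrt(np.sum((aligned_unit - y) ** 2)))
    mapped = aligned_unit * centroid_size(target.coords) + target.coords.mean(axis=0)
    aligned = LandmarkConfiguration(
        mapped, source.mark_type, source.class_label, source.specimen_id
    )
    return aligned, distance


@dataclass
class ProcrustesResult:
    """GPA output.

    ``aligned`` holds the tangent-projected shape coordinates (n, k, d):
    centred, with centroid size 1 up to the (second-order) effect of the
    tangent projection, and mean equal to ``consensus``.  ``centroid_sizes``
    are the original sizes in input units.  ``trace`` records the summed
    squared residuals about the consensus per iteration (non-increasing).
    """

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    iterations: int
    final_change: float
    trace: list[float]
    labels: list[str]
    mark_type: str

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def dims(self) -> tuple[int, int]:
        return self.aligned.shape[1], self.aligned.shape[2]

    def flattened(self) -> np.ndarray:
        """Aligned coordinates as an (n, k*d) matrix for linear statistics."""
        return self.aligned.reshape(self.n, -1)

    def consensus_configuration(self) -> LandmarkConfiguration:
        return LandmarkConfiguration(
            self.consensus.copy(), self.mark_type, None, "consensus"
        )

    def to_dataset(self) -> LandmarkDataset:
        from .io import dataset_from_arrays

        return dataset_from_arrays(self.aligned, self.labels, self.mark_type)


def gpa(
    dataset: LandmarkDataset, tol: float = 1e-10, max_iter: int = 100
) -> ProcrustesResult:
    """Generalized Procrustes Analysis with tangent projection.

    Iterates rotate-to-consensus / recompute-consensus until the consensus
    moves less than ``tol`` (Frobenius norm), then projects every aligned
    configuration orthogonally onto the tangent space at the consensus.
    """
    if len(dataset) < 1:
        raise ValidationError("gpa requires at least one configuration")
    raw = dataset.coords_array()
    n = raw.shape[0]
    sizes = np.array([centroid_size(c) for c in raw])
    aligned = np.stack([_center_unit(c) for c in raw])

    consensus = aligned[0].copy()
    trace: list[float] = []
    change = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = aligned[i] @ optimal_rotation(aligned[i], consensus)
        mean = aligned.mean(axis=0)
        new_consensus = _center_unit(mean)
        change = float(np.linalg.norm(new_consensus - consensus))
        consensus = new_consensus
        trace.append(float(np.sum((aligned - consensus) ** 2)))
        if change < tol:
            break
    else:
        raise ConvergenceError(
            f"GPA did not converge in {max_iter} iterations "
            f"(final consensus change {change:.3e})"
        )
    # final rotation pass so every configuration is optimally aligned to the
    # converged consensus (makes the result an exact fixed point)
    for i in range(n):
        aligned[i] = aligned[i] @ optimal_rotation(aligned[i], consensus)

    # canonical orientation: rotate the whole sample so the consensus sits on
    # its principal axes, with a deterministic sign convention.  This pins the
    # global rotation GPA leaves free, making the output invariant to how the
    # raw data happened to be oriented and the whole analysis idempotent.
    rotation = _canonical_axes(consensus)
    consensus = consensus @ rotation
    aligned = aligned @ rotation

    # tangent projection at the consensus: rescale each shape along its ray so
    # its component on the consensus direction is exactly 1 (the projective
    # map onto the tangent plane).  Unlike subtracting the normal component,
    # this rescaling cancels exactly under re-normalization, so re-running GPA
    # on its own output reproduces it to convergence tolerance.
    c = consensus.ravel()
    flat = aligned.reshape(n, -1)
    flat = flat / (flat @ c)[:, None]
    aligned = flat.reshape(aligned.shape)
    consensus = aligned.mean(axis=0)

    return ProcrustesResult(
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        iterations=iterations,
        final_change=change,
        trace=trace,
        labels=list(dataset.labels),
        mark_type=dataset.mark_type,
    )


def _canonical_axes(consensus: np.ndarray) -> np.ndarray:
    """Rotation putting the consensus on its principal axes.

    Column signs are fixed so the largest-magnitude consensus coordinate on
    each axis is positive; if the resulting matrix is a reflection, the axis
    with the weakest sign statistic is flipped back to restore det = +1.
    """
    d = consensus.shape[1]
    _, _, vt = np.linalg.svd(consensus, full_matrices=False)
    axes = vt.T
    magnitudes = np.empty(d)
    for j in range(d):
        col = consensus @ axes[:, j]
        i = int(np.argmax(np.abs(col)))
        magnitudes[j] = abs(col[i])
        if col[i] < 0:
            axes[:, j] = -axes[:, j]
    if np.linalg.det(axes) < 0:
        axes[:, int(np.argmin(magnitudes))] *= -1
    return axes


@dataclass
class FormMatrix:
    """Form-space data: aligned coordinates rescaled by ln(centroid size).

    Keeps all k*d coordinate columns, so a 7x2 model yields 14 columns and a
    17x3 model 51.
    """

    values: np.ndarray
    basis: str
    labels: list[str]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def to_form_space(result: ProcrustesResult, unit_scale: float = 1.0) -> FormMatrix:
    """Build the form matrix: row i = aligned_i (flattened) x ln(CS_i).

    ``unit_scale`` converts centroid sizes to a unit in which they exceed 1
    (e.g. 1000 for mm -> um); any rescaled CS <= 1 is an error because its log
    would destroy or flip the size signal.
    """
    cs = result.centroid_sizes * unit_scale
    if np.any(cs <= 1.0):
        raise ValidationError(
            "centroid sizes <= 1 in working units; rescale units so ln(CS) > 0 "
            "(e.g. unit_scale=1000 for millimetre data)"
        )
    values = result.flattened() * np.log(cs)[:, None]
    return FormMatrix(
        values=values,
        basis=f"aligned coordinates x ln(CS x {unit_scale:g})",
        labels=list(result.labels),
    )


class TPSWarp:
    """Thin-plate-spline interpolant mapping reference landmarks onto targets.

    Kernel U(r) = r^2 ln r^2 in 2D and U(r) = -r in 3D.  ``bending_energy``
    is the quadratic form of the non-affine part; it vanishes exactly when the
    target is an affine image of the reference.
    """

    def __init__(self, reference: np.ndarray, target: np.ndarray) -> None:
        reference = np.asarray(reference, dtype=float)
        target = np.asarray(target, dtype=float)
        if reference.shape != target.shape:
            raise ValidationError("reference and target must share (k, d)")
        k, d = reference.shape
        if d not in (2, 3):
            raise ValidationError("TPS supports 2D and 3D landmarks only")
        self.reference = reference
        self.target = target
        self.d = d

        kernel = self._kernel_matrix(reference, reference)
        p = np.hstack([np.ones((k, 1)), reference])
        system = np.zeros((k + d + 1, k + d + 1))
        system[:k, :k] = kernel
        system[:k, k:] = p
        system[k:, :k] = p.T
        rhs = np.vstack([target, np.zeros((d + 1, d))])
        try:
            solution = scipy.linalg.solve(system, rhs)
        except scipy.linalg.LinAlgError as exc:
            raise ValidationError(
                "singular TPS system (collinear/coplanar reference landmarks?); "
                "jitter the reference slightly"
            ) from exc
        if not np.all(np.isfinite(solution)):
            raise ValidationError("singular TPS system; jitter the reference")
        self.weights = solution[:k]
        self.affine = solution[k:]
        self._kernel = kernel

    def _radii(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        diff = a[:, None, :] - b[None, :, :]
        return np.sqrt(np.sum(diff**2, axis=-1))

    def _kernel_matrix(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        r = self._radii(a, b)
        if self.d == 2:
            with np.errstate(divide="ignore", invalid="ignore"):
                u = np.where(r > 0, r**2 * np.log(r**2), 0.0)
        else:
            u = -r
        return u

    def __call__(self, query_points: np.ndarray) -> np.ndarray:
        query = np.asarray(query_points, dtype=float)
        if query.ndim == 1:
            query = query[None, :]
        if query.shape[1] != self.d:
            raise ValidationError(f"query points must be m x {self.d}")
        u = self._kernel_matrix(query, self.reference)
        p = np.hstack([np.ones((query.shape[0], 1)), query])
        return u @ self.weights + p @ self.affine

    @property
    def bending_energy(self) -> float:
        energy = float(np.trace(self.weights.T @ self._kernel @ self.weights))
        return abs(energy)


def tps_warp(
    reference: LandmarkConfiguration,
    target: LandmarkConfiguration,
    query_points: np.ndarray,
) -> np.ndarray:
    """Evaluate the reference->target thin-plate spline at ``query_points``."""
    warp = TPSWarp(reference.coords, target.coords)
    return warp(query_points)
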
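"""PCA bookkeeping, two-group MANOVA with a homogeneity gate, and PC-extreme
shape reconstruction.

Two PC-counting conventions coexist deliberately.  Shape space reports the
*informative* components — eigenvalues above 1e-10 of the largest — which for
GPA-aligned, tangent-projected data equals the geometric rank
k*d - d - d(d-1)/2 - 1 (10 for 7x2, 44 for 17x3).  Form space reports all
score *columns*, min(n-1, k*d) (14 for 7x2 with n=105, 51 for 17x3 with
n=83): the log-size rescaling spreads variance across every coordinate
column, so none is structurally zero.

MANOVA follows the protocol's rule: Box's M decides homogeneity of the group
covariances; homogeneous samples are tested with the Hotelling-Lawley trace,
inhomogeneous ones with Wilks' Lambda.  In the two-group case both reduce to
Hotelling's T-squared and give identical p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.decomposition import PCA as _SKPCA
from statsmodels.multivariate.manova import MANOVA as _SMManova

from .types import LandmarkConfiguration, ValidationError

_EIGENVALUE_RTOL = 1e-10


@dataclass
class PCAResult:
    """Covariance PCA of an n x p matrix.

    ``scores`` is n x m with m = min(n-1, p); ``loadings`` is p x m with
    orthonormal columns; ``eigenvalues`` are the sample-covariance eigenvalues
    in descending order; ``explained`` their proportions of total variance.
    """

    scores: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    explained: np.ndarray
    center: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(data: np.ndarray) -> PCAResult:
    """Column-mean-centred covariance PCA, components by descending eigenvalue."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValidationError("pca requires an n x p matrix with n >= 2")
    if not np.all(np.isfinite(data)):
        raise ValidationError("pca input must be finite")
    n, p = data.shape
    model = _SKPCA(n_components=min(n - 1, p), svd_solver="full")
    scores = model.fit_transform(data)
    return PCAResult(
        scores=scores,
        loadings=model.components_.T,
        eigenvalues=model.explained_variance_,
        explained=model.explained_variance_ratio_,
        center=model.mean_,
    )


def count_pc_scores(result: PCAResult, mode: str) -> int:
    """PC-score count under the shape (informative rank) or form (all columns)
    convention; see the module docstring."""
    if mode == "shape":
        top = result.eigenvalues[0]
        if top <= 0:
            return 0
        return int(np.sum(result.eigenvalues > _EIGENVALUE_RTOL * top))
    if mode == "form":
        return result.n_components
    raise ValidationError(f"mode must be 'shape' or 'form', got {mode!r}")


def boxs_m(groups: list[np.ndarray]) -> tuple[float, float, float]:
    """Box's M test of covariance homogeneity (chi-square approximation).

    Returns (M statistic, chi2, p).  Requires every group to have more rows
    than columns so its covariance is non-singular.
    """
    g = len(groups)
    p = groups[0].shape[1]
    ns = np.array([grp.shape[0] for grp in groups])
    if np.any(ns <= p):
        raise ValidationError(
            f"Box's M needs n_i > p in every group (got n={ns.tolist()}, p={p})"
        )
    covs = [np.cov(grp, rowvar=False) for grp in groups]
    dof = ns - 1
    pooled = sum(df * c for df, c in zip(dof, covs)) / dof.sum()
    sign, logdet_pooled = np.linalg.slogdet(np.atleast_2d(pooled))
    if sign <= 0:
        raise ValidationError("singular pooled covariance in Box's M")
    m_stat = dof.sum() * logdet_pooled
    for df, c in zip(dof, covs):
        sign, logdet = np.linalg.slogdet(np.atleast_2d(c))
        if sign <= 0:
            raise ValidationError("singular group covariance in Box's M")
        m_stat -= df * logdet
    correction = (
        (2 * p**2 + 3 * p - 1)
        / (6 * (p + 1) * (g - 1))
        * (np.sum(1.0 / dof) - 1.0 / dof.sum())
    )
    chi2 = m_stat * (1.0 - correction)
    df_chi = p * (p + 1) * (g - 1) / 2
    p_value = float(sps.chi2.sf(chi2, df_chi))
    return float(m_stat), float(chi2), p_value


@dataclass
class ManovaResult:
    statistic_name: str  # "Hotelling-Lawley" or "Wilks"
    statistic: float
    F_approx: float
    df: tuple[float, float]
    p_value: float
    homogeneity_p: float
    n_components_used: int

    def to_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "F": self.F_approx,
            "df": list(self.df),
            "p_value": self.p_value,
            "homogeneity_p": self.homogeneity_p,
            "n_components_used": self.n_components_used,
        }


def _truncate_columns(
    data: np.ndarray, n_a: int, n_b: int, var_threshold: float
) -> int:
    """Leading columns reaching ``var_threshold`` cumulative variance, capped
    so the error degrees of freedom stay positive and covariances invertible."""
    variances = data.var(axis=0, ddof=1)
    total = variances.sum()
    if total <= 0:
        raise ValidationError("zero-variance data passed to MANOVA")
    cumulative = np.cumsum(variances) / total
    m = int(np.searchsorted(cumulative, var_threshold) + 1)
    # keep the test genuinely multivariate: at least two responses
    m = max(m, 2)
    m = min(m, n_a + n_b - 3, min(n_a, n_b) - 1, data.shape[1])
    if m < 2:
        raise ValidationError(
            "fewer than two usable response columns after truncation"
        )
    return m


def manova_pairwise(
    scores: np.ndarray,
    labels: list[str] | np.ndarray,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    var_threshold: float = 0.95,
) -> ManovaResult:
    """Two-group MANOVA on the leading score columns.

    Columns (assumed variance-ordered, e.g. PC scores) are truncated to the
    leading ones explaining ``var_threshold`` of cumulative variance, capped
    at n_a + n_b - 3.  Box's M then gates the statistic: Hotelling-Lawley when
    homogeneous (p >= alpha), Wilks' Lambda otherwise.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    rows_a = scores[labels == group_a]
    rows_b = scores[labels == group_b]
    for name, rows in ((group_a, rows_a), (group_b, rows_b)):
        if rows.shape[0] < 3:
            raise ValidationError(
                f"group {name!r} has {rows.shape[0]} members; need >= 3"
            )
    data = np.vstack([rows_a, rows_b])
    n_a, n_b = rows_a.shape[0], rows_b.shape[0]
    m = _truncate_columns(data, n_a, n_b, var_threshold)
    data = data[:, :m]

    _, _, homogeneity_p = boxs_m([data[:n_a], data[n_a:]])
    statistic_name = "Hotelling-Lawley" if homogeneity_p >= alpha else "Wilks"

    # identical group means make the hypothesis SSP exactly zero, which the
    # downstream eigen-solver cannot represent; that case is an exact null
    scale = float(np.sqrt(np.mean(data.var(axis=0, ddof=1))))
    mean_gap = float(np.linalg.norm(data[:n_a].mean(0) - data[n_a:].mean(0)))
    if mean_gap <= 1e-12 * max(scale, 1.0):
        return ManovaResult(
            statistic_name=statistic_name,
            statistic=0.0 if statistic_name == "Hotelling-Lawley" else 1.0,
            F_approx=0.0,
            df=(float(m), float(n_a + n_b - m - 1)),
            p_value=1.0,
            homogeneity_p=homogeneity_p,
            n_components_used=m,
        )

    exog = np.column_stack([np.ones(n_a + n_b), np.r_[np.zeros(n_a), np.ones(n_b)]])
    contrast = np.array([[0.0, 1.0]])
    table = (
        _SMManova(data, exog)
        .mv_test(hypotheses=[("group", contrast, None)])
        .results["group"]["stat"]
    )
    row = table.loc[
        "Wilks' lambda" if statistic_name == "Wilks" else "Hotelling-Lawley trace"
    ]
    return ManovaResult(
        statistic_name=statistic_name,
        statistic=float(row["Value"]),
        F_approx=float(row["F Value"]),
        df=(float(row["Num DF"]), float(row["Den DF"])),
        p_value=float(row["Pr > F"]),
        homogeneity_p=homogeneity_p,
        n_components_used=m,
    )


def pc_extreme_shapes(
    result: PCAResult, consensus: LandmarkConfiguration, component: int
) -> tuple[LandmarkConfiguration, LandmarkConfiguration]:
    """Configurations at the observed extremes of one shape-space component.

    Returns consensus + (min score) x loading and consensus + (max score) x
    loading, unflattened to k x d — the inputs for deformation-grid warps
    against the consensus.
    """
    if not 0 <= component < result.n_components:
        raise ValidationError(
            f"component {component} out of range [0, {result.n_components})"
        )
    loading = result.loadings[:, component]
    scores = result.scores[:, component]
    k, d = consensus.coords.shape
    low = consensus.coords + (scores.min() * loading).reshape(k, d)
    high = consensus.coords + (scores.max() * loading).reshape(k, d)
    make = lambda coords, tag: LandmarkConfiguration(
        coords, consensus.mark_type, None, f"PC{component + 1}_{tag}"
    )
    return make(low, "low"), make(high, "high")
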
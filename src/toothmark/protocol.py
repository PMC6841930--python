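"""End-to-end orchestration of the four-view discrimination protocol.

The four data views mirror the reference analysis design:

1. ``with_oa``      — the seven score cross-section measurements;
2. ``without_oa``   — the same table excluding the opening angle;
3. ``scores_shape`` — shape-space PC scores of GPA-aligned score
   cross-sections (size removed);
4. ``pits_form``    — form-space PC scores of GPA-aligned pits (size
   retained via ln centroid size).

Each enabled view runs through pairwise MANOVA (dog vs wolf, dog vs fox) and
the full SVM protocol.  Every random draw derives from the single top-level
seed, so re-runs are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .classify import ClassificationReport, ProtocolParams, run_svm_protocol
from .metrics import measurement_table
from .procrustes import gpa, to_form_space
from .simulate import SimulationSpec, simulate_dataset
from .stats import ManovaResult, count_pc_scores, manova_pairwise, pca
from .types import ValidationError

VIEWS = ("with_oa", "without_oa", "scores_shape", "pits_form")

#: mm -> um conversion applied before ln(CS) in form space
FORM_UNIT_SCALE = 1000.0

#: row labels of the rendered metric table
REPORT_ROWS = (
    "Optimal Cost", "Optimal Gamma", "Kappa", "Accuracy", "Lower CI",
    "Upper CI", "MSE", "Sensitivity", "Specificity", "Training Time (ms)",
)


@dataclass
class ProtocolConfig:
    """Configuration of one full protocol run."""

    seed: int = 0
    spec: SimulationSpec | None = None
    views: tuple[str, ...] = VIEWS
    svm: ProtocolParams = field(default_factory=ProtocolParams)
    manova_pairs: tuple[tuple[str, str], ...] = (("dog", "wolf"), ("dog", "fox"))

    def __post_init__(self) -> None:
        unknown = set(self.views) - set(VIEWS)
        if unknown:
            raise ValidationError(f"unknown views {sorted(unknown)}")
        if not self.views:
            raise ValidationError("at least one analysis view must be enabled")


@dataclass
class ReportBundle:
    """All outputs of one protocol run."""

    seed: int
    classification: dict[str, ClassificationReport]
    manova: dict[str, dict[str, ManovaResult]]
    pca_summary: dict[str, int]
    view_dims: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "classification": {
                view: report.to_dict() for view, report in self.classification.items()
            },
            "manova": {
                view: {pair: res.to_dict() for pair, res in results.items()}
                for view, results in self.manova.items()
            },
            "pca_summary": self.pca_summary,
            "view_dims": self.view_dims,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def build_views(
    config: ProtocolConfig,
) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], dict[str, int]]:
    """Simulate the reference sample and assemble the enabled feature views.

    Also returns the PC-score bookkeeping for both mark types in both spaces
    (shape: informative components; form: all score columns).
    """
    spec = config.spec if config.spec is not None else SimulationSpec(seed=config.seed)
    if spec.seed != config.seed:
        spec = replace(spec, seed=config.seed)

    views: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    summary: dict[str, int] = {}

    scores_ds = simulate_dataset(spec, "score")
    pits_ds = simulate_dataset(spec, "pit")
    table = measurement_table(scores_ds, include_oa=True)
    labels_scores = np.asarray(table.labels)
    labels_pits = np.asarray(pits_ds.labels)

    if "with_oa" in config.views:
        views["with_oa"] = (table.values, labels_scores)
    if "without_oa" in config.views:
        views["without_oa"] = (table.drop_oa().values, labels_scores)

    scores_gpa = gpa(scores_ds)
    pits_gpa = gpa(pits_ds)

    scores_shape_pca = pca(scores_gpa.flattened())
    pits_shape_pca = pca(pits_gpa.flattened())
    scores_form_pca = pca(to_form_space(scores_gpa, FORM_UNIT_SCALE).values)
    pits_form_pca = pca(to_form_space(pits_gpa, FORM_UNIT_SCALE).values)
    summary["scores_shape_pcs"] = count_pc_scores(scores_shape_pca, "shape")
    summary["pits_shape_pcs"] = count_pc_scores(pits_shape_pca, "shape")
    summary["scores_form_pcs"] = count_pc_scores(scores_form_pca, "form")
    summary["pits_form_pcs"] = count_pc_scores(pits_form_pca, "form")

    if "scores_shape" in config.views:
        m = summary["scores_shape_pcs"]
        views["scores_shape"] = (scores_shape_pca.scores[:, :m], labels_scores)
    if "pits_form" in config.views:
        views["pits_form"] = (pits_form_pca.scores, labels_pits)
    return views, summary


def run_full_protocol(config: ProtocolConfig | None = None) -> ReportBundle:
    """Run MANOVA and the SVM protocol on every enabled view."""
    config = config or ProtocolConfig()
    views, summary = build_views(config)

    classification: dict[str, ClassificationReport] = {}
    manova: dict[str, dict[str, ManovaResult]] = {}
    # distinct, seed-derived stream per view (kept < 2**31)
    view_seed = {v: (config.seed * 7 + i) % (2**31) for i, v in enumerate(VIEWS)}
    for view in config.views:
        X, y = views[view]
        try:
            # metric views go through PCA before MANOVA (the GM views' X are
            # already PC scores); note the raw angle columns are linearly
            # dependent (OA + LWA + RWA = 180), so this is also required
            manova_X = pca(X).scores if view in ("with_oa", "without_oa") else X
            manova[view] = {
                f"{a}_vs_{b}": manova_pairwise(manova_X, y, a, b)
                for a, b in config.manova_pairs
            }
            # measurements mix units (mm, degrees) and need standardizing;
            # PC-score views must stay on their variance-ordered scale
            svm_params = replace(
                config.svm, scale_features=view in ("with_oa", "without_oa")
            )
            classification[view] = run_svm_protocol(
                X, y, seed=view_seed[view], params=svm_params
            )
        except Exception as exc:
            raise RuntimeError(f"protocol stage failed in view {view!r}: {exc}") from exc

    view_dims = {view: views[view][0].shape[1] for view in config.views}
    return ReportBundle(
        seed=config.seed,
        classification=classification,
        manova=manova,
        pca_summary=summary,
        view_dims=view_dims,
    )


def _fmt(x: float | None) -> str:
    if x is None:
        return "-"
    return f"{x:.4g}"


def report_render(bundle: ReportBundle, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the JSON bundle and a human-readable summary table.

    The text table has one column per data view,
    one row per evaluation metric, plus a pairwise-MANOVA p-value block.
    """
    missing = [v for v in bundle.classification if v not in bundle.manova]
    if missing:
        raise ValidationError(f"incomplete bundle: missing MANOVA for {missing}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "bundle.json"
    json_path.write_text(bundle.to_json() + "\n")

    views = list(bundle.classification)
    getters = {
        "Optimal Cost": lambda r: r.config.cost if r.config else None,
        "Optimal Gamma": lambda r: r.config.gamma if r.config else None,
        "Kappa": lambda r: r.kappa,
        "Accuracy": lambda r: r.balanced_accuracy,
        "Lower CI": lambda r: r.ci_low,
        "Upper CI": lambda r: r.ci_high,
        "MSE": lambda r: r.mse,
        "Sensitivity": lambda r: r.sensitivity,
        "Specificity": lambda r: r.specificity,
        "Training Time (ms)": lambda r: r.training_time_ms,
    }
    width = max(len(r) for r in REPORT_ROWS) + 2
    col = 14
    lines = ["SVM evaluation metrics", "=" * (width + col * len(views))]
    lines.append(" " * width + "".join(f"{v:>{col}}" for v in views))
    for row in REPORT_ROWS:
        cells = [_fmt(getters[row](bundle.classification[v])) for v in views]
        lines.append(f"{row:<{width}}" + "".join(f"{c:>{col}}" for c in cells))
    lines.append("")
    lines.append("MANOVA p-values")
    lines.append("-" * (width + col * len(views)))
    pairs = sorted({p for res in bundle.manova.values() for p in res})
    for pair in pairs:
        cells = [
            _fmt(bundle.manova[v][pair].p_value) if pair in bundle.manova.get(v, {})
            else "-"
            for v in views
        ]
        lines.append(f"{pair:<{width}}" + "".join(f"{c:>{col}}" for c in cells))
    lines.append("")
    lines.append("PC-score bookkeeping: " + json.dumps(bundle.pca_summary, sort_keys=True))
    text_path = out_dir / "summary.txt"
    text_path.write_text("\n".join(lines) + "\n")
    return json_path, text_path
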
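"""Confusion matrices, sensitivities, PCA screening scores, and the
calculated-vs-measured comparison tables.

Percentages are reported to one decimal; raw counts are always kept
alongside.  Plotting is optional and file-only — no numeric report
depends on it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

__all__ = [
    "confusion_and_accuracy",
    "pca_scores",
    "compare_provenance",
    "per_level_table",
    "conformity",
]


def confusion_and_accuracy(
    y_true, y_pred, labels: list | None = None,
) -> tuple[pd.DataFrame, float, pd.Series]:
    """Confusion counts, overall accuracy (%) and per-class sensitivity (%).

    Overall accuracy is ``100 * trace / total``; the sensitivity of class
    c is ``100 * diag_c / rowsum_c`` (rows = truth, columns = prediction).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label sequences")
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences differ in length")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    conf = pd.DataFrame(cm, index=labels, columns=labels)
    overall = 100.0 * np.trace(cm) / cm.sum()
    rowsum = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(rowsum > 0, 100.0 * np.diag(cm) / rowsum, np.nan)
    return conf, float(overall), pd.Series(sens, index=labels)


def pca_scores(pretreated: pd.DataFrame,
               n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Mean-centred PCA scores for screening plots.

    Returns the per-row scores and the explained-variance fractions
    (non-increasing, summing to <= 1).
    """
    X = pretreated.to_numpy(dtype=float)
    n, p = X.shape
    if n <= n_components:
        raise ValueError(
            f"n_components={n_components} requires more than "
            f"{n_components} rows, got {n}"
        )
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    explained = var[:n_components] / var.sum()
    scores = Xc @ Vt[:n_components].T
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores, columns=cols,
                        index=pretreated.index), explained


def per_level_table(levels, detected_measured: pd.Series | None,
                    detected_calculated: pd.Series | None) -> pd.DataFrame:
    """Per-adulteration-level accuracy table with the %pt difference.

    ``detected_*`` map level -> accuracy in percent.  Columns follow the
    conventional order: level, measured, calculated, absolute difference
    in percentage points (one decimal).
    """
    rows = []
    for lv in levels:
        m = (np.nan if detected_measured is None
             else float(detected_measured.get(lv, np.nan)))
        c = (np.nan if detected_calculated is None
             else float(detected_calculated.get(lv, np.nan)))
        d = (round(abs(m - c), 1)
             if not (np.isnan(m) or np.isnan(c)) else np.nan)
        rows.append({"adulteration_level": lv,
                     "accuracy_measured": m,
                     "accuracy_calculated": c,
                     "difference_pct_pt": d})
    return pd.DataFrame(rows)


def conformity(per_level: pd.DataFrame) -> float:
    """Agreement between calculated and measured results, in percent.

    Defined as 100 minus the mean absolute percentage-point difference
    across adulteration levels.
    """
    d = per_level["difference_pct_pt"].dropna()
    if len(d) == 0:
        return float("nan")
    return float(100.0 - d.abs().mean())


def compare_provenance(report_calculated, report_measured) -> dict:
    """Summarise calc-vs-measured differences of two matched runs.

    Both inputs are :class:`~elemix.approaches.EvaluationReport` objects
    from the same world, plan and model; only provenance differs.
    """
    a, b = report_calculated, report_measured
    if (a.approach, a.focal_country) != (b.approach, b.focal_country):
        raise ValueError(
            "mismatched runs: "
            f"{(a.approach, a.focal_country)} vs "
            f"{(b.approach, b.focal_country)}"
        )
    out: dict = {"approach": a.approach, "focal_country": a.focal_country}
    if a.overall_accuracy is not None and b.overall_accuracy is not None:
        out["difference_pct_pt"] = round(
            abs(b.overall_accuracy - a.overall_accuracy), 1)
    if a.detection_rate is not None and b.detection_rate is not None:
        out["detection_difference_pct_pt"] = round(
            abs(b.detection_rate - a.detection_rate), 1)
    if a.per_level is not None and b.per_level is not None:
        tbl = per_level_table(
            a.per_level["adulteration_level"].tolist(),
            b.per_level.set_index("adulteration_level")[
                "accuracy_measured"].dropna()
            if "accuracy_measured" in b.per_level else None,
            a.per_level.set_index("adulteration_level")[
                "accuracy_calculated"].dropna()
            if "accuracy_calculated" in a.per_level else None,
        )
        out["per_level"] = tbl
        out["conformity"] = conformity(tbl)
    return out


def plot_pca_scores(scores: pd.DataFrame, groups: pd.Series,
                    path: str) -> None:
    """Write a PC1-vs-PC2 score plot to ``path`` (optional helper)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for g, sub in scores.groupby(groups):
        ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], label=str(g), s=18)
    ax.set_xlabel(scores.columns[0])
    ax.set_ylabel(scores.columns[1])
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
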
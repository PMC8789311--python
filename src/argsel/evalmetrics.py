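"""Evaluation harness: ROC/AUROC, regression errors, stratified reports,
and the demographic-mismatch robustness grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EvalReport",
    "roc_auroc",
    "regression_metrics",
    "stratify",
    "robustness_grid",
    "DEFAULT_S_BINS",
]

# default selection-coefficient strata mirroring the stratified analysis
DEFAULT_S_BINS = (0.0, 0.0025, 0.005, 0.0075, 0.02)


@dataclass
class EvalReport:
    """Overall metrics plus a per-stratum table and provenance metadata."""

    overall: dict
    per_stratum: Optional[pd.DataFrame] = None
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        import json

        payload = {"overall": self.overall, "metadata": self.metadata}
        if self.per_stratum is not None:
            payload["per_stratum"] = self.per_stratum.reset_index().to_dict(
                orient="records"
            )
        return json.dumps(payload, default=float, indent=2)


def roc_auroc(scores: Sequence[float], labels: Sequence[int]):
    """ROC curve and its area, by threshold sweep with trapezoid area.

    The curve records (FPR, TPR) at every distinct score threshold,
    sweeping from above the maximum score to below the minimum; tied
    scores enter simultaneously.  Raises on single-class labels.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    tp = np.cumsum(l_sorted)
    fp = np.cumsum(1 - l_sorted)
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    auroc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auroc


def regression_metrics(y_true, y_pred) -> dict:
    """mae, rmse and coefficient of determination r2."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal shapes")
    if y_true.size < 2:
        raise ValueError("need at least 2 observations")
    err = y_pred - y_true
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return {"mae": mae, "rmse": rmse, "r2": r2}


def stratify(
    y_true: Sequence[float],
    y_pred: Sequence[float],
    s_values: Sequence[float],
    daf_values: Sequence[float],
    s_bins: Sequence[float] = DEFAULT_S_BINS,
    daf_bins: Optional[Sequence[float]] = None,
    metadata: Optional[dict] = None,
) -> EvalReport:
    """Regression metrics per (s bin x DAF bin) cell.

    ``daf_bins`` defaults to the DAF quartiles of the test set.  Cells
    with fewer than 2 items are flagged (n recorded, metrics NaN), never
    dropped.
    """
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    s_values = np.asarray(s_values, float)
    daf_values = np.asarray(daf_values, float)
    if daf_bins is None:
        daf_bins = np.quantile(daf_values, [0, 0.25, 0.5, 0.75, 1.0])
        daf_bins[-1] += 1e-9
    rows = []
    for i in range(len(s_bins) - 1):
        for j in range(len(daf_bins) - 1):
            sel = (
                (s_values >= s_bins[i]) & (s_values < s_bins[i + 1])
                & (daf_values >= daf_bins[j]) & (daf_values < daf_bins[j + 1])
            )
            cell = {
                "s_lo": s_bins[i], "s_hi": s_bins[i + 1],
                "daf_lo": daf_bins[j], "daf_hi": daf_bins[j + 1],
                "n": int(sel.sum()),
            }
            if sel.sum() >= 2:
                cell.update(regression_metrics(y_true[sel], y_pred[sel]))
            else:
                cell.update({"mae": np.nan, "rmse": np.nan, "r2": np.nan})
            rows.append(cell)
    table = pd.DataFrame(rows)
    return EvalReport(
        overall=regression_metrics(y_true, y_pred),
        per_stratum=table,
        metadata=metadata or {},
    )


def robustness_grid(
    model,
    grid,
    mismatch_specs: List[dict],
    predict_fn: Optional[Callable] = None,
) -> List[EvalReport]:
    """Evaluate a trained model on test sets from mismatched simulators.

    Each spec is a dict with keys ``name``, ``prior``
    (:class:`~argsel.regions.PriorSpec`), ``demography``, ``L``, ``n``,
    ``n_regions`` and ``seed``; regions are simulated under the spec,
    features extracted on ``grid``, and the model evaluated *without
    retraining*.  Returns one report per spec, with the spec recorded in
    the report metadata.
    """
    from argsel.nn.model import predict
    from argsel.regions import sample_priors, simulate_region, region_features

    if predict_fn is None:
        predict_fn = lambda fv: predict(model, fv).point

    reports = []
    for spec in mismatch_specs:
        rng = np.random.default_rng(spec.get("seed", 0))
        y_true, y_pred, dafs = [], [], []
        for _ in range(spec["n_regions"]):
            params = sample_priors(spec["prior"], rng)
            region = simulate_region(
                params, spec["demography"], L=spec["L"], n=spec["n"], rng=rng
            )
            fv = region_features(region, grid)
            y_true.append(region.params.s)
            y_pred.append(float(np.asarray(predict_fn(fv)).ravel()[0]))
            dafs.append(region.focal_site.daf(region.n))
        rep = stratify(
            y_true, y_pred, y_true, dafs,
            metadata={"spec": spec["name"],
                      "bias": float(np.mean(np.array(y_pred) - np.array(y_true)))},
        )
        reports.append(rep)
    return reports
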
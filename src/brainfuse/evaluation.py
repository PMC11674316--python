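"""Accuracy metrics and brain-age-gap bias correction.

Predicted brain age systematically regresses toward the training mean, so
the brain age gap (predicted minus chronological age) correlates with age.
The standard remedy fits, on the *training split only*, an ordinary
least-squares model ``gap = alpha * age + beta`` and subtracts the fitted
trend from every prediction:

    corrected = predicted - (alpha * age + beta)

Metrics are mean absolute error (MAE, years), root mean square error
(RMSE, years) and the coefficient of determination R^2 computed against
chronological age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "mae", "rmse", "r_squared", "BiasCorrectionModel", "fit_bias_correction",
    "apply_bias_correction", "metrics_by_split", "metrics_report",
    "report_to_markdown",
]

#: column layout of a prediction table
PREDICTION_COLUMNS = ["subject_id", "split", "age", "predicted"]


def _pair(y_true, y_pred):
    y = np.asarray(y_true, dtype=np.float64)
    yhat = np.asarray(y_pred, dtype=np.float64)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError(f"need matching 1D arrays, got {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty prediction set")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
        raise ValueError("non-finite ages or predictions")
    return y, yhat


def mae(y_true, y_pred) -> float:
    """Mean absolute error in years."""
    y, yhat = _pair(y_true, y_pred)
    return float(np.mean(np.abs(y - yhat)))


def rmse(y_true, y_pred) -> float:
    """Root mean square error in years."""
    y, yhat = _pair(y_true, y_pred)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y, yhat = _pair(y_true, y_pred)
    if y.size < 2:
        raise ValueError("R^2 needs at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: chronological ages are constant")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class BiasCorrectionModel:
    """OLS fit of the brain age gap on chronological age (training split)."""

    alpha: float            # gap slope per year of age
    beta: float             # gap intercept, years
    fit_split: str = "train"

    def correct(self, age, predicted):
        age = np.asarray(age, dtype=np.float64)
        predicted = np.asarray(predicted, dtype=np.float64)
        return predicted - (self.alpha * age + self.beta)


def fit_bias_correction(predictions: pd.DataFrame,
                        predicted_col: str = "predicted") -> BiasCorrectionModel:
    """Fit gap-on-age OLS. ``predictions`` must contain *training rows only*
    (test/validation labels must never leak into the correction fit)."""
    if "split" in predictions.columns:
        bad = set(predictions["split"].unique()) - {"train"}
        if bad:
            raise ValueError(
                f"bias correction is fit on the training split only; "
                f"found rows labelled {sorted(bad)}")
    y = predictions["age"].to_numpy(dtype=np.float64)
    yhat = predictions[predicted_col].to_numpy(dtype=np.float64)
    if y.size < 3:
        raise ValueError(f"need >= 3 training subjects, got {y.size}")
    if np.var(y) == 0:
        raise ValueError("cannot fit bias correction: ages are constant")
    gap = yhat - y
    alpha, beta = np.polyfit(y, gap, deg=1)
    return BiasCorrectionModel(alpha=float(alpha), beta=float(beta))


def apply_bias_correction(predictions: pd.DataFrame,
                          model: BiasCorrectionModel,
                          predicted_col: str = "predicted",
                          out_col: str = "corrected") -> pd.DataFrame:
    """Return a copy of ``predictions`` with a corrected-age column, using
    the train-fit model uniformly on all splits."""
    if not (np.isfinite(model.alpha) and np.isfinite(model.beta)):
        raise ValueError("bias-correction coefficients must be finite")
    out = predictions.copy()
    out[out_col] = model.correct(out["age"].to_numpy(),
                                 out[predicted_col].to_numpy())
    return out


def metrics_by_split(predictions: pd.DataFrame,
                     predicted_col: str = "corrected") -> pd.DataFrame:
    """Per-split MAE/RMSE/R^2 table (rows ordered train, val, test)."""
    if predicted_col not in predictions.columns:
        raise KeyError(f"no column {predicted_col!r} in predictions")
    rows = []
    order = [s for s in ("train", "val", "test")
             if s in set(predictions["split"])]
    for split in order:
        sub = predictions[predictions["split"] == split]
        y, yhat = sub["age"].to_numpy(), sub[predicted_col].to_numpy()
        rows.append({
            "split": split,
            "n": len(sub),
            "mae": mae(y, yhat),
            "rmse": rmse(y, yhat),
            "r2": r_squared(y, yhat) if len(sub) >= 2 else np.nan,
        })
    return pd.DataFrame(rows)


def metrics_report(predictions_by_strategy: dict,
                   predicted_col: str = "corrected") -> pd.DataFrame:
    """Stack per-strategy metric tables: one row per (strategy, split)."""
    if not predictions_by_strategy:
        raise ValueError("no strategies to report")
    frames = []
    for name, preds in predictions_by_strategy.items():
        tab = metrics_by_split(preds, predicted_col=predicted_col)
        tab.insert(0, "strategy", name)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def report_to_markdown(report: pd.DataFrame) -> str:
    cols = list(report.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in report.iterrows():
        cells = [f"{v:.3f}" if isinstance(v, float) else str(v) for v in row]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
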
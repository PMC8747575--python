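"""Leave-one-out cross-validation, error metrics, and kernel grid search.

With only a few dozen training molecules, LOOCV makes the most of every
sample: each molecule is predicted by a model trained on all the others.
Metrics follow the usual definitions — RMSE, MAE, the average relative
error ARE = mean |1 - yhat/y| (taken with the absolute value so the
quantity is an error, not a signed bias), and the coefficient of
determination R^2. LOOCV metrics are computed on the pooled vector of the
n held-out predictions, not averaged per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import product

import numpy as np
import pandas as pd

from .models import krr_trainer


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class EvaluationReport:
    r2: float
    mae: float
    rmse: float
    are: float
    n: int
    split: str = "training"  # training | loocv | external

    def as_dict(self) -> dict:
        return asdict(self)

    def __str__(self) -> str:
        return (
            f"[{self.split}] n={self.n}  R2={self.r2:.3f}  MAE={self.mae:.3f}  "
            f"RMSE={self.rmse:.3f}  ARE={self.are:.3f}"
        )


def metrics(y, y_pred, split: str = "training") -> EvaluationReport:
    """RMSE, MAE, ARE and R^2 for a (reference, prediction) pair set."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape or y.ndim != 1:
        raise ValidationError(f"shape mismatch: {y.shape} vs {y_pred.shape}")
    if np.any(y == 0.0):
        raise ValidationError(
            "ARE is undefined when a reference value is exactly zero"
        )
    resid = y - y_pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    are = float(np.mean(np.abs(1.0 - y_pred / y)))
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return EvaluationReport(r2=r2, mae=mae, rmse=rmse, are=are, n=len(y), split=split)


def loocv(X, y, trainer) -> np.ndarray:
    """Leave-one-out predictions: entry i comes from a fit without row i.

    ``trainer`` is a callable (X, y) -> model with a .predict(X) method
    (see models.mlr_trainer / models.krr_trainer).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValidationError(f"LOOCV needs at least 3 samples, got {n}")
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            model = trainer(X[mask], y[mask])
            preds[i] = float(np.ravel(model.predict(X[i : i + 1]))[0])
        except Exception as err:
            raise ValidationError(f"trainer failed on fold {i}: {err}") from err
    return preds


def grid_search(
    X,
    y,
    c_values,
    d_values,
    alpha: float = 0.001,
    standardize: bool = True,
):
    """Exhaustive (c, d) sweep for polynomial KRR, scored by LOOCV RMSE.

    Returns ``(best_c, best_d, table)`` where the table holds one row per
    grid cell with training and LOOCV metrics. Ties are broken toward the
    smaller degree, then the smaller c.
    """
    c_values = list(c_values)
    d_values = list(d_values)
    if not c_values or not d_values:
        raise ValidationError("grid search needs non-empty c and d lists")
    rows = []
    for c, d in product(c_values, d_values):
        trainer = krr_trainer(alpha=alpha, c=c, d=int(d), standardize=standardize)
        model = trainer(X, y)
        train_rep = metrics(y, model.predict(X), split="training")
        loo_rep = metrics(y, loocv(X, y, trainer), split="loocv")
        rows.append(
            {
                "c": c,
                "d": int(d),
                "train_rmse": train_rep.rmse,
                "train_mae": train_rep.mae,
                "train_r2": train_rep.r2,
                "loocv_rmse": loo_rep.rmse,
                "loocv_mae": loo_rep.mae,
                "loocv_r2": loo_rep.r2,
            }
        )
    table = pd.DataFrame(rows)
    order = table.sort_values(
        ["loocv_rmse", "d", "c"], kind="stable"
    ).index
    best = table.loc[order[0]]
    return float(best["c"]), int(best["d"]), table


def report_frame(reports) -> pd.DataFrame:
    """Tabulate evaluation reports: full precision plus 3-decimal display."""
    rows = []
    for rep in reports:
        row = rep.as_dict()
        for key in ("r2", "mae", "rmse", "are"):
            row[f"{key}_display"] = f"{row[key]:.3f}"
        rows.append(row)
    return pd.DataFrame(rows)
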
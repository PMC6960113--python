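"""Agreement metrics between chronological and predicted age.

Four summaries are reported per (network, method) cell: Pearson r, R², MAE
and RMSE.  R² is ambiguous in the brain-age literature — some reports use
the squared correlation r², others the coefficient of determination
1 - SS_res/SS_tot (which can be negative and additionally penalizes bias).
Both are computed; the squared correlation is carried in the primary
``r2`` column, with the coefficient-of-determination variant alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PredictionResult:
    """Per-subject test-set predictions for one (network, method) cell."""

    network: str
    method: str
    subject_ids: tuple[str, ...]
    age: np.ndarray
    predicted_age: np.ndarray

    def __post_init__(self) -> None:
        age = np.asarray(self.age, dtype=float)
        pred = np.asarray(self.predicted_age, dtype=float)
        if age.shape != pred.shape or age.ndim != 1:
            raise ValueError("age and predicted_age must be equal-length 1D")
        if len(self.subject_ids) != age.size:
            raise ValueError("one subject id per prediction required")
        if not (np.isfinite(age).all() and np.isfinite(pred).all()):
            raise ValueError("ages and predictions must be finite")
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "predicted_age", pred)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": list(self.subject_ids),
                "age": self.age,
                "predicted_age": self.predicted_age,
            }
        )


@dataclass(frozen=True)
class MetricsRow:
    """One cell of the evaluation table.

    ``r2`` is the squared Pearson correlation (primary); ``r2_cod`` is the
    coefficient-of-determination variant 1 - SS_res / SS_tot.  When the
    predictions are constant, r (and both R² variants) are undefined and
    reported as NaN while MAE/RMSE remain valid.
    """

    network: str
    method: str
    r: float
    r2: float
    r2_cod: float
    mae: float
    rmse: float
    n: int


def compute_metrics(pred: PredictionResult) -> MetricsRow:
    """Evaluate one prediction set against chronological age."""
    y = pred.age
    yhat = pred.predicted_age
    if y.size < 3:
        raise ValueError("need at least 3 test subjects")
    if np.ptp(y) == 0:
        raise ValueError("chronological ages are constant; metrics undefined")
    err = yhat - y
    mae = float(np.abs(err).mean())
    rmse = float(math.sqrt(np.square(err).mean()))
    ss_res = float(np.square(err).sum())
    ss_tot = float(np.square(y - y.mean()).sum())
    r2_cod = 1.0 - ss_res / ss_tot
    if np.ptp(yhat) == 0:
        r = r2 = float("nan")
    else:
        r = float(np.corrcoef(y, yhat)[0, 1])
        r2 = r * r
    return MetricsRow(
        network=pred.network,
        method=pred.method,
        r=r,
        r2=r2,
        r2_cod=r2_cod,
        mae=mae,
        rmse=rmse,
        n=y.size,
    )


def metrics_table(rows: list[MetricsRow]) -> pd.DataFrame:
    """Stack MetricsRows into the networks x methods evaluation table."""
    if not rows:
        raise ValueError("no metrics rows")
    return pd.DataFrame(
        [
            {
                "network": m.network,
                "method": m.method,
                "r": m.r,
                "r2": m.r2,
                "r2_cod": m.r2_cod,
                "mae": m.mae,
                "rmse": m.rmse,
                "n": m.n,
            }
            for m in rows
        ]
    )
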
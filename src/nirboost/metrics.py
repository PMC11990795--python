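"""Evaluation statistics with fixed sign and denominator conventions.

- rmse = sqrt(mean((pred - true)^2))
- mae  = mean(|pred - true|)
- bias = mean(pred - true): positive means over-prediction
- r    = Pearson correlation (not R^2)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import FitError

__all__ = ["EvalReport", "evaluate"]


@dataclass
class EvalReport:
    rmse: float
    r: float
    mae: float
    bias: float
    n: int
    context: str = "prediction"  # or "calibration_cv"


def evaluate(
    y_true: np.ndarray, y_pred: np.ndarray, context: str = "prediction"
) -> EvalReport:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise FitError(
            f"length mismatch: {y_true.size} observed vs {y_pred.size} predicted"
        )
    if y_true.size < 2:
        raise FitError("need at least 2 samples")
    if np.isnan(y_true).any() or np.isnan(y_pred).any():
        raise FitError("NaN in inputs")
    resid = y_pred - y_true
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    bias = float(np.mean(resid))
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        # error magnitudes are still well defined; only r degenerates
        warnings.warn("constant vector: correlation undefined (r = NaN)",
                      stacklevel=2)
        r = float("nan")
    else:
        r = float(np.corrcoef(y_true, y_pred)[0, 1])
    return EvalReport(rmse=rmse, r=r, mae=mae, bias=bias,
                      n=int(y_true.size), context=context)
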
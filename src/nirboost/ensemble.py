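"""AdaBoost-style weighting of pre-built PLS member models.

The members (one per frequency tier) are already fitted; boosting here only
allocates the combination weights. Per-sample losses come from a graded,
two-knot piecewise-linear map of the absolute calibration deviation with
knots at the error thresholds (default 1.0 and 1.5 °Brix):

    loss = 0.5 * d / t1                    for d <= t1
    loss = 0.5 + 0.5 * (d - t1)/(t2 - t1)  for t1 < d <= t2
    loss = 1                               for d > t2

Member m gets weighted error eps_m = sum_i w_i * loss_i, beta_m =
eps_m / (1 - eps_m) and combination weight alpha_m = ln(1 / beta_m),
normalized to sum 1. By default each member is scored against the same
uniform sample weights (one-shot mode), which makes identical members earn
exactly equal weights; ``update_sample_weights=True`` enables the classic
sequential sweep where w_i <- w_i * beta^(1 - loss_i) between members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import FitError
from .plsr import PLSModel, cross_validate, pls_predict

__all__ = ["EnsembleModel", "graded_loss", "adaboost_fit", "ensemble_predict"]


@dataclass
class EnsembleModel:
    members: List[PLSModel]
    weights: np.ndarray  # non-negative, sums to 1
    error_thresholds: Tuple[float, float] = (1.0, 1.5)
    training_errors: Optional[np.ndarray] = None  # weighted error per member

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return ensemble_predict(self, X_new)

    def to_dict(self) -> dict:
        return {
            "members": [m.to_dict() for m in self.members],
            "weights": self.weights.tolist(),
            "error_thresholds": list(self.error_thresholds),
            "training_errors": None
            if self.training_errors is None
            else self.training_errors.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        return cls(
            members=[PLSModel.from_dict(m) for m in d["members"]],
            weights=np.asarray(d["weights"], dtype=float),
            error_thresholds=tuple(d["error_thresholds"]),
            training_errors=None
            if d.get("training_errors") is None
            else np.asarray(d["training_errors"], dtype=float),
        )


def graded_loss(deviation: np.ndarray, t1: float, t2: float) -> np.ndarray:
    """Two-knot piecewise-linear loss in [0, 1] of |prediction error|."""
    d = np.abs(np.asarray(deviation, dtype=float))
    if not 0 < t1 < t2:
        raise FitError("thresholds must satisfy 0 < t1 < t2")
    loss = np.where(
        d <= t1,
        0.5 * d / t1,
        np.where(d <= t2, 0.5 + 0.5 * (d - t1) / (t2 - t1), 1.0),
    )
    return loss


def _member_cv_predictions(
    member: PLSModel, X_cal: np.ndarray, y_cal: np.ndarray, k: int, seed: int
) -> np.ndarray:
    """Out-of-fold calibration predictions for a member's variable subset."""
    Xm = X_cal[:, member.variable_indices]
    cv = cross_validate(
        Xm, y_cal, max_lv=member.n_lv, k=k, seed=seed, scale=False
    )
    return cv.oof_predictions[:, min(member.n_lv, cv.oof_predictions.shape[1]) - 1]


def adaboost_fit(
    members: Sequence[PLSModel],
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    thresholds: Tuple[float, float] = (1.0, 1.5),
    member_predictions: Optional[Sequence[np.ndarray]] = None,
    update_sample_weights: bool = False,
    k: int = 5,
    seed: int = 0,
) -> EnsembleModel:
    """Allocate combination weights over pre-built members.

    Deviations come from out-of-fold (cross-validated) calibration
    predictions so an overfitting member cannot dominate; pass
    ``member_predictions`` to supply them directly. Members with weighted
    error >= 0.5 are down-weighted toward zero with a warning; errors are
    floored at 1/(2n) to keep ln(1/beta) finite.
    """
    members = list(members)
    if len(members) < 1:
        raise FitError("need at least one member model")
    X_cal = np.atleast_2d(np.asarray(X_cal, dtype=float))
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    n = y_cal.size
    t1, t2 = thresholds
    if member_predictions is None:
        member_predictions = [
            _member_cv_predictions(m, X_cal, y_cal, k, seed) for m in members
        ]
    if len(member_predictions) != len(members):
        raise FitError("one prediction vector required per member")

    w = np.full(n, 1.0 / n)
    eps_floor = 1.0 / (2 * n)
    alphas = np.zeros(len(members))
    errors = np.zeros(len(members))
    for m, pred in enumerate(member_predictions):
        loss = graded_loss(pred - y_cal, t1, t2)
        eps = float(np.clip(w @ loss, eps_floor, 1.0 - eps_floor))
        errors[m] = eps
        if eps >= 0.5:
            warnings.warn(
                f"member {m} has weighted error {eps:.3f} >= 0.5; "
                "down-weighted toward zero",
                stacklevel=2,
            )
            alphas[m] = 0.0
            continue
        beta = eps / (1.0 - eps)
        alphas[m] = np.log(1.0 / beta)
        if update_sample_weights:
            w = w * beta ** (1.0 - loss)
            w = w / w.sum()

    total = alphas.sum()
    if total <= 0:
        warnings.warn("all members down-weighted; falling back to uniform",
                      stacklevel=2)
        weights = np.full(len(members), 1.0 / len(members))
    else:
        weights = alphas / total
    return EnsembleModel(
        members=members,
        weights=weights,
        error_thresholds=(t1, t2),
        training_errors=errors,
    )


def ensemble_predict(model: EnsembleModel, X_new: np.ndarray) -> np.ndarray:
    """Weighted linear combination of member predictions.

    ``X_new`` must span the full parent wavelength grid (each member slices
    its own ``variable_indices``). Because weights are a convex combination,
    every prediction lies within the member min/max envelope.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    n_cols = X_new.shape[1]
    for m, member in enumerate(model.members):
        missing = member.variable_indices[member.variable_indices >= n_cols]
        if missing.size:
            raise FitError(
                f"member {m} needs wavelength columns {missing.tolist()} "
                f"but X_new has only {n_cols}"
            )
    preds = np.stack([
        # ascontiguousarray keeps the BLAS path identical to a direct
        # prediction on X_new (bitwise-equal single-member ensembles)
        pls_predict(m, np.ascontiguousarray(X_new[:, m.variable_indices]))
        for m in model.members
    ])
    return model.weights @ preds
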
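"""PLS1 regression (NIPALS) with k-fold cross-validated latent-variable choice.

This is the base learner for every calibration model in the package. The
implementation is the classic single-response NIPALS with X-deflation only;
coefficients are folded back into the original (uncentered, unscaled)
variable space so a fitted model is just an affine map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .errors import FitError

__all__ = [
    "PLSModel",
    "CVResult",
    "pls_fit",
    "pls_predict",
    "coefficient_path",
    "cross_validate",
]


@dataclass
class PLSModel:
    """Fitted PLS1 model: ``yhat = intercept + X @ coefficients``."""

    n_lv: int
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    coefficients: np.ndarray  # original variable space
    intercept: float
    variable_indices: np.ndarray  # columns of the parent grid this model uses

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return pls_predict(self, X_new)

    def to_dict(self) -> dict:
        return {
            "n_lv": int(self.n_lv),
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": float(self.y_mean),
            "coefficients": self.coefficients.tolist(),
            "intercept": float(self.intercept),
            "variable_indices": self.variable_indices.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            n_lv=int(d["n_lv"]),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_sd=np.asarray(d["x_sd"], dtype=float),
            y_mean=float(d["y_mean"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            variable_indices=np.asarray(d["variable_indices"], dtype=int),
        )


def _nipals(X, y, n_lv, scale, strict):
    """NIPALS PLS1 decomposition (X-deflation only).

    Returns centering/scaling parameters and the (W, P, q) triplet. With
    ``strict=False`` the sweep stops early at rank exhaustion instead of
    raising, returning however many components were extracted.
    """
    n, p = X.shape
    x_mean = X.mean(axis=0)
    if scale:
        x_sd = X.std(axis=0, ddof=1)
        x_sd = np.where(x_sd > 0, x_sd, 1.0)
    else:
        x_sd = np.ones(p)
    y_mean = float(y.mean())
    E = (X - x_mean) / x_sd
    f = y - y_mean

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    a_done = 0
    for a in range(n_lv):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            if strict:
                raise FitError(
                    f"n_lv={n_lv} exceeds the effective rank of X (stalled "
                    f"at component {a + 1})"
                )
            break
        w /= norm
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-24:
            if strict:
                raise FitError(f"degenerate score vector at component {a + 1}")
            break
        P[:, a] = E.T @ t / tt
        q[a] = float(f @ t) / tt
        W[:, a] = w
        E = E - np.outer(t, P[:, a])
        a_done = a + 1
    return x_mean, x_sd, y_mean, W[:, :a_done], P[:, :a_done], q[:a_done]


def coefficient_path(
    X: np.ndarray, y: np.ndarray, max_lv: int, scale: bool = False
) -> tuple[np.ndarray, np.ndarray, float]:
    """Coefficients (original variable space) for every LV count 1..max_lv.

    Returns ``(B, intercepts, n_extracted)`` where column ``a`` of ``B`` is
    the coefficient vector of the (a+1)-component model. Components beyond
    the effective rank repeat the last valid column.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    x_mean, x_sd, y_mean, W, P, q = _nipals(X, y, max_lv, scale, strict=False)
    n_done = W.shape[1]
    if n_done == 0:
        raise FitError("X carries no covariance with y (rank 0 path)")
    p = X.shape[1]
    B = np.zeros((p, max_lv))
    R = np.linalg.solve(P.T @ W, np.eye(n_done))  # (P'W)^-1, lower-tri-ish
    for a in range(max_lv):
        a_eff = min(a + 1, n_done)
        beta_scaled = W[:, :a_eff] @ (R[:a_eff, :a_eff] @ q[:a_eff])
        B[:, a] = beta_scaled / x_sd
    intercepts = y_mean - x_mean @ B
    return B, intercepts, n_done


def pls_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    scale: bool = False,
    variable_indices: Optional[Sequence[int]] = None,
) -> PLSModel:
    """Fit a PLS1 model with ``n_lv`` latent variables.

    ``scale=True`` autoscales columns internally (unit sample SD); by default
    the caller is expected to standardize once upstream. ``variable_indices``
    records which columns of a parent wavelength grid ``X`` corresponds to
    (bookkeeping only; defaults to ``0..p-1``).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise FitError(f"y has length {y.size}, X has {n} rows")
    if n_lv < 1:
        raise FitError("n_lv must be >= 1")
    if n < n_lv + 1:
        raise FitError(f"need at least n_lv + 1 = {n_lv + 1} samples, got {n}")
    if np.std(y) == 0:
        raise FitError("zero-variance response")

    x_mean, x_sd, y_mean, W, P, q = _nipals(X, y, n_lv, scale, strict=True)
    # B = W (P'W)^-1 q in the scaled-centered space
    beta_scaled = W @ np.linalg.solve(P.T @ W, q)
    coefficients = beta_scaled / x_sd
    intercept = y_mean - float(x_mean @ coefficients)
    if variable_indices is None:
        variable_indices = np.arange(p)
    return PLSModel(
        n_lv=n_lv,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        coefficients=coefficients,
        intercept=intercept,
        variable_indices=np.asarray(variable_indices, dtype=int),
    )


def pls_predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.coefficients.size:
        raise FitError(
            f"X_new has {X_new.shape[1]} columns, model expects "
            f"{model.coefficients.size}"
        )
    return model.intercept + X_new @ model.coefficients


@dataclass
class CVResult:
    """Cross-validation summary for the latent-variable sweep."""

    rmsecv: np.ndarray  # RMSECV per LV, index a -> a+1 latent variables
    n_lv: int  # argmin of the curve (smaller LV wins ties)
    fold_assignment: np.ndarray  # fold id per sample
    r_cv: float  # Pearson r of out-of-fold predictions at n_lv
    mae_cv: float
    oof_predictions: np.ndarray = field(repr=False, default=None)  # (n, max_lv)

    @property
    def oof_at_best(self) -> np.ndarray:
        return self.oof_predictions[:, self.n_lv - 1]


def _make_folds(
    n: int, k: int, scheme: str, seed: Optional[int]
) -> np.ndarray:
    if scheme == "random":
        rng = np.random.default_rng(seed)
        assignment = np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))
        rng.shuffle(assignment)
        return assignment
    if scheme == "blocks":
        return (np.arange(n) * k) // n
    raise FitError(f"unknown fold scheme {scheme!r}")


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int = 15,
    k: int = 5,
    fold_scheme: str = "random",
    seed: Optional[int] = 0,
    scale: bool = False,
) -> CVResult:
    """k-fold cross-validation over latent-variable counts 1..max_lv.

    RMSECV(L) is computed from the concatenated out-of-fold predictions; the
    chosen n_lv minimizes the curve, with ties resolved toward the smaller
    count. ``max_lv`` is silently reduced if a training fold cannot support
    it (rank / sample-count limits).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if k < 2:
        raise FitError("k must be >= 2")
    if k > n:
        raise FitError(f"k={k} exceeds the number of samples ({n})")
    if max_lv < 1:
        raise FitError("max_lv must be >= 1")
    min_train = n - int(np.ceil(n / k))
    max_lv = min(max_lv, X.shape[1], min_train - 1)
    if max_lv < 1:
        raise FitError("too few samples per training fold for even 1 LV")

    assignment = _make_folds(n, k, fold_scheme, seed)
    oof = np.full((n, max_lv), np.nan)
    for fold in range(k):
        test = assignment == fold
        train = ~test
        Xtr, ytr = X[train], y[train]
        # one NIPALS sweep per fold yields the whole 1..max_lv path
        B, intercepts, _ = coefficient_path(Xtr, ytr, max_lv, scale=scale)
        oof[test, :] = X[test] @ B + intercepts[None, :]
    rmsecv = np.sqrt(np.mean((oof - y[:, None]) ** 2, axis=0))
    best = int(np.argmin(rmsecv)) + 1  # argmin returns first (smallest) index
    pred = oof[:, best - 1]
    r_cv = float(np.corrcoef(y, pred)[0, 1])
    mae_cv = float(np.mean(np.abs(pred - y)))
    return CVResult(
        rmsecv=rmsecv,
        n_lv=best,
        fold_assignment=assignment,
        r_cv=r_cv,
        mae_cv=mae_cv,
        oof_predictions=oof,
    )
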
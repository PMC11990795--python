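"""Uninformative variable elimination with noise augmentation, repeated runs
and frequency-tier stratification.

A single UVE run appends tiny-amplitude random columns to the (standardized)
spectra, refits a fixed-LV PLS model across k folds, and scores every real
variable by the stability of its fold-wise regression coefficients
(mean / SD). The cutoff is an empirical quantile of the |stability| of the
appended noise columns, so only variables provably steadier than noise
survive. Repeating the run R times with fresh noise yields per-wavelength
selection counts, which are bucketed into high / mid / low frequency tiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .errors import FitError
from .plsr import coefficient_path, cross_validate

__all__ = [
    "UVEConfig",
    "UVERunResult",
    "FrequencyProfile",
    "uve_run",
    "uve_repeat",
    "tier_partition",
]


@dataclass
class UVEConfig:
    n_noise: int = 200
    k_folds: int = 5
    confidence: float = 0.99
    noise_scale: float = 1e-10
    noise_distribution: str = "uniform"  # or "gaussian"
    n_runs: int = 100
    seed: int = 0
    t_high: int = 90
    t_low: int = 30
    max_lv: int = 15

    def __post_init__(self) -> None:
        if self.n_noise < 10:
            raise FitError("n_noise must be >= 10")
        if not 0.5 < self.confidence < 1.0:
            raise FitError("confidence must be in (0.5, 1)")
        if self.n_runs < 1:
            raise FitError("n_runs must be >= 1")
        if self.noise_distribution not in ("uniform", "gaussian"):
            raise FitError(f"unknown noise distribution {self.noise_distribution!r}")


@dataclass
class UVERunResult:
    stability: np.ndarray  # signed, per real variable
    noise_stability: np.ndarray  # per appended noise variable
    cutoff: float  # derived only from noise_stability
    selected: np.ndarray  # boolean mask over real variables
    n_lv_used: int


@dataclass
class FrequencyProfile:
    """Per-wavelength selection counts over repeated UVE runs."""

    counts: np.ndarray  # integer, in [0, n_runs]
    n_runs: int
    t_high: int = 90
    t_low: int = 30

    @property
    def tiers(self) -> np.ndarray:
        """Label per wavelength: 'high', 'mid', 'low' or 'never'.

        high: count >= t_high; mid: t_low <= count < t_high;
        low: 1 <= count < t_low; never: count == 0. Disjoint and exhaustive.
        """
        c = self.counts
        labels = np.full(c.size, "never", dtype=object)
        labels[(c >= 1) & (c < self.t_low)] = "low"
        labels[(c >= self.t_low) & (c < self.t_high)] = "mid"
        labels[c >= self.t_high] = "high"
        return labels

    def to_dict(self) -> dict:
        high, mid, low = tier_partition(self)
        return {
            "counts": self.counts.tolist(),
            "n_runs": int(self.n_runs),
            "t_high": int(self.t_high),
            "t_low": int(self.t_low),
            "high": high.tolist(),
            "mid": mid.tolist(),
            "low": low.tolist(),
        }


def _fold_assignment(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    sizes = np.diff(np.linspace(0, n, k + 1).astype(int))
    assignment = np.repeat(np.arange(k), sizes)
    rng.shuffle(assignment)
    return assignment


def uve_run(
    X: np.ndarray,
    y: np.ndarray,
    config: UVEConfig,
    run_seed: int,
    n_lv: int,
) -> UVERunResult:
    """One UVE pass: noise augmentation, fold-wise refits, stability cutoff.

    ``X`` is expected already standardized; ``n_lv`` is the latent-variable
    count (typically the cross-validated optimum of the full-variable model,
    fixed across repeated runs). Internal PLS fits never autoscale, so the
    tiny noise columns cannot influence the fit — only their coefficient
    statistics are used, to calibrate the cutoff.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < config.k_folds:
        raise FitError(f"need at least k_folds={config.k_folds} samples, got {n}")
    rng = np.random.default_rng(run_seed)
    if config.noise_distribution == "gaussian":
        noise = rng.normal(0.0, 1.0, size=(n, config.n_noise))
    else:
        noise = rng.uniform(0.0, 1.0, size=(n, config.n_noise))
    Xa = np.hstack([X, noise * config.noise_scale])

    assignment = _fold_assignment(n, config.k_folds, rng)
    coefs = np.zeros((config.k_folds, p + config.n_noise))
    for fold in range(config.k_folds):
        train = assignment != fold
        lv = min(n_lv, int(train.sum()) - 1)
        B, _, _ = coefficient_path(Xa[train], y[train], lv, scale=False)
        coefs[fold] = B[:, lv - 1]

    mean = coefs.mean(axis=0)
    sd = coefs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stab = np.where(sd > 0, mean / sd, np.sign(mean) * np.inf)
    stab = np.nan_to_num(stab, nan=0.0, posinf=np.inf, neginf=-np.inf)
    stability, noise_stability = stab[:p], stab[p:]

    finite_noise = np.abs(noise_stability[np.isfinite(noise_stability)])
    if finite_noise.size == 0:
        raise FitError("noise stability degenerate; cannot calibrate a cutoff")
    cutoff = float(np.quantile(finite_noise, config.confidence, method="lower"))
    selected = np.abs(stability) > cutoff
    if not selected.any():
        warnings.warn("UVE eliminated every variable", stacklevel=2)
    return UVERunResult(
        stability=stability,
        noise_stability=noise_stability,
        cutoff=cutoff,
        selected=selected,
        n_lv_used=n_lv,
    )


def uve_repeat(
    X: np.ndarray,
    y: np.ndarray,
    config: UVEConfig,
    n_lv: Optional[int] = None,
) -> Tuple[List[UVERunResult], FrequencyProfile]:
    """Run UVE ``config.n_runs`` times and tally per-wavelength selections.

    The internal LV count is the cross-validated optimum of the
    full-variable model, computed once and shared by all runs (pass ``n_lv``
    to skip that step). Per-run seeds are spawned from ``config.seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if n_lv is None:
        cv = cross_validate(
            X, y, max_lv=config.max_lv, k=config.k_folds, seed=config.seed
        )
        n_lv = cv.n_lv
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    runs = [
        uve_run(X, y, config, run_seed=s, n_lv=n_lv)  # type: ignore[arg-type]
        for s in seeds
    ]
    counts = np.sum([r.selected for r in runs], axis=0).astype(int)
    profile = FrequencyProfile(
        counts=counts,
        n_runs=config.n_runs,
        t_high=config.t_high,
        t_low=config.t_low,
    )
    return runs, profile


def tier_partition(
    profile: FrequencyProfile,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split wavelength indices into (high, mid, low) frequency tiers.

    Never-selected wavelengths appear in no tier. Warns when the high tier
    is empty (the leading member model would have no variables).
    """
    c = profile.counts
    high = np.flatnonzero(c >= profile.t_high)
    mid = np.flatnonzero((c >= profile.t_low) & (c < profile.t_high))
    low = np.flatnonzero((c >= 1) & (c < profile.t_low))
    if high.size == 0:
        warnings.warn("high-frequency tier is empty", stacklevel=2)
    return high, mid, low
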
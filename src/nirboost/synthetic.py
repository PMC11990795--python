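"""Synthetic NIR fruit spectra with a known analyte signal.

Spectra are sums of broad Gaussian absorption bands on a 1000-2500 nm grid.
Bands flagged *informative* have amplitudes affine in the response, so the
ground-truth informative wavelengths are known exactly; the rest of the
generative model (per-sample baseline offset, multiplicative scatter,
heteroscedastic noise, optional planted outliers) mimics the nuisance
structure of diffuse-reflectance fruit spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .dataio import SpectraSet
from .errors import SpectraValidationError

__all__ = ["Band", "SimConfig", "SimTruth", "simulate", "plant_outliers"]


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band."""

    center: float  # nm
    width: float  # nm (Gaussian sigma)
    amplitude: float
    informative: bool = False


#: Band loci follow the C-H / O-H / C-O overtone and combination regions that
#: dominate fruit NIR spectra; three are coupled to the response.
DEFAULT_BANDS: Tuple[Band, ...] = (
    Band(center=1200.0, width=60.0, amplitude=0.6, informative=False),
    Band(center=1450.0, width=40.0, amplitude=1.0, informative=True),
    Band(center=1650.0, width=40.0, amplitude=0.8, informative=True),
    Band(center=1950.0, width=50.0, amplitude=1.2, informative=True),
)


@dataclass
class SimConfig:
    n_samples: int = 189
    wl_start: float = 1000.0
    wl_end: float = 2500.0
    n_points: int = 1557
    bands: Tuple[Band, ...] = DEFAULT_BANDS
    y_range: Tuple[float, float] = (14.6, 28.5)
    baseline_sd: float = 0.02
    scatter_sd: float = 0.02
    noise_sd: float = 0.12
    #: heteroscedasticity: noise SD scales as noise_sd * (1 + noise_het *
    #: |clean signal|); set 0 for iid noise
    noise_het: float = 1.0
    #: relative SD of sample-wise amplitude variation of *uninformative*
    #: bands (e.g. water-band strength varying independently of the analyte)
    uninformative_jitter: float = 0.0
    #: SD (nm) of sample-wise center shifts of uninformative bands — a
    #: high-rank nuisance (cf. temperature-driven water-band shifts) that
    #: penalizes models retaining those spectral regions
    uninformative_center_jitter: float = 0.0
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise SpectraValidationError("n_samples must be positive")
        if self.n_points < len(self.bands):
            raise SpectraValidationError(
                f"n_points={self.n_points} < number of bands ({len(self.bands)})"
            )
        if min(self.baseline_sd, self.scatter_sd, self.noise_sd) < 0:
            raise SpectraValidationError("noise SDs must be non-negative")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise SpectraValidationError("outlier_fraction must be in [0, 1)")
        lo, hi = self.y_range
        if hi > lo and not any(b.informative for b in self.bands):
            raise SpectraValidationError(
                "at least one band must be informative for a non-degenerate y_range"
            )

    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_start, self.wl_end, self.n_points)


@dataclass
class SimTruth:
    """Ground truth attached to a simulated dataset."""

    informative_indices: np.ndarray = field(default_factory=lambda: np.array([], int))
    outlier_indices: np.ndarray = field(default_factory=lambda: np.array([], int))

    def to_dict(self) -> dict:
        return {
            "informative_indices": self.informative_indices.tolist(),
            "outlier_indices": self.outlier_indices.tolist(),
        }


def _band_profiles(wl: np.ndarray, bands: Tuple[Band, ...]) -> np.ndarray:
    centers = np.array([b.center for b in bands])
    widths = np.array([b.width for b in bands])
    return np.exp(-0.5 * ((wl[None, :] - centers[:, None]) / widths[:, None]) ** 2)


def simulate(config: SimConfig) -> Tuple[SpectraSet, SimTruth]:
    """Draw a reproducible synthetic dataset from ``config``.

    For sample i: ``x_i = baseline_i + scatter_i * sum_b a_b(y_i) g_b(wl) +
    noise``, where informative-band amplitudes are affine in ``y_i``
    (``a_b(y) = amplitude_b * (0.5 + (y - lo)/(hi - lo))``), the response is
    uniform on ``y_range``, scatter is log-normal with median 1 and the noise
    SD scales with local signal strength (heteroscedastic), reducing to
    ``noise_sd`` where the structure is flat.
    """
    rng = np.random.default_rng(config.seed)
    wl = config.wavelengths()
    n = config.n_samples
    lo, hi = config.y_range
    y = rng.uniform(lo, hi, size=n)

    profiles = _band_profiles(wl, config.bands)  # (n_bands, p)
    clean = np.zeros((n, wl.size))
    for b, band in enumerate(config.bands):
        if band.informative and hi > lo:
            amp = band.amplitude * (0.5 + (y - lo) / (hi - lo))
        elif config.uninformative_jitter > 0:
            amp = band.amplitude * (
                1.0 + config.uninformative_jitter * rng.normal(size=n)
            )
        else:
            amp = np.full(n, band.amplitude)
        cj = config.uninformative_center_jitter
        if not band.informative and cj > 0:
            centers = band.center + cj * rng.normal(size=n)
            prof = np.exp(
                -0.5 * ((wl[None, :] - centers[:, None]) / band.width) ** 2
            )
            clean += amp[:, None] * prof
        else:
            clean += np.outer(amp, profiles[b])

    baseline = rng.normal(0.0, config.baseline_sd, size=(n, 1))
    scatter = rng.lognormal(0.0, config.scatter_sd, size=(n, 1)) \
        if config.scatter_sd > 0 else np.ones((n, 1))
    noise_scale = config.noise_sd * (1.0 + config.noise_het * np.abs(clean))
    noise = rng.normal(0.0, 1.0, size=clean.shape) * noise_scale
    X = baseline + scatter * clean + noise

    informative = np.zeros(wl.size, dtype=bool)
    for band in config.bands:
        if band.informative:
            informative |= np.abs(wl - band.center) <= band.width
    truth = SimTruth(informative_indices=np.flatnonzero(informative))

    ds = SpectraSet(wavelengths=wl, X=X, y=y)
    if config.outlier_fraction > 0:
        ds, out_idx = plant_outliers(
            ds,
            fraction=config.outlier_fraction,
            magnitude=config.outlier_magnitude,
            seed=int(rng.integers(2**31)),
        )
        truth.outlier_indices = out_idx
    return ds, truth


def plant_outliers(
    ds: SpectraSet,
    fraction: float,
    magnitude: float,
    seed: int = 0,
) -> Tuple[SpectraSet, np.ndarray]:
    """Perturb ``ceil(fraction * n)`` rows with gross artifacts.

    Rows alternate between two contamination classes: a flat baseline jump
    (a leverage point in the score space) and an injected spurious band (an
    orthogonal-residual point off the clean PCA plane). ``magnitude = 0``
    returns the input unchanged. Returns the perturbed copy and the exact,
    sorted perturbed row indices.
    """
    if not 0.0 < fraction < 0.5:
        raise SpectraValidationError(
            "fraction must be in (0, 0.5): robust screening assumes minority "
            "contamination"
        )
    rng = np.random.default_rng(seed)
    n = ds.n_samples
    m = int(np.ceil(fraction * n))
    indices = np.sort(rng.choice(n, size=m, replace=False))
    X = ds.X.copy()
    wl = ds.wavelengths
    span = wl[-1] - wl[0] if wl.size > 1 else 1.0
    # spurious band parked away from the mid-grid structure
    ghost_center = wl[0] + 0.87 * span
    ghost = np.exp(-0.5 * ((wl - ghost_center) / (span / 40.0)) ** 2)
    for rank, i in enumerate(indices):
        if rank % 2 == 0:
            X[i] = X[i] + magnitude
        else:
            X[i] = X[i] + magnitude * ghost
    out = SpectraSet(
        wavelengths=wl.copy(),
        X=X,
        y=None if ds.y is None else ds.y.copy(),
        ids=list(ds.ids),
    )
    return out, indices
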
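"""Spectra dataset container and on-disk round-tripping.

The canonical on-disk layout is a wide CSV: one row per sample, an ``id``
column, one numeric column per wavelength (header value is the wavelength in
nm, ascending), and an optional trailing ``y`` response column. Model
artifacts are versioned single-file JSON containers.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ModelIOError, SpectraFormatError, SpectraValidationError

__all__ = [
    "SpectraSet",
    "read_spectra",
    "write_spectra",
    "save_model",
    "load_model",
]

ARTIFACT_FORMAT_VERSION = 1


@dataclass
class SpectraSet:
    """A spectra matrix with its wavelength grid and optional response.

    Parameters
    ----------
    wavelengths : (p,) array
        Strictly increasing positions in nm.
    X : (n, p) array
        Spectral values (reflectance or absorbance), unitless.
    y : (n,) array, optional
        Response values (e.g. total soluble solids, °Brix).
    ids : sequence of str, optional
        Unique sample identifiers; defaults to ``s0001``-style labels.
    """

    wavelengths: np.ndarray
    X: np.ndarray
    y: Optional[np.ndarray] = None
    ids: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
        if not self.ids:
            self.ids = [f"s{i + 1:04d}" for i in range(self.X.shape[0])]
        self.ids = list(map(str, self.ids))
        self.validate()

    def validate(self) -> None:
        if self.wavelengths.ndim != 1:
            raise SpectraValidationError("wavelengths must be a 1-D vector")
        if self.X.ndim != 2:
            raise SpectraValidationError("X must be a 2-D matrix")
        n, p = self.X.shape
        if p != self.wavelengths.size:
            raise SpectraValidationError(
                f"X has {p} columns but {self.wavelengths.size} wavelengths given"
            )
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise SpectraValidationError("wavelengths must be strictly increasing")
        if np.isnan(self.X).any():
            raise SpectraValidationError("X contains NaN")
        if self.y is not None:
            if self.y.ndim != 1 or self.y.size != n:
                raise SpectraValidationError(
                    f"y has length {self.y.size}, expected {n}"
                )
            if np.isnan(self.y).any():
                raise SpectraValidationError("y contains NaN")
        if len(self.ids) != n:
            raise SpectraValidationError(f"{len(self.ids)} ids for {n} samples")
        if len(set(self.ids)) != n:
            raise SpectraValidationError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.X.shape[1]

    def subset(self, indices: Sequence[int]) -> "SpectraSet":
        """Row subset (copying), preserving wavelength grid and y slices."""
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            wavelengths=self.wavelengths.copy(),
            X=self.X[idx].copy(),
            y=None if self.y is None else self.y[idx].copy(),
            ids=[self.ids[i] for i in idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectraSet):
            return NotImplemented
        same_y = (self.y is None and other.y is None) or (
            self.y is not None
            and other.y is not None
            and np.array_equal(self.y, other.y)
        )
        return (
            np.array_equal(self.wavelengths, other.wavelengths)
            and np.array_equal(self.X, other.X)
            and same_y
            and list(self.ids) == list(other.ids)
        )


def read_spectra(path: str | os.PathLike) -> SpectraSet:
    """Read a wide-CSV spectra file into a :class:`SpectraSet`.

    Header must be ``id,<wl_1>,...,<wl_p>[,y]`` with numeric wavelength
    labels. Row order is preserved.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SpectraFormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 2 or df.columns[0] != "id":
        raise SpectraFormatError(
            f"{path}: first column must be 'id', got {df.columns[0]!r}"
        )
    cols = list(df.columns[1:])
    has_y = cols and cols[-1] == "y"
    wl_cols = cols[:-1] if has_y else cols
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise SpectraFormatError(
            f"{path}: non-numeric wavelength in header: {exc}"
        ) from exc
    ids = df["id"].astype(str).tolist()
    for name in wl_cols + (["y"] if has_y else []):
        bad = df[name].map(lambda v: not _is_number(v))
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise SpectraFormatError(
                f"{path}: non-numeric cell at row {row}, column {name!r}"
            )
    X = df[wl_cols].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float) if has_y else None
    if X.shape[0] == 0:
        X = X.reshape(0, len(wl_cols))
    return SpectraSet(wavelengths=wavelengths, X=X, y=y, ids=ids)


def _is_number(v: object) -> bool:
    try:
        float(v)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False


def write_spectra(ds: SpectraSet, path: str | os.PathLike) -> str:
    """Write ``ds`` as a wide CSV (id, wavelengths ascending, y last).

    Uses ``repr``-precision floats so ``read_spectra(write_spectra(ds)) == ds``
    bitwise.
    """
    ds.validate()
    # floats are written via repr (shortest round-trip form): pandas' own
    # CSV float formatter is not bit-exact
    cols: dict[str, object] = {"id": list(ds.ids)}
    for j, wl in enumerate(ds.wavelengths):
        cols[repr(float(wl))] = [repr(float(v)) for v in ds.X[:, j]]
    if ds.y is not None:
        cols["y"] = [repr(float(v)) for v in ds.y]
    df = pd.DataFrame(cols, columns=list(cols), index=range(ds.n_samples))
    df.to_csv(path, index=False)
    return str(path)


def _model_to_dict(model) -> dict:
    # local imports avoid a circular dependency at module load
    from .ensemble import EnsembleModel
    from .plsr import PLSModel

    if isinstance(model, PLSModel):
        return {"kind": "pls", **model.to_dict()}
    if isinstance(model, EnsembleModel):
        return {"kind": "ensemble", **model.to_dict()}
    raise TypeError(f"unsupported model type: {type(model).__name__}")


def save_model(model, path: str | os.PathLike) -> str:
    """Serialize a fitted PLS or ensemble model to a versioned JSON artifact."""
    payload = {"format_version": ARTIFACT_FORMAT_VERSION, **_model_to_dict(model)}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)
    return str(path)


def load_model(path: str | os.PathLike):
    """Load a model artifact saved by :func:`save_model`.

    Reloaded models predict identically to the originals (floats are stored
    via JSON ``repr`` round-trip, which is exact for IEEE doubles).
    """
    from .ensemble import EnsembleModel
    from .plsr import PLSModel

    try:
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelIOError(f"corrupt model artifact {path}: {exc}") from exc
    version = payload.get("format_version")
    if version != ARTIFACT_FORMAT_VERSION:
        raise ModelIOError(
            f"{path}: artifact format version {version!r}, "
            f"expected {ARTIFACT_FORMAT_VERSION}"
        )
    kind = payload.get("kind")
    if kind == "pls":
        return PLSModel.from_dict(payload)
    if kind == "ensemble":
        return EnsembleModel.from_dict(payload)
    raise ModelIOError(f"{path}: unknown model kind {kind!r}")
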
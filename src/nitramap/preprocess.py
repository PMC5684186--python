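"""Spectral pretreatments: SNV, gap-segment derivative, cropping, recipes.

Each pretreatment is a scikit-learn compatible, stateless transformer so
pretreatment chains compose with :class:`sklearn.pipeline.Pipeline`; the
plain functions below are thin wrappers.  A :class:`PreprocessRecipe` is the
serializable form attached to a fitted calibration model: an ordered list of
steps that transforms both a spectrum matrix and its wavelength axis.

Conventions, stated because chemometrics codes disagree on them:

* SNV uses the sample (n-1) standard deviation.
* The gap-segment derivative averages two ``segment``-point windows
  separated by ``gap`` bands and divides by the center-to-center separation
  ``segment + gap`` in index units, so a unit-slope line yields exactly 1.
* Edges shrink (no padding): the output has ``n - 2*segment - gap + 1``
  bands, each a pure function of observed data, and the wavelength axis
  shrinks to the window midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .cube import HyperCube, LeafMask

__all__ = [
    "SpectrumMatrix",
    "PreprocessRecipe",
    "StandardNormalVariate",
    "GapSegmentDerivative",
    "WavelengthCropper",
    "snv",
    "gap_segment_first_derivative",
    "mean_spectrum",
    "apply_recipe",
]


@dataclass
class SpectrumMatrix:
    """n_samples x n_bands spectra with a shared wavelength axis (nm)."""

    values: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"{self.values.shape[1]} columns vs {self.wavelengths.size} wavelengths"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectra must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]


class StandardNormalVariate(TransformerMixin, BaseEstimator):
    """Row-wise centering and scaling to unit sample standard deviation.

    Removes per-spectrum multiplicative scatter and additive offset. Raises
    on any zero-variance row (a flat spectrum carries no SNV-normalizable
    signal), naming the offending row.
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        sd = X.std(axis=1, ddof=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(f"SNV undefined for zero-variance spectrum row(s) {bad.tolist()}")
        return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


class GapSegmentDerivative(TransformerMixin, BaseEstimator):
    """Gap-segment first derivative (noise-robust finite difference).

    For each output band the mean of the trailing ``segment`` points is
    subtracted from the mean of the leading ``segment`` points, with ``gap``
    bands skipped between the windows, and the difference divided by the
    center-to-center separation ``segment + gap`` (index units).
    """

    def __init__(self, gap: int = 1, segment: int = 2):
        self.gap = gap
        self.segment = segment

    def _check(self, n_bands: int) -> int:
        if self.gap < 1 or self.segment < 1:
            raise ValueError("gap and segment must both be >= 1")
        span = 2 * self.segment + self.gap
        if n_bands < span:
            raise ValueError(
                f"derivative window (span {span}) does not fit {n_bands} bands"
            )
        return span

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        span = self._check(X.shape[1])
        g, s = self.gap, self.segment
        csum = np.cumsum(np.concatenate([np.zeros((X.shape[0], 1)), X], axis=1), axis=1)
        n_out = X.shape[1] - span + 1
        idx = np.arange(n_out)
        lower = (csum[:, idx + s] - csum[:, idx]) / s
        upper = (csum[:, idx + span] - csum[:, idx + s + g]) / s
        return (upper - lower) / (s + g)

    def transform_wavelengths(self, wavelengths: np.ndarray) -> np.ndarray:
        """Shrink a wavelength axis to the midpoints of the derivative spans."""
        w = np.asarray(wavelengths, dtype=float)
        span = self._check(w.size)
        return 0.5 * (w[: w.size - span + 1] + w[span - 1 :])


class WavelengthCropper(TransformerMixin, BaseEstimator):
    """Keep the bands whose wavelength lies in a closed interval [lo, hi] nm."""

    def __init__(self, lo_nm: float, hi_nm: float, wavelengths=None):
        self.lo_nm = lo_nm
        self.hi_nm = hi_nm
        self.wavelengths = wavelengths

    def _keep(self, wavelengths) -> np.ndarray:
        w = np.asarray(wavelengths, dtype=float)
        keep = (w >= self.lo_nm) & (w <= self.hi_nm)
        if not keep.any():
            raise ValueError(f"no band inside [{self.lo_nm}, {self.hi_nm}] nm")
        return keep

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        if self.wavelengths is None:
            raise ValueError("WavelengthCropper.transform requires wavelengths")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X[:, self._keep(self.wavelengths)]

    def transform_wavelengths(self, wavelengths: np.ndarray) -> np.ndarray:
        w = np.asarray(wavelengths, dtype=float)
        return w[self._keep(w)]


# ---------------------------------------------------------------------------
# Function wrappers on SpectrumMatrix
# ---------------------------------------------------------------------------

def snv(m: SpectrumMatrix) -> SpectrumMatrix:
    """Standard normal variate, row-wise; wavelength axis unchanged."""
    return SpectrumMatrix(StandardNormalVariate().transform(m.values), m.wavelengths)


def gap_segment_first_derivative(m: SpectrumMatrix, gap: int = 1, segment: int = 2) -> SpectrumMatrix:
    t = GapSegmentDerivative(gap=gap, segment=segment)
    return SpectrumMatrix(t.transform(m.values), t.transform_wavelengths(m.wavelengths))


def mean_spectrum(cube: HyperCube, region: LeafMask | np.ndarray) -> SpectrumMatrix:
    """Per-band arithmetic mean over a pixel region, excluding invalid pixels."""
    mask = region.mask if isinstance(region, LeafMask) else np.asarray(region, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("region shape does not match cube spatial dims")
    if not mask.any():
        raise ValueError("empty region")
    px = cube.data[mask]  # (n_pixels, bands)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(px, axis=0)
    if not np.all(np.isfinite(mean)):
        raise ValueError("region has bands with no valid pixel")
    return SpectrumMatrix(mean[np.newaxis, :], cube.wavelengths)


# ---------------------------------------------------------------------------
# Recipes
# ---------------------------------------------------------------------------

_STEP_NAMES = ("crop", "snv", "derivative")


@dataclass
class PreprocessRecipe:
    """Ordered, serializable chain of pretreatment steps.

    Steps are ``("crop", {"lo_nm": .., "hi_nm": ..})``, ``("snv", {})`` and
    ``("derivative", {"gap": .., "segment": ..})``. The default calibration
    recipe crops to 932.1-2,217.8 nm, applies SNV, then the gap=1/segment=2
    first derivative.
    """

    steps: list[tuple[str, dict[str, Any]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, params in self.steps:
            if name not in _STEP_NAMES:
                raise ValueError(f"unknown recipe step {name!r}")
            dict(params)  # must be mapping

    @classmethod
    def default(cls) -> "PreprocessRecipe":
        return cls(
            steps=[
                ("crop", {"lo_nm": 932.1, "hi_nm": 2217.8}),
                ("snv", {}),
                ("derivative", {"gap": 1, "segment": 2}),
            ]
        )

    def apply(self, values: np.ndarray, wavelengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Apply all steps in order; returns (values, wavelengths)."""
        X = np.atleast_2d(np.asarray(values, dtype=float))
        w = np.asarray(wavelengths, dtype=float)
        for name, params in self.steps:
            if name == "crop":
                t = WavelengthCropper(params["lo_nm"], params["hi_nm"], wavelengths=w)
                X, w = t.transform(X), t.transform_wavelengths(w)
            elif name == "snv":
                X = StandardNormalVariate().transform(X)
            else:
                t = GapSegmentDerivative(gap=params.get("gap", 1), segment=params.get("segment", 2))
                X, w = t.transform(X), t.transform_wavelengths(w)
        return X, w

    def to_dict(self) -> dict:
        return {"steps": [[name, dict(params)] for name, params in self.steps]}

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessRecipe":
        return cls(steps=[(name, dict(params)) for name, params in d["steps"]])


def apply_recipe(m: SpectrumMatrix, recipe: PreprocessRecipe) -> SpectrumMatrix:
    values, wavelengths = recipe.apply(m.values, m.wavelengths)
    return SpectrumMatrix(values, wavelengths)
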
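"""Pixel-wise application of a fitted calibration model: nitrate maps.

Every in-mask pixel spectrum is run through the model's stored preprocessing
recipe and predicted, yielding a 2-D mg/kg field over the leaf. Predictions
are clipped to a configurable range (PLS extrapolates freely at veins and
petioles, which exceed the blade-only calibration range) with the clipped
pixel count recorded. Maps render as false-color PNGs with a lossless CSV
matrix alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .chemometrics import NIPALSPLS
from .cube import HyperCube, LeafMask
from .destripe import ALONG_TRACK, smooth_map as _smooth_values
from .preprocess import PreprocessRecipe

__all__ = [
    "CalibrationModel",
    "ConcentrationMap",
    "map_concentration",
    "region_mean",
    "smooth_concentration_map",
    "render_map",
]


@dataclass
class CalibrationModel:
    """A fitted PLS model bundled with its preprocessing recipe and axis.

    The recipe is applied to *raw reflectance* spectra on the cube's native
    wavelength axis; ``wavelengths`` records that training axis so axis
    mismatches are caught before prediction.
    """

    pls: NIPALSPLS
    recipe: PreprocessRecipe
    wavelengths: np.ndarray
    calibration_max_mg_per_kg: float | None = None

    def predict_spectra(self, values: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
        w = np.asarray(wavelengths, dtype=float)
        if w.size != self.wavelengths.size or not np.allclose(w, self.wavelengths):
            raise ValueError("spectra wavelength axis differs from the training axis")
        Xp, _ = self.recipe.apply(values, w)
        return self.pls.predict(Xp)

    def to_json(self, path) -> None:
        m = self.pls
        payload = {
            "recipe": self.recipe.to_dict(),
            "wavelengths": self.wavelengths.tolist(),
            "calibration_max_mg_per_kg": self.calibration_max_mg_per_kg,
            "n_factors": m.n_factors_,
            "x_mean": m.x_mean_.tolist(),
            "y_mean": m.y_mean_,
            "x_weights": m.x_weights_.tolist(),
            "x_loadings": m.x_loadings_.tolist(),
            "y_loadings": m.y_loadings_.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            d = json.load(fh)
        m = NIPALSPLS(n_factors=d["n_factors"])
        m.x_mean_ = np.array(d["x_mean"])
        m.y_mean_ = float(d["y_mean"])
        m.x_weights_ = np.array(d["x_weights"])
        m.x_loadings_ = np.array(d["x_loadings"])
        m.y_loadings_ = np.array(d["y_loadings"])
        m.n_factors_ = int(d["n_factors"])
        m._rotation_ = m.x_weights_ @ np.linalg.inv(
            np.triu(m.x_loadings_.T @ m.x_weights_)
        )
        m.coef_ = m._rotation_ @ m.y_loadings_
        return cls(
            pls=m,
            recipe=PreprocessRecipe.from_dict(d["recipe"]),
            wavelengths=np.array(d["wavelengths"]),
            calibration_max_mg_per_kg=d.get("calibration_max_mg_per_kg"),
        )


@dataclass
class ConcentrationMap:
    """2-D nitrate field (mg/kg) defined inside a leaf mask; NaN outside."""

    values: np.ndarray
    mask: LeafMask
    clip_bounds: tuple[float, float] | None = None
    n_clipped: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.mask.shape:
            raise ValueError("map and mask shapes differ")

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",", fmt="%.6g")

    @classmethod
    def values_from_csv(cls, path) -> np.ndarray:
        return np.loadtxt(path, delimiter=",", ndmin=2)


def default_clip_bounds(calibration_max: float) -> tuple[float, float]:
    """[0, 1.5 x calibration max]: tolerate vein/petiole extrapolation, bound it."""
    return (0.0, 1.5 * calibration_max)


def map_concentration(
    cube: HyperCube,
    model: CalibrationModel,
    mask: LeafMask,
    clip_bounds: tuple[float, float] | None = "auto",
    block_rows: int = 32,
) -> ConcentrationMap:
    """Predict nitrate per in-mask pixel of a reflectance cube.

    Pixels stream through in blocks of ``block_rows`` image rows, so cubes
    larger than memory can be mapped; results are independent of block size.
    ``clip_bounds='auto'`` derives [0, 1.5 x calibration max] from the model
    when available, ``None`` disables clipping.
    """
    if cube.kind != "reflectance":
        raise ValueError("map_concentration expects a reflectance cube")
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask does not match cube spatial dims")
    if mask.n_leaf_pixels == 0:
        raise ValueError("empty leaf mask")
    if clip_bounds == "auto":
        clip_bounds = (
            default_clip_bounds(model.calibration_max_mg_per_kg)
            if model.calibration_max_mg_per_kg is not None
            else None
        )
    out = np.full(mask.shape, np.nan)
    n_clipped = 0
    for r0 in range(0, cube.shape[0], block_rows):
        sl = slice(r0, min(r0 + block_rows, cube.shape[0]))
        block_mask = mask.mask[sl]
        if not block_mask.any():
            continue
        spectra = cube.data[sl][block_mask]
        valid = np.all(np.isfinite(spectra), axis=1)
        preds = np.full(spectra.shape[0], np.nan)
        if valid.any():
            preds[valid] = model.predict_spectra(spectra[valid], cube.wavelengths)
        if clip_bounds is not None:
            lo, hi = clip_bounds
            n_clipped += int(np.sum((preds < lo) | (preds > hi)))
            preds = np.clip(preds, lo, hi)
        block_out = np.full(block_mask.shape, np.nan)
        block_out[block_mask] = preds
        out[sl] = block_out
    return ConcentrationMap(
        values=out,
        mask=mask,
        clip_bounds=clip_bounds,
        n_clipped=n_clipped,
        provenance={"recipe": model.recipe.to_dict(), "n_factors": model.pls.n_factors_},
    )


def region_mean(cmap: ConcentrationMap, region: LeafMask | np.ndarray) -> float:
    """Arithmetic mean of map values over a pixel region inside the leaf mask."""
    rmask = region.mask if isinstance(region, LeafMask) else np.asarray(region, bool)
    sel = rmask & cmap.mask.mask & np.isfinite(cmap.values)
    if not sel.any():
        raise ValueError("region does not intersect the mapped leaf")
    return float(cmap.values[sel].mean())


def smooth_concentration_map(
    cmap: ConcentrationMap, window: int, stripe_axis: str = ALONG_TRACK
) -> ConcentrationMap:
    """Stripe smoothing filter (directional moving average) on the map."""
    sm = _smooth_values(cmap.values, cmap.mask.mask, window, stripe_axis)
    return ConcentrationMap(sm, cmap.mask, cmap.clip_bounds, cmap.n_clipped,
                            dict(cmap.provenance, smoothed_window=window))


def render_map(cmap: ConcentrationMap, out_path, palette: str = "jet",
               vmin: float | None = None, vmax: float | None = None) -> None:
    """False-color PNG with a colorbar; lossless CSV matrix written alongside.

    Background (out-of-mask) pixels render neutral gray. The CSV shares the
    PNG's basename with a ``.csv`` suffix.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from pathlib import Path

    out_path = Path(out_path)
    vals = np.where(cmap.mask.mask, cmap.values, np.nan)
    fig, ax = plt.subplots(figsize=(6, 5))
    cm = plt.get_cmap(palette).copy()
    cm.set_bad(color="0.85")
    im = ax.imshow(vals, cmap=cm, vmin=vmin, vmax=vmax, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="nitrate (mg/kg)")
    ax.set_axis_off()
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    cmap.to_csv(out_path.with_suffix(".csv"))
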
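"""Hyperspectral cube container, ENVI-style I/O, reflectance calibration and leaf masking.

A push-broom NIR line-scan instrument produces a 3-D cube with two spatial
axes (scan lines x detector columns) and one wavelength axis (here nominally
256 bands over 913-2,519 nm at a ~6.2 nm step, 156 um square pixels).  Raw
intensities are converted to relative reflectance against a white-plate scan
and a dark (capped-lens) scan:

    R = (S - B) / (W - B)

per pixel and band.  Pixels where the white and dark references coincide are
flagged invalid (NaN) rather than propagated as infinities.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "HyperCube",
    "ReferencePair",
    "LeafMask",
    "CubeFormatError",
    "CubeIntegrityError",
    "EmptyMaskWarning",
    "read_envi_cube",
    "write_envi_cube",
    "compute_reflectance",
    "crop_wavelengths",
    "segment_leaf",
]


class CubeFormatError(ValueError):
    """Raised when an ENVI header is missing, unparseable, or incomplete."""


class CubeIntegrityError(ValueError):
    """Raised when header metadata and binary payload disagree."""


class EmptyMaskWarning(UserWarning):
    """Emitted when leaf segmentation finds no foreground pixels."""


@dataclass
class HyperCube:
    """A (rows, cols, bands) intensity or reflectance cube with a wavelength axis.

    Parameters
    ----------
    data : ndarray, shape (rows, cols, bands)
        Raw counts (``kind='raw'``) or relative reflectance (``kind='reflectance'``).
        Reflectance cubes may contain NaN where the reference pair was degenerate.
    wavelengths : ndarray, shape (bands,)
        Band-center wavelengths in nm, strictly increasing.
    pixel_size_um : float
        Ground footprint of one pixel (square), default 156 um.
    kind : {'raw', 'reflectance'}
    """

    data: np.ndarray
    wavelengths: np.ndarray
    pixel_size_um: float = 156.0
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D (rows, cols, bands), got ndim={self.data.ndim}")
        if self.data.shape[2] == 0:
            raise ValueError("cube must have at least one band")
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.data.shape[2]:
            raise ValueError(
                f"wavelength axis length {self.wavelengths.size} does not match "
                f"band count {self.data.shape[2]}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"kind must be 'raw' or 'reflectance', got {self.kind!r}")
        if self.kind == "raw":
            d = self.data[np.isfinite(self.data)]
            if d.size and d.min() < 0:
                raise ValueError("raw intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band whose center is nearest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))


@dataclass
class ReferencePair:
    """White-plate and dark (capped lens) reference scans.

    Stored as (cols, bands) single-line scans — one detector line replicated
    down-track — or as full (rows, cols, bands) cubes. White must dominate
    dark wherever the sensor is valid; equality marks a dead region.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark references must share a shape")
        if self.white.ndim not in (2, 3):
            raise ValueError("references must be (cols, bands) lines or (rows, cols, bands) cubes")
        if np.any(self.white < self.dark):
            raise ValueError("white reference must be >= dark reference elementwise")


@dataclass
class LeafMask:
    """Boolean foreground mask over the cube's spatial grid."""

    mask: np.ndarray
    n_leaf_pixels: int = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        self.n_leaf_pixels = int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


# ---------------------------------------------------------------------------
# ENVI I/O — header text file + raw binary, BSQ/BIL interleaves,
# uint16 (ENVI data type 12) and float32 (type 4) payloads.
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.dtype("<f4"), 12: np.dtype("<u2")}
_ENVI_CODES = {v: k for k, v in _ENVI_DTYPES.items()}


def _header_path(path: Path) -> Path:
    if path.suffix == ".hdr":
        return path
    return path.with_suffix(path.suffix + ".hdr") if path.suffix else Path(str(path) + ".hdr")


def _data_path(path: Path) -> Path:
    if path.suffix == ".hdr":
        return path.with_suffix("")
    return path


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise CubeFormatError("missing ENVI magic line in header")
    # join { ... } blocks onto one line before parsing key = value pairs
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi_cube(path) -> HyperCube:
    """Read an ENVI header + binary cube pair into a :class:`HyperCube`.

    ``path`` may point at either member of the pair. Supports BSQ and BIL
    interleaves with uint16 or little-endian float32 payloads; the header
    must carry a ``wavelength`` block.
    """
    path = Path(path)
    hdr = _header_path(path)
    dat = _data_path(path)
    if not hdr.exists():
        raise CubeFormatError(f"ENVI header not found: {hdr}")
    fields = _parse_envi_header(hdr.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise CubeFormatError(f"ENVI header missing required field: {exc}") from exc
    if dtype_code not in _ENVI_DTYPES:
        raise CubeFormatError(f"unsupported ENVI data type {dtype_code} (only 4 and 12)")
    if interleave not in ("bsq", "bil"):
        raise CubeFormatError(f"unsupported interleave {interleave!r} (only bsq, bil)")
    wl_match = re.search(r"\{([^}]*)\}", fields.get("wavelength", ""))
    if wl_match is None:
        raise CubeFormatError("ENVI header has no wavelength block")
    wavelengths = np.array([float(v) for v in wl_match.group(1).split(",") if v.strip()])
    if wavelengths.size != bands:
        raise CubeFormatError(
            f"wavelength list length {wavelengths.size} != bands {bands}"
        )
    dtype = _ENVI_DTYPES[dtype_code]
    raw = np.fromfile(dat, dtype=dtype)
    expected = lines * samples * bands
    if raw.size != expected:
        raise CubeIntegrityError(
            f"payload holds {raw.size} values but header declares "
            f"{lines}x{samples}x{bands} = {expected}"
        )
    if interleave == "bsq":  # (bands, lines, samples)
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:  # bil: (lines, bands, samples)
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    pixel_size = float(fields.get("pixel size um", 156.0))
    kind = fields.get("cube kind", "raw")
    return HyperCube(np.ascontiguousarray(data), wavelengths, pixel_size, kind)


def write_envi_cube(cube: HyperCube, path, interleave: str = "bsq") -> Path:
    """Write ``cube`` as an ENVI header/binary pair; returns the binary path.

    Round-trips losslessly through :func:`read_envi_cube`. Float data is
    written as little-endian float32, integer data as uint16.
    """
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    path = Path(path)
    dat = _data_path(path)
    hdr = _header_path(path)
    rows, cols, bands = cube.shape
    if np.issubdtype(cube.data.dtype, np.integer):
        payload = cube.data.astype("<u2")
    else:
        payload = cube.data.astype("<f4")
    code = _ENVI_CODES[payload.dtype.newbyteorder("<")]
    if interleave == "bsq":
        ordered = payload.transpose(2, 0, 1)
    else:
        ordered = payload.transpose(0, 2, 1)
    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    hdr.write_text(
        "ENVI\n"
        "description = {nitramap hyperspectral cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"pixel size um = {cube.pixel_size_um}\n"
        f"cube kind = {cube.kind}\n"
        f"wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    ordered.tofile(dat)
    return dat


# ---------------------------------------------------------------------------
# Reflectance calibration and wavelength cropping
# ---------------------------------------------------------------------------

def compute_reflectance(sample: HyperCube, refs: ReferencePair) -> HyperCube:
    """Convert raw counts to relative reflectance, R = (S - B)/(W - B).

    The references may be single-line (cols, bands) scans, broadcast down the
    scan axis, or full cubes matching the sample geometry. Pixels/bands where
    ``white == dark`` are set to NaN (invalid), never +-inf.
    """
    if sample.kind != "raw":
        raise ValueError("compute_reflectance expects a raw cube")
    rows, cols, bands = sample.shape
    white, dark = refs.white, refs.dark
    if white.ndim == 2:
        if white.shape != (cols, bands):
            raise ValueError(
                f"line references of shape {white.shape} do not match cube "
                f"(cols, bands) = {(cols, bands)}"
            )
        white = white[np.newaxis, :, :]
        dark = dark[np.newaxis, :, :]
    elif white.shape != sample.shape:
        raise ValueError(f"reference shape {white.shape} does not match cube {sample.shape}")
    denom = white - dark
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (sample.data.astype(float) - dark) / denom
    refl = np.where(np.broadcast_to(denom > 0, refl.shape), refl, np.nan)
    return HyperCube(refl, sample.wavelengths, sample.pixel_size_um, kind="reflectance")


def crop_wavelengths(cube: HyperCube, lo_nm: float, hi_nm: float) -> HyperCube:
    """Keep exactly the bands with lo_nm <= lambda <= hi_nm (closed interval)."""
    if not lo_nm < hi_nm:
        raise ValueError("lo_nm must be < hi_nm")
    keep = (cube.wavelengths >= lo_nm) & (cube.wavelengths <= hi_nm)
    if not keep.any():
        raise ValueError(f"no band inside [{lo_nm}, {hi_nm}] nm")
    return HyperCube(
        cube.data[:, :, keep], cube.wavelengths[keep], cube.pixel_size_um, cube.kind
    )


# ---------------------------------------------------------------------------
# Leaf segmentation
# ---------------------------------------------------------------------------

def segment_leaf(
    cube: HyperCube,
    band_nm: float = 1450.0,
    threshold: float = 0.5,
    leaf_below: bool = True,
) -> LeafMask:
    """Threshold a single reflectance band to separate leaf from background.

    The default band sits in the 1,450 nm water absorption feature, where a
    hydrated leaf is dark against a dry background, so leaf pixels fall
    *below* the threshold. Only the largest 8-connected component is kept and
    its holes are filled. Emits :class:`EmptyMaskWarning` when nothing is
    found.
    """
    if cube.kind != "reflectance":
        raise ValueError("segment_leaf expects a reflectance cube")
    band = cube.data[:, :, cube.band_index(band_nm)]
    with np.errstate(invalid="ignore"):
        fg = (band < threshold) if leaf_below else (band > threshold)
    fg &= np.isfinite(band)
    if not fg.any():
        warnings.warn("segmentation produced an empty leaf mask", EmptyMaskWarning)
        return LeafMask(fg)
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_fill_holes(fg)
    return LeafMask(fg)
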
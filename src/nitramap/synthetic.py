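"""Synthetic calibration sets, leaf phantoms and storage series.

No spectra from the motivating experiments are publicly deposited, so every
pipeline stage is exercised on synthetic data that carries its own ground
truth. The forward model is a Beer-Lambert-style mixture: an absorbance
spectrum

    A(lambda) = baseline(lambda) + (c / c_ref) * analyte(lambda)
                + w * interferent(lambda)

is turned into reflectance

    R(lambda) = m * 10**(-A(lambda)) + o + eps

with per-sample (or per-pixel) multiplicative scatter ``m``, additive offset
``o`` and Gaussian sensor noise ``eps``. Each distortion is aimed at one
preprocessing step: SNV removes ``m`` and ``o``, the gap-segment derivative
removes smooth baselines, the FFT notch filter removes the column-gain
stripes applied to raw phantom cubes. The analyte signature is a sum of
Gaussian absorption peaks (a modelling stand-in — near 1,500 and 2,050 nm,
where N-H/O-H combination bands plausibly sit); the interferent mimics leaf
water (1,450 / 1,940 nm). ``c_ref`` = 5,000 mg/kg puts unit signature
amplitude at a realistic absorbance scale for mid-range nitrate.

Default concentration structure follows field expectations for spinach:
blade 2,178-8,767 mg/kg (the calibration design range), veins and petioles
above 10,000 mg/kg, blade center richer than the edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .chemometrics import CalibrationTable
from .cube import HyperCube, LeafMask, ReferencePair
from .physiology import StorageObservation
from .preprocess import SpectrumMatrix

__all__ = [
    "GaussianPeak",
    "PhantomConfig",
    "PhantomTruth",
    "make_signature",
    "generate_calibration_set",
    "generate_leaf_phantom",
    "generate_storage_series",
]

BLADE, VEIN, PETIOLE = 1, 2, 3


@dataclass(frozen=True)
class GaussianPeak:
    center_nm: float
    width_nm: float
    amplitude: float = 1.0


@dataclass
class PhantomConfig:
    """All knobs of the forward model; defaults are the study conditions."""

    # wavelength axis (256 bands from 913 nm at a 6.2 nm step)
    n_bands: int = 256
    wavelength_start_nm: float = 913.0
    wavelength_step_nm: float = 6.2
    # spectral building blocks
    analyte_peaks: tuple[GaussianPeak, ...] = (
        GaussianPeak(1500.0, 60.0, 1.0),
        GaussianPeak(2050.0, 45.0, 0.7),
    )
    interferent_peaks: tuple[GaussianPeak, ...] = (
        GaussianPeak(1450.0, 55.0, 1.0),
        GaussianPeak(1940.0, 70.0, 1.3),
    )
    analyte_amplitude: float = 0.10   # absorbance at c == c_ref
    interferent_amplitude: float = 0.55
    interferent_rel_spread: float = 0.15  # per-sample water variability
    baseline_coeffs: tuple[float, ...] = (0.35, 0.10)  # polynomial in axis fraction
    c_ref_mg_per_kg: float = 5000.0
    # concentration structure (mg/kg)
    blade_range: tuple[float, float] = (2178.0, 8767.0)
    blade_level: float = 3000.0
    vein_level: float = 12000.0
    petiole_level: float = 14000.0
    blade_gradient: float = 0.25  # center-to-edge relative enrichment
    # scatter / noise
    scatter_range: tuple[float, float] = (0.85, 1.15)
    offset_sd: float = 0.01
    noise_sd: float = 0.002
    # push-broom stripe model (column gains on raw counts)
    stripe_amplitude: float = 0.10
    stripe_period_px: float = 4.0
    # raw-count model
    dark_level: float = 120.0
    white_level: float = 3000.0
    seed: int = 0

    def wavelengths(self) -> np.ndarray:
        return self.wavelength_start_nm + self.wavelength_step_nm * np.arange(self.n_bands)

    def __post_init__(self) -> None:
        if self.n_bands < 2 or self.wavelength_step_nm <= 0:
            raise ValueError("need >= 2 bands with a positive wavelength step")
        if self.blade_range[0] <= 0 or self.blade_range[1] <= self.blade_range[0]:
            raise ValueError("blade_range must be a positive increasing interval")
        if self.vein_level <= 0 or self.petiole_level <= 0:
            raise ValueError("vein and petiole levels must be positive")


def _eval_peaks(wavelengths: np.ndarray, peaks, warn_outside: bool = True) -> np.ndarray:
    import warnings

    out = np.zeros_like(wavelengths, dtype=float)
    lo, hi = wavelengths[0], wavelengths[-1]
    for p in peaks:
        if warn_outside and not lo <= p.center_nm <= hi:
            warnings.warn(
                f"peak at {p.center_nm} nm lies outside the axis [{lo}, {hi}]; truncated"
            )
        out += p.amplitude * np.exp(-0.5 * ((wavelengths - p.center_nm) / p.width_nm) ** 2)
    return out


def make_signature(config: PhantomConfig, which: str = "analyte") -> np.ndarray:
    """Per-band absorbance signature (unit peak scale) on the configured axis."""
    peaks = config.analyte_peaks if which == "analyte" else config.interferent_peaks
    return _eval_peaks(config.wavelengths(), peaks)


def _baseline(config: PhantomConfig) -> np.ndarray:
    u = np.linspace(0.0, 1.0, config.n_bands)
    return sum(c * u**k for k, c in enumerate(config.baseline_coeffs))


def _absorbance(config: PhantomConfig, conc: np.ndarray, water: np.ndarray) -> np.ndarray:
    """Forward absorbance for concentrations (mg/kg) and water factors (...,1 bcast)."""
    analyte = make_signature(config, "analyte")
    interf = make_signature(config, "interferent")
    base = _baseline(config)
    c = np.asarray(conc, dtype=float)[..., None]
    w = np.asarray(water, dtype=float)[..., None]
    return (
        base
        + (c / config.c_ref_mg_per_kg) * config.analyte_amplitude * analyte
        + w * config.interferent_amplitude * interf
    )


def generate_calibration_set(
    config: PhantomConfig | None = None, n_samples: int = 210, seed: int | None = None
) -> CalibrationTable:
    """Draw a calibration set: reflectance spectra with known nitrate truth.

    Concentrations are uniform over ``blade_range`` (the reference-design
    span); each sample gets its own scatter factor, offset, water level and
    band noise. The reference value in the table *is* the truth, mimicking
    an accurate wet-chemistry reference.
    """
    config = config or PhantomConfig()
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    c = rng.uniform(*config.blade_range, size=n_samples)
    water = 1.0 + config.interferent_rel_spread * rng.uniform(-1, 1, size=n_samples)
    A = _absorbance(config, c, water)
    m = rng.uniform(*config.scatter_range, size=(n_samples, 1))
    o = rng.normal(0.0, config.offset_sd, size=(n_samples, 1))
    eps = rng.normal(0.0, config.noise_sd, size=A.shape)
    R = m * 10.0 ** (-A) + o + eps
    import pandas as pd

    return CalibrationTable(
        sample_ids=[f"syn{k:03d}" for k in range(n_samples)],
        nitrate_mg_per_kg=c,
        spectra=SpectrumMatrix(R, config.wavelengths()),
        metadata=pd.DataFrame({"truth_mg_per_kg": c, "water_factor": water}),
    )


# ---------------------------------------------------------------------------
# Leaf phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomTruth:
    """A raw phantom cube plus everything needed to score the pipeline."""

    cube: HyperCube
    refs: ReferencePair
    reflectance_truth: np.ndarray  # noise/stripe-free reflectance cube
    concentration_truth: np.ndarray
    mask_truth: LeafMask
    region_labels: np.ndarray  # 0 bg, 1 blade, 2 vein, 3 petiole
    config: PhantomConfig
    seed: int

    def region_mask(self, label: int) -> np.ndarray:
        return self.region_labels == label


def _leaf_geometry(rows: int, cols: int) -> np.ndarray:
    """Procedural leaf silhouette with labelled blade, veins and petiole.

    A superellipse blade with its long axis across the image, a tapered
    petiole extending left, a midrib, and paired oblique side veins; no
    image assets involved.
    """
    labels = np.zeros((rows, cols), dtype=np.int8)
    r0, c0 = rows / 2.0, cols * 0.58
    a_r, a_c, p = rows * 0.36, cols * 0.33, 2.5
    rr, cc = np.mgrid[0:rows, 0:cols]
    inside = (np.abs((rr - r0) / a_r) ** p + np.abs((cc - c0) / a_c) ** p) < 1.0
    labels[inside] = BLADE
    # petiole: tapered horizontal band from the left edge of the blade
    blade_left = int(c0 - a_c)
    pet_start = max(2, int(cols * 0.06))
    for c in range(pet_start, blade_left + 2):
        frac = (c - pet_start) / max(1, blade_left + 2 - pet_start)
        hw = 1.5 + 1.5 * frac
        band = np.abs(rr[:, c] - r0) <= hw
        labels[band, c] = PETIOLE
    # midrib through the blade
    mid = np.abs(rr - r0) <= 1.0
    labels[mid & inside] = VEIN
    # paired side veins leaving the midrib at ~40 degrees
    for cs in range(int(c0 - a_c * 0.8), int(c0 + a_c * 0.9), max(6, cols // 14)):
        for sgn in (+1, -1):
            for step in range(int(rows * 0.45)):
                r = int(round(r0 + sgn * step * 0.84))
                c = int(round(cs + step * 0.55))
                if 0 <= r < rows and 0 <= c < cols and labels[r, c] == BLADE:
                    labels[r, c] = VEIN
                elif step > 2:
                    break
    return labels


def generate_leaf_phantom(
    config: PhantomConfig | None = None,
    seed: int | None = None,
    shape: tuple[int, int] = (128, 160),
) -> PhantomTruth:
    """Build a raw phantom cube with references, truth field and labels.

    The concentration field sets petiole >= vein > blade, with a smooth
    center-to-edge gradient inside the blade. Raw counts follow
    ``S = B + g(col) * R * (W - B)`` where ``g`` is a sinusoidal column gain
    (a detector-sensitivity drift relative to the stripe-free white/dark
    reference scans); sensor noise is applied per pixel and band.
    """
    config = config or PhantomConfig()
    rows, cols = shape
    if rows < 64 or cols < 64:
        raise ValueError("phantom dims must be at least 64 x 64")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    labels = _leaf_geometry(rows, cols)
    leaf = labels > 0

    # concentration truth
    conc = np.zeros((rows, cols))
    blade = labels == BLADE
    if blade.any():
        dist = ndimage.distance_transform_edt(leaf)
        dmax = dist[blade].max()
        centrality = np.clip(dist / max(dmax, 1e-9), 0.0, 1.0)
        conc[blade] = config.blade_level * (
            1.0 - config.blade_gradient / 2.0 + config.blade_gradient * centrality[blade]
        )
    conc[labels == VEIN] = config.vein_level
    conc[labels == PETIOLE] = config.petiole_level

    # per-pixel water: smooth field around 1 on leaf, near 0 on dry background
    water = np.zeros((rows, cols))
    bump = ndimage.gaussian_filter(rng.normal(0, 1, (rows, cols)), 6.0)
    water[leaf] = 1.0 + config.interferent_rel_spread * bump[leaf] / max(np.abs(bump).max(), 1e-9)

    A = _absorbance(config, conc, water)
    # dry background: flat, bright
    A[~leaf] = 0.08
    # smooth multiplicative scatter field (leaf curvature / illumination)
    m_lo, m_hi = config.scatter_range
    m_field = ndimage.gaussian_filter(rng.uniform(m_lo, m_hi, (rows, cols)), 8.0)
    m_field = 1.0 + (m_field - m_field.mean())
    R_true = m_field[..., None] * 10.0 ** (-A)

    wavelengths = config.wavelengths()
    white_line = np.full((cols, config.n_bands), config.dark_level + config.white_level)
    dark_line = np.full((cols, config.n_bands), config.dark_level)
    gain = 1.0 + config.stripe_amplitude * np.sin(
        2.0 * np.pi * np.arange(cols) / config.stripe_period_px
    )
    eps = rng.normal(0.0, config.noise_sd, size=R_true.shape)
    signal = (R_true + eps) * config.white_level * gain[None, :, None]
    raw = np.clip(config.dark_level + signal, 0.0, None)

    cube = HyperCube(raw, wavelengths, kind="raw")
    return PhantomTruth(
        cube=cube,
        refs=ReferencePair(white=white_line, dark=dark_line),
        reflectance_truth=R_true,
        concentration_truth=conc,
        mask_truth=LeafMask(leaf),
        region_labels=labels,
        config=config,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Storage series
# ---------------------------------------------------------------------------

#: first-order RNC decay rates per storage temperature (1/day), chosen to
#: reproduce the observed declines: ~10% by day 4 at 10 C, ~20% at 20 C,
#: ~50% by day 3 at 30 C, ~40% by day 2 at 40 C.
DEFAULT_RNC_RATES = {10.0: 0.026, 20.0: 0.056, 30.0: 0.23, 40.0: 0.26}
#: RWC decays slowly and temperature-independently (~10% over 4 days).
DEFAULT_RWC_RATE = 0.026


def generate_storage_series(
    temps=(10.0, 20.0, 30.0, 40.0),
    days=(0, 1, 2, 3, 4),
    replicates: int = 8,
    seed: int = 0,
    rnc_rates: dict[float, float] | None = None,
    rwc_rate: float = DEFAULT_RWC_RATE,
    noise_sd: float = 0.02,
    baseline_nitrate: float = 4000.0,
) -> list[StorageObservation]:
    """Simulate leaves stored at several temperatures, measured daily.

    RNC follows exp(-k(T) * day) with temperature-ordered rates; RWC follows
    a single temperature-independent rate. Multiplicative observational
    noise is added to both; day-0 values are 1 in expectation.
    """
    if replicates < 2:
        raise ValueError("need >= 2 replicates per cell")
    rates = DEFAULT_RNC_RATES if rnc_rates is None else rnc_rates
    rng = np.random.default_rng(seed)
    obs: list[StorageObservation] = []
    for T in temps:
        k = rates[float(T)]
        for rep in range(replicates):
            PW = 5.0 * (1.0 + 0.1 * rng.uniform(-1, 1))
            DW = 0.1 * PW
            PNC = baseline_nitrate * (1.0 + 0.15 * rng.uniform(-1, 1))
            for d in days:
                rwc = np.exp(-rwc_rate * d) * (1.0 + rng.normal(0.0, noise_sd))
                rnc = np.exp(-k * d) * (1.0 + rng.normal(0.0, noise_sd))
                obs.append(
                    StorageObservation(
                        sample_id=f"T{T:g}_r{rep}",
                        day=int(d),
                        temperature_C=float(T),
                        FW=DW + (PW - DW) * rwc,
                        DW=DW,
                        PW=PW,
                        NC=PNC * rnc,
                        PNC=PNC,
                    )
                )
    return obs
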
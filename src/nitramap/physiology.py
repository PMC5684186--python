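"""Wet-reference and storage-dynamics arithmetic.

Three small, unit-critical formulas connect the imaging pipeline to leaf
physiology:

* nitrate content of a sample from its extraction, NC_s = NC_l * V_l / W_s —
  with NC_l in mg/L, V_l in mL and W_s in g, the mg/L * mL / g product
  resolves to mg/kg (0.001 L / 0.001 kg cancel);
* relative water content, RWC = (FW - DW) / (PW - DW), fresh weight against
  the initial (pre-storage) fresh weight with dry weight as the floor;
* relative nitrate content, RNC = NC / PNC, nitrate (from the mapping
  result) normalized to its day-0 value.

RWC and RNC are deliberately not clamped to [0, 1]: measurement noise can
push them past baseline and clamping would hide it. Storage experiments are
summarized per day and temperature as mean +- standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExtractionRecord",
    "StorageObservation",
    "nitrate_content",
    "relative_water_content",
    "relative_nitrate_content",
    "storage_series",
]


@dataclass(frozen=True)
class ExtractionRecord:
    """One boiled-extract measurement: concentration mg/L, weight g, volume mL."""

    NC_l: float  # extract nitrate concentration, mg/L
    W_s: float   # sample fresh weight, g
    V_l: float   # extraction volume, mL

    def __post_init__(self) -> None:
        if self.W_s <= 0 or self.V_l <= 0:
            raise ValueError("sample weight and extraction volume must be positive")
        if self.NC_l < 0:
            raise ValueError("extract concentration cannot be negative")


@dataclass(frozen=True)
class StorageObservation:
    """One leaf at one storage day: weights (g) and nitrate contents (mg/kg).

    ``PW`` and ``PNC`` are the leaf's initial fresh weight and initial
    nitrate content (the day-0 baselines RWC and RNC normalize against).
    """

    sample_id: str
    day: int
    temperature_C: float
    FW: float
    DW: float
    PW: float
    NC: float
    PNC: float

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("day must be >= 0")
        if not self.DW < self.PW:
            raise ValueError(f"sample {self.sample_id}: dry weight must be below initial weight")
        if self.PNC <= 0:
            raise ValueError(f"sample {self.sample_id}: initial nitrate content must be positive")

    @property
    def rwc(self) -> float:
        return relative_water_content(self.FW, self.DW, self.PW)

    @property
    def rnc(self) -> float:
        return relative_nitrate_content(self.NC, self.PNC)


def nitrate_content(rec: ExtractionRecord) -> float:
    """Sample nitrate content NC_s = NC_l * V_l / W_s, in mg/kg."""
    return rec.NC_l * rec.V_l / rec.W_s


def relative_water_content(FW: float, DW: float, PW: float) -> float:
    """RWC = (FW - DW) / (PW - DW); 1 at initial weight, 0 at dry weight."""
    if not PW > DW:
        raise ZeroDivisionError("RWC undefined: initial weight must exceed dry weight")
    return (FW - DW) / (PW - DW)


def relative_nitrate_content(NC: float, PNC: float) -> float:
    """RNC = NC / PNC; 1 at the initial nitrate content."""
    if PNC <= 0:
        raise ValueError("initial nitrate content must be positive")
    return NC / PNC


def storage_series(observations: list[StorageObservation]) -> pd.DataFrame:
    """Per-temperature, per-day storage summary: mean +- se of RWC and RNC.

    Returns a DataFrame indexed by (temperature_C, day), days ascending,
    with columns ``rwc_mean, rwc_se, rnc_mean, rnc_se, n``. Standard errors
    use the sample standard deviation over replicates; every cell needs at
    least 2 replicates.
    """
    if not observations:
        raise ValueError("no observations")
    df = pd.DataFrame(
        {
            "temperature_C": [o.temperature_C for o in observations],
            "day": [o.day for o in observations],
            "rwc": [o.rwc for o in observations],
            "rnc": [o.rnc for o in observations],
        }
    )
    def _agg(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        if n < 2:
            raise ValueError(
                f"cell (T, day) = {g.name} has {n} replicate(s); "
                f">= 2 required for a standard error"
            )
        return pd.Series(
            {
                "rwc_mean": g["rwc"].mean(),
                "rwc_se": g["rwc"].std(ddof=1) / np.sqrt(n),
                "rnc_mean": g["rnc"].mean(),
                "rnc_se": g["rnc"].std(ddof=1) / np.sqrt(n),
                "n": n,
            }
        )

    out = (
        df.groupby(["temperature_C", "day"], sort=True)
        .apply(_agg, include_groups=False)
        .sort_index()
    )
    out["n"] = out["n"].astype(int)
    return out
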
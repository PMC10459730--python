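"""Reference chemistry: spectrophotometric absorbances to pigment
concentrations (mg/L of ethanol extract).

Conversion (Lichtenthaler-style coefficients at 665/649/470 nm):

    Chla = 13.95*A665 - 6.88*A649
    Chlb = 24.96*A649 - 7.32*A665
    Chls = Chla + Chlb
    Cars = (1000*A470 - 2.05*Chla - 114.8*Chlb) / 245
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PigmentPanel", "pigments_from_absorbance", "convert_absorbance_table", "PIGMENTS"]

PIGMENTS = ("chla", "chlb", "chls", "cars")


@dataclass
class PigmentPanel:
    """Per-sample pigment concentrations; ``chls == chla + chlb`` always."""

    chla: np.ndarray
    chlb: np.ndarray
    chls: np.ndarray
    cars: np.ndarray

    def __post_init__(self) -> None:
        for name in PIGMENTS:
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if not np.allclose(self.chls, self.chla + self.chlb, rtol=0, atol=1e-12):
            raise ValueError("chls must equal chla + chlb")

    def __len__(self) -> int:
        return self.chla.size

    def __getitem__(self, pigment: str) -> np.ndarray:
        if pigment not in PIGMENTS:
            raise KeyError(pigment)
        return getattr(self, pigment)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({name: getattr(self, name) for name in PIGMENTS})


def pigments_from_absorbance(a665, a649, a470) -> PigmentPanel:
    """Convert an absorbance triplet (vectorized) to a pigment panel.

    Negative concentrations are physically implausible; they are returned
    as-is but trigger a warning.
    """
    a665 = np.atleast_1d(np.asarray(a665, dtype=float))
    a649 = np.atleast_1d(np.asarray(a649, dtype=float))
    a470 = np.atleast_1d(np.asarray(a470, dtype=float))
    for name, arr in (("A665", a665), ("A649", a649), ("A470", a470)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} contains non-finite values")
        if np.any(arr < 0):
            raise ValueError(f"{name} contains negative absorbances")

    chla = 13.95 * a665 - 6.88 * a649
    chlb = 24.96 * a649 - 7.32 * a665
    chls = chla + chlb
    cars = (1000.0 * a470 - 2.05 * chla - 114.8 * chlb) / 245.0
    if np.any(chla < 0) or np.any(chlb < 0) or np.any(cars < 0):
        warnings.warn("negative pigment concentration computed — implausible input", UserWarning)
    return PigmentPanel(chla=chla, chlb=chlb, chls=chls, cars=cars)


def convert_absorbance_table(df: pd.DataFrame) -> pd.DataFrame:
    """Append pigment columns to a table with A665/A649/A470 columns.

    Replicate absorbance columns (``A665_1``, ``A665_2``, ...) are averaged
    at the absorbance level before conversion.
    """
    out = df.copy()
    trip = {}
    for band in ("A665", "A649", "A470"):
        if band in out.columns:
            trip[band] = out[band].to_numpy(dtype=float)
        else:
            reps = [c for c in out.columns if c.startswith(band + "_")]
            if not reps:
                raise ValueError(f"missing column {band}")
            trip[band] = out[reps].to_numpy(dtype=float).mean(axis=1)
    panel = pigments_from_absorbance(trip["A665"], trip["A649"], trip["A470"])
    for name in PIGMENTS:
        out[name] = panel[name]
    return out
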
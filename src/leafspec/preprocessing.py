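"""Spectral pretreatment: Savitzky-Golay smoothing, standard normal variate,
and ordered compositions of the two."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = ["sg_smooth", "snv", "PreprocessRecipe", "DEFAULT_RECIPES"]

#: per-pigment best pretreatment (overridable in pipeline configs)
DEFAULT_RECIPES = {
    "chla": "sg+snv",
    "chlb": "sg",
    "chls": "snv",
    "cars": "snv",
}

_VALID_STEPS = ("none", "sg", "snv", "sg+snv")


def sg_smooth(spectra: np.ndarray, window: int = 11, polyorder: int = 2) -> np.ndarray:
    """Row-wise Savitzky-Golay smoothing.

    Band count is preserved; edges use a polynomial fit over the terminal
    window evaluated at the edge positions (scipy ``mode='interp'``), so any
    row that is globally a degree <= polyorder polynomial is reproduced
    exactly.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if spectra.shape[-1] < window:
        raise ValueError("window exceeds band count")
    return savgol_filter(spectra, window_length=window, polyorder=polyorder, axis=-1, mode="interp")


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: each row mapped to (x - mean) / sd.

    Uses the sample (ddof=1) standard deviation. Rows become mean 0 / sd 1;
    multiplicative gain and additive offset distortions are removed exactly.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    mean = spectra.mean(axis=-1, keepdims=True)
    sd = spectra.std(axis=-1, ddof=1, keepdims=True)
    bad = np.nonzero(sd.ravel() == 0)[0]
    if bad.size:
        raise ValueError(f"constant spectrum (zero sd) in sample(s) {bad.tolist()}")
    return (spectra - mean) / sd


@dataclass
class PreprocessRecipe:
    """Ordered pretreatment recipe; for ``sg+snv`` smoothing runs first."""

    steps: str = "none"
    sg_window: int = 11
    sg_polyorder: int = 2

    def __post_init__(self) -> None:
        self.steps = self.steps.lower()
        if self.steps not in _VALID_STEPS:
            raise ValueError(f"steps must be one of {_VALID_STEPS}")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and exceed sg_polyorder")

    def apply(self, spectra: np.ndarray) -> np.ndarray:
        out = np.atleast_2d(np.asarray(spectra, dtype=float))
        if self.steps in ("sg", "sg+snv"):
            out = sg_smooth(out, self.sg_window, self.sg_polyorder)
        if self.steps in ("snv", "sg+snv"):
            out = snv(out)
        return out

    def to_dict(self) -> dict:
        return {"steps": self.steps, "sg_window": self.sg_window, "sg_polyorder": self.sg_polyorder}

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessRecipe":
        return cls(**d)
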
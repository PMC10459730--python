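"""Pixel-wise inversion of fitted models onto leaf cubes: leaf segmentation,
gray concentration map, enhanced Lee despeckling, pseudo-color rendering."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

from .hsi_io import SpectralCube
from .pls import FittedModel

__all__ = [
    "ConcentrationMap",
    "LeeParams",
    "segment_leaf",
    "invert_pixels",
    "enhanced_lee",
    "render_pseudocolor",
    "value_from_color",
]


@dataclass
class ConcentrationMap:
    """Per-pixel concentration image (mg/L); background is NaN."""

    values: np.ndarray
    pigment: str = ""
    display_range: tuple = (0.0, 30.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("map must be 2-D")
        lo, hi = self.display_range
        if not lo < hi:
            raise ValueError("display_range min must be < max")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def foreground_mean(self) -> float:
        return float(np.nanmean(self.values))


@dataclass
class LeeParams:
    """Enhanced Lee filter parameters (window, damping, CV thresholds)."""

    window: int = 3
    damping: float = 1.0
    homogeneity: float = 0.52
    heterogeneous: float = 1.73

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be odd and >= 3")
        if not 0 < self.homogeneity < self.heterogeneous:
            raise ValueError("require 0 < homogeneity < heterogeneous")


def segment_leaf(
    cube: SpectralCube,
    nir_nm: float = 800.0,
    red_nm: float = 670.0,
    threshold: float = 0.3,
) -> np.ndarray:
    """Foreground mask via a band-ratio (NDVI-style) threshold on
    (R_nir - R_red)/(R_nir + R_red), keeping the largest connected
    component. Raises if the foreground is empty."""
    nir = cube.data[:, :, cube.band_index(nir_nm)].astype(float)
    red = cube.data[:, :, cube.band_index(red_nm)].astype(float)
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        index = np.where(denom != 0, (nir - red) / denom, 0.0)
    mask = index > threshold
    if not mask.any():
        raise ValueError("empty foreground after thresholding")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def _match_bands(model: FittedModel, cube: SpectralCube) -> np.ndarray:
    """Nearest cube band for each model wavelength; error beyond half a
    band spacing."""
    if np.all(np.isnan(model.wavelengths)):
        return model.band_indices
    spacing = float(np.median(np.diff(cube.wavelengths))) if cube.wavelengths.size > 1 else np.inf
    idx = np.empty(model.wavelengths.size, dtype=int)
    for k, wl in enumerate(model.wavelengths):
        i = int(np.argmin(np.abs(cube.wavelengths - wl)))
        if abs(cube.wavelengths[i] - wl) > spacing / 2 + 1e-9:
            raise ValueError(f"model wavelength {wl} nm not present in cube axis")
        idx[k] = i
    return idx


def invert_pixels(
    cube: SpectralCube,
    model: FittedModel,
    mask: np.ndarray | None = None,
    pigment: str | None = None,
) -> ConcentrationMap:
    """Apply a fitted model pixel-wise: preprocess each foreground pixel
    spectrum with the model's recipe, then evaluate the collapsed affine map
    over the model's bands. Background pixels become NaN."""
    if mask is None:
        mask = segment_leaf(cube)
    rows, cols, bands = cube.shape
    band_idx = _match_bands(model, cube)

    fg = np.flatnonzero(mask.ravel())
    values = np.full(rows * cols, np.nan)
    if fg.size:
        pixels = cube.data.reshape(-1, bands)[fg].astype(float)
        if model.recipe is not None:
            pixels = model.recipe.apply(pixels)
        values[fg] = pixels[:, band_idx] @ model.coefficients + model.intercept
    return ConcentrationMap(
        values=values.reshape(rows, cols),
        pigment=pigment or model.pigment or "",
    )


def enhanced_lee(cmap: ConcentrationMap, params: LeeParams | None = None) -> ConcentrationMap:
    """Enhanced Lee despeckling.

    Per foreground pixel, over the finite values of its window compute the
    coefficient of variation Ci = sd/mean (sample sd):
      Ci <= homogeneity        -> window mean
      homogeneity < Ci < het.  -> mean + w * (center - mean),
                                  w = exp(-damping * (Ci - homog)/(het - Ci))
      Ci >= heterogeneous      -> center preserved
    Background (NaN) is excluded from windows and left untouched.
    """
    if params is None:
        params = LeeParams()
    vals = cmap.values
    half = params.window // 2
    out = vals.copy()
    rows, cols = vals.shape
    for r in range(rows):
        for c in range(cols):
            center = vals[r, c]
            if not np.isfinite(center):
                continue
            win = vals[max(0, r - half): r + half + 1, max(0, c - half): c + half + 1]
            w = win[np.isfinite(win)]
            mean = w.mean()
            sd = w.std(ddof=1) if w.size > 1 else 0.0
            ci = sd / abs(mean) if mean != 0 else 0.0
            if ci <= params.homogeneity:
                out[r, c] = mean
            elif ci < params.heterogeneous:
                weight = np.exp(
                    -params.damping * (ci - params.homogeneity) / (params.heterogeneous - ci)
                )
                out[r, c] = mean + weight * (center - mean)
            # else: pass-through, center preserved
    return ConcentrationMap(values=out, pigment=cmap.pigment, display_range=cmap.display_range)


# --------------------------------------------------------------------------- #
# pseudo-color rendering
# --------------------------------------------------------------------------- #

def _to_rgba(cmap: ConcentrationMap, display_range: tuple | None) -> np.ndarray:
    lo, hi = display_range if display_range is not None else cmap.display_range
    if not lo < hi:
        raise ValueError("display range min must be < max")
    t = np.clip((cmap.values - lo) / (hi - lo), 0.0, 1.0)
    rgba = np.zeros(cmap.values.shape + (4,), dtype=np.uint8)
    fg = cmap.mask
    rgba[..., 0] = np.where(fg, np.round(255 * np.nan_to_num(t)), 255)
    rgba[..., 2] = np.where(fg, np.round(255 * np.nan_to_num(1 - t)), 255)
    rgba[..., 1] = np.where(fg, 0, 255)
    rgba[..., 3] = np.where(fg, 255, 0)  # transparent background
    return rgba


def render_pseudocolor(
    cmap: ConcentrationMap,
    display_range: tuple | None = None,
    out_path=None,
) -> np.ndarray:
    """Linear blue (range min) -> red (range max) rendering, clipped;
    background transparent white. Returns the RGBA array; writes a PNG when
    ``out_path`` is given."""
    rgba = _to_rgba(cmap, display_range)
    if out_path is not None:
        Image.fromarray(rgba, mode="RGBA").save(out_path)
    return rgba


def value_from_color(rgba_pixel: np.ndarray, display_range: tuple = (0.0, 30.0)) -> float:
    """Invert the blue->red LUT (valid for in-range foreground pixels)."""
    lo, hi = display_range
    return lo + (hi - lo) * float(rgba_pixel[0]) / 255.0
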
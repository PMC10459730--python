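"""Hyperspectral cube I/O (ENVI header + raw raster), white/dark reflectance
correction, and elliptical-ROI pixel harvesting into mean spectra."""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectralCube",
    "SpectraMatrix",
    "CalibrationFrames",
    "ROIEllipse",
    "DegenerateReferenceError",
    "correct_reflectance",
    "roi_pixels",
    "mean_spectrum",
    "read_cube",
    "write_cube",
]

# ENVI numeric data-type codes we support
_DTYPE_TO_CODE = {np.dtype("float32"): 4, np.dtype("float64"): 5}
_CODE_TO_DTYPE = {v: k for k, v in _DTYPE_TO_CODE.items()}
_INTERLEAVES = ("bsq", "bil", "bip")


class DegenerateReferenceError(ValueError):
    """White and dark references coincide at some applied element."""


@dataclass
class SpectralCube:
    """Reflectance raster of shape (lines, samples, bands) with a strictly
    increasing wavelength axis in nm."""

    data: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube must be 3-D (lines, samples, bands)")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError("band count does not match wavelength axis")
        if self.wavelengths.size >= 2 and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength axis must be strictly increasing")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band nearest a target wavelength."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))


@dataclass
class SpectraMatrix:
    """Samples x bands matrix of mean ROI spectra."""

    values: np.ndarray
    wavelengths: np.ndarray
    sample_ids: list = field(default_factory=list)
    metadata: pd.DataFrame | None = None  # per-sample factors (position, nitrogen, ...)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.shape[1] != self.wavelengths.size:
            raise ValueError("band count mismatch")
        if self.wavelengths.size >= 2 and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength axis must be strictly increasing")
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1:04d}" for i in range(self.values.shape[0])]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample id count mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite reflectance values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=[f"{w:.4f}" for w in self.wavelengths])
        df.insert(0, "sample_id", self.sample_ids)
        if self.metadata is not None:
            for i, col in enumerate(self.metadata.columns):
                df.insert(1 + i, col, self.metadata[col].to_numpy())
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectraMatrix":
        df = pd.read_csv(path)
        wl_cols = [c for c in df.columns if re.fullmatch(r"\d+(\.\d+)?", c)]
        meta_cols = [c for c in df.columns if c not in wl_cols and c != "sample_id"]
        return cls(
            values=df[wl_cols].to_numpy(dtype=float),
            wavelengths=np.array([float(c) for c in wl_cols]),
            sample_ids=df["sample_id"].astype(str).tolist(),
            metadata=df[meta_cols] if meta_cols else None,
        )


@dataclass
class CalibrationFrames:
    """Raw cube plus white/dark reference frames.

    References may be full cubes, single (samples, bands) line frames that
    broadcast across the scan direction, or scalars.
    """

    raw: SpectralCube
    white: np.ndarray
    dark: np.ndarray


def _broadcast_frame(frame: np.ndarray, shape: tuple) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 2:  # (samples, bands) line reference
        frame = frame[np.newaxis, :, :]
    return np.broadcast_to(frame, shape)


def correct_reflectance(frames: CalibrationFrames) -> SpectralCube:
    """White/dark correction: R = (R0 - Rb) / (Rw - Rb), elementwise.

    No clipping is applied; specular pixels may exceed [0, 1].
    """
    raw = frames.raw.data.astype(float)
    white = _broadcast_frame(frames.white, raw.shape)
    dark = _broadcast_frame(frames.dark, raw.shape)
    denom = white - dark
    bad = np.argwhere(denom == 0)
    if bad.size:
        line, sample, band = bad[0]
        raise DegenerateReferenceError(
            f"white == dark at line={line}, sample={sample}, band={band}"
        )
    return SpectralCube(data=(raw - dark) / denom, wavelengths=frames.raw.wavelengths)


# --------------------------------------------------------------------------- #
# elliptical ROI
# --------------------------------------------------------------------------- #

@dataclass
class ROIEllipse:
    """Elliptical ROI: center (row, col), semi-axes (a along columns/x,
    b along rows/y), integer grid spacing (dx, dy)."""

    center: tuple
    semi_axes: tuple
    step: tuple = (1, 1)

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        dx, dy = self.step
        if a <= 0 or b <= 0:
            raise ValueError("semi-axes must be positive")
        if dx < 1 or dy < 1:
            raise ValueError("step must be >= 1")


def roi_pixels(ellipse: ROIEllipse, image_shape: tuple) -> list[tuple[int, int]]:
    """Integer pixels inside the ellipse, ordered top-to-bottom then
    left-to-right, clipped to image bounds.

    Offsets (xi, yi) relative to the center satisfy xi^2/a^2 + yi^2/b^2 <= 1
    on the (dx, dy) grid.
    """
    cy, cx = ellipse.center
    a, b = ellipse.semi_axes
    dx, dy = int(ellipse.step[0]), int(ellipse.step[1])
    n_rows, n_cols = image_shape[:2]

    coords = []
    for yi in range(-int(np.floor(b)), int(np.floor(b)) + 1):
        if yi % dy:
            continue
        for xi in range(-int(np.floor(a)), int(np.floor(a)) + 1):
            if xi % dx:
                continue
            if xi * xi / (a * a) + yi * yi / (b * b) <= 1.0:
                r, c = int(round(cy)) + yi, int(round(cx)) + xi
                if 0 <= r < n_rows and 0 <= c < n_cols:
                    coords.append((r, c))
    if not coords:
        raise ValueError("ROI does not intersect the image")
    return coords


def mean_spectrum(cube: SpectralCube, pixels: list[tuple[int, int]]) -> np.ndarray:
    """Arithmetic mean spectrum over a pixel coordinate list."""
    if len(pixels) == 0:
        raise ValueError("empty pixel list")
    rows, cols = zip(*pixels)
    return cube.data[np.asarray(rows), np.asarray(cols), :].mean(axis=0)


# --------------------------------------------------------------------------- #
# ENVI I/O
# --------------------------------------------------------------------------- #

def _header_path(path: str) -> tuple[str, str]:
    """(header, raster) paths from either given."""
    if path.endswith(".hdr"):
        return path, path[:-4]
    return path + ".hdr", path


def write_cube(cube: SpectralCube, path: str, interleave: str = "bsq") -> str:
    """Write a cube as an ENVI header (.hdr) + raw raster.

    Returns the header path. float32/float64 rasters round-trip
    bit-identically.
    """
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"interleave must be one of {_INTERLEAVES}")
    data = cube.data
    if data.dtype not in _DTYPE_TO_CODE:
        data = data.astype("float64")
    hdr_path, ras_path = _header_path(path)
    lines, samples, bands = data.shape

    if interleave == "bip":
        arr = data  # (lines, samples, bands)
    elif interleave == "bil":
        arr = np.transpose(data, (0, 2, 1))  # (lines, bands, samples)
    else:  # bsq
        arr = np.transpose(data, (2, 0, 1))  # (bands, lines, samples)
    arr = np.ascontiguousarray(arr)
    arr.tofile(ras_path)

    wl = ",\n ".join(f"{w:.6f}" for w in cube.wavelengths)
    with open(hdr_path, "w") as fh:
        fh.write(
            "ENVI\n"
            f"samples = {samples}\n"
            f"lines = {lines}\n"
            f"bands = {bands}\n"
            "header offset = 0\n"
            "file type = ENVI Standard\n"
            f"data type = {_DTYPE_TO_CODE[data.dtype]}\n"
            f"interleave = {interleave}\n"
            "byte order = 0\n"
            "wavelength units = Nanometers\n"
            f"wavelength = {{\n {wl}}}\n"
        )
    return hdr_path


def _parse_envi_header(hdr_path: str) -> dict:
    with open(hdr_path) as fh:
        text = fh.read()
    if not text.lstrip().startswith("ENVI"):
        raise ValueError("not an ENVI header")
    fields: dict = {}
    # brace-enclosed (possibly multi-line) values first
    for m in re.finditer(r"^([\w ]+?)\s*=\s*\{(.*?)\}", text, re.S | re.M):
        fields[m.group(1).strip().lower()] = m.group(2)
    for m in re.finditer(r"^([\w ]+?)\s*=\s*([^{\n]+)$", text, re.M):
        key = m.group(1).strip().lower()
        fields.setdefault(key, m.group(2).strip())
    return fields


def read_cube(header_path: str, wavelength_range: tuple | None = None) -> SpectralCube:
    """Read an ENVI header + raster pair into a :class:`SpectralCube`.

    ``wavelength_range=(lo, hi)`` subsets the band axis at read time
    (inclusive), e.g. ``(430, 900)`` to trim sensor-edge bands.
    """
    hdr_path, ras_path = _header_path(header_path)
    fields = _parse_envi_header(hdr_path)
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        interleave = fields["interleave"].lower()
        code = int(fields["data type"])
    except KeyError as exc:
        raise ValueError(f"ENVI header missing required field: {exc}") from exc
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    if code not in _CODE_TO_DTYPE:
        raise ValueError(f"unsupported ENVI data type code {code}")
    if "wavelength" not in fields:
        raise ValueError("ENVI header missing wavelength list")
    wavelengths = np.array(
        [float(tok) for tok in re.split(r"[,\s]+", fields["wavelength"].strip()) if tok]
    )
    if wavelengths.size != bands:
        raise ValueError(
            f"wavelength list length {wavelengths.size} does not match bands {bands}"
        )

    count = lines * samples * bands
    raw = np.fromfile(ras_path, dtype=_CODE_TO_DTYPE[code], count=count)
    if raw.size != count:
        raise ValueError(f"raster too small: {raw.size} values for {count} expected")
    if interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    data = np.ascontiguousarray(data)

    if wavelength_range is not None:
        lo, hi = wavelength_range
        keep = (wavelengths >= lo) & (wavelengths <= hi)
        if not keep.any():
            raise ValueError("wavelength_range excludes every band")
        data = data[:, :, keep]
        wavelengths = wavelengths[keep]
    return SpectralCube(data=data, wavelengths=wavelengths)


def extract_spectra(
    cube: SpectralCube,
    rois: list[ROIEllipse],
) -> tuple[np.ndarray, int]:
    """Pooled mean spectrum over several elliptical ROIs (pixels pooled as a
    multiset). Returns (spectrum, n_pixels)."""
    pooled: list[tuple[int, int]] = []
    for roi in rois:
        pooled.extend(roi_pixels(roi, cube.shape[:2]))
    return mean_spectrum(cube, pooled), len(pooled)
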
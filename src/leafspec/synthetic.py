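"""Synthetic hyperspectral leaf data with known ground truth.

The forward model builds each spectrum as a smooth baseline reflectance
minus pigment-concentration-weighted Gaussian absorption profiles centered
on configurable "planted" bands, then distorts it with per-sample
multiplicative gain + additive offset (scatter, exactly removable by SNV)
and i.i.d. high-frequency noise (suppressible by Savitzky-Golay smoothing).
Concentrations follow a concave nitrogen response peaking at the middle
level and a monotone Upper > Middle > Lower leaf-position effect, with
total chlorophyll equal to chla + chlb exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .hsi_io import SpectralCube, SpectraMatrix
from .wet_chem import PigmentPanel

__all__ = ["SimulationConfig", "GroundTruth", "SyntheticCube", "generate_dataset", "generate_cube"]

_DEFAULT_PLANTED = {
    # 8 centers per pigment inside the 435-510 / 630-760 / 800-895 nm
    # regions, interleaved so cross-pigment centers stay > 1 profile width
    # apart (keeps per-pigment band recovery well-posed)
    "chla": (436.0, 472.0, 508.0, 660.0, 702.0, 744.0, 816.0, 858.0),
    "chlb": (448.0, 484.0, 632.0, 674.0, 716.0, 758.0, 830.0, 872.0),
    "cars": (460.0, 496.0, 646.0, 688.0, 730.0, 802.0, 844.0, 886.0),
}

#: absorption depth (reflectance units per mg/L) per pigment profile
_DEFAULT_AMPLITUDE = {"chla": 0.010, "chlb": 0.020, "cars": 0.045}

_POSITION_GAIN = {"Upper": 1.18, "Middle": 1.0, "Lower": 0.84}


@dataclass
class SimulationConfig:
    n_samples: int = 435
    n_bands: int = 646
    wavelength_range: tuple = (430.0, 900.0)
    nitrogen_levels: tuple = tuple(f"N{20 * (i + 1)}" for i in range(10))
    leaf_positions: tuple = ("Upper", "Middle", "Lower")
    pigment_ranges: dict = field(
        default_factory=lambda: {
            "chla": (3.37, 21.13),
            "chlb": (1.22, 8.49),
            "cars": (0.60, 3.23),
        }
    )
    planted_bands: dict = field(default_factory=lambda: dict(_DEFAULT_PLANTED))
    band_width: float = 10.0  # Gaussian sigma, nm
    scatter_sd: float = 0.05
    noise_sd: float = 0.004  # i.i.d. high-frequency noise (S-G suppressible)
    drift_sd: float = 0.028  # smooth band-correlated interference (baseline drift)
    drift_corr_nm: float = 11.0  # correlation length of the drift
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.n_bands < 2:
            raise ValueError("n_bands must be >= 2")
        lo, hi = self.wavelength_range
        if not lo < hi:
            raise ValueError("wavelength_range must be increasing")
        for name, (mn, mx) in self.pigment_ranges.items():
            if mn <= 0 or mn >= mx:
                raise ValueError(f"pigment range for {name} must be positive with min < max")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(*self.wavelength_range, self.n_bands)


@dataclass
class GroundTruth:
    """Generator-side truth used as the recovery oracle downstream."""

    concentrations: PigmentPanel
    informative_band_indices: dict  # pigment -> index array (within 1 sigma of a center)
    pure_spectra: dict  # pigment -> absorption profile over the wavelength axis
    planted_centers: dict  # pigment -> nm centers
    metadata: pd.DataFrame  # sample_id, nitrogen, position

    def recovery_fraction(self, pigment: str, selected_indices: np.ndarray, wavelengths: np.ndarray, tol_nm: float | None = None) -> float:
        """Fraction of planted centers with at least one selected wavelength
        within ``tol_nm`` (default: one profile sigma)."""
        centers = np.asarray(self.planted_centers[pigment])
        sel_wl = np.asarray(wavelengths, dtype=float)[np.asarray(selected_indices, dtype=int)]
        if tol_nm is None:
            tol_nm = self._sigma
        hit = [np.any(np.abs(sel_wl - c) <= tol_nm) for c in centers]
        return float(np.mean(hit))

    _sigma: float = 15.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "concentrations": self.concentrations.to_frame().to_dict(orient="list"),
                    "informative_band_indices": {
                        k: np.asarray(v).tolist() for k, v in self.informative_band_indices.items()
                    },
                    "planted_centers": {k: list(v) for k, v in self.planted_centers.items()},
                    "metadata": self.metadata.to_dict(orient="list"),
                },
                fh,
            )


def _profiles(config: SimulationConfig) -> dict:
    """Per-pigment absorption profile over the wavelength axis (sum of unit
    Gaussians at the planted centers, scaled by the pigment amplitude)."""
    wl = config.wavelengths
    out = {}
    for pig, centers in config.planted_bands.items():
        amp = _DEFAULT_AMPLITUDE.get(pig, 0.01)
        prof = np.zeros_like(wl)
        for c in centers:
            prof += np.exp(-0.5 * ((wl - c) / config.band_width) ** 2)
        out[pig] = amp * prof
    return out


def _baseline(wl: np.ndarray) -> np.ndarray:
    """Smooth leaf-like baseline: low visible reflectance rising across a
    red-edge-like sigmoid into a bright NIR plateau."""
    return 0.32 + 0.55 / (1.0 + np.exp(-(wl - 705.0) / 18.0))


def _draw_concentrations(config: SimulationConfig, rng: np.random.Generator):
    """Concentrations with concave nitrogen response (peak at the middle
    level) and Upper > Middle > Lower position effect; chls = chla + chlb."""
    n = config.n_samples
    levels = list(config.nitrogen_levels)
    positions = list(config.leaf_positions)
    combos = [(lv, pos) for lv in levels for pos in positions]
    meta = [combos[i % len(combos)] for i in range(n)]
    nitrogen = np.array([m[0] for m in meta])
    position = np.array([m[1] for m in meta])

    peak = (len(levels) - 1) / 2.0  # concave response peaks mid-gradient
    lvl_idx = np.array([levels.index(lv) for lv in nitrogen], dtype=float)
    nitro_gain = 1.0 - 0.45 * ((lvl_idx - peak) / max(peak, 1.0)) ** 2
    pos_gain = np.array([_POSITION_GAIN.get(p, 1.0) for p in position])

    conc = {}
    for pig, (mn, mx) in config.pigment_ranges.items():
        jitter = rng.normal(1.0, 0.16, size=n)
        raw = nitro_gain * pos_gain * np.clip(jitter, 0.5, 1.5)
        lo, hi = raw.min(), raw.max()
        span = hi - lo if hi > lo else 1.0
        conc[pig] = mn + (mx - mn) * (raw - lo) / span
    zeros = np.zeros(n)
    chla = conc.get("chla", zeros)
    chlb = conc.get("chlb", zeros)
    panel = PigmentPanel(
        chla=chla,
        chlb=chlb,
        chls=chla + chlb,
        cars=conc.get("cars", zeros),
    )
    metadata = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:04d}" for i in range(n)],
            "nitrogen": nitrogen,
            "position": position,
        }
    )
    return panel, metadata


def _forward(concs: dict, profiles: dict, wl: np.ndarray) -> np.ndarray:
    """Clean spectra: baseline minus sum of concentration-weighted profiles."""
    base = _baseline(wl)
    spectra = np.tile(base, (len(next(iter(concs.values()))), 1))
    for pig, prof in profiles.items():
        spectra -= np.outer(concs[pig], prof)
    return spectra


def generate_dataset(config: SimulationConfig | None = None) -> tuple[SpectraMatrix, GroundTruth]:
    """Generate a samples x bands spectra matrix with paired ground truth.

    Deterministic given ``config.seed`` (bit-identical on rerun).
    """
    if config is None:
        config = SimulationConfig()
    wl = config.wavelengths
    root = np.random.SeedSequence(config.seed)
    conc_rng, scatter_rng, noise_rng, drift_rng = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    panel, metadata = _draw_concentrations(config, conc_rng)
    profiles = _profiles(config)
    clean = _forward(
        {pig: panel[pig] for pig in profiles}, profiles, wl
    )

    n = config.n_samples
    if config.drift_sd > 0:
        # smooth pigment-unrelated drift: band-correlated noise that neither
        # SNV nor smoothing removes; makes neighboring bands redundant so
        # that variable selection genuinely matters
        spacing = (wl[-1] - wl[0]) / max(config.n_bands - 1, 1)
        sigma_bands = config.drift_corr_nm / spacing
        drift = gaussian_filter1d(
            drift_rng.normal(0.0, 1.0, size=(n, config.n_bands)), sigma_bands, axis=1
        )
        sd = drift.std()
        if sd > 0:
            clean = clean + drift * (config.drift_sd / sd)
    if config.scatter_sd > 0:
        gain = scatter_rng.normal(1.0, config.scatter_sd, size=(n, 1))
        offset = scatter_rng.normal(0.0, config.scatter_sd * 0.2, size=(n, 1))
        spectra = gain * clean + offset
    else:
        spectra = clean.copy()
    if config.noise_sd > 0:
        spectra = spectra + noise_rng.normal(0.0, config.noise_sd, size=spectra.shape)

    informative = {}
    for pig, prof in profiles.items():
        amp = _DEFAULT_AMPLITUDE.get(pig, 0.01)
        informative[pig] = np.flatnonzero(prof >= amp * np.exp(-0.5))
    centers = {pig: tuple(c) for pig, c in config.planted_bands.items()}
    if "chla" in informative and "chlb" in informative:
        informative["chls"] = np.union1d(informative["chla"], informative["chlb"])
        centers["chls"] = tuple(sorted(set(centers["chla"]) | set(centers["chlb"])))

    truth = GroundTruth(
        concentrations=panel,
        informative_band_indices=informative,
        pure_spectra=profiles,
        planted_centers=centers,
        metadata=metadata,
        _sigma=config.band_width,
    )
    matrix = SpectraMatrix(
        values=spectra,
        wavelengths=wl,
        sample_ids=metadata["sample_id"].tolist(),
        metadata=metadata[["nitrogen", "position"]],
    )
    return matrix, truth


# --------------------------------------------------------------------------- #
# pixel cubes for the visualization round trip
# --------------------------------------------------------------------------- #

_BACKGROUND_REFLECTANCE = 0.12  # flat spectrum; low band-ratio index
_WHITE_LEVEL = 0.92
_DARK_LEVEL = 0.04


@dataclass
class SyntheticCube:
    """Corrected-reflectance cube plus the raw/white/dark trio that
    reproduces it through white/dark correction."""

    reflectance: SpectralCube
    raw: SpectralCube
    white: np.ndarray  # (samples, bands) line reference
    dark: np.ndarray
    mask: np.ndarray  # True where leaf (foreground)
    concentration_maps: dict  # pigment -> 2-D mg/L truth


def generate_cube(
    config: SimulationConfig,
    concentration_map,
) -> SyntheticCube:
    """Generate a per-pixel cube from a concentration map via the same
    forward model.

    ``concentration_map`` is either a 2-D chla map in mg/L (chlb and cars
    are then scaled to 0.35x and 0.15x) or a dict of per-pigment 2-D maps.
    Zero-valued pixels (all pigments) are background and carry a flat
    spectrum. Negative concentrations raise.
    """
    if isinstance(concentration_map, dict):
        maps = {k: np.asarray(v, dtype=float) for k, v in concentration_map.items()}
    else:
        chla = np.asarray(concentration_map, dtype=float)
        maps = {"chla": chla, "chlb": 0.35 * chla, "cars": 0.15 * chla}
    for pig, arr in maps.items():
        if arr.ndim != 2:
            raise ValueError("concentration maps must be 2-D")
        if np.any(arr < 0):
            raise ValueError(f"negative concentrations in {pig} map")
    shape = next(iter(maps.values())).shape
    mask = np.zeros(shape, dtype=bool)
    for arr in maps.values():
        mask |= arr > 0

    wl = config.wavelengths
    profiles = _profiles(config)
    rows, cols = shape
    fg = np.flatnonzero(mask.ravel())
    flat_concs = {pig: maps.get(pig, np.zeros(shape)).ravel()[fg] for pig in profiles}

    data = np.full((rows * cols, wl.size), _BACKGROUND_REFLECTANCE)
    if fg.size:
        data[fg] = _forward(flat_concs, profiles, wl)
    if config.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape)
    reflectance = SpectralCube(data=data.reshape(rows, cols, wl.size), wavelengths=wl)

    white = np.full((cols, wl.size), _WHITE_LEVEL)
    dark = np.full((cols, wl.size), _DARK_LEVEL)
    raw_data = reflectance.data * (white - dark)[np.newaxis] + dark[np.newaxis]
    raw = SpectralCube(data=raw_data, wavelengths=wl)

    maps_full = {pig: maps.get(pig, np.zeros(shape)) for pig in profiles}
    maps_full["chls"] = maps_full["chla"] + maps_full["chlb"]
    return SyntheticCube(
        reflectance=reflectance,
        raw=raw,
        white=white,
        dark=dark,
        mask=mask,
        concentration_maps=maps_full,
    )
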
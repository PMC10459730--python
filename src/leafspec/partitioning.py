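"""SPXY calibration/prediction split: Kennard-Stone selection on a joint,
max-normalized spectral (X) + response (Y) distance."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["SplitResult", "spxy_split", "random_split"]


@dataclass
class SplitResult:
    calibration_indices: np.ndarray
    prediction_indices: np.ndarray
    fraction: float

    def __post_init__(self) -> None:
        self.calibration_indices = np.asarray(self.calibration_indices, dtype=int)
        self.prediction_indices = np.asarray(self.prediction_indices, dtype=int)
        cal, pred = set(self.calibration_indices), set(self.prediction_indices)
        if cal & pred:
            raise ValueError("calibration and prediction sets overlap")

    @property
    def n_calibration(self) -> int:
        return self.calibration_indices.size

    @property
    def n_prediction(self) -> int:
        return self.prediction_indices.size

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "fraction": self.fraction,
                    "calibration_indices": self.calibration_indices.tolist(),
                    "prediction_indices": self.prediction_indices.tolist(),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "SplitResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            calibration_indices=d["calibration_indices"],
            prediction_indices=d["prediction_indices"],
            fraction=d["fraction"],
        )


def spxy_split(X: np.ndarray, y: np.ndarray, fraction: float = 0.75) -> SplitResult:
    """Deterministic SPXY split.

    Joint distance d(i,j) = dX(i,j)/max dX + dY(i,j)/max dY with Euclidean
    dX and (for 1-D y) absolute-difference dY. Selection seeds with the most
    distant pair, then repeatedly adds the sample whose minimum distance to
    the chosen set is largest (ties -> lowest index), until
    floor(fraction * N) calibration samples are chosen.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = X.shape[0]
    if y.shape[0] != n:
        raise ValueError("X and y sample counts differ")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")

    dx = squareform(pdist(X, metric="euclidean"))
    dy = squareform(pdist(y, metric="euclidean"))
    if dx.max() == 0 and dy.max() == 0:
        raise ValueError("all samples identical; SPXY distance degenerate")
    d = np.zeros_like(dx)
    if dx.max() > 0:
        d += dx / dx.max()
    if dy.max() > 0:
        d += dy / dy.max()

    n_cal = int(math.floor(fraction * n))
    n_cal = max(2, min(n_cal, n - 1))

    # seed: most distant pair, lowest-index pair on ties
    flat = np.argmax(d)  # argmax is row-major -> lowest (i, j) on exact ties
    i0, j0 = np.unravel_index(flat, d.shape)
    selected = [min(i0, j0), max(i0, j0)]
    in_set = np.zeros(n, dtype=bool)
    in_set[selected] = True
    min_dist = np.minimum(d[selected[0]], d[selected[1]])

    while len(selected) < n_cal:
        min_dist[in_set] = -np.inf
        nxt = int(np.argmax(min_dist))  # lowest index on ties
        selected.append(nxt)
        in_set[nxt] = True
        min_dist = np.minimum(min_dist, d[nxt])

    cal = np.sort(np.asarray(selected))
    pred = np.setdiff1d(np.arange(n), cal, assume_unique=True)
    return SplitResult(calibration_indices=cal, prediction_indices=pred, fraction=fraction)


def random_split(n: int, fraction: float = 0.75, seed: int = 0) -> SplitResult:
    """Seeded random alternative (explicitly flagged; not the default)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    order = np.random.default_rng(seed).permutation(n)
    n_cal = int(math.floor(fraction * n))
    return SplitResult(
        calibration_indices=np.sort(order[:n_cal]),
        prediction_indices=np.sort(order[n_cal:]),
        fraction=fraction,
    )
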
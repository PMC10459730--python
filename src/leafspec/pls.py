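"""Partial least squares regression core: SIMPLS fitting, k-fold
cross-validation and the evaluation metrics (R2, RMSE, RPD) used by every
model-building stage.

The fitter collapses the latent-variable model into a single affine map
(coefficients + intercept) so that downstream pixel-wise inversion is one
matrix-vector product per pixel.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FittedModel",
    "ModelMetrics",
    "fit_plsr",
    "cross_validate",
    "rmsecv",
    "evaluate",
    "rpd_label",
    "kfold_indices",
    "default_max_latent",
]


# --------------------------------------------------------------------------- #
# data containers
# --------------------------------------------------------------------------- #

@dataclass
class ModelMetrics:
    """Evaluation metrics for one model on one evaluation set.

    ``rpd`` is the standard deviation (ddof=1) of the reference values over
    the RMSE of prediction; ``rpd`` is ``inf`` when RMSE is exactly zero
    (flagged via :attr:`rpd_overflow`).
    """

    r2: float
    rmse: float
    rpd: float | None = None
    label: str | None = None

    @property
    def rpd_overflow(self) -> bool:
        return self.rpd is not None and np.isinf(self.rpd)

    def to_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "rpd": self.rpd, "label": self.label}


@dataclass
class FittedModel:
    """Collapsed PLSR model over a subset of bands.

    ``band_indices`` index into the full wavelength axis the model was
    trained against; ``coefficients`` has one weight per selected band.
    """

    band_indices: np.ndarray
    wavelengths: np.ndarray
    coefficients: np.ndarray
    intercept: float
    n_latent: int
    recipe: object | None = None  # PreprocessRecipe; kept loose to avoid cycle
    pigment: str | None = None
    metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.band_indices = np.asarray(self.band_indices, dtype=int)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape[0] != self.band_indices.shape[0]:
            raise ValueError("coefficient count must match band count")

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict from a matrix holding only the model's bands (columns
        aligned with ``band_indices`` order)."""
        X = np.asarray(X, dtype=float)
        return X @ self.coefficients + self.intercept

    def predict_full(self, X_full: np.ndarray) -> np.ndarray:
        """Predict from a matrix over the full band axis."""
        return self.predict(np.asarray(X_full, dtype=float)[:, self.band_indices])

    # ---- serialization ---------------------------------------------------- #

    def to_dict(self) -> dict:
        from .preprocessing import PreprocessRecipe  # local import, no cycle at module load

        recipe = self.recipe.to_dict() if isinstance(self.recipe, PreprocessRecipe) else self.recipe
        return {
            "pigment": self.pigment,
            "band_indices": self.band_indices.tolist(),
            "wavelengths": self.wavelengths.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": float(self.intercept),
            "n_latent": int(self.n_latent),
            "recipe": recipe,
            "metrics": self.metrics,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        from .preprocessing import PreprocessRecipe

        recipe = d.get("recipe")
        if isinstance(recipe, dict):
            recipe = PreprocessRecipe.from_dict(recipe)
        return cls(
            band_indices=np.asarray(d["band_indices"], dtype=int),
            wavelengths=np.asarray(d["wavelengths"], dtype=float),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            n_latent=int(d["n_latent"]),
            recipe=recipe,
            pigment=d.get("pigment"),
            metrics=d.get("metrics", {}),
        )

    @classmethod
    def from_json(cls, path) -> "FittedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# --------------------------------------------------------------------------- #
# SIMPLS core
# --------------------------------------------------------------------------- #

def _simpls(X: np.ndarray, y: np.ndarray, n_latent: int):
    """de Jong's SIMPLS for a single response.

    Returns (coef, intercept, T, R, q, x_mean, y_mean) where the latent-score
    route ``(X - x_mean) @ R @ q + y_mean`` equals the collapsed route
    ``X @ coef + intercept``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean

    s = Xc.T @ yc
    R = np.empty((p, n_latent))
    T = np.empty((n, n_latent))
    V = np.empty((p, n_latent))
    q = np.empty(n_latent)
    a_used = 0
    for a in range(n_latent):
        r = s.copy()
        t = Xc @ r
        tnorm = np.linalg.norm(t)
        if tnorm <= np.finfo(float).eps * max(n, p):
            break  # X exhausted; stop early
        t /= tnorm
        r /= tnorm
        pl = Xc.T @ t
        v = pl.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pl)
        vnorm = np.linalg.norm(v)
        if vnorm <= np.finfo(float).eps * max(n, p):
            break
        v /= vnorm
        s = s - v * (v @ s)
        R[:, a] = r
        T[:, a] = t
        V[:, a] = v
        q[a] = yc @ t
        a_used = a + 1

    R = R[:, :a_used]
    T = T[:, :a_used]
    q = q[:a_used]
    coef = R @ q
    intercept = y_mean - x_mean @ coef
    return coef, intercept, T, R, q, x_mean, y_mean


def default_max_latent(n_samples: int, n_vars: int, cap: int = 15) -> int:
    """Latent-count ceiling used across CV loops: min(cap, 20, N/3, vars)."""
    return max(1, min(cap, 20, n_samples // 3, n_vars))


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    n_latent: int,
    *,
    band_indices: Sequence[int] | None = None,
    wavelengths: Sequence[float] | None = None,
    recipe=None,
    pigment: str | None = None,
) -> FittedModel:
    """Fit a PLSR model and collapse it to an affine map.

    Raises if ``n_latent`` exceeds min(n_samples - 1, n_vars) or if ``y``
    has zero variance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x bands)")
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y sample counts differ")
    rank_bound = min(n - 1, p)
    if not (1 <= n_latent <= rank_bound):
        raise ValueError(f"n_latent={n_latent} outside [1, {rank_bound}]")
    if np.std(y) == 0:
        raise ValueError("zero-variance response")

    coef, intercept, *_ = _simpls(X, y, n_latent)
    if band_indices is None:
        band_indices = np.arange(p)
    if wavelengths is None:
        wavelengths = np.full(p, np.nan)
    return FittedModel(
        band_indices=np.asarray(band_indices),
        wavelengths=np.asarray(wavelengths, dtype=float),
        coefficients=coef,
        intercept=float(intercept),
        n_latent=int(n_latent),
        recipe=recipe,
        pigment=pigment,
    )


# --------------------------------------------------------------------------- #
# cross-validation
# --------------------------------------------------------------------------- #

def kfold_indices(n: int, k: int, seed: int | None = 0) -> list[np.ndarray]:
    """Seeded-random fold assignment; ``seed=None`` gives contiguous folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("fewer samples than folds")
    order = np.arange(n)
    if seed is not None:
        order = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(order, k)
    for f in folds:
        if f.size < 1:
            raise ValueError("empty fold")
    return folds


def rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    n_latent: int,
    folds: list[np.ndarray],
) -> float:
    """Pooled k-fold cross-validated RMSE at a fixed latent count."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    sq = 0.0
    for test in folds:
        train = np.setdiff1d(np.arange(n), test, assume_unique=False)
        if train.size < 2:
            raise ValueError("fold leaves < 2 training samples")
        a = min(n_latent, train.size - 1, X.shape[1])
        coef, intercept, *_ = _simpls(X[train], y[train], a)
        resid = X[test] @ coef + intercept - y[test]
        sq += float(resid @ resid)
    return float(np.sqrt(sq / n))


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    max_latent: int | None = None,
    seed: int = 0,
) -> tuple[int, float]:
    """Select the latent count minimizing k-fold RMSEcv.

    Returns ``(best_n_latent, best_rmsecv)``; ties go to the smaller count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if max_latent is None:
        max_latent = default_max_latent(n, p)
    max_latent = max(1, min(max_latent, n - 1 - (n // k), p))
    folds = kfold_indices(n, k, seed)
    best = (1, np.inf)
    for a in range(1, max_latent + 1):
        err = rmsecv(X, y, a, folds)
        if err < best[1]:
            best = (a, err)
    return best


# --------------------------------------------------------------------------- #
# metrics
# --------------------------------------------------------------------------- #

def rpd_label(rpd: float) -> str:
    """Three-way interpretation: >2 good, 1.4-2 some ability, <1.4 unable."""
    if rpd >= 2.0:
        return "good"
    if rpd >= 1.4:
        return "some ability"
    return "unable"


def evaluate(model: FittedModel, X: np.ndarray, y: np.ndarray, *, full_axis: bool = False) -> ModelMetrics:
    """R2, RMSE and RPD of ``model`` on an evaluation set.

    ``full_axis=True`` means X spans the whole wavelength axis and the
    model's band subset is taken internally.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 2 or np.std(y) == 0:
        raise ValueError("zero-variance reference vector")
    yhat = model.predict_full(X) if full_axis else model.predict(X)
    resid = y - yhat
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(ss_res / y.size))
    sd = float(np.std(y, ddof=1))
    if rmse == 0.0:
        warnings.warn("RMSE is exactly zero; RPD overflows", RuntimeWarning)
        rpd = float("inf")
    else:
        rpd = sd / rmse
    return ModelMetrics(r2=r2, rmse=rmse, rpd=rpd, label=rpd_label(rpd))
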
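"""Competitive adaptive reweighted sampling (CARS): coarse wavelength
screening by Monte Carlo sampling, an exponentially decreasing retention
schedule (EDF) and adaptive reweighted sampling (ARS), with each run's
subset scored by k-fold RMSEcv on the full calibration set."""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls import _simpls, cross_validate, default_max_latent, kfold_indices, rmsecv

__all__ = ["EDFSchedule", "VariableSubset", "CARSTrace", "edf_schedule", "cars_select"]


@dataclass
class EDFSchedule:
    """Exponentially decreasing retention-ratio schedule r_j = a * exp(-b*j),
    pinned so r_1 = 1 and r_N = 2/p."""

    p: int
    n_runs: int
    a: float
    b: float
    ratios: np.ndarray

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)


def edf_schedule(p: int, n_runs: int) -> EDFSchedule:
    """Build the EDF schedule: a = (p/2)^(1/(N-1)), b = ln(p/2)/(N-1)."""
    if p < 3:
        raise ValueError("p must be >= 3")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    a = (p / 2.0) ** (1.0 / (n_runs - 1))
    b = math.log(p / 2.0) / (n_runs - 1)
    j = np.arange(1, n_runs + 1)
    ratios = a * np.exp(-b * j)
    return EDFSchedule(p=p, n_runs=n_runs, a=a, b=b, ratios=ratios)


@dataclass
class VariableSubset:
    """Ordered selected band indices with selection provenance."""

    indices: np.ndarray
    wavelengths: np.ndarray
    source: str
    score: float  # RMSEcv of the winning subset

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if np.unique(self.indices).size != self.indices.size:
            raise ValueError("duplicate indices in subset")
        if not np.all(np.diff(self.indices) > 0):
            raise ValueError("indices must be sorted ascending")

    def __len__(self) -> int:
        return self.indices.size

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "indices": self.indices.tolist(),
                    "wavelengths": self.wavelengths.tolist(),
                    "source": self.source,
                    "score": self.score,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "VariableSubset":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


@dataclass
class CARSTrace:
    """Per-run diagnostics: retained-variable counts, RMSEcv, subsets and
    regression-coefficient paths (for NSV / RMSEcv / RC-path style plots)."""

    runs: pd.DataFrame  # columns: run, n_retained, rmsecv
    subsets: list = field(default_factory=list)  # retained index arrays per run
    coef_path: np.ndarray | None = None  # (n_runs, p) |K| magnitudes, 0 where dropped
    best_run: int = -1
    n_latent: int = 0

    def to_csv(self, path) -> None:
        self.runs.to_csv(path, index=False)


def _rank_keep(abs_k: np.ndarray, retained: np.ndarray, n_keep: int) -> np.ndarray:
    """Top ``n_keep`` of ``retained`` by |K|, ties to the lower band index."""
    order = np.lexsort((retained, -abs_k))  # primary: -|K| desc, secondary: index asc
    return np.sort(retained[order[:n_keep]])


def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    *,
    wavelengths: np.ndarray | None = None,
    n_runs: int = 100,
    cv_folds: int = 5,
    seed: int = 0,
    n_latent: int | None = None,
    sample_fraction: float = 0.8,
) -> tuple[VariableSubset, CARSTrace]:
    """Run CARS on a (preprocessed) calibration set.

    Per run j: draw ``sample_fraction`` of the samples without replacement,
    fit PLSR on the currently retained variables, rank |K_i|, keep the top
    ceil(r_j * p) (EDF), then resample with replacement with weights
    w_i = |K_i| / sum|K| keeping the distinct draws (ARS). Each run's subset
    is scored by k-fold RMSEcv on the *full* calibration set; the subset
    with minimal RMSEcv wins.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if wavelengths is None:
        wavelengths = np.arange(p, dtype=float)
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")

    sched = edf_schedule(p, n_runs)
    root = np.random.SeedSequence(seed)
    mc_rng = np.random.default_rng(root.spawn(1)[0])
    fold_seed = int(root.generate_state(1)[0] % (2**31))
    folds = kfold_indices(n, cv_folds, fold_seed)

    # inner latent count fixed once on the full calibration set (cost control)
    if n_latent is None:
        n_latent, _ = cross_validate(X, y, k=cv_folds, max_latent=default_max_latent(n, p), seed=fold_seed)

    n_sub = max(2, int(round(sample_fraction * n)))
    retained = np.arange(p)
    rows = []
    subsets: list[np.ndarray] = []
    coef_path = np.zeros((n_runs, p))

    for j in range(1, n_runs + 1):
        pick = mc_rng.choice(n, size=n_sub, replace=False)
        a = min(n_latent, len(retained), n_sub - 1)
        coef, *_ = _simpls(X[np.ix_(pick, retained)], y[pick], a)
        abs_k = np.abs(coef)
        coef_path[j - 1, retained] = abs_k

        # EDF: keep top ceil(r_j * p) of the retained set by |K|
        n_keep = min(len(retained), int(math.ceil(sched.ratios[j - 1] * p)))
        retained = _rank_keep(abs_k, retained, n_keep)
        abs_k = coef_path[j - 1, retained]

        # ARS: weighted resample with replacement, keep distinct draws.
        # Draw count is the original variable count p (drawing only the
        # currently retained count shrinks the set geometrically on its own).
        total = abs_k.sum()
        w = abs_k / total if total > 0 else np.full(len(retained), 1.0 / len(retained))
        draws = mc_rng.choice(retained, size=p, replace=True, p=w)
        retained = np.unique(draws)

        if len(retained) < 2:
            warnings.warn(f"CARS subset collapsed below 2 variables at run {j}; truncating")
            break

        score = rmsecv(X[:, retained], y, min(n_latent, len(retained)), folds)
        rows.append({"run": j, "n_retained": len(retained), "rmsecv": score})
        subsets.append(retained.copy())

    if not rows:
        raise RuntimeError("CARS produced no scorable run")
    runs = pd.DataFrame(rows)
    best_pos = int(runs["rmsecv"].idxmin())
    best = subsets[best_pos]
    trace = CARSTrace(
        runs=runs,
        subsets=subsets,
        coef_path=coef_path[: len(rows)],
        best_run=int(runs.loc[best_pos, "run"]),
        n_latent=int(n_latent),
    )
    subset = VariableSubset(
        indices=best,
        wavelengths=np.asarray(wavelengths, dtype=float)[best],
        source="CARS",
        score=float(runs.loc[best_pos, "rmsecv"]),
    )
    return subset, trace
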
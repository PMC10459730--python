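"""Iteratively retained informative variables (IRIV): fine screening of a
variable set via random balanced binary-inclusion submodels, a Mann-Whitney
classification into strong / weak / uninformative / interfering variables,
iterated elimination, and a final backward-elimination pass."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .cars import VariableSubset
from .pls import _simpls, kfold_indices

__all__ = [
    "mann_whitney_u",
    "iriv_classify",
    "iriv_iterate",
    "backward_eliminate",
    "IRIVResult",
]

CLASSES = ("strong", "weak", "uninformative", "interfering")
_EXACT_MAX_N = 12


# --------------------------------------------------------------------------- #
# Mann-Whitney U
# --------------------------------------------------------------------------- #

def mann_whitney_u(sample1, sample2) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U1, p) where U1 is the statistic of ``sample1`` (number of
    pairs x > y, counting ties as 1/2). Combined n <= 12 uses the exact
    permutation distribution (full enumeration, ties handled naturally);
    larger samples use the normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(sample1, dtype=float).ravel()
    y = np.asarray(sample2, dtype=float).ravel()
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if n1 + n2 <= _EXACT_MAX_N:
        # exact: enumerate every split of the pooled values into group sizes
        offset = n1 * (n1 + 1) / 2.0
        us = np.asarray(
            [ranks[list(combo)].sum() - offset for combo in combinations(range(n1 + n2), n1)]
        )
        p_le = np.mean(us <= u1 + 1e-12)
        p_ge = np.mean(us >= u1 - 1e-12)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u1, float(p)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u1, 1.0
    z = (abs(u1 - mu) - 0.5) / np.sqrt(var)  # continuity-corrected
    z = max(z, 0.0)
    return u1, float(min(1.0, 2.0 * norm.sf(z)))


# --------------------------------------------------------------------------- #
# classification round
# --------------------------------------------------------------------------- #

def _fold_id(n: int, k: int, seed: int) -> np.ndarray:
    """Per-sample fold labels matching :func:`leafspec.pls.kfold_indices`."""
    fold_id = np.empty(n, dtype=np.int64)
    for f, idx in enumerate(kfold_indices(n, k, seed)):
        fold_id[idx] = f
    return fold_id


def _balanced_inclusion_matrix(m: int, p: int, rng: np.random.Generator) -> np.ndarray:
    """m x p binary matrix, each column exactly m/2 ones.

    Rows that end up with no included variable are repaired by moving a 1
    from a donor row in a random column (keeps column sums balanced).
    """
    if m % 2 or m < 20:
        raise ValueError("m must be even and >= 20")
    half = np.concatenate([np.ones(m // 2, dtype=np.int8), np.zeros(m // 2, dtype=np.int8)])
    A = np.column_stack([rng.permutation(half) for _ in range(p)])
    for _ in range(10 * m):
        empty = np.flatnonzero(A.sum(axis=1) == 0)
        if empty.size == 0:
            return A
        k = int(empty[0])
        j = int(rng.integers(p))
        donors = np.flatnonzero((A[:, j] == 1) & (A.sum(axis=1) >= 2))
        if donors.size == 0:
            continue
        donor = int(rng.choice(donors))
        A[k, j], A[donor, j] = 1, 0
    raise RuntimeError("could not repair inclusion matrix")


def _cv_rmse_py(X: np.ndarray, y: np.ndarray, fold_id: np.ndarray, k: int, n_latent: int) -> float:
    """Pooled k-fold RMSE (pure-numpy reference path)."""
    sq = 0.0
    n = y.size
    idx = np.arange(n)
    for f in range(k):
        train = idx[fold_id != f]
        test = idx[fold_id == f]
        a = min(n_latent, train.size - 1, X.shape[1])
        coef, intercept, *_ = _simpls(X[train], y[train], a)
        resid = X[test] @ coef + intercept - y[test]
        sq += float(resid @ resid)
    return float(np.sqrt(sq / n))


try:  # jitted kernel: same algorithm, ~7x faster on the m*p submodel loops
    import numba as _nb

    @_nb.njit(cache=True)
    def _cv_rmse_nb(X, y, fold_id, k, n_latent):  # pragma: no cover - parity-tested
        n, p = X.shape
        sq = 0.0
        for f in range(k):
            ntr = 0
            for i in range(n):
                if fold_id[i] != f:
                    ntr += 1
            Xtr = np.empty((ntr, p))
            ytr = np.empty(ntr)
            j = 0
            for i in range(n):
                if fold_id[i] != f:
                    Xtr[j] = X[i]
                    ytr[j] = y[i]
                    j += 1
            A = min(n_latent, ntr - 1, p)
            xm = np.zeros(p)
            for i in range(ntr):
                xm += Xtr[i]
            xm /= ntr
            ym = ytr.mean()
            Xc = Xtr - xm
            yc = ytr - ym
            s = Xc.T @ yc
            Rt = np.zeros((A, p))  # row-contiguous weight/basis storage
            Vt = np.zeros((A, p))
            q = np.zeros(A)
            aused = 0
            for a in range(A):
                r = s.copy()
                t = Xc @ r
                tn = np.sqrt((t * t).sum())
                if tn <= 1e-13 * max(ntr, p):
                    break
                t /= tn
                r /= tn
                pl = Xc.T @ t
                v = pl.copy()
                for b in range(a):
                    v -= (Vt[b] * pl).sum() * Vt[b]
                vn = np.sqrt((v * v).sum())
                if vn <= 1e-13 * max(ntr, p):
                    break
                v /= vn
                s -= v * (v * s).sum()
                Rt[a] = r
                Vt[a] = v
                q[a] = (yc * t).sum()
                aused = a + 1
            coef = np.zeros(p)
            for a in range(aused):
                coef += Rt[a] * q[a]
            icept = ym - (xm * coef).sum()
            for i in range(n):
                if fold_id[i] == f:
                    pred = (X[i] * coef).sum() + icept
                    d = pred - y[i]
                    sq += d * d
        return np.sqrt(sq / n)

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _cv_rmse(X, y, fold_id, k, n_latent, use_numba: bool = True) -> float:
    if _HAVE_NUMBA and use_numba:
        return float(_cv_rmse_nb(np.ascontiguousarray(X), y, fold_id, k, n_latent))
    return _cv_rmse_py(X, y, fold_id, k, n_latent)


def iriv_classify(
    X: np.ndarray,
    y: np.ndarray,
    m: int = 200,
    cv_folds: int = 5,
    seed: int = 0,
    n_latent_cap: int = 10,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """One IRIV classification round over the columns of X.

    For each row of a balanced m x p inclusion matrix A, the included
    variables are cross-validated (RMSEcv0). For each variable i, column i
    is flipped (matrix B) and each row refit (RMSEcvi). Phi0/Phi_i pool, per
    row, the RMSEcv of whichever model includes / excludes variable i;
    DM_i = mean(Phi0) - mean(Phi_i), and a two-sided Mann-Whitney p-value on
    (Phi0, Phi_i) discriminates strong vs weak (DM<0) and uninformative vs
    interfering (DM>0).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 variables")

    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    fold_seed = int(root.generate_state(1)[0] % (2**31))
    fold_id = _fold_id(n, cv_folds, fold_seed)

    A = _balanced_inclusion_matrix(m, p, rng)

    rmse0 = np.empty(m)
    for k in range(m):
        cols = np.flatnonzero(A[k])
        rmse0[k] = _cv_rmse(X[:, cols], y, fold_id, cv_folds, min(n_latent_cap, cols.size))

    rmse_flip = np.empty((m, p))
    for i in range(p):
        for k in range(m):
            row = A[k].copy()
            row[i] ^= 1
            cols = np.flatnonzero(row)
            if cols.size == 0:
                rmse_flip[k, i] = np.inf  # excluded-everything row; cannot model
                continue
            rmse_flip[k, i] = _cv_rmse(
                X[:, cols], y, fold_id, cv_folds, min(n_latent_cap, cols.size)
            )

    records = []
    for i in range(p):
        inc = A[:, i] == 1
        phi0 = np.where(inc, rmse0, rmse_flip[:, i])  # models containing i
        phii = np.where(inc, rmse_flip[:, i], rmse0)  # models excluding i
        finite = np.isfinite(phi0) & np.isfinite(phii)
        dm = float(phi0[finite].mean() - phii[finite].mean())
        _, pval = mann_whitney_u(phi0[finite], phii[finite])
        if dm < 0:
            cls = "strong" if pval < p_threshold else "weak"
        else:
            cls = "interfering" if pval < p_threshold else "uninformative"
        records.append({"variable": i, "DM": dm, "p_value": pval, "class": cls})
    return pd.DataFrame(records)


# --------------------------------------------------------------------------- #
# iteration + backward elimination
# --------------------------------------------------------------------------- #

@dataclass
class IRIVResult:
    subset: VariableSubset
    rounds: pd.DataFrame  # classification table of every round (column 'round')
    n_rounds: int


def iriv_iterate(
    X: np.ndarray,
    y: np.ndarray,
    m: int = 200,
    cv_folds: int = 5,
    seed: int = 0,
    n_latent_cap: int = 10,
    *,
    wavelengths: np.ndarray | None = None,
    max_rounds: int = 50,
) -> IRIVResult:
    """Repeat classification, dropping uninformative + interfering variables,
    until a round eliminates nothing; survivors keep their final labels."""
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if wavelengths is None:
        wavelengths = np.arange(p, dtype=float)
    survivors = np.arange(p)
    tables = []
    root = np.random.SeedSequence(seed)

    for rnd in range(1, max_rounds + 1):
        round_seed = int(root.generate_state(rnd)[-1] % (2**31))
        if survivors.size < 2:
            break
        table = iriv_classify(
            X[:, survivors], y, m=m, cv_folds=cv_folds, seed=round_seed, n_latent_cap=n_latent_cap
        )
        global_idx = survivors[table["variable"].to_numpy()]
        table = table.assign(
            variable=global_idx,
            wavelength=np.asarray(wavelengths, dtype=float)[global_idx],
            round=rnd,
        )
        tables.append(table)
        keep = table["class"].isin(["strong", "weak"]).to_numpy()
        if keep.all():
            break
        survivors = table.loc[keep, "variable"].to_numpy()
        if survivors.size == 0:
            raise RuntimeError(
                "IRIV eliminated every variable; increase m or skip selection"
            )

    rounds = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    subset = VariableSubset(
        indices=np.sort(survivors),
        wavelengths=np.asarray(wavelengths, dtype=float)[np.sort(survivors)],
        source="CARS-IRIV",
        score=float("nan"),
    )
    return IRIVResult(subset=subset, rounds=rounds, n_rounds=len(tables))


def backward_eliminate(
    X: np.ndarray,
    y: np.ndarray,
    indices: np.ndarray,
    cv_folds: int = 5,
    seed: int = 0,
    n_latent_cap: int = 10,
    *,
    wavelengths: np.ndarray | None = None,
    n_fold_repeats: int = 3,
    rel_improvement: float = 0.002,
) -> VariableSubset:
    """Greedy backward elimination on RMSEcv.

    Each pass removes the single variable whose removal lowers RMSEcv the
    most; stops when no removal improves, or 2 variables remain. Two guards
    against CV selection noise (the greedy argmin over many near-tied
    candidates otherwise over-prunes): RMSEcv is averaged over
    ``n_fold_repeats`` fold assignments, and a removal must beat the current
    score by a relative margin of ``rel_improvement``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    current = np.asarray(indices, dtype=int).copy()
    if current.size < 2:
        raise ValueError("need at least 2 variables to eliminate from")
    if wavelengths is None:
        wavelengths = np.arange(X.shape[1], dtype=float)

    fold_ids = [_fold_id(n, cv_folds, seed + k) for k in range(max(1, n_fold_repeats))]

    def score(cols: np.ndarray) -> float:
        return float(
            np.mean(
                [
                    _cv_rmse(X[:, cols], y, fid, cv_folds, min(n_latent_cap, cols.size))
                    for fid in fold_ids
                ]
            )
        )

    best_rmse = score(current)
    while current.size > 2:
        trials = np.array(
            [score(np.delete(current, pos)) for pos in range(current.size)]
        )
        pos = int(np.argmin(trials))
        if trials[pos] < best_rmse * (1.0 - rel_improvement):
            best_rmse = float(trials[pos])
            current = np.delete(current, pos)
        else:
            break

    current = np.sort(current)
    return VariableSubset(
        indices=current,
        wavelengths=np.asarray(wavelengths, dtype=float)[current],
        source="CARS-IRIV",
        score=best_rmse,
    )
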
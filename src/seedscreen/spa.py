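"""Successive projections algorithm (SPA) for wavelength selection.

Forward selection that grows low-collinearity variable chains by
orthogonal projection, then scores every chain prefix with an ordinary
least-squares model on a held-out validation set and returns the subset
with minimal validation RMSE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = ["SPAResult", "spa_chain", "spa_select", "exhaustive_best_subset"]

_TOL = 1e-10


@dataclass
class SPAResult:
    """Outcome of an SPA selection run.

    ``selected`` holds band indices in chain order; ``rmse_path`` is the
    validation RMSE of the winning start's chain prefixes for each
    candidate size ``k_min..k_max``.
    """

    selected: list[int]
    selected_nm: np.ndarray | None
    rmse: float
    rmse_path: np.ndarray
    start: int
    chain_store: dict[int, list[int]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.selected)

    def to_dict(self) -> dict:
        return {
            "selected_indices": [int(i) for i in self.selected],
            "selected_nm": None
            if self.selected_nm is None
            else [float(w) for w in self.selected_nm],
            "rmse": float(self.rmse),
            "rmse_path": [float(r) for r in self.rmse_path],
            "start": int(self.start),
            "flags": list(self.flags),
        }


def spa_chain(X: np.ndarray, start: int, k: int, center: bool = False) -> list[int]:
    """Grow one projection chain of (at most) ``k`` bands from ``start``.

    At each step the next band is the one whose column has maximal norm
    after projection onto the orthogonal complement of the span of the
    columns already chosen; ties break toward the lowest index.  The
    chain is truncated with a warning once no candidate retains norm
    above tolerance (rank exhausted).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not (0 <= start < p):
        raise ValueError(f"start {start} outside band range 0..{p - 1}")
    if not (1 <= k <= p):
        raise ValueError(f"chain length {k} outside 1..{p}")
    if center:
        X = X - X.mean(axis=0)

    scale = float(np.linalg.norm(X, axis=0).max())
    if scale == 0:
        raise ValueError("all columns are zero")
    work = X.copy()
    chain = [start]
    chosen = np.zeros(p, dtype=bool)
    chosen[start] = True
    for _ in range(k - 1):
        xj = work[:, chain[-1]]
        nj = xj @ xj
        if nj <= (_TOL * scale) ** 2:
            warnings.warn("chain truncated: projected pivot has zero norm", stacklevel=2)
            break
        work = work - np.outer(xj, xj @ work) / nj
        norms = np.einsum("ij,ij->j", work, work)
        norms[chosen] = -np.inf
        best = norms.max()
        if best <= (_TOL * scale) ** 2:
            warnings.warn("chain truncated: rank exhausted", stacklevel=2)
            break
        # tolerance-aware tie break toward the lowest index
        nxt = int(np.flatnonzero(norms >= best * (1 - 1e-12))[0])
        chain.append(nxt)
        chosen[nxt] = True
    return chain


def _ols_val_rmse(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cols: list[int],
) -> tuple[float, bool]:
    """Validation RMSE of an intercept + selected-columns OLS fit.

    Rank-deficient designs are solved with the minimum-norm least-squares
    solution; the second return value flags that condition.
    """
    A = np.column_stack([np.ones(len(X_train)), X_train[:, cols]])
    coef, _, rank, _ = np.linalg.lstsq(A, y_train, rcond=None)
    deficient = rank < A.shape[1]
    Av = np.column_stack([np.ones(len(X_val)), X_val[:, cols]])
    resid = y_val - Av @ coef
    return float(np.sqrt(np.mean(resid**2))), deficient


def spa_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    k_min: int = 1,
    k_max: int = 30,
    wavelengths: np.ndarray | None = None,
    center: bool = True,
) -> SPAResult:
    """Select characteristic bands by SPA + validation-RMSE minimisation.

    Every band serves as a chain start; every prefix size in
    ``[k_min, k_max]`` of every chain is scored by OLS validation RMSE.
    The winner is the subset with minimal RMSE; ties resolve to the
    smaller size, then to lexicographically smaller index tuples.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    n, p = X_train.shape
    k_max = min(k_max, max(n - 2, 1), p)
    k_min = max(1, min(k_min, k_max))

    if center:
        mu = X_train.mean(axis=0)
        Xc_train = X_train - mu
        Xc_val = X_val - mu
    else:
        Xc_train, Xc_val = X_train, X_val

    flags: list[str] = []
    chain_store: dict[int, list[int]] = {}
    best = None  # (rmse, k, sorted_subset, chain_prefix, start)
    rmse_paths: dict[int, np.ndarray] = {}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # chain truncation handled via prefix length
        for start in range(p):
            chain = spa_chain(Xc_train, start, k_max, center=False)
            chain_store[start] = chain
            path = np.full(k_max - k_min + 1, np.nan)
            for k in range(k_min, min(k_max, len(chain)) + 1):
                prefix = chain[:k]
                rmse, deficient = _ols_val_rmse(Xc_train, y_train, Xc_val, y_val, prefix)
                if deficient and "rank_deficient_prefix" not in flags:
                    flags.append("rank_deficient_prefix")
                path[k - k_min] = rmse
                key = (rmse, k, tuple(sorted(prefix)))
                if best is None or _beats(key, best[:3]):
                    best = (rmse, k, tuple(sorted(prefix)), prefix, start)
            rmse_paths[start] = path

    assert best is not None
    rmse, k, _, prefix, start = best
    selected_nm = None if wavelengths is None else np.asarray(wavelengths)[prefix]
    return SPAResult(
        selected=list(prefix),
        selected_nm=selected_nm,
        rmse=rmse,
        rmse_path=rmse_paths[start],
        start=start,
        chain_store=chain_store,
        flags=flags,
    )


def _beats(candidate: tuple, incumbent: tuple, tol: float = 1e-12) -> bool:
    """Candidate (rmse, k, subset) wins on smaller rmse, then k, then indices."""
    r_c, k_c, s_c = candidate
    r_i, k_i, s_i = incumbent
    if r_c < r_i - tol:
        return True
    if r_c > r_i + tol:
        return False
    return (k_c, s_c) < (k_i, s_i)


def exhaustive_best_subset(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    k_min: int = 1,
    k_max: int = 3,
    center: bool = True,
) -> tuple[float, tuple[int, ...]]:
    """Brute-force oracle: minimal validation RMSE over all subsets.

    Enumerates every band subset of size ``k_min..k_max`` and scores it
    with the same OLS criterion as :func:`spa_select`.  Intended for
    small problems (``p <= ~12``) in tests and audits.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    p = X_train.shape[1]
    if center:
        mu = X_train.mean(axis=0)
        X_train = X_train - mu
        X_val = X_val - mu
    best_rmse = np.inf
    best_subset: tuple[int, ...] = ()
    for k in range(k_min, min(k_max, p) + 1):
        for subset in combinations(range(p), k):
            rmse, _ = _ols_val_rmse(X_train, y_train, X_val, y_val, list(subset))
            if rmse < best_rmse - 1e-12:
                best_rmse = rmse
                best_subset = subset
    return float(best_rmse), best_subset
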
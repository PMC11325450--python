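"""Spatial eigenfunctions, (partial) RDA with adjusted R2, permutation
forward selection, and three-set variation partitioning.

PCNM (principal coordinates of neighbour matrices) builds spatial
predictors by truncating the inter-site distance matrix at the longest
minimum-spanning-tree edge, replacing larger distances by 4x the
truncation, and taking the positive-eigenvalue principal coordinates of
the result.  RDA here is the multivariate least-squares projection of a
column-centred response on a predictor matrix; explained variance is
summarized by Ezekiel's adjusted R2, and variation partitioning decomposes
the adjusted R2 of three predictor sets (parent-core membership dummies,
selected PCNM axes, selected elemental-composition z-scores) by
inclusion-exclusion.  Fractions on the adjusted scale may be negative;
display layers conventionally truncate at zero, stored values are raw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

__all__ = ["PcnmBasis", "FitResult", "VarpartResult", "pcnm", "rda",
           "partial_rda", "forward_select", "variation_partition3",
           "core_dummies"]


@dataclass(frozen=True)
class PcnmBasis:
    ids: tuple
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    truncation: float


@dataclass(frozen=True)
class FitResult:
    R2: float
    R2_adj: float
    n: int
    p: int
    permutation_p: float = np.nan


@dataclass(frozen=True)
class VarpartResult:
    """Adjusted-R2 fractions for three predictor sets.

    ``individual``, ``pairwise`` and ``triple`` follow the standard
    inclusion-exclusion decomposition; ``r2adj`` maps each non-empty
    predictor-set union (frozenset of names) to its adjusted R2.
    """

    set_names: tuple
    individual: dict
    pairwise: dict
    triple: float
    residual: float
    r2adj: dict

    def largest_individual(self) -> str:
        return max(self.individual, key=self.individual.get)


def pcnm(coords: np.ndarray, ids=None, truncation: float | None = None) -> PcnmBasis:
    """Spatial eigenfunctions from a truncated distance matrix.

    Default truncation is the longest edge of the minimum spanning tree of
    the Euclidean distance matrix; distances above it are replaced by
    4x the truncation before PCoA.  Axes with positive eigenvalues are
    returned, scaled by the square root of their eigenvalue.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 3:
        raise ValueError("need at least 3 sites")
    if ids is None:
        ids = tuple(str(i) for i in range(n))
    d = squareform(pdist(coords))
    if truncation is None:
        mst = minimum_spanning_tree(d).toarray()
        truncation = float(mst.max())
    if truncation <= 0:
        raise ValueError("all sites coincident")
    dm = np.where(d > truncation, 4.0 * truncation, d)
    np.fill_diagonal(dm, 0.0)
    a = -0.5 * dm ** 2
    centre = np.eye(n) - np.ones((n, n)) / n
    g = centre @ a @ centre
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-9, abs(eigval).max() * 1e-10)
    vecs = eigvec[:, pos] * np.sqrt(eigval[pos])
    # deterministic sign: largest-magnitude loading positive
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return PcnmBasis(tuple(ids), vecs, eigval[pos], truncation)


def _as_matrix(Y) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y[:, None] if Y.ndim == 1 else Y


def _basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of centred X (collinear
    columns dropped)."""
    if X.size == 0:
        return np.empty((X.shape[0], 0))
    Xc = X - X.mean(axis=0)
    q, r = np.linalg.qr(Xc)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-9 * max(1.0, diag.max())
    return q[:, keep]


def _r2(Y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """R2 of the least-squares projection of centred Y on [1, X]; returns
    (R2, effective predictor count after dropping collinear columns)."""
    Yc = Y - Y.mean(axis=0)
    sst = float((Yc ** 2).sum())
    if sst == 0:
        raise ValueError("response has zero variance")
    q = _basis(X)
    if q.shape[1] == 0:
        return 0.0, 0
    return float(((q.T @ Yc) ** 2).sum()) / sst, q.shape[1]


def _ezekiel(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        raise ValueError("model unestimable: p >= n - 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def rda(Y, X, n_perm: int = 0, seed: int = 0) -> FitResult:
    """Redundancy analysis: multivariate OLS of centred Y on X.

    For univariate Y this is ordinary least-squares R2.  With
    ``n_perm > 0`` a permutation p-value for the global model (row
    permutation of Y) is included.
    """
    Y, X = _as_matrix(Y), _as_matrix(X) if np.size(X) else np.empty((len(_as_matrix(Y)), 0))
    n = Y.shape[0]
    if X.shape[0] not in (0, n) and X.size:
        raise ValueError("Y and X row counts differ")
    r2, p = _r2(Y, X)
    if n - p - 1 <= 0:
        raise ValueError("model unestimable: p >= n - 1")
    perm_p = np.nan
    if n_perm > 0 and p > 0:
        rng = np.random.default_rng(seed)
        q = _basis(X)
        Yc = Y - Y.mean(axis=0)
        sst = float((Yc ** 2).sum())
        hits = 1
        for _ in range(n_perm):
            Yp = Yc[rng.permutation(n)]
            r2p = float(((q.T @ Yp) ** 2).sum()) / sst
            if r2p >= r2 - 1e-12:
                hits += 1
        perm_p = hits / (n_perm + 1)
    return FitResult(R2=r2, R2_adj=_ezekiel(r2, n, p), n=n, p=p,
                     permutation_p=perm_p)


def partial_rda(Y, X, Z, n_perm: int = 0, seed: int = 0) -> FitResult:
    """Individual (conditional) fraction of X given conditioning set Z.

    R2 and adjusted R2 are differences R2(X u Z) - R2(Z); the permutation
    test, when requested, permutes residuals of Y on Z (Freedman-Lane).
    """
    Y = _as_matrix(Y)
    X = _as_matrix(X) if np.size(X) else np.empty((Y.shape[0], 0))
    Z = _as_matrix(Z) if np.size(Z) else np.empty((Y.shape[0], 0))
    n = Y.shape[0]
    if Z.shape[1] == 0:
        return rda(Y, X, n_perm=n_perm, seed=seed)
    both = np.hstack([Z, X])
    r2_zx, p_zx = _r2(Y, both)
    r2_z, p_z = _r2(Y, Z)
    if n - p_zx - 1 <= 0:
        raise ValueError("model unestimable: p >= n - 1")
    frac = _ezekiel(r2_zx, n, p_zx) - _ezekiel(r2_z, n, p_z)
    perm_p = np.nan
    if n_perm > 0:
        # Freedman-Lane: permute residuals of Y on the conditioning set
        rng = np.random.default_rng(seed)
        Yc = Y - Y.mean(axis=0)
        qz = _basis(Z)
        qzx = _basis(both)
        fitted_z = qz @ (qz.T @ Yc)
        resid_z = Yc - fitted_z
        stat = r2_zx - r2_z
        hits = 1
        for _ in range(n_perm):
            Yp = fitted_z + resid_z[rng.permutation(n)]
            Yp = Yp - Yp.mean(axis=0)
            sst = float((Yp ** 2).sum())
            gain = (float(((qzx.T @ Yp) ** 2).sum())
                    - float(((qz.T @ Yp) ** 2).sum())) / sst
            if gain >= stat - 1e-12:
                hits += 1
        perm_p = hits / (n_perm + 1)
    return FitResult(R2=r2_zx - r2_z, R2_adj=frac, n=n, p=p_zx - p_z,
                     permutation_p=perm_p)


def forward_select(Y, candidates: pd.DataFrame, alpha: float = 0.05,
                   n_perm: int = 999, seed: int = 0) -> list:
    """Permutation forward selection with the double stopping rule.

    Candidates must be centred and scaled.  At each step the candidate
    maximizing R2 is tested by residual permutation (given the already
    selected set); it enters only if its permutation p <= alpha and the
    cumulative adjusted R2 stays at or below the adjusted R2 of the full
    candidate model.  Returns the selected column names, in entry order.
    """
    if candidates.shape[1] == 0:
        raise ValueError("no candidates")
    Y = _as_matrix(Y)
    n = Y.shape[0]
    Xall = candidates.to_numpy(dtype=float)
    r2_full, p_full = _r2(Y, Xall)
    if n - p_full - 1 <= 0:
        raise ValueError("full candidate model unestimable")
    r2adj_full = _ezekiel(r2_full, n, p_full)
    rng = np.random.default_rng(seed)
    selected: list = []
    remaining = list(candidates.columns)
    while remaining:
        Z = candidates[selected].to_numpy(dtype=float) if selected else \
            np.empty((n, 0))
        best, best_r2 = None, -np.inf
        for name in remaining:
            X = np.hstack([Z, candidates[[name]].to_numpy(dtype=float)])
            r2, _ = _r2(Y, X)
            if r2 > best_r2:
                best, best_r2 = name, r2
        res = partial_rda(Y, candidates[[best]].to_numpy(dtype=float), Z,
                          n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
        if res.permutation_p > alpha:
            break
        new_p = len(selected) + 1
        new_adj = _ezekiel(best_r2, n, new_p)
        if new_adj > r2adj_full + 1e-12:
            break
        selected.append(best)
        remaining.remove(best)
    return selected


def core_dummies(core_ids) -> pd.DataFrame:
    """Reference-cell dummy coding of parent-core membership."""
    s = pd.Series(list(core_ids), name="core_id").astype(str)
    d = pd.get_dummies(s, prefix="core", drop_first=True, dtype=float)
    return d


def variation_partition3(Y, X_sets: dict, n_perm: int = 0,
                         seed: int = 0) -> VarpartResult:
    """Three-set variation partitioning on the adjusted-R2 scale.

    ``X_sets`` maps three set names to predictor matrices (n x p_i; an
    empty matrix is allowed and contributes nothing).  Adjusted R2 is
    computed for all 7 non-empty unions; individual, pairwise-joint and
    triple-joint fractions follow by inclusion-exclusion, and the residual
    is 1 - R2adj(union of all three).
    """
    names = tuple(X_sets)
    if len(names) != 3:
        raise ValueError("exactly three predictor sets required")
    Y = _as_matrix(Y)
    n = Y.shape[0]
    mats = {k: (_as_matrix(v) if np.size(v) else np.empty((n, 0)))
            for k, v in X_sets.items()}
    r2adj: dict = {}
    for mask in range(1, 8):
        combo = frozenset(names[i] for i in range(3) if mask >> i & 1)
        X = np.hstack([mats[k] for k in names if k in combo])
        r2, p = _r2(Y, X)
        r2adj[combo] = _ezekiel(r2, n, p)
    a, b, c = names
    A, B, C = r2adj[frozenset({a})], r2adj[frozenset({b})], r2adj[frozenset({c})]
    AB, AC, BC = (r2adj[frozenset({a, b})], r2adj[frozenset({a, c})],
                  r2adj[frozenset({b, c})])
    ABC = r2adj[frozenset({a, b, c})]
    individual = {
        a: ABC - BC,
        b: ABC - AC,
        c: ABC - AB,
    }
    # pairwise joints: shared between exactly two sets
    pairwise = {
        frozenset({a, b}): ABC - C - individual[a] - individual[b],
        frozenset({a, c}): ABC - B - individual[a] - individual[c],
        frozenset({b, c}): ABC - A - individual[b] - individual[c],
    }
    triple = A + B + C - AB - AC - BC + ABC
    return VarpartResult(set_names=names, individual=individual,
                         pairwise=pairwise, triple=triple,
                         residual=1.0 - ABC, r2adj=r2adj)
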
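"""Genotype PCA and Tukey halfspace depth for leverage diagnosis.

Individuals with *divergent* multi-SNP genotypes (high-leverage
observations) and individuals with *average* genotypes (low-leverage) are
identified by the trivariate halfspace depth of their coordinates on the
first three genetic principal components: the depth of a point relative to
a finite set is the smallest number of observations lying in any closed
half-space determined by a hyperplane through that point.  Depth 1 marks
the most extreme genotypes; the deepest point is the most "average".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "PcaScores",
    "DepthResult",
    "genotype_pca",
    "halfspace_depth",
    "leverage_extremes",
]

#: exact plane enumeration is O(n^3); beyond this size the seeded
#: random-projection approximation is used by default.
EXACT_DEPTH_MAX_N = 600


@dataclass
class PcaScores:
    """Principal-component coordinates of individuals in genotype space."""

    scores: np.ndarray  # (n, k), columns ordered by decreasing eigenvalue
    eigenvalues: np.ndarray  # (k,)
    center: np.ndarray  # per-SNP centering used (twice the allele frequency)
    scale: np.ndarray  # per-SNP scaling used
    kept_snps: np.ndarray = field(default=None)  # column indices retained


@dataclass
class DepthResult:
    """Integer halfspace depths, 1 <= depth_i <= n for all i."""

    depth: np.ndarray
    method: str  # "exact" or "projection"
    n_directions: Optional[int] = None


def genotype_pca(G: np.ndarray, k: int = 3) -> PcaScores:
    """Eigenstrat-convention PCA of an individuals x SNPs dosage matrix.

    Each SNP column is centered by twice its sample allele frequency and
    scaled by ``sqrt(2 p (1 - p))`` with the shrunk frequency estimate
    ``p = (1 + sum(dosages)) / (2 + 2n)`` (avoids zero scales for rare
    alleles).  Monomorphic SNPs are dropped with a warning.
    """
    G = np.asarray(G, dtype=float)
    n, p = G.shape
    if n < 4:
        raise ValueError(f"need at least 4 individuals for depth-based leverage, got {n}")
    poly = G.std(axis=0) > 0
    if not poly.all():
        warnings.warn(
            f"dropping {int((~poly).sum())} monomorphic SNP(s) before PCA",
            stacklevel=2,
        )
        G = G[:, poly]
    if G.shape[1] < k:
        raise ValueError(f"need at least k={k} polymorphic SNPs, got {G.shape[1]}")
    center = G.mean(axis=0)  # = 2 * sample allele frequency
    p_hat = (1.0 + G.sum(axis=0)) / (2.0 + 2.0 * n)
    scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    Z = (G - center) / scale
    # singular values give the eigenvalues of Z'Z / n
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :k] * s[:k]
    eigenvalues = s[:k] ** 2 / n
    return PcaScores(
        scores=scores,
        eigenvalues=eigenvalues,
        center=center,
        scale=scale,
        kept_snps=np.flatnonzero(poly),
    )


def _exact_depth_point(i: int, X: np.ndarray, tol: float) -> int:
    """Exact halfspace depth of point ``i`` in a 3-D cloud.

    Enumerates candidate hyperplanes through the query point spanned by
    pairs of other points; for each, an infinitesimal tilt can push
    generic on-plane points off the closed side, so the attained count is
    1 (the query point) + points exactly at the query location + the
    smaller strict-side count, minimized over all candidate planes.
    """
    D = np.delete(X, i, axis=0) - X[i]
    norms = np.linalg.norm(D, axis=1)
    dup = norms <= tol
    n_dup = int(dup.sum())
    D = D[~dup]
    m = len(D)
    if m < 2:
        return n_dup + 1 + (m + 1) // 2  # degenerate tiny cloud
    jj, kk = np.triu_indices(m, k=1)
    best = m  # worst case: everything on one side
    chunk = 20000
    for start in range(0, len(jj), chunk):
        j = jj[start : start + chunk]
        q = kk[start : start + chunk]
        normals = np.cross(D[j], D[q])
        lens = np.linalg.norm(normals, axis=1)
        ok = lens > tol * tol  # drop collinear pairs
        if not ok.any():
            continue
        normals = normals[ok] / lens[ok, None]
        S = normals @ D.T  # (planes, m)
        neg = (S < -tol).sum(axis=1)
        pos = (S > tol).sum(axis=1)
        best = min(best, int(np.minimum(neg, pos).min()))
    return 1 + n_dup + best


def _exact_depth_2d(X: np.ndarray, tol: float) -> np.ndarray:
    """Exact bivariate depth (lines through the query point and one other)."""
    n = len(X)
    depth = np.empty(n, dtype=int)
    for i in range(n):
        D = np.delete(X, i, axis=0) - X[i]
        norms = np.linalg.norm(D, axis=1)
        dup = norms <= tol
        n_dup = int(dup.sum())
        D = D[~dup]
        if len(D) < 1:
            depth[i] = n_dup + 1
            continue
        normals = np.column_stack([-D[:, 1], D[:, 0]])
        normals /= np.linalg.norm(normals, axis=1)[:, None]
        S = normals @ D.T
        neg = (S < -tol).sum(axis=1)
        pos = (S > tol).sum(axis=1)
        depth[i] = 1 + n_dup + int(np.minimum(neg, pos).min())
    return depth


def halfspace_depth(
    scores: np.ndarray,
    method: str = "auto",
    n_directions: int = 5000,
    seed: int = 0,
) -> DepthResult:
    """Trivariate halfspace (Tukey) depth of every row of ``scores``.

    ``method="exact"`` enumerates candidate hyperplanes spanned by pairs of
    points through each query point (exact in general position, O(n^3));
    ``method="projection"`` minimizes the weakly-smaller-side count over
    ``n_directions`` seeded random unit directions, an upper bound on the
    exact depth that converges to it as the number of directions grows.
    ``"auto"`` picks exact up to n=600 and projection beyond.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"scores must be an (n, 3) array, got shape {X.shape}")
    n = len(X)
    if n < 4:
        raise ValueError(f"need at least 4 points, got {n}")
    spread = max(X.std(axis=0).max(), 1.0)
    tol = 1e-9 * spread

    if method == "auto":
        method = "exact" if n <= EXACT_DEPTH_MAX_N else "projection"
    if method not in ("exact", "projection"):
        raise ValueError(f"unknown depth method {method!r}")

    # degenerate coplanar cloud: fall back to 2-D depth in the spanned plane
    centered = X - X.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[2] <= 1e-10 * max(svals[0], 1.0):
        warnings.warn(
            "score cloud is (numerically) coplanar; computing bivariate depth "
            "in the spanned plane",
            stacklevel=2,
        )
        _, _, Vt = np.linalg.svd(centered, full_matrices=False)
        return DepthResult(
            depth=_exact_depth_2d(centered @ Vt[:2].T, tol), method="exact"
        )

    if method == "exact":
        depth = np.array([_exact_depth_point(i, X, tol) for i in range(n)])
        return DepthResult(depth=depth, method="exact")

    rng = np.random.default_rng(seed)
    U = rng.normal(size=(n_directions, 3))
    U /= np.linalg.norm(U, axis=1)[:, None]
    P = X @ U.T  # (n, n_directions)
    depth = np.full(n, n, dtype=int)
    for d in range(n_directions):
        col = P[:, d]
        order = np.sort(col)
        lo = np.searchsorted(order, col + tol, side="right")
        hi = n - np.searchsorted(order, col - tol, side="left")
        depth = np.minimum(depth, np.minimum(lo, hi))
    return DepthResult(depth=depth, method="projection", n_directions=n_directions)


def leverage_extremes(result: DepthResult) -> tuple[int, int]:
    """Indices of the most average and most divergent genotypes.

    Returns ``(index_low_leverage, index_high_leverage)``: the deepest
    point (argmax depth, the "average genotype") and the shallowest
    (argmin depth, the "divergent genotype").  Ties break to the smallest
    index.
    """
    d = np.asarray(result.depth)
    return int(np.argmax(d)), int(np.argmin(d))
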
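"""Spatial neighborhoods, SAR error regression and autocorrelation diagnostics.

Botanical countries are irregularly sized and spaced, so neighborhoods use
the sphere-of-influence rule: each unit gets a circle whose radius is its
distance to its nearest neighbor, and two units are neighbors when their
circles overlap (strictly — tangency does not count). The resulting symmetric
graph is row-standardized into a weight matrix W.

The SAR error model y = Xb + u, u = lam W u + e, is fitted by maximum
likelihood: for fixed lam, b and sigma^2 follow from OLS on the spatially
filtered variables (I - lam W) y and (I - lam W) X, and the concentrated
log-likelihood

    ll(lam) = -n/2 (log(2 pi sigma^2(lam)) + 1) + sum_i log(1 - lam e_i)

is maximized over lam in (1/min(e), 1), where e_i are the (real) eigenvalues
of W. Remaining autocorrelation is diagnosed with Moran's I on the filtered
innovations, with both normal-approximation and permutation p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import squareform, pdist
from scipy.stats import norm


@dataclass
class SpatialWeights:
    """Neighbor lists plus the row-standardized weight matrix."""

    neighbors: list[np.ndarray]
    w: np.ndarray                    # row-standardized; zero rows for isolates
    isolated: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n(self) -> int:
        return len(self.neighbors)

    @property
    def symmetric_graph(self) -> bool:
        adj = self.w > 0
        return bool(np.array_equal(adj, adj.T))

    def to_edge_list(self) -> pd.DataFrame:
        rows = [(i, int(j), self.w[i, j]) for i in range(self.n)
                for j in self.neighbors[i]]
        return pd.DataFrame(rows, columns=["i", "j", "weight"])


def soi_neighbors(centroids) -> list[np.ndarray]:
    """Sphere-of-influence neighbor lists from projected (x, y) centroids.

    i ~ j iff dist(i, j) < r_i + r_j with r_i the nearest-neighbor distance
    of i. Strict inequality: tangent circles are not neighbors. The relation
    is symmetric and (because each unit's circle reaches its nearest
    neighbor) leaves no unit isolated.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two centroids with (x, y) coordinates")
    d = squareform(pdist(pts))
    off = d + np.diag(np.full(len(pts), np.inf))
    if np.any(off == 0):
        raise ValueError("duplicate centroids")
    r = off.min(axis=1)
    adjacency = (d < r[:, None] + r[None, :]) & ~np.eye(len(pts), dtype=bool)
    return [np.flatnonzero(row) for row in adjacency]


def row_standardize(neighbors: list[np.ndarray]) -> SpatialWeights:
    """Binary neighbor graph to row-standardized W: w_ij = 1/deg(i)."""
    n = len(neighbors)
    w = np.zeros((n, n))
    isolated = []
    for i, nb in enumerate(neighbors):
        if len(nb) == 0:
            isolated.append(i)
            continue
        w[i, nb] = 1.0 / len(nb)
    if isolated:
        warnings.warn(f"{len(isolated)} unit(s) have no neighbors (zero weight rows)",
                      stacklevel=2)
    return SpatialWeights(neighbors=[np.asarray(nb, dtype=int) for nb in neighbors],
                          w=w, isolated=np.asarray(isolated, dtype=int))


def lattice_rook_neighbors(n_rows: int, n_cols: int) -> list[np.ndarray]:
    """Rook adjacency on a regular grid (row-major indexing); test scaffolding
    for SAR recovery studies."""
    out = []
    for r in range(n_rows):
        for c in range(n_cols):
            nb = []
            if r > 0:
                nb.append((r - 1) * n_cols + c)
            if r < n_rows - 1:
                nb.append((r + 1) * n_cols + c)
            if c > 0:
                nb.append(r * n_cols + c - 1)
            if c < n_cols - 1:
                nb.append(r * n_cols + c + 1)
            out.append(np.asarray(sorted(nb), dtype=int))
    return out


def _w_eigenvalues(weights: SpatialWeights) -> np.ndarray:
    """Eigenvalues of row-standardized W from a symmetric binary graph.

    W = D^-1 A is similar to the symmetric D^-1/2 A D^-1/2, so its spectrum
    is real; isolated (zero) rows contribute zero eigenvalues.
    """
    deg = (weights.w > 0).sum(axis=1).astype(float)
    d = np.where(deg > 0, deg, 1.0)
    a = (weights.w > 0).astype(float)
    s = a / np.sqrt(d[:, None] * d[None, :])
    return np.linalg.eigvalsh(s)


@dataclass
class MoranResult:
    i: float
    expectation: float
    variance_norm: float
    z_norm: float
    p_norm: float
    p_perm: float
    permutation_sd: float


def morans_i(values, weights: SpatialWeights, permutations: int = 999,
             seed: int | None = 0, two_sided: bool = True) -> MoranResult:
    """Moran's I = (n/S0) z'Wz / z'z with normal and permutation inference."""
    x = np.asarray(values, dtype=float)
    if np.std(x) == 0:
        raise ValueError("Moran's I undefined for a constant vector")
    w = weights.w
    n = len(x)
    z = x - x.mean()
    s0 = w.sum()
    stat = (n / s0) * (z @ w @ z) / (z @ z)

    e_i = -1.0 / (n - 1)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    var = ((n**2 * s1 - n * s2 + 3 * s0**2)
           / ((n**2 - 1) * s0**2)) - e_i**2
    z_norm = (stat - e_i) / np.sqrt(var)
    p_norm = 2 * norm.sf(abs(z_norm)) if two_sided else norm.sf(z_norm)

    rng = np.random.default_rng(seed)
    sims = np.empty(permutations)
    for k in range(permutations):
        zp = rng.permutation(z)
        sims[k] = (n / s0) * (zp @ w @ zp) / (zp @ zp)
    if two_sided:
        extreme = np.sum(np.abs(sims - sims.mean()) >= abs(stat - sims.mean()))
    else:
        extreme = np.sum(sims >= stat)
    p_perm = (extreme + 1) / (permutations + 1)
    return MoranResult(i=float(stat), expectation=e_i, variance_norm=float(var),
                       z_norm=float(z_norm), p_norm=float(p_norm),
                       p_perm=float(p_perm), permutation_sd=float(sims.std(ddof=1)))


@dataclass
class SarFit:
    """ML fit of the SAR error model."""

    lam: float
    params: pd.Series            # includes "const"
    sigma2: float
    loglik: float
    pseudo_r2: float
    resid: np.ndarray            # response residuals y - Xb
    innovations: np.ndarray      # (I - lam W)(y - Xb)
    moran_innovations: MoranResult | None
    boundary: bool
    lam_bounds: tuple[float, float]


def sar_error_fit(y, X: pd.DataFrame | None, weights: SpatialWeights,
                  lam: float | None = None, moran_permutations: int = 199,
                  moran_seed: int = 0) -> SarFit:
    """Maximum-likelihood SAR error fit; ``lam`` fixes the spatial coefficient
    (lam=0 reduces exactly to OLS)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if len(weights.isolated) > 0:
        raise ValueError("weight matrix has isolated units; drop them before fitting")
    if X is None:
        design = pd.DataFrame({"const": np.ones(n)})
    else:
        design = X.copy()
        design.insert(0, "const", 1.0)
    Xm = design.to_numpy()
    w = weights.w
    eigs = _w_eigenvalues(weights)
    lo = 1.0 / eigs.min() + 1e-6 if eigs.min() < 0 else -0.999999
    hi = 1.0 - 1e-6

    def profile(l: float) -> tuple[float, np.ndarray, float]:
        a = np.eye(n) - l * w
        ys, Xs = a @ y, a @ Xm
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        e = ys - Xs @ beta
        sigma2 = float(e @ e) / n
        logdet = float(np.sum(np.log1p(-l * eigs)))
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet
        return ll, beta, sigma2

    if lam is None:
        res = minimize_scalar(lambda l: -profile(l)[0], bounds=(lo, hi),
                              method="bounded",
                              options={"xatol": 1e-8})
        lam_hat = float(res.x)
    else:
        lam_hat = float(lam)
    ll, beta, sigma2 = profile(lam_hat)
    boundary = lam is None and (lam_hat - lo < 1e-4 or hi - lam_hat < 1e-4)
    if boundary:
        warnings.warn(f"lambda estimate {lam_hat:.4f} is at the interval boundary",
                      stacklevel=2)

    fitted = Xm @ beta
    resid = y - fitted
    innov = (np.eye(n) - lam_hat * w) @ resid
    r = np.corrcoef(fitted, y)[0, 1] if np.std(fitted) > 0 else 0.0
    moran = None
    if moran_permutations and np.std(innov) > 0:
        moran = morans_i(innov, weights, permutations=moran_permutations,
                         seed=moran_seed)
    return SarFit(lam=lam_hat, params=pd.Series(beta, index=design.columns),
                  sigma2=sigma2, loglik=float(ll), pseudo_r2=float(r**2),
                  resid=resid, innovations=innov, moran_innovations=moran,
                  boundary=boundary, lam_bounds=(lo, hi))


def spatial_variance_decomposition(y, X: pd.DataFrame, weights: SpatialWeights):
    """Two-stage decomposition: intercept-only SAR error fit, then LMG shares
    of an OLS of its response residuals on the predictors.

    Returns ``(VarianceShares, SarFit)``; shares sum to the stage-2 R^2 and
    are a pseudo-decomposition of variance once spatial structure has been
    absorbed by the intercept-only spatial model.
    """
    from .model_averaging import lmg_shares

    stage1 = sar_error_fit(y, None, weights, moran_permutations=0)
    shares = lmg_shares(stage1.resid, X)
    return shares, stage1
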
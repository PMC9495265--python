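"""Distance-based Moran's Eigenvector Maps, Moran's I and Mantel statistics.

The MEM basis follows the classical truncated-distance construction: inter-site
distances above a truncation threshold (default: the longest minimum-spanning-
tree edge, which keeps the site graph connected) are replaced by four times the
threshold, the matrix is Gower double-centered, and eigenvectors with positive
eigenvalues serve as spatial predictors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .core_io import EnvironmentTable, SiteGeometry, ValidationError

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-9


@dataclass(frozen=True)
class MEMBasis:
    """Positive-eigenvalue Moran eigenvectors usable as spatial predictors."""

    eigenvectors: np.ndarray        # sites x axes, centered orthonormal columns
    eigenvalues: np.ndarray         # descending, all > 0
    truncation_distance: float      # km
    site_ids: tuple

    @property
    def n_axes(self) -> int:
        return self.eigenvectors.shape[1]


@dataclass(frozen=True)
class MantelCorrelogram:
    class_breaks: np.ndarray        # km, len = n_classes + 1
    midpoints: np.ndarray
    r: np.ndarray
    p_raw: np.ndarray
    p_corrected: np.ndarray         # progressive (Holm-style) correction
    n_pairs: np.ndarray
    variables: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class_mid_km": self.midpoints,
            "mantel_r": self.r,
            "p_raw": self.p_raw,
            "p_corrected": self.p_corrected,
            "n_pairs": self.n_pairs,
        })


def longest_mst_edge(dist: np.ndarray) -> float:
    """Longest edge of the minimum spanning tree of the distance graph."""
    mst = minimum_spanning_tree(dist).toarray()
    return float(mst.max())


def build_mem(geom: SiteGeometry, truncation: float | None = None) -> MEMBasis:
    """Construct the db-MEM spatial predictor basis.

    Distances above the truncation threshold are replaced by 4x the threshold
    before Gower double-centering; axes with positive eigenvalues are kept,
    ordered by descending eigenvalue.
    """
    n = geom.n_sites
    if n < 4:
        raise ValidationError("MEM construction needs at least 4 sites")
    d = geom.dist
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0):
        i, j = np.argwhere((d == 0) & off)[0]
        raise ValidationError(
            f"duplicate coordinates: sites {geom.site_ids[i]!r} and "
            f"{geom.site_ids[j]!r} are at zero distance"
        )
    t = longest_mst_edge(d) if truncation is None else float(truncation)
    mst_edge = longest_mst_edge(d)
    if t < mst_edge:
        raise ValidationError(
            f"truncation {t} km is below the longest MST edge {mst_edge:.3f} km"
        )
    dstar = d.copy()
    dstar[dstar > t] = 4.0 * t
    a = -0.5 * dstar ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    g = a - row - col + a.mean()
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > _EIG_TOL * abs(vals).max()
    if not keep.any():
        raise ValidationError("no positive MEM eigenvalues")
    return MEMBasis(vecs[:, keep], vals[keep], t, geom.site_ids)


def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I with row-sum-normalized weights."""
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = x.size
    if n < 4:
        raise ValidationError("Moran's I needs at least 4 sites")
    if w.shape != (n, n) or np.any(w < 0) or np.any(np.diag(w) != 0):
        raise ValidationError("weights must be non-negative with a zero diagonal")
    rowsum = w.sum(axis=1, keepdims=True)
    if w.sum() == 0:
        raise ValidationError("zero total weight")
    wn = np.divide(w, rowsum, out=np.zeros_like(w), where=rowsum > 0)
    z = x - x.mean()
    denom = z @ z
    if denom == 0:
        raise ValidationError("constant values: Moran's I undefined")
    s0 = wn.sum()
    return float((n / s0) * (z @ wn @ z) / denom)


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def _check_distance_matrix(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError(f"{name} must be square")
    if not np.allclose(m, m.T) or np.any(np.diag(m) != 0):
        raise ValidationError(f"{name} must be symmetric with a zero diagonal")
    return m


def mantel(dx: np.ndarray, dy: np.ndarray, n_perm: int = 999, seed: int = 0,
           alternative: str = "greater"):
    """Mantel correlation between two distance matrices with permutation p.

    ``r`` is the Pearson correlation over corresponding upper-triangle
    entries; ``p`` comes from permuting the site order of the second matrix,
    with the (count + 1) / (n_perm + 1) convention.
    """
    dx = _check_distance_matrix(dx, "dx")
    dy = _check_distance_matrix(dy, "dy")
    if dx.shape != dy.shape:
        raise ValidationError("matrices must share dimensions")
    ux, uy = _upper(dx), _upper(dy)
    if np.std(ux) == 0 or np.std(uy) == 0:
        raise ValidationError("constant upper triangle: Mantel r undefined")
    r_obs = float(np.corrcoef(ux, uy)[0, 1])
    if n_perm <= 0:
        return r_obs, float("nan")
    rng = np.random.default_rng(seed)
    n = dx.shape[0]
    zx = (ux - ux.mean()) / ux.std()
    count = 0
    npair = ux.size
    for _ in range(n_perm):
        p = rng.permutation(n)
        up = _upper(dy[np.ix_(p, p)])
        r_perm = float(zx @ ((up - up.mean()) / up.std())) / npair
        if alternative == "greater":
            hit = r_perm >= r_obs
        elif alternative == "two-sided":
            hit = abs(r_perm) >= abs(r_obs)
        else:
            raise ValidationError(f"unknown alternative {alternative!r}")
        count += hit
    return r_obs, (count + 1) / (n_perm + 1)


def _sturges_classes(n_pairs: int) -> int:
    return max(2, int(math.ceil(1 + math.log2(n_pairs))))


def distance_classes(geo_upper: np.ndarray, min_pairs: int = 10):
    """Equal-width Sturges classes on geographic pair distances.

    Classes with fewer than ``min_pairs`` pairs are merged with their
    neighbour (rightmost small classes merge leftward).
    """
    k = _sturges_classes(geo_upper.size)
    breaks = np.linspace(geo_upper.min(), geo_upper.max(), k + 1)
    breaks[-1] += 1e-9  # include the max distance
    while len(breaks) > 2:
        counts = np.histogram(geo_upper, bins=breaks)[0]
        small = np.flatnonzero(counts < min_pairs)
        if not len(small):
            break
        j = small[0]
        drop = j + 1 if j + 1 < len(breaks) - 1 else j  # merge with neighbour
        logger.info("merging distance class %d (%d pairs) with neighbour", j, counts[j])
        breaks = np.delete(breaks, drop)
    return breaks


def mantel_correlogram(env: EnvironmentTable, geom: SiteGeometry,
                       retained_vars, n_perm: int = 999, seed: int = 0,
                       min_pairs: int = 10) -> MantelCorrelogram:
    """Mantel correlogram of environmental distance against geography.

    Environmental distance is Euclidean on z-scored retained variables.  Per
    distance class, the statistic is the (sign-flipped) Mantel correlation
    between environmental distance and class membership, so positive ``r`` at
    short distances means nearby sites have similar environments.  P-values
    are two-sided permutation tests with progressive Holm-style correction.
    """
    retained_vars = list(retained_vars)
    if not retained_vars:
        raise ValidationError("retained_vars must be non-empty")
    x = env.matrix(retained_vars)
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    diff = x[:, None, :] - x[None, :, :]
    env_dist = np.sqrt((diff ** 2).sum(axis=-1))
    geo_upper = _upper(geom.dist)
    breaks = distance_classes(geo_upper, min_pairs=min_pairs)
    n_classes = len(breaks) - 1
    iu = np.triu_indices(geom.n_sites, k=1)
    env_upper = env_dist[iu]
    rng = np.random.default_rng(seed)
    n = geom.n_sites
    perms = [rng.permutation(n) for _ in range(n_perm)]

    r = np.empty(n_classes)
    p_raw = np.empty(n_classes)
    n_pairs = np.empty(n_classes, dtype=int)
    ez = (env_upper - env_upper.mean()) / env_upper.std()
    for c in range(n_classes):
        member = ((geo_upper >= breaks[c]) & (geo_upper < breaks[c + 1])).astype(float)
        n_pairs[c] = int(member.sum())
        full = np.zeros((n, n))
        full[iu] = member
        full = full + full.T
        if member.std() == 0:  # degenerate single-class case
            r[c], p_raw[c] = 0.0, 1.0
            continue
        mz = (member - member.mean()) / member.std()
        r_obs = -float(ez @ mz) / member.size  # sign flip: + means similarity nearby
        count = 0
        for p in perms:
            mp = _upper(full[np.ix_(p, p)])
            rp = -float(ez @ ((mp - mp.mean()) / mp.std())) / member.size
            count += abs(rp) >= abs(r_obs)
        r[c] = r_obs
        p_raw[c] = (count + 1) / (n_perm + 1)
    # progressive correction: class k tested after classes 1..k-1
    p_corr = np.minimum(1.0, np.maximum.accumulate(p_raw * np.arange(1, n_classes + 1)))
    mids = 0.5 * (breaks[:-1] + breaks[1:])
    return MantelCorrelogram(breaks, mids, r, p_raw, p_corr, n_pairs,
                             tuple(retained_vars))
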
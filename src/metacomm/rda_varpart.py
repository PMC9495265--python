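"""Redundancy analysis, collinearity screening and three-set variation
partitioning.

RDA here is the linear constrained-ordination form: the community matrix is
column-centered, predictors are column-standardized, and the explained
fraction is trace(Yhat' Yhat) / trace(Y' Y) with Yhat the least-squares
projection of Y onto the predictor space.  Significance comes from Monte
Carlo permutation of community rows (or of residuals for partial models).

Variation partitioning fits the seven models over predictor blocks
E (environment), S (space) and C (connectivity) and decomposes the full-model
fraction by inclusion–exclusion; the seven fractions sum to the full-model
r2 exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .connectivity import DEFAULT_ALPHA_GRID, metric_C, metric_N
from .core_io import CommunityMatrix, EnvironmentTable, SiteGeometry, ValidationError

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-9


@dataclass(frozen=True)
class RDAResult:
    r2: float
    adj_r2: float
    f_stat: float
    p_perm: float
    n_perm: int
    rank: int


@dataclass(frozen=True)
class CollinearityReport:
    rho: pd.DataFrame               # Spearman correlation matrix
    dropped: pd.DataFrame           # variable, partner, rho


@dataclass(frozen=True)
class VarPartResult:
    """Unique/shared/total explained-variation fractions for blocks E, S, C."""

    r2_e: float
    r2_s: float
    r2_c: float
    unique_e: float
    unique_s: float
    unique_c: float
    shared_es: float
    shared_ec: float
    shared_sc: float
    shared_esc: float
    total: float
    residual: float
    adj_r2_e: float
    adj_r2_s: float
    adj_r2_c: float
    adj_total: float
    p_e: float = float("nan")
    p_s: float = float("nan")
    p_c: float = float("nan")
    p_total: float = float("nan")
    p_unique_e: float = float("nan")
    p_unique_s: float = float("nan")
    p_unique_c: float = float("nan")
    n_perm: int = 0
    alpha: float = float("nan")

    def fractions(self) -> dict:
        return {
            "unique_e": self.unique_e, "unique_s": self.unique_s,
            "unique_c": self.unique_c, "shared_es": self.shared_es,
            "shared_ec": self.shared_ec, "shared_sc": self.shared_sc,
            "shared_esc": self.shared_esc,
        }

    def dominant(self, noise_threshold: float = 0.1) -> str:
        """Label of the strongest signal, judged on adjusted single-set r2.

        Returns ``"noise"`` when the full model's adjusted fraction falls
        below ``noise_threshold``.
        """
        if self.adj_total < noise_threshold:
            return "noise"
        vals = {"environment": self.adj_r2_e, "space": self.adj_r2_s,
                "connectivity": self.adj_r2_c}
        return max(vals, key=vals.get)


# ---------------------------------------------------------------------------
# linear algebra helpers
# ---------------------------------------------------------------------------

def standardize(x: np.ndarray, drop_constant: bool = True) -> np.ndarray:
    """Column z-scores; constant columns are dropped (or rejected)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValidationError("all predictor columns are constant")
    if not drop_constant and not keep.all():
        raise ValidationError("constant predictor column")
    x = x[:, keep]
    return (x - x.mean(axis=0)) / x[:, :].std(axis=0, ddof=0)


def _orthobasis(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of standardized x."""
    xs = standardize(x)
    u, s, _ = np.linalg.svd(xs, full_matrices=False)
    rank = int((s > s[0] * _RANK_TOL).sum()) if s.size else 0
    return u[:, :rank]


def _center(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    return y - y.mean(axis=0)


def _ezekiel(r2: float, n: int, m: int) -> float:
    if n - 1 - m <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - m)


def rda(y: np.ndarray, x: np.ndarray, n_perm: int = 999, seed: int = 0) -> RDAResult:
    """Redundancy analysis of community matrix ``y`` on predictors ``x``.

    ``y`` is column-centered and ``x`` column-standardized internally.  The
    permutation p-value uses unrestricted row permutation of ``y`` and the
    (count >= observed F + 1) / (n_perm + 1) convention.
    """
    yc = _center(y)
    q = _orthobasis(x)
    n = yc.shape[0]
    if q.shape[0] != n:
        raise ValidationError("predictor rows do not match community rows")
    m = q.shape[1]
    if m >= n - 1:
        raise ValidationError(
            f"predictor rank {m} >= n_sites - 1 = {n - 1}: reduce predictor axes"
        )
    total = float((yc ** 2).sum())
    if total == 0:
        raise ValidationError("community matrix has zero variance")
    r2 = float(((q.T @ yc) ** 2).sum()) / total
    f_stat = (r2 / m) / ((1.0 - r2) / (n - 1 - m))
    p = float("nan")
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            yp = yc[rng.permutation(n)]
            r2p = float(((q.T @ yp) ** 2).sum()) / total
            count += r2p >= r2
        p = (count + 1) / (n_perm + 1)
    return RDAResult(r2, _ezekiel(r2, n, m), f_stat, p, n_perm, m)


def partial_rda(y: np.ndarray, x: np.ndarray, z: np.ndarray,
                n_perm: int = 999, seed: int = 0) -> RDAResult:
    """Test of ``x`` after removing the effect of conditioning block ``z``.

    The reported r2 is the semi-partial fraction R([Z X]) - R(Z) of the total
    variance of ``y``.  Permutations shuffle the residuals of ``y`` on ``z``
    (residualized-model permutation).
    """
    yc = _center(y)
    n = yc.shape[0]
    qz = _orthobasis(z)
    qzx = _orthobasis(np.hstack([np.asarray(z, float).reshape(n, -1),
                                 np.asarray(x, float).reshape(n, -1)]))
    m_full, m_z = qzx.shape[1], qz.shape[1]
    m_x = m_full - m_z
    if m_full >= n - 1:
        raise ValidationError("combined predictor rank >= n_sites - 1")
    if m_x == 0:
        return RDAResult(0.0, 0.0, 0.0, 1.0, n_perm, 0)
    total = float((yc ** 2).sum())
    r_z = float(((qz.T @ yc) ** 2).sum()) / total
    r_full = float(((qzx.T @ yc) ** 2).sum()) / total
    delta = r_full - r_z
    f_stat = (delta / m_x) / ((1.0 - r_full) / (n - 1 - m_full))
    p = float("nan")
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        resid = yc - qz @ (qz.T @ yc)
        fitted = yc - resid
        count = 0
        for _ in range(n_perm):
            yp = fitted + resid[rng.permutation(n)]
            yp = yp - yp.mean(axis=0)
            tot_p = float((yp ** 2).sum())
            rz_p = float(((qz.T @ yp) ** 2).sum()) / tot_p
            rf_p = float(((qzx.T @ yp) ** 2).sum()) / tot_p
            fp = ((rf_p - rz_p) / m_x) / ((1.0 - rf_p) / (n - 1 - m_full))
            count += fp >= f_stat
        p = (count + 1) / (n_perm + 1)
    return RDAResult(delta, _ezekiel(delta, n, m_x), f_stat, p, n_perm, m_x)


# ---------------------------------------------------------------------------
# variable screening
# ---------------------------------------------------------------------------

def collinearity_screen(env: EnvironmentTable, threshold: float = 0.9):
    """Drop one member of every |Spearman rho| >= threshold variable pair.

    Of a flagged pair, the variable with the larger mean |rho| against all
    other variables is dropped (ties: the later column).  Repeats until no
    pair exceeds the threshold.
    """
    if len(env.variables) < 2:
        raise ValidationError("need at least 2 environment variables")
    rho = env.data.corr(method="spearman")
    remaining = list(env.variables)
    drops = []
    while len(remaining) > 1:
        sub = rho.loc[remaining, remaining].abs()
        np.fill_diagonal(sub.values, 0.0)
        peak = sub.values.max()
        if peak < threshold:
            break
        i, j = np.unravel_index(np.argmax(sub.values), sub.shape)
        v1, v2 = remaining[i], remaining[j]
        mean1 = sub[v1].drop(index=v1).mean()
        mean2 = sub[v2].drop(index=v2).mean()
        if mean1 > mean2:
            victim, partner = v1, v2
        elif mean2 > mean1:
            victim, partner = v2, v1
        else:  # tie: drop the later column in table order
            later = v1 if env.variables.index(v1) > env.variables.index(v2) else v2
            victim, partner = later, (v2 if later == v1 else v1)
        drops.append({"variable": victim, "partner": partner,
                      "rho": float(rho.loc[victim, partner])})
        logger.info("collinearity: dropping %s (rho=%.3f with %s)",
                    victim, rho.loc[victim, partner], partner)
        remaining.remove(victim)
    report = CollinearityReport(rho, pd.DataFrame(drops, columns=["variable",
                                                                  "partner", "rho"]))
    reduced = EnvironmentTable(env.site_ids, env.data[remaining])
    return report, reduced


def marginal_env_screen(y: np.ndarray, env: EnvironmentTable,
                        n_perm: int = 999, seed: int = 0,
                        p_threshold: float = 0.05) -> pd.DataFrame:
    """Single-variable RDA per environmental variable; retain p < threshold.

    Returns a table ordered by r2 descending with a ``retained`` flag.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for var in env.variables:
        res = rda(y, env.matrix([var]), n_perm=n_perm,
                  seed=int(rng.integers(2 ** 31)))
        rows.append({"variable": var, "r2": res.r2, "adj_r2": res.adj_r2,
                     "p": res.p_perm,
                     "retained": bool(res.p_perm < p_threshold)})
    df = pd.DataFrame(rows).sort_values("r2", ascending=False).reset_index(drop=True)
    return df


def reduce_connectivity(metric_c: np.ndarray | None, metric_n: np.ndarray | None = None,
                        variance_kept: float = 0.9,
                        max_axes: int | None = None) -> np.ndarray:
    """Principal-component predictor axes of standardized [C | N].

    Keeps the smallest axis count reaching ``variance_kept`` of the variance,
    capped at n_sites / 3 axes (at least one axis is always returned).
    """
    blocks = [b for b in (metric_c, metric_n) if b is not None]
    if not blocks:
        raise ValidationError("need at least one connectivity matrix")
    x = np.hstack([np.asarray(b, float).reshape(len(blocks[0]), -1) for b in blocks])
    sd = x.std(axis=0, ddof=0)
    x = x[:, sd > 0]
    if x.shape[1] == 0:
        raise ValidationError("all connectivity columns are constant")
    xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    u, s, _ = np.linalg.svd(xs, full_matrices=False)
    rank = int((s > s[0] * _RANK_TOL).sum())
    var = s[:rank] ** 2
    cum = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(cum, variance_kept) + 1)
    cap = max_axes if max_axes is not None else max(1, x.shape[0] // 3)
    k = max(1, min(k, cap, rank))
    return u[:, :k] * s[:k]


# ---------------------------------------------------------------------------
# variation partitioning
# ---------------------------------------------------------------------------

def variation_partition(y: np.ndarray, e_axes: np.ndarray, s_axes: np.ndarray,
                        c_axes: np.ndarray, n_perm: int = 999,
                        seed: int = 0) -> VarPartResult:
    """Three-set variation partitioning on unadjusted RDA r2.

    Fits the seven models (E, S, C, ES, EC, SC, ESC); unique and shared
    fractions come from inclusion–exclusion, so they sum to the full-model r2
    exactly.  With ``n_perm > 0``, single-set and full models are tested by
    row permutation and unique fractions by residualized permutation.
    """
    yc = _center(y)
    n = yc.shape[0]
    blocks = {"e": np.asarray(e_axes, float).reshape(n, -1),
              "s": np.asarray(s_axes, float).reshape(n, -1),
              "c": np.asarray(c_axes, float).reshape(n, -1)}
    for name, b in blocks.items():
        if b.shape[1] == 0:
            raise ValidationError(f"predictor block {name!r} is empty")
    total_ss = float((yc ** 2).sum())

    def r2_of(*names):
        x = np.hstack([blocks[nm] for nm in names])
        q = _orthobasis(x)
        if q.shape[1] >= n - 1:
            raise ValidationError("combined predictor rank >= n_sites - 1")
        return float(((q.T @ yc) ** 2).sum()) / total_ss, q.shape[1]

    r = {}
    ranks = {}
    for combo in ("e", "s", "c", "es", "ec", "sc", "esc"):
        r[combo], ranks[combo] = r2_of(*combo)

    u_e = r["esc"] - r["sc"]
    u_s = r["esc"] - r["ec"]
    u_c = r["esc"] - r["es"]
    sh_es = r["ec"] + r["sc"] - r["esc"] - r["c"]
    sh_ec = r["es"] + r["sc"] - r["esc"] - r["s"]
    sh_sc = r["es"] + r["ec"] - r["esc"] - r["e"]
    sh_esc = r["esc"] - (u_e + u_s + u_c + sh_es + sh_ec + sh_sc)

    result = VarPartResult(
        r2_e=r["e"], r2_s=r["s"], r2_c=r["c"],
        unique_e=u_e, unique_s=u_s, unique_c=u_c,
        shared_es=sh_es, shared_ec=sh_ec, shared_sc=sh_sc, shared_esc=sh_esc,
        total=r["esc"], residual=1.0 - r["esc"],
        adj_r2_e=_ezekiel(r["e"], n, ranks["e"]),
        adj_r2_s=_ezekiel(r["s"], n, ranks["s"]),
        adj_r2_c=_ezekiel(r["c"], n, ranks["c"]),
        adj_total=_ezekiel(r["esc"], n, ranks["esc"]),
        n_perm=n_perm,
    )
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        seeds = rng.integers(2 ** 31, size=7)
        p_e = rda(yc, blocks["e"], n_perm, int(seeds[0])).p_perm
        p_s = rda(yc, blocks["s"], n_perm, int(seeds[1])).p_perm
        p_c = rda(yc, blocks["c"], n_perm, int(seeds[2])).p_perm
        p_tot = rda(yc, np.hstack(list(blocks.values())), n_perm, int(seeds[3])).p_perm
        pu_e = partial_rda(yc, blocks["e"], np.hstack([blocks["s"], blocks["c"]]),
                           n_perm, int(seeds[4])).p_perm
        pu_s = partial_rda(yc, blocks["s"], np.hstack([blocks["e"], blocks["c"]]),
                           n_perm, int(seeds[5])).p_perm
        pu_c = partial_rda(yc, blocks["c"], np.hstack([blocks["e"], blocks["s"]]),
                           n_perm, int(seeds[6])).p_perm
        result = replace(result, p_e=p_e, p_s=p_s, p_c=p_c, p_total=p_tot,
                         p_unique_e=pu_e, p_unique_s=pu_s, p_unique_c=pu_c)
    return result


def alpha_sweep_varpart(cm: CommunityMatrix, geom: SiteGeometry,
                        e_axes: np.ndarray, s_axes: np.ndarray,
                        alpha_grid=None, n_perm: int = 0, seed: int = 0,
                        variance_kept: float = 0.9,
                        use_abundance: bool = True,
                        include_metric_n: bool = True) -> list:
    """Variation partitioning re-run over a grid of kernel scales.

    Metric C is rebuilt (and re-reduced) at each alpha; metric N, which does
    not vary with alpha, is optionally included in the connectivity block.
    """
    grid = np.asarray(DEFAULT_ALPHA_GRID if alpha_grid is None else alpha_grid,
                      dtype=float)
    y = _center(cm.incidence())
    n_mat = metric_N(cm, geom)[0] if include_metric_n else None
    rng = np.random.default_rng(seed)
    # fix the connectivity axis count across the sweep (chosen at the median
    # alpha) so fractions are comparable between grid points
    c_mid = metric_C(cm, geom, float(np.median(grid)), use_abundance=use_abundance)
    n_axes = reduce_connectivity(c_mid, n_mat, variance_kept=variance_kept).shape[1]
    out = []
    for alpha in grid:
        c = metric_C(cm, geom, alpha, use_abundance=use_abundance)
        c_axes = reduce_connectivity(c, n_mat, variance_kept=1.0, max_axes=n_axes)
        vp = variation_partition(y, e_axes, s_axes, c_axes, n_perm=n_perm,
                                 seed=int(rng.integers(2 ** 31)))
        out.append(replace(vp, alpha=float(alpha)))
    return out


def sweep_frame(results: list) -> pd.DataFrame:
    """Long-format table of an alpha sweep (alpha, fraction, value, p)."""
    rows = []
    for vp in results:
        for frac, val, p in (("total", vp.total, vp.p_total),
                             ("unique_e", vp.unique_e, vp.p_unique_e),
                             ("unique_s", vp.unique_s, vp.p_unique_s),
                             ("unique_c", vp.unique_c, vp.p_unique_c)):
            rows.append({"alpha_km": vp.alpha, "fraction": frac, "value": val,
                         "p": p, "significant": bool(p < 0.05) if p == p else None})
    return pd.DataFrame(rows)
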
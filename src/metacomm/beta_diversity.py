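"""Pairwise Sørensen-family beta diversity and its turnover/nestedness partition.

For a pair of sites with ``a`` shared species and ``b``, ``c`` species unique
to either site:

    beta_sor = (b + c) / (2a + b + c)        total dissimilarity
    beta_sim = min(b, c) / (a + min(b, c))   turnover (replacement)
    beta_nes = beta_sor - beta_sim           nestedness-resultant component

so the additive identity ``beta_sor = beta_sim + beta_nes`` holds by
construction.  Group comparisons use rank-based tests (Kruskal–Wallis and
pairwise Mann–Whitney).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CommunityMatrix, ValidationError


@dataclass(frozen=True)
class PairwiseDissimilarity:
    """Condensed upper-triangle dissimilarity vectors over all site pairs."""

    site_ids: tuple
    beta_sor: np.ndarray
    beta_sim: np.ndarray
    beta_nes: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.beta_sor)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.site_ids)
        iu, ju = np.triu_indices(n, k=1)
        return pd.DataFrame({
            "site_a": [self.site_ids[i] for i in iu],
            "site_b": [self.site_ids[j] for j in ju],
            "beta_sor": self.beta_sor,
            "beta_sim": self.beta_sim,
            "beta_nes": self.beta_nes,
        })


@dataclass(frozen=True)
class BetaSummary:
    """Mean ± SE of each index over site pairs, plus the nestedness ratio (%)."""

    mean_sor: float
    se_sor: float
    mean_sim: float
    se_sim: float
    mean_nes: float
    se_nes: float
    beta_ratio: float  # percent: 100 * mean_nes / mean_sor
    n_pairs: int


def pair_components(x: np.ndarray, y: np.ndarray):
    """Shared/unique species counts (a, b, c) for two incidence vectors."""
    x = np.asarray(x) > 0
    y = np.asarray(y) > 0
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    return a, b, c


def partition_from_components(a: float, b: float, c: float):
    """(beta_sor, beta_sim, beta_nes) from shared/unique counts."""
    m = min(b, c)
    denom = 2 * a + b + c
    if denom == 0:
        raise ValidationError("both sites empty: Sørensen denominator degenerates")
    sor = (b + c) / denom
    sim = m / (a + m) if (a + m) > 0 else 0.0
    return sor, sim, sor - sim


def total_from_components(beta_sim: float, beta_nes: float) -> float:
    """Total Sørensen dissimilarity via the additive partition identity."""
    return beta_sim + beta_nes


def pairwise_partition(cm: CommunityMatrix) -> PairwiseDissimilarity:
    """Partition pairwise Sørensen dissimilarity into turnover and nestedness."""
    inc = cm.incidence()
    empty = np.flatnonzero(inc.sum(axis=1) == 0)
    if len(empty):
        names = [cm.site_ids[i] for i in empty]
        raise ValidationError(f"sites with zero presences: {names}")
    shared = inc @ inc.T
    rich = inc.sum(axis=1)
    iu, ju = np.triu_indices(cm.n_sites, k=1)
    a = shared[iu, ju]
    b = rich[iu] - a
    c = rich[ju] - a
    m = np.minimum(b, c)
    sor = (b + c) / (2 * a + b + c)
    with np.errstate(invalid="ignore"):
        sim = np.where(a + m > 0, m / (a + m), 0.0)
    return PairwiseDissimilarity(cm.site_ids, sor, sim, sor - sim)


def summarize(pd_: PairwiseDissimilarity) -> BetaSummary:
    """Mean ± SE per index; SE = sd / sqrt(n_pairs) over pair values.

    Site pairs are not independent, so these SEs understate uncertainty;
    they replicate the descriptive per-pair convention.
    """
    if pd_.n_pairs < 3:
        raise ValidationError("need at least 3 site pairs to summarize")
    n = pd_.n_pairs

    def mse(v):
        return float(np.mean(v)), float(np.std(v, ddof=1) / np.sqrt(n))

    m_sor, s_sor = mse(pd_.beta_sor)
    m_sim, s_sim = mse(pd_.beta_sim)
    m_nes, s_nes = mse(pd_.beta_nes)
    ratio = 100.0 * m_nes / m_sor if m_sor > 0 else 0.0
    return BetaSummary(m_sor, s_sor, m_sim, s_sim, m_nes, s_nes, ratio, n)


def summary_frame(summaries: dict) -> pd.DataFrame:
    """Stack named :class:`BetaSummary` objects into a report table."""
    rows = []
    for name, s in summaries.items():
        rows.append({
            "metacommunity": name, "n_pairs": s.n_pairs,
            "beta_sor": s.mean_sor, "se_sor": s.se_sor,
            "beta_sim": s.mean_sim, "se_sim": s.se_sim,
            "beta_nes": s.mean_nes, "se_nes": s.se_nes,
            "beta_ratio_pct": s.beta_ratio,
        })
    return pd.DataFrame(rows)


def compare_groups(groups: dict, index_name: str = "beta_sor") -> dict:
    """Kruskal–Wallis across groups plus pairwise two-sided Mann–Whitney tests.

    ``groups`` maps group name -> 1-D array of pairwise dissimilarity values.
    Mann–Whitney uses exact enumeration for small samples without ties and the
    tie-corrected normal approximation otherwise.
    """
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 values")
        arrays[name] = v
    h, p_kw = stats.kruskal(*arrays.values())
    names = list(arrays)
    rows = []
    for i, g1 in enumerate(names):
        for g2 in names[i + 1:]:
            x, y = arrays[g1], arrays[g2]
            combined = np.concatenate([x, y])
            ties = len(np.unique(combined)) < combined.size
            method = "exact" if (combined.size <= 20 and not ties) else "asymptotic"
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            rows.append({"group_a": g1, "group_b": g2,
                         "U": float(res.statistic), "p": float(res.pvalue),
                         "method": method})
    return {
        "index": index_name,
        "kruskal_h": float(h),
        "kruskal_p": float(p_kw),
        "pairwise": pd.DataFrame(rows),
    }
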
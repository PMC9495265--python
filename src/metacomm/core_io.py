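"""Domain types, validation and table I/O for metacommunity analyses.

The pipeline operates on three aligned tables — a site x species community
matrix, site coordinates (decimal degrees), and a site x environment table —
plus an optional per-site landscape label.  All downstream stages assume the
site ordering of the community matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(labels, what: str) -> None:
    seen: set = set()
    dups = [x for x in labels if x in seen or seen.add(x)]
    if dups:
        raise ValidationError(f"duplicate {what} labels: {sorted(set(dups))}")


@dataclass(frozen=True)
class CommunityMatrix:
    """Sites x species counts or incidences.

    ``values[i, k]`` is the abundance (or 0/1 incidence) of species ``k``
    at site ``i``.  An incidence view is always derivable.
    """

    site_ids: tuple
    species_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "site_ids", tuple(str(s) for s in self.site_ids))
        object.__setattr__(self, "species_ids", tuple(str(s) for s in self.species_ids))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        _check_unique(self.site_ids, "site")
        _check_unique(self.species_ids, "species")
        if vals.shape != (len(self.site_ids), len(self.species_ids)):
            raise ValidationError(
                f"values shape {vals.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.species_ids)} species"
            )
        if len(self.site_ids) < 2:
            raise ValidationError("need at least 2 sites")
        if len(self.species_ids) < 1:
            raise ValidationError("need at least 1 species")
        if not np.all(np.isfinite(vals)):
            raise ValidationError("community matrix contains non-finite values")
        if np.any(vals < 0):
            raise ValidationError("community matrix contains negative values")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def incidence(self) -> np.ndarray:
        """0/1 presence/absence view of the matrix."""
        return (self.values > 0).astype(float)

    def occupancy(self) -> np.ndarray:
        """Number of sites occupied, per species."""
        return (self.values > 0).sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.site_ids),
                            columns=list(self.species_ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CommunityMatrix":
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy(dtype=float))


def great_circle_distances(lat, lon) -> np.ndarray:
    """Haversine distance matrix (km) on a sphere of radius 6371 km.

    Parameters
    ----------
    lat, lon : array-like
        Decimal-degree coordinates; latitude must lie in [-90, 90] and
        longitude in [-180, 180].
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(~np.isfinite(lat)):
        raise ValidationError("latitude outside [-90, 90]")
    if np.any(np.abs(lon) > 180) or np.any(~np.isfinite(lon)):
        raise ValidationError("longitude outside [-180, 180]")
    phi = np.radians(lat)[:, None]
    lam = np.radians(lon)[:, None]
    dphi = phi - phi.T
    dlam = lam - lam.T
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi) * np.cos(phi.T) * np.sin(dlam / 2.0) ** 2
    h = np.clip(h, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))
    np.fill_diagonal(d, 0.0)
    return 0.5 * (d + d.T)


@dataclass(frozen=True)
class SiteGeometry:
    """Per-site coordinates plus the derived great-circle distance matrix."""

    site_ids: tuple
    lat: np.ndarray
    lon: np.ndarray
    dist: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "site_ids", tuple(str(s) for s in self.site_ids))
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)
        _check_unique(self.site_ids, "site")
        n = len(self.site_ids)
        if lat.shape != (n,) or lon.shape != (n,):
            raise ValidationError("lat/lon length does not match site_ids")
        if self.dist is None:
            object.__setattr__(self, "dist", great_circle_distances(lat, lon))
        else:
            d = np.asarray(self.dist, dtype=float)
            if d.shape != (n, n) or not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
                raise ValidationError("distance matrix must be symmetric with zero diagonal")
            object.__setattr__(self, "dist", d)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def subset(self, idx: np.ndarray) -> "SiteGeometry":
        idx = np.asarray(idx)
        return SiteGeometry(
            tuple(self.site_ids[i] for i in idx),
            self.lat[idx], self.lon[idx], self.dist[np.ix_(idx, idx)],
        )


@dataclass(frozen=True)
class EnvironmentTable:
    """Named numeric environmental variables, one row per site."""

    site_ids: tuple
    data: pd.DataFrame

    def __post_init__(self):
        object.__setattr__(self, "site_ids", tuple(str(s) for s in self.site_ids))
        _check_unique(self.site_ids, "site")
        df = self.data.copy()
        df.index = list(self.site_ids)
        if df.isna().any().any():
            bad = df.columns[df.isna().any()].tolist()
            raise ValidationError(f"missing values in environment columns {bad}")
        for col in df.columns:
            if not np.issubdtype(df[col].dtype, np.number):
                raise ValidationError(f"non-numeric environment column {col!r}")
        var = df.var(axis=0, ddof=0)
        dead = var.index[var.to_numpy() == 0].tolist()
        if dead:
            raise ValidationError(f"zero-variance environment columns {dead}")
        object.__setattr__(self, "data", df)

    @property
    def variables(self) -> list:
        return list(self.data.columns)

    def matrix(self, columns=None) -> np.ndarray:
        cols = list(columns) if columns is not None else self.variables
        return self.data[cols].to_numpy(dtype=float)


@dataclass(frozen=True)
class MetacommunityPartition:
    """Per-site categorical landscape assignment.

    The whole-area metacommunity is the union of all labelled sites.
    """

    site_ids: tuple
    labels: tuple

    def __post_init__(self):
        object.__setattr__(self, "site_ids", tuple(str(s) for s in self.site_ids))
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        _check_unique(self.site_ids, "site")
        if len(self.labels) != len(self.site_ids):
            raise ValidationError("labels length does not match site_ids")
        counts = pd.Series(self.labels).value_counts()
        small = counts.index[counts < 3].tolist()
        if small:
            raise ValidationError(
                f"labels {small} have fewer than 3 sites; too small for statistics"
            )

    @property
    def label_set(self) -> list:
        return sorted(set(self.labels))

    def indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels) == label)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_delimited(path) -> pd.DataFrame:
    """Read a CSV/TSV with auto-detected delimiter; first column is site label."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    return df


def _require_numeric(df: pd.DataFrame, path) -> None:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad) or coerced.isna().any():
            row = bad[0] if len(bad) else df.index[coerced.isna()][0]
            raise ValidationError(
                f"{path}: non-numeric or missing cell at row {row!r}, column {col!r}"
            )


def read_tables(community_path, coords_path, env_path, labels_path=None):
    """Read and cross-validate the input tables.

    Returns ``(CommunityMatrix, SiteGeometry, EnvironmentTable,
    MetacommunityPartition | None)`` with all objects aligned to the row
    order of the community matrix.
    """
    com = _read_delimited(community_path)
    _require_numeric(com, community_path)
    cm = CommunityMatrix.from_frame(com)
    order = list(cm.site_ids)

    def _align(df: pd.DataFrame, path) -> pd.DataFrame:
        missing = sorted(set(order) - set(df.index))
        extra = sorted(set(df.index) - set(order))
        if missing or extra:
            raise ValidationError(
                f"{path}: site set mismatch with community matrix "
                f"(missing {missing}, unexpected {extra})"
            )
        return df.loc[order]

    coords = _align(_read_delimited(coords_path), coords_path)
    _require_numeric(coords, coords_path)
    cols = {c.lower(): c for c in coords.columns}
    try:
        lat = coords[cols["lat"]].to_numpy(float)
        lon = coords[cols["lon"]].to_numpy(float)
    except KeyError as exc:
        raise ValidationError(f"{coords_path}: needs 'lat' and 'lon' columns") from exc
    geom = SiteGeometry(tuple(order), lat, lon)

    envdf = _align(_read_delimited(env_path), env_path)
    _require_numeric(envdf, env_path)
    env = EnvironmentTable(tuple(order), envdf)

    part = None
    if labels_path is not None:
        ldf = _align(_read_delimited(labels_path), labels_path)
        part = MetacommunityPartition(tuple(order), tuple(ldf.iloc[:, 0].astype(str)))
    return cm, geom, env, part


def write_tables(outdir, cm: CommunityMatrix, geom: SiteGeometry,
                 env: EnvironmentTable, part: MetacommunityPartition | None = None):
    """Write canonical TSVs readable by :func:`read_tables`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "community": outdir / "community.tsv",
        "coords": outdir / "coords.tsv",
        "env": outdir / "environment.tsv",
    }
    cm.to_frame().rename_axis("site").to_csv(paths["community"], sep="\t")
    pd.DataFrame({"lat": geom.lat, "lon": geom.lon}, index=list(geom.site_ids)) \
        .rename_axis("site").to_csv(paths["coords"], sep="\t")
    env.data.rename_axis("site").to_csv(paths["env"], sep="\t")
    if part is not None:
        paths["labels"] = outdir / "labels.tsv"
        pd.DataFrame({"landscape": list(part.labels)}, index=list(part.site_ids)) \
            .rename_axis("site").to_csv(paths["labels"], sep="\t")
    return paths


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def filter_rare_species(cm: CommunityMatrix, min_sites: int = 2) -> CommunityMatrix:
    """Drop species occupying fewer than ``min_sites`` sites.

    The default of 2 keeps species recorded at more than one site.
    """
    if min_sites < 1:
        raise ValidationError("min_sites must be >= 1")
    occ = cm.occupancy()
    keep = occ >= min_sites
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValidationError("rarity filter removed every species")
    logger.info("filter_rare_species: removed %d of %d species", n_removed, cm.n_species)
    if n_removed == 0:
        return cm
    kept = [s for s, k in zip(cm.species_ids, keep) if k]
    return CommunityMatrix(cm.site_ids, tuple(kept), cm.values[:, keep])


@dataclass(frozen=True)
class RichnessOverlap:
    richness: dict              # label -> species count
    pairwise_shared: dict       # (label1, label2) sorted tuple -> shared count
    shared_all: int             # species present in every label
    total_richness: int


def richness_overlap(cm: CommunityMatrix, part: MetacommunityPartition) -> RichnessOverlap:
    """Per-landscape richness and shared-species (Venn) counts."""
    labels = part.label_set
    if len(labels) < 2:
        raise ValidationError("need at least 2 labels for overlap summaries")
    inc = cm.incidence()
    sets = {}
    for lab in labels:
        idx = part.indices(lab)
        present = inc[idx].sum(axis=0) > 0
        sets[lab] = {sp for sp, p in zip(cm.species_ids, present) if p}
    richness = {lab: len(s) for lab, s in sets.items()}
    pairwise = {}
    for i, l1 in enumerate(labels):
        for l2 in labels[i + 1:]:
            pairwise[(l1, l2)] = len(sets[l1] & sets[l2])
    shared_all = len(set.intersection(*sets.values()))
    total = len(set.union(*sets.values()))
    return RichnessOverlap(richness, pairwise, shared_all, total)
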
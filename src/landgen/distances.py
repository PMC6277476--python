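"""Predictor distance matrices for landscape-genetic hypothesis testing.

Three predictors and one response live here:

* geographic distance (great-circle km, optionally log-transformed) — the
  isolation-by-distance hypothesis;
* environmental distance (absolute difference of a site climate variable) —
  isolation by environment;
* least-cost distance over an elevation raster with an impassability
  threshold — isolation by resistance;
* the Rousset linearization x/(1-x) of a pairwise FST matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .genotypes import SiteTable
from .raster import ElevationRaster

__all__ = [
    "DistanceMatrix",
    "EARTH_RADIUS_KM",
    "haversine_km",
    "geographic_matrix",
    "environment_matrix",
    "least_cost_matrix",
    "linearize_fst",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix with zero diagonal.

    The lingua franca between pipeline stages: genetic, geographic,
    environmental and cost matrices all use this container.  Infinite entries
    are only tolerated for cost matrices with disconnected pairs.
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "generic"
    transform: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-9, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        off = self.values[~np.eye(n, dtype=bool)]
        if np.any(np.isnan(off)):
            raise ValueError("NaN entries are not allowed")
        if np.any(np.isinf(off)):
            if self.kind != "cost":
                raise ValueError("infinite entries only allowed for cost matrices")
            warnings.warn("cost matrix contains disconnected (infinite) pairs")

    def __len__(self) -> int:
        return len(self.labels)

    def to_vector(self) -> np.ndarray:
        """Upper-triangle entries (excluding the diagonal), row-major."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)],
                              self.kind, self.transform)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    def write_phylip(self, path: str | Path) -> None:
        """PHYLIP-style square matrix text."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(f"{lab:<10s} " + " ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path, kind: str = "generic") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), kind)


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (spherical earth, R = 6371.0088 km)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def geographic_matrix(sites: SiteTable, log_transform: bool = False) -> DistanceMatrix:
    """Pairwise great-circle distances (km) between sites.

    With ``log_transform`` the natural log is applied off-diagonal (the
    standard linearization against FST/(1-FST)); coincident sites are then an
    error because log 0 is undefined.
    """
    coords = sites.coords()
    lat, lon = coords[:, 0], coords[:, 1]
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    labels = sites.populations
    if log_transform:
        n = len(labels)
        off = ~np.eye(n, dtype=bool)
        zero = off & (d <= 0.0)
        if zero.any():
            i, j = np.argwhere(zero)[0]
            raise ValueError(
                f"sites {labels[i]!r} and {labels[j]!r} coincide; log distance undefined"
            )
        d = np.where(off, np.log(np.where(off, d, 1.0)), 0.0)
    return DistanceMatrix(labels, d, kind="geographic",
                          transform="log" if log_transform else None)


def environment_matrix(sites: SiteTable, variable: str) -> DistanceMatrix:
    """Pairwise absolute difference of one site climate variable (deg C)."""
    if variable not in sites.data.columns:
        raise ValueError(f"site table has no variable {variable!r}")
    v = sites.data[variable].to_numpy(dtype=float)
    if np.any(np.isnan(v)):
        raise ValueError(f"variable {variable!r} missing for some sites")
    d = np.abs(v[:, None] - v[None, :])
    return DistanceMatrix(sites.populations, d, kind="environmental",
                          transform=variable)


def _passable_graph(raster: ElevationRaster, threshold_m: float) -> tuple[coo_matrix, np.ndarray]:
    """Sparse 8-neighbor graph over passable cells; edge weight in meters.

    A move between adjacent passable cells costs step length times the mean
    friction of the two cells; friction is 1 everywhere passable, so the cost
    reduces to the metric step length (diagonal steps are the diagonal of the
    per-row step rectangle).
    """
    passable = np.isfinite(raster.values) & (raster.values >= threshold_m)
    nr, nc = passable.shape
    node = -np.ones((nr, nc), dtype=np.int64)
    node[passable] = np.arange(int(passable.sum()))
    dx, dy = raster.step_lengths_m()

    src, dst, wgt = [], [], []
    # displacements covering each undirected edge once
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r0 = slice(0, nr - dr)
        r1 = slice(dr, nr)
        c0 = slice(max(0, -dc), nc - max(0, dc))
        c1 = slice(max(0, dc), nc - max(0, -dc))
        ok = passable[r0, c0] & passable[r1, c1]
        if not ok.any():
            continue
        rows0 = np.broadcast_to(np.arange(0, nr - dr)[:, None], ok.shape)[ok]
        a = node[r0, c0][ok]
        b = node[r1, c1][ok]
        if dr and dc:
            # diagonal step: mean east-west span of the two rows, crossed with dy
            ew = 0.5 * (dx[rows0] + dx[rows0 + dr])
            w = np.hypot(ew, dy)
        elif dr:
            w = np.full(a.shape, dy)
        else:
            w = dx[rows0]
        src.append(a)
        dst.append(b)
        wgt.append(w)
    n = int(passable.sum())
    if src:
        src_a = np.concatenate(src)
        dst_a = np.concatenate(dst)
        wgt_a = np.concatenate(wgt)
        graph = coo_matrix((wgt_a, (src_a, dst_a)), shape=(n, n))
    else:
        graph = coo_matrix((n, n))
    return graph.tocsr(), node


def least_cost_matrix(raster: ElevationRaster, sites: SiteTable,
                      threshold_m: float = 1280.0) -> DistanceMatrix:
    """Least-cost distances (meters) between sites over an elevation raster.

    Cells below ``threshold_m`` (default 1280 m a.s.l.) or NODATA are
    impassable; movement uses the standard eight directions; the cost of a
    move is its metric step length (uniform friction).  Sites snap to the
    center of their containing cell — located by (lon, lat) on geographic
    rasters and by the site table's ``x``/``y`` columns on projected ones.
    Disconnected pairs come back infinite with a warning.
    """
    graph, node = _passable_graph(raster, threshold_m)
    use_xy = not raster.geographic and {"x", "y"} <= set(sites.data.columns)
    cells = []
    for pop, row in sites.data.iterrows():
        if use_xy:
            r, c = raster.cell_of(float(row["x"]), float(row["y"]))
        else:
            r, c = raster.cell_of(float(row["lon"]), float(row["lat"]))
        if node[r, c] < 0:
            elev = raster.values[r, c]
            raise ValueError(
                f"site {pop!r} falls on an impassable cell "
                f"(elevation {elev!r} < threshold {threshold_m})"
            )
        cells.append(node[r, c])
    cells_arr = np.asarray(cells)
    dist = dijkstra(graph, directed=False, indices=cells_arr)
    d = dist[:, cells_arr]
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(sites.populations, d, kind="cost",
                          transform=f"threshold={threshold_m:g}m")


def linearize_fst(fst: DistanceMatrix) -> DistanceMatrix:
    """Rousset's linearization x/(1-x), flooring negative estimates at 0."""
    v = np.array(fst.values, dtype=float)
    if np.any(v >= 1.0):
        raise ValueError("FST entry >= 1; linearization undefined")
    if np.any(v < 0.0):
        warnings.warn("negative FST estimates floored at 0 before linearization")
        v = np.maximum(v, 0.0)
    out = v / (1.0 - v)
    np.fill_diagonal(out, 0.0)
    return DistanceMatrix(list(fst.labels), out, kind="genetic",
                          transform="fst/(1-fst)")
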
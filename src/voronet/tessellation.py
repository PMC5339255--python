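"""Voronoi tessellation of the map: cell areas, densities, neighbor graph.

Each map point owns a Voronoi cell; the inverse of a bounded cell's area
is a direct local density estimate at the point. Densities are
normalized by the inverse mean bounded-cell area, so

    f~_i = (mean bounded-cell area) / (own area),

which makes f~ dimensionless and centres the harmonic mean of f~ over
bounded cells at 1 (sum of 1/f~_i over bounded cells = n_finite, an
algebraic identity used as a runtime check).

Cells on the boundary of the diagram have infinite area and carry no
density; they are flagged unbounded and excluded from the mean. The
neighbor graph starts from the Delaunay triangulation (cells sharing a
boundary) and keeps the edges passing the midpoint test: a Delaunay pair
(p, q) is a *qualified* neighbor pair iff the midpoint of pq is at least
as close to p (and q) as to any other site — the Gabriel graph condition
with a non-strict boundary (a site exactly on the diametral circle does
not disqualify).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi

from .exceptions import DegenerateInputError, InputError
from .score_map import GeneVariantMap

__all__ = [
    "VoronoiCell", "NeighborEdge", "Tessellation",
    "tessellate", "normalize_densities", "qualified_neighbors",
    "cells_frame", "edges_frame",
]

#: relative tolerance for the harmonic-identity runtime check
_HARMONIC_RTOL = 1e-9


@dataclass
class VoronoiCell:
    """One Voronoi cell; ``area`` and the densities are None when unbounded."""

    site_index: int
    area: Optional[float]
    density: Optional[float]
    normalized_density: Optional[float] = None

    @property
    def bounded(self) -> bool:
        return self.area is not None


@dataclass(frozen=True)
class NeighborEdge:
    """A Delaunay edge; ``is_qualified`` marks the midpoint nearest-neighbor test."""

    site_a: int
    site_b: int
    is_qualified: Optional[bool] = None

    # every stored edge comes from the triangulation
    is_delaunay: bool = True

    def __post_init__(self) -> None:
        if not self.site_a < self.site_b:
            raise InputError("edge endpoints must satisfy site_a < site_b")


@dataclass
class Tessellation:
    """Sites with their Voronoi cells and the (qualified-)neighbor edge set."""

    sites: np.ndarray
    names: list[str]
    cells: list[VoronoiCell]
    edges: list[NeighborEdge]

    @property
    def n_sites(self) -> int:
        return len(self.cells)

    @property
    def n_finite(self) -> int:
        """Number of bounded cells (the *n* of the density normalization)."""
        return sum(c.bounded for c in self.cells)

    @property
    def normalized_densities(self) -> np.ndarray:
        """Per-site f~ (NaN for unbounded cells)."""
        return np.array(
            [np.nan if c.normalized_density is None else c.normalized_density
             for c in self.cells], dtype=float)

    def bounded_normalized_densities(self) -> np.ndarray:
        """f~ of the bounded cells only, in site order."""
        return np.array([c.normalized_density for c in self.cells
                         if c.normalized_density is not None], dtype=float)

    def qualified_edges(self) -> list[tuple[int, int]]:
        return [(e.site_a, e.site_b) for e in self.edges if e.is_qualified]

    def delaunay_edges(self) -> list[tuple[int, int]]:
        return [(e.site_a, e.site_b) for e in self.edges]

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(name) from None


def _as_points(data, names: Optional[Sequence[str]] = None):
    if isinstance(data, GeneVariantMap):
        return data.coordinates(), list(data.genes)
    pts = np.asarray(data, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InputError("sites must be an (n, 2) array")
    if names is None:
        names = [f"S{i:04d}" for i in range(len(pts))]
    return pts, list(names)


def _check_sites(points: np.ndarray, names: Sequence[str]) -> None:
    if len(points) < 3:
        raise DegenerateInputError("at least 3 sites are required")
    if not np.all(np.isfinite(points)):
        raise InputError("non-finite site coordinates")
    _, inverse, counts = np.unique(points, axis=0, return_inverse=True,
                                   return_counts=True)
    if np.any(counts > 1):
        dup_groups = [
            sorted(np.asarray(names)[inverse == g].tolist())
            for g in np.nonzero(counts > 1)[0]
        ]
        raise InputError(
            "duplicate coordinates for genes: "
            + "; ".join(", ".join(g) for g in dup_groups)
            + " (use jitter= to perturb deterministically)")
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-12) < 2:
        raise DegenerateInputError("all sites are collinear; no 2D tessellation")


def _polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a convex cell, vertices ordered by angle about the mean."""
    centre = vertices.mean(axis=0)
    d = vertices - centre
    order = np.argsort(np.arctan2(d[:, 1], d[:, 0]))
    v = vertices[order]
    x, y = v[:, 0], v[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


def _reflect_about_square(points: np.ndarray) -> np.ndarray:
    """Mirror images across the four sides of the unit square."""
    refl = [points.copy() for _ in range(4)]
    refl[0][:, 0] = -refl[0][:, 0]          # x = 0
    refl[1][:, 0] = 2.0 - refl[1][:, 0]     # x = 1
    refl[2][:, 1] = -refl[2][:, 1]          # y = 0
    refl[3][:, 1] = 2.0 - refl[3][:, 1]     # y = 1
    return np.vstack(refl)


def tessellate(data, names: Optional[Sequence[str]] = None, *,
               jitter: float = 0.0, seed: Optional[int] = None,
               bounding_box: bool = False) -> Tessellation:
    """Compute the Voronoi diagram and Delaunay edge set of the map.

    Parameters
    ----------
    data
        A :class:`~voronet.score_map.GeneVariantMap` or an (n, 2) array.
    jitter
        Optional half-width of a deterministic uniform perturbation in
        [-jitter, jitter]^2 added to every site (requires ``seed``);
        explicit opt-in for maps with coinciding points.
    bounding_box
        Extension mode: close the boundary cells by clipping the diagram
        to the unit square (implemented by tessellating the sites
        together with their mirror images across the four sides), so
        every cell is bounded. The default mirrors the convention of
        excluding boundary cells.
    """
    points, site_names = _as_points(data, names)
    points = points.copy()
    if jitter:
        if seed is None:
            raise InputError("jitter requires an explicit seed")
        rng = np.random.default_rng(seed)
        points += rng.uniform(-jitter, jitter, size=points.shape)
    _check_sites(points, site_names)

    n = len(points)
    if bounding_box:
        vor = Voronoi(np.vstack([points, _reflect_about_square(points)]))
    else:
        vor = Voronoi(points)

    cells: list[VoronoiCell] = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if len(region) == 0 or -1 in region:
            cells.append(VoronoiCell(i, None, None))
            continue
        area = _polygon_area(vor.vertices[np.asarray(region)])
        cells.append(VoronoiCell(i, area, 1.0 / area))

    # ridge_points are exactly the Delaunay edges (Voronoi duality);
    # in bounding-box mode keep only pairs of original sites.
    pairs = {(min(a, b), max(a, b)) for a, b in vor.ridge_points
             if a < n and b < n}
    edges = [NeighborEdge(a, b) for a, b in sorted(pairs)]

    return Tessellation(sites=points, names=site_names, cells=cells,
                        edges=edges)


def normalize_densities(t: Tessellation) -> Tessellation:
    """Fill f~ = mean bounded-cell area / own area for every bounded cell.

    Unbounded cells are untouched. Raises when no cell is bounded.
    Returns ``t`` for chaining.
    """
    areas = np.array([c.area for c in t.cells if c.bounded], dtype=float)
    if len(areas) == 0:
        raise DegenerateInputError(
            "no bounded Voronoi cell; density normalization undefined "
            "(fewer than ~5 sites, or all sites on the hull)")
    mean_area = float(areas.mean())
    for c in t.cells:
        if c.bounded:
            c.normalized_density = mean_area / c.area  # type: ignore[operator]
    _assert_harmonic_identity(t)
    return t


def _assert_harmonic_identity(t: Tessellation) -> None:
    nd = t.bounded_normalized_densities()
    total = float(np.sum(1.0 / nd))
    if abs(total - len(nd)) > _HARMONIC_RTOL * max(1.0, len(nd)):
        raise AssertionError(
            f"harmonic identity violated: sum 1/f~ = {total}, n = {len(nd)}")


def qualified_neighbors(t: Tessellation) -> Tessellation:
    """Apply the midpoint nearest-neighbor test to every Delaunay edge.

    Edge (p, q) qualifies iff no other site is strictly closer to the
    midpoint of pq than p is — i.e. the open disk on diameter pq is
    empty of other sites. Returns ``t`` for chaining.
    """
    if not t.edges:
        return t
    ij = np.array([(e.site_a, e.site_b) for e in t.edges], dtype=int)
    mid = 0.5 * (t.sites[ij[:, 0]] + t.sites[ij[:, 1]])
    radius = np.linalg.norm(t.sites[ij[:, 0]] - mid, axis=1)
    # distance from each midpoint to every site; endpoints masked out
    d = np.linalg.norm(mid[:, None, :] - t.sites[None, :, :], axis=2)
    rows = np.arange(len(ij))
    d[rows, ij[:, 0]] = np.inf
    d[rows, ij[:, 1]] = np.inf
    blocked = d.min(axis=1) < radius
    t.edges = [NeighborEdge(e.site_a, e.site_b, is_qualified=bool(~b))
               for e, b in zip(t.edges, blocked)]
    return t


def cells_frame(t: Tessellation) -> pd.DataFrame:
    """Per-gene cell table: coordinates, area, density, normalized density."""
    return pd.DataFrame(
        {"gene": t.names,
         "x": t.sites[:, 0],
         "y": t.sites[:, 1],
         "area": [c.area for c in t.cells],
         "density": [c.density for c in t.cells],
         "normalized_density": [c.normalized_density for c in t.cells]}
    )


def edges_frame(t: Tessellation) -> pd.DataFrame:
    """Neighbor-edge table with the qualified (midpoint-test) flag."""
    return pd.DataFrame(
        {"gene_a": [t.names[e.site_a] for e in t.edges],
         "gene_b": [t.names[e.site_b] for e in t.edges],
         "qualified": [int(bool(e.is_qualified)) for e in t.edges]}
    )
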
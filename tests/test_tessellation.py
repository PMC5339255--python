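"""Tessellation geometry: areas, density normalization, neighbor graph."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from voronet import tessellation as T
from voronet.exceptions import DegenerateInputError, InputError

from conftest import random_sites
from oracles import gabriel_pairs_brute, mc_cell_areas


def full_tessellation(points, **kw):
    t = T.tessellate(points, **kw)
    T.normalize_densities(t)
    T.qualified_neighbors(t)
    return t


class TestTessellate:
    def test_square_corners_plus_center(self):
        """5 sites: only the center cell is bounded, with area exactly 1/2,
        confirmed by a >=1e6-sample Monte-Carlo nearest-site estimate."""
        pts = np.array([(0, 0), (1, 0), (1, 1), (0, 1), (0.5, 0.5)], float)
        t = T.tessellate(pts)
        bounded = [c for c in t.cells if c.bounded]
        assert len(bounded) == 1 and bounded[0].site_index == 4
        assert bounded[0].area == pytest.approx(0.5, rel=1e-12)
        mc = mc_cell_areas(pts, 1_500_000, seed=3, box=(-0.5, 1.5, -0.5, 1.5))
        assert mc[4] == pytest.approx(0.5, rel=5e-3)

    def test_three_sites_all_unbounded(self):
        t = T.tessellate(np.array([(0, 0), (1, 0), (0.3, 0.8)]))
        assert t.n_finite == 0
        with pytest.raises(DegenerateInputError):
            T.normalize_densities(t)

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        pts = random_sites(rng, 40)
        a = full_tessellation(pts)
        b = full_tessellation(pts + np.array([10.0, -7.0]))
        for ca, cb in zip(a.cells, b.cells):
            assert ca.bounded == cb.bounded
            if ca.bounded:
                assert ca.area == pytest.approx(cb.area, rel=1e-9)
        assert a.delaunay_edges() == b.delaunay_edges()
        assert a.qualified_edges() == b.qualified_edges()

    def test_duplicate_coordinates_error_names_genes(self):
        pts = np.array([(0.1, 0.1), (0.1, 0.1), (0.5, 0.5), (0.9, 0.2)])
        with pytest.raises(InputError, match="GA.*GB|GB.*GA"):
            T.tessellate(pts, names=["GA", "GB", "GC", "GD"])

    def test_deterministic_jitter_resolves_duplicates(self):
        pts = np.array([(0.1, 0.1), (0.1, 0.1), (0.5, 0.5), (0.9, 0.2)])
        t1 = T.tessellate(pts, jitter=1e-6, seed=7)
        t2 = T.tessellate(pts, jitter=1e-6, seed=7)
        assert np.array_equal(t1.sites, t2.sites)
        with pytest.raises(InputError):
            T.tessellate(pts, jitter=1e-6)  # jitter without seed

    def test_collinear_sites_error(self):
        pts = np.column_stack([np.linspace(0, 1, 6), np.linspace(0, 1, 6)])
        with pytest.raises(DegenerateInputError, match="collinear"):
            T.tessellate(pts)


class TestNormalizeDensities:
    def test_single_bounded_cell_has_unit_density(self):
        pts = np.array([(0, 0), (1, 0), (1, 1), (0, 1), (0.5, 0.5)], float)
        t = T.normalize_densities(T.tessellate(pts))
        center = t.cells[4]
        assert center.normalized_density == pytest.approx(1.0)

    def test_equal_area_cells_all_unit(self):
        """Regular grid clipped to the unit square: every cell has the
        same area, so every f~ = 1."""
        xs = np.linspace(0.1, 0.9, 5)
        pts = np.array([(x, y) for y in xs for x in xs])
        t = T.normalize_densities(T.tessellate(pts, bounding_box=True))
        assert t.n_finite == len(pts)
        np.testing.assert_allclose(t.bounded_normalized_densities(), 1.0,
                                   rtol=1e-9)

    def test_harmonic_identity_random_maps(self):
        for seed in range(5):
            t = T.normalize_densities(
                T.tessellate(random_sites(np.random.default_rng(seed), 60)))
            nd = t.bounded_normalized_densities()
            assert np.sum(1.0 / nd) == pytest.approx(t.n_finite, rel=1e-9)

    def test_perturbed_grid_matches_monte_carlo_oracle(self, perturbed_grid):
        """Normalized densities recomputed from Monte-Carlo nearest-site
        areas agree within 1% with the shoelace-based values.

        Bounded cells bordering the hull are slivers with circumcenters
        hundreds of units away, hopeless for uniform sampling, so the
        oracle compares the compact cells (all vertices inside a small
        box) and normalizes by the mean over that same subset on both
        routes."""
        from scipy.spatial import Voronoi

        t = T.normalize_densities(T.tessellate(perturbed_grid))
        box = (-0.1, 1.1, -0.1, 1.1)
        vor = Voronoi(perturbed_grid)
        compact = []
        for c in t.cells:
            if not c.bounded:
                continue
            v = vor.vertices[vor.regions[vor.point_region[c.site_index]]]
            if (v[:, 0].min() > box[0] and v[:, 0].max() < box[1]
                    and v[:, 1].min() > box[2] and v[:, 1].max() < box[3]):
                compact.append(c)
        assert len(compact) >= 20
        mc = mc_cell_areas(perturbed_grid, 10_000_000, seed=9, box=box)
        mc_areas = np.array([mc[c.site_index] for c in compact])
        impl_areas = np.array([c.area for c in compact])
        np.testing.assert_allclose(mc_areas.mean() / mc_areas,
                                   impl_areas.mean() / impl_areas, rtol=1e-2)

    @given(st.floats(0.1, 20.0), st.floats(0.0, 2 * np.pi))
    def test_similarity_invariance(self, scale, angle):
        """f~ is unchanged by rotation and uniform scaling of the sites."""
        pts = random_sites(np.random.default_rng(17), 30)
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        moved = scale * pts @ rot.T
        a = T.normalize_densities(T.tessellate(pts))
        b = T.normalize_densities(T.tessellate(moved))
        np.testing.assert_allclose(a.normalized_densities,
                                   b.normalized_densities, rtol=1e-6,
                                   equal_nan=True)


class TestQualifiedNeighbors:
    def test_blocking_third_site_disqualifies(self):
        """Midpoint of (0,0)-(1,0) is 0.4 from (0.5,0.4) but 0.5 from the
        endpoints, so the edge fails the midpoint test."""
        pts = np.array([(0.0, 0.0), (1.0, 0.0), (0.5, 0.4)])
        t = T.qualified_neighbors(T.tessellate(pts))
        flags = {(e.site_a, e.site_b): e.is_qualified for e in t.edges}
        assert flags[(0, 1)] is False
        assert flags[(0, 2)] is True and flags[(1, 2)] is True

    def test_isolated_distant_pairs_qualify(self):
        pts = np.array([(0.0, 0.0), (0.05, 0.0), (10.0, 10.0), (10.05, 10.0)])
        t = T.qualified_neighbors(T.tessellate(pts))
        flags = {(e.site_a, e.site_b): e.is_qualified for e in t.edges}
        assert flags[(0, 1)] is True and flags[(2, 3)] is True

    def test_qualified_subset_of_delaunay(self):
        t = full_tessellation(random_sites(np.random.default_rng(23), 80))
        assert set(t.qualified_edges()) <= set(t.delaunay_edges())

    @pytest.mark.parametrize("seed,n", [(0, 30), (1, 100), (2, 100), (3, 200)])
    def test_matches_brute_force_gabriel_graph(self, seed, n):
        pts = random_sites(np.random.default_rng(seed), n)
        t = full_tessellation(pts)
        assert set(t.qualified_edges()) == gabriel_pairs_brute(pts)


class TestFrames:
    def test_cell_and_edge_tables_round_trip(self, tmp_path):
        t = full_tessellation(random_sites(np.random.default_rng(2), 25),
                              names=[f"g{i}" for i in range(25)])
        cells = T.cells_frame(t)
        edges = T.edges_frame(t)
        assert list(cells.columns) == ["gene", "x", "y", "area", "density",
                                       "normalized_density"]
        assert list(edges.columns) == ["gene_a", "gene_b", "qualified"]
        # unbounded cells have empty area fields
        assert cells["area"].isna().sum() == t.n_sites - t.n_finite

        from voronet.cli import tessellation_from_frames
        cells.to_csv(tmp_path / "c.tsv", sep="\t", index=False)
        edges.to_csv(tmp_path / "e.tsv", sep="\t", index=False)
        import pandas as pd
        t2 = tessellation_from_frames(pd.read_csv(tmp_path / "c.tsv", sep="\t"),
                                      pd.read_csv(tmp_path / "e.tsv", sep="\t"))
        assert t2.n_finite == t.n_finite
        assert t2.qualified_edges() == t.qualified_edges()
        np.testing.assert_allclose(t2.normalized_densities,
                                   t.normalized_densities, rtol=1e-12,
                                   equal_nan=True)
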
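"""Parametric construction, contour extraction, and lattice invariants."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage

from ahflow.errors import GeometryError, SegmentationError
from ahflow.geometry import (
    AnteriorSegmentSpec,
    Contour,
    NodeType,
    build_domain_from_contour,
    build_parametric_domain,
    extract_cornea_contour,
    grid_resolution_report,
)
from ahflow.image import EdgeMap


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"as_width": -1.0},
            {"indentation_depth": 3.5},
            {"pupil_diameter": 13.0},
            {"cornea_radius": 6.0},
            {"crypt_list": ((0.0, 1.0, 0.6),)},  # deeper than the iris
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AnteriorSegmentSpec(**kwargs)

    def test_mirrored_negates_shift_and_crypts(self):
        spec = AnteriorSegmentSpec(asymmetry_shift=0.5, crypt_list=((2.0, 1.0, 0.3),))
        m = spec.mirrored()
        assert m.asymmetry_shift == -0.5
        assert m.crypt_list == ((-2.0, 1.0, 0.3),)


class TestParametricDomain:
    def test_physical_extents_of_default_eye(self, default_spec):
        grid = build_parametric_domain(default_spec, 0.05)
        report = grid_resolution_report(grid)
        assert report["fluid_extent_x_mm"] == pytest.approx(12.8, abs=0.1)
        assert report["inlet_height_mm"] == pytest.approx(0.5, abs=0.05)

    def test_symmetric_spec_yields_mirror_symmetric_labels(self, default_spec):
        grid = build_parametric_domain(default_spec, 0.1)
        np.testing.assert_array_equal(grid.labels, np.fliplr(grid.labels))

    def test_mirrored_spec_yields_mirrored_grid_exactly(self):
        spec = AnteriorSegmentSpec(asymmetry_shift=0.8, crypt_list=((2.0, 1.0, 0.3),))
        g1 = build_parametric_domain(spec, 0.1)
        g2 = build_parametric_domain(spec.mirrored(), 0.1)
        np.testing.assert_array_equal(np.fliplr(g1.labels), g2.labels)

    def test_indentation_strictly_removes_volume(self, default_spec):
        counts = [
            int(build_parametric_domain(replace(default_spec, indentation_depth=d), 0.05).fluid_mask.sum())
            for d in (0.0, 0.3, 0.5)
        ]
        assert counts[0] > counts[1] > counts[2]

    def test_refinement_stability_of_fluid_area(self, default_spec):
        areas = {}
        for dx in (0.05, 0.025):
            g = build_parametric_domain(default_spec, dx)
            areas[dx] = g.fluid_mask.sum() * dx**2
        assert abs(areas[0.025] - areas[0.05]) / areas[0.05] < 0.02

    def test_halving_dx_quadruples_fluid_count(self, default_spec):
        n1 = build_parametric_domain(default_spec, 0.1).fluid_mask.sum()
        n2 = build_parametric_domain(default_spec, 0.05).fluid_mask.sum()
        assert n2 / n1 == pytest.approx(4.0, rel=0.1)

    def test_paper_scale_resolution_node_count(self, default_spec):
        grid = build_parametric_domain(default_spec, 0.0125)
        report = grid_resolution_report(grid)
        assert 3e5 <= report["total_nodes"] <= 1e6

    def test_resolution_report_on_fluidless_grid(self):
        from ahflow.geometry import NodeGrid

        grid = NodeGrid(labels=np.zeros((5, 5), dtype=np.int8), dx=0.1)
        report = grid_resolution_report(grid)
        assert report["counts"]["FLUID"] == 0
        assert "fluid_area_mm2" not in report

    def test_too_coarse_dx_rejected(self, default_spec):
        with pytest.raises(GeometryError, match="pc_inlet_height"):
            build_parametric_domain(default_spec, 0.2)

    def test_deep_indentation_disconnects_and_errors(self, default_spec):
        with pytest.raises(GeometryError):
            build_parametric_domain(replace(default_spec, indentation_depth=2.95), 0.1)

    def test_crypts_add_fluid_recesses_in_iris(self, default_spec):
        plain = build_parametric_domain(default_spec, 0.05)
        crypt = build_parametric_domain(
            replace(default_spec, crypt_list=((2.5, 1.2, 0.3), (-2.5, 1.2, 0.3))), 0.05
        )
        assert crypt.fluid_mask.sum() > plain.fluid_mask.sum()


class TestGridInvariants:
    @pytest.mark.parametrize("dx", [0.1, 0.05])
    def test_every_fluid_node_has_a_fluid_neighbor(self, default_spec, dx):
        grid = build_parametric_domain(default_spec, dx)
        fluid = grid.fluid_mask
        nbr = ndimage.uniform_filter(fluid.astype(float), 3, mode="constant") * 9 - fluid
        assert not np.any(fluid & (nbr < 0.5))

    def test_fluid_region_is_four_connected(self, coarse_grid):
        fluid = coarse_grid.fluid_mask
        _, ncomp = ndimage.label(fluid, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        assert ncomp == 1

    def test_inlet_and_tm_border_fluid_on_both_sides(self, coarse_grid):
        labels = coarse_grid.labels
        fluid = coarse_grid.fluid_mask
        adj = np.zeros_like(fluid)
        for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            adj |= np.roll(np.roll(fluid, dr, axis=0), dc, axis=1)
        for kind in (NodeType.INLET, NodeType.TM_OUTLET):
            mask = labels == kind
            assert mask.any()
            assert np.all(adj[mask])
            cols = np.nonzero(mask.any(axis=0))[0]
            mid = labels.shape[1] // 2
            assert (cols < mid).any() and (cols > mid).any()

    def test_exterior_nodes_do_not_touch_fluid(self, coarse_grid):
        fluid = coarse_grid.fluid_mask
        ext = coarse_grid.labels == NodeType.EXTERIOR
        near = ndimage.binary_dilation(fluid, structure=np.ones((3, 3), bool))
        assert not np.any(ext & near)


class TestContourExtraction:
    def _arc_edge_map(self, nrow=60, ncol=101, radius=45.0):
        mask = np.zeros((nrow, ncol), dtype=bool)
        cx, cy = 50.0, 55.0
        cols = np.arange(5, 96)
        rows = cy - np.sqrt(radius**2 - (cols - cx) ** 2)
        rr = np.round(rows).astype(int)
        mask[rr, cols] = True
        return mask, cols, rows

    def test_semicircular_arc_recovered_within_one_pixel(self):
        mask, cols, rows = self._arc_edge_map()
        A = (55.0, 5.0)
        B = (55.0, 95.0)
        C = (25.0, 50.0)
        contour = extract_cornea_contour(EdgeMap(mask), A, B, C)
        got = dict((int(c), r) for r, c in contour.points)
        for c, r in zip(cols, rows):
            assert abs(got[int(c)] - r) <= 1.0

    def test_empty_edge_map_is_a_segmentation_failure(self):
        mask = np.zeros((40, 40), dtype=bool)
        with pytest.raises(SegmentationError):
            extract_cornea_contour(EdgeMap(mask), (30, 5), (30, 35), (10, 20))

    def test_feature_point_outside_image_rejected(self):
        mask = np.ones((20, 20), dtype=bool)
        with pytest.raises(ValueError, match="outside"):
            extract_cornea_contour(EdgeMap(mask), (30, 5), (10, 15), (5, 10))

    def test_missing_columns_filled_by_interpolation(self):
        mask, cols, rows = self._arc_edge_map()
        mask[:, 40:45] = False  # knock out a few columns
        contour = extract_cornea_contour(EdgeMap(mask), (55.0, 5.0), (55.0, 95.0), (25.0, 50.0))
        got = dict((int(c), r) for r, c in contour.points)
        for c in range(40, 45):
            assert abs(got[c] - (55.0 - np.sqrt(45.0**2 - (c - 50.0) ** 2))) <= 1.5


class TestDomainFromContour:
    def test_exact_contour_round_trip_matches_parametric(self, default_spec, oct_fixture):
        rebuilt = build_domain_from_contour(
            oct_fixture.cornea_contour, [], default_spec, 0.05
        )
        mismatch = np.mean(rebuilt.labels != oct_fixture.grid.labels)
        assert mismatch < 0.02

    def test_cornea_only_fallback_builds_valid_grid(self, default_spec, oct_fixture):
        grid = build_domain_from_contour(oct_fixture.cornea_contour, [], default_spec, 0.1)
        fluid = grid.fluid_mask
        _, ncomp = ndimage.label(fluid, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        assert ncomp == 1
        assert (grid.labels == NodeType.TM_OUTLET).any()
        assert (grid.labels == NodeType.INLET).any()
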
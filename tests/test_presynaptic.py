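import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import binary_mask, disc_px, mask_from_string
from nmjmorph.errors import EmptyMaskError
from nmjmorph.presynaptic import (
    AxonInput,
    axon_diameter,
    branch_lengths,
    classify_skeleton,
    complexity,
    erase_axon,
    measure_region,
    skeleton_stats,
    skeletonize,
)


class TestMeasureRegion:
    def test_square_area(self):
        m = binary_mask(np.pad(np.ones((10, 10), dtype=bool), 2), cal=0.1)
        area, perim = measure_region(m)
        assert area == pytest.approx(1.0)

    def test_single_pixel_area(self):
        px = np.zeros((5, 5), dtype=bool)
        px[2, 2] = True
        area, _ = measure_region(binary_mask(px, 0.1))
        assert area == pytest.approx(0.01)

    def test_square_perimeter_corner_tracing(self):
        # 10x10 px block: 36 px of boundary under the through-centre
        # contour convention, i.e. 3.6 um at 0.1 um/px.
        m = binary_mask(np.pad(np.ones((10, 10), dtype=bool), 2), cal=0.1)
        _, perim = measure_region(m)
        assert perim == pytest.approx(3.6)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            measure_region(binary_mask(np.zeros((4, 4), dtype=bool)))

    def test_area_additive_over_particles(self):
        m = disc_px((40, 80), (20, 18), 6) | disc_px((40, 80), (20, 60), 6)
        a_both, _ = measure_region(binary_mask(m, 0.1))
        a1, _ = measure_region(binary_mask(disc_px((40, 80), (20, 18), 6), 0.1))
        a2, _ = measure_region(binary_mask(disc_px((40, 80), (20, 60), 6), 0.1))
        assert a_both == pytest.approx(a1 + a2)


def polygon_oracle(shape, vertices):
    """Set-difference oracle: pixel centres strictly inside the polygon."""
    from shapely.geometry import Point, Polygon

    poly = Polygon([(c, r) for r, c in vertices])
    out = np.zeros(shape, dtype=bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            if poly.contains(Point(c, r)):
                out[r, c] = True
    return out


class TestEraseAxon:
    T_SHAPE = """
..........
.#########
....#.....
....#.....
....#.....
"""

    def test_disjoint_region_is_noop(self):
        m = mask_from_string(self.T_SHAPE)
        axon = AxonInput(((0.0, 0.0), (1.0, 1.0)), erase_region=[(0, 0), (0, 0.5), (0.5, 0.5)])
        out = erase_axon(m, axon)
        np.testing.assert_array_equal(out.pixels, m.pixels)

    def test_full_frame_region_empties_mask(self):
        m = mask_from_string(self.T_SHAPE)
        h, w = m.pixels.shape
        axon = AxonInput(
            ((0.0, 0.0), (1.0, 1.0)),
            erase_region=[(-0.5, -0.5), (-0.5, w - 0.5), (h - 0.5, w - 0.5), (h - 0.5, -0.5)],
        )
        assert erase_axon(m, axon).is_empty()

    def test_t_stem_erased_leaves_crossbar(self):
        m = mask_from_string(self.T_SHAPE)
        verts = [(1.5, 3.0), (1.5, 6.0), (4.5, 6.0), (4.5, 3.0)]
        axon = AxonInput(((0.0, 0.0), (1.0, 1.0)), erase_region=verts)
        out = erase_axon(m, axon)
        expected = m.pixels & ~polygon_oracle(m.pixels.shape, verts)
        np.testing.assert_array_equal(out.pixels, expected)
        assert out.pixels[1].sum() == 9 and not out.pixels[2:].any()

    def test_without_region_is_noop(self):
        m = mask_from_string(self.T_SHAPE)
        out = erase_axon(m, AxonInput(((0.0, 0.0), (1.0, 1.0))))
        assert out is m

    def test_out_of_bounds_polygon_rejected(self):
        m = mask_from_string(self.T_SHAPE)
        axon = AxonInput(((0.0, 0.0), (1.0, 1.0)), erase_region=[(0, 0), (0, 99), (5, 99)])
        with pytest.raises(ValueError):
            erase_axon(m, axon)

    def test_erase_never_grows_area(self):
        m = mask_from_string(self.T_SHAPE)
        axon = AxonInput(((0.0, 0.0), (1.0, 1.0)), erase_region=[(0, 0), (0, 5), (4, 5)])
        assert erase_axon(m, axon).area_px <= m.area_px


class TestAxonDiameter:
    def test_3_4_5_triangle(self):
        axon = AxonInput(((0.0, 0.0), (3.0, 4.0)))
        assert axon_diameter(axon, 0.1) == pytest.approx(0.5)

    def test_axis_aligned(self):
        axon = AxonInput(((0.0, 0.0), (0.0, 10.0)))
        assert axon_diameter(axon, 1.0) == pytest.approx(10.0)

    def test_identical_endpoints_rejected(self):
        with pytest.raises(ValueError):
            AxonInput(((1.0, 2.0), (1.0, 2.0)))


class TestSkeletonize:
    def test_thin_line_unchanged(self):
        px = np.zeros((5, 9), dtype=bool)
        px[2, 1:8] = True
        out = skeletonize(binary_mask(px))
        np.testing.assert_array_equal(out.pixels, px)

    def test_thick_bar_reduces_to_axis(self):
        px = np.zeros((11, 30), dtype=bool)
        px[3:8, 2:28] = True  # 5 px thick bar
        skel = skeletonize(binary_mask(px))
        assert (skel.pixels & ~px).sum() == 0
        rows = np.nonzero(skel.pixels)[0]
        assert set(rows) <= {4, 5, 6}  # collapses to the central axis
        assert skel.area_px <= 28

    def test_disc_degenerates(self):
        skel = skeletonize(binary_mask(disc_px((30, 30), (15, 15), 8)))
        assert skel.area_px <= 6

    def test_idempotent(self):
        m = binary_mask(disc_px((30, 60), (15, 20), 7) | disc_px((30, 60), (15, 40), 7))
        once = skeletonize(m)
        np.testing.assert_array_equal(skeletonize(once).pixels, once.pixels)


class TestClassifySkeleton:
    def test_three_pixel_line(self):
        px = np.zeros((3, 5), dtype=bool)
        px[1, 1:4] = True
        stats = classify_skeleton(binary_mask(px))
        assert stats.n_end_points == 2
        assert stats.n_branch_points == 0
        assert stats.n_terminal_branches == 1

    def test_plus_sign(self):
        px = np.zeros((5, 5), dtype=bool)
        px[2, 1:4] = True
        px[1:4, 2] = True
        stats = classify_skeleton(binary_mask(px))
        assert stats.n_end_points == 4
        assert stats.n_branch_points == 1
        assert stats.n_terminal_branches == 4

    def test_t_shape(self):
        px = np.zeros((5, 5), dtype=bool)
        px[1, 0:5] = True
        px[1:4, 2] = True
        stats = classify_skeleton(binary_mask(px))
        assert stats.n_end_points == 3
        assert stats.n_branch_points == 1
        assert stats.n_terminal_branches == 3

    def test_h_shape(self):
        px = np.zeros((7, 7), dtype=bool)
        px[1:6, 1] = True
        px[1:6, 5] = True
        px[3, 1:6] = True
        stats = classify_skeleton(binary_mask(px))
        assert stats.n_branch_points == 2
        assert stats.n_terminal_branches == 5

    def test_adjacent_junction_pixels_merge(self):
        # two degree-3 pixels side by side count as one branch point
        px = np.zeros((7, 8), dtype=bool)
        px[3, 1:7] = True
        px[1:3, 3] = True  # arm up into (3,3)
        px[4:6, 4] = True  # arm down from (3,4)
        stats = classify_skeleton(binary_mask(px))
        assert stats.n_branch_points == 1
        assert stats.n_terminal_branches == 4

    def test_tree_matches_degree_sum_oracle(self):
        # independent oracle for acyclic skeletons: segments = sum of degrees
        # over non-degree-2 nodes / 2, on the corner-pruned adjacency graph
        import networkx as nx

        px = np.zeros((20, 40), dtype=bool)
        px[10, 3:35] = True
        for col, d, length in ((8, -1, 5), (16, 1, 7), (27, -1, 6)):
            for k in range(length + 1):
                px[10 + d * k, col] = True
        g = nx.Graph()
        nodes = list(zip(*np.nonzero(px)))
        g.add_nodes_from(nodes)
        for (r, c) in nodes:
            for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                q = (r + dr, c + dc)
                if q in g:
                    if dr and dc and (px[r, c + dc] or px[r + dr, c]):
                        continue  # corner-pruned diagonal
                    g.add_edge((r, c), q)
        oracle_segments = sum(d for _, d in g.degree if d != 2) // 2
        stats = classify_skeleton(binary_mask(px))
        assert stats.n_terminal_branches == oracle_segments == 7
        assert stats.n_branch_points == 3


class TestBranchLengths:
    def test_collinear_pixels(self):
        px = np.zeros((3, 13), dtype=bool)
        px[1, 1:12] = True  # 11 px, 10 orthogonal steps
        total, avg = branch_lengths(binary_mask(px, 0.1))
        assert total == pytest.approx(1.0)
        assert avg == pytest.approx(1.0)

    def test_diagonal_line(self):
        px = np.zeros((5, 5), dtype=bool)
        px[1, 1] = px[2, 2] = px[3, 3] = True
        total, _ = branch_lengths(binary_mask(px))
        assert total == pytest.approx(2 * math.sqrt(2))

    def test_plus_sign_arms(self):
        px = np.zeros((5, 5), dtype=bool)
        px[2, 1:4] = True
        px[1:4, 2] = True
        total, avg = branch_lengths(binary_mask(px))
        assert total == pytest.approx(4.0)
        assert avg == pytest.approx(1.0)

    def test_imagej_parity_uses_pixel_count(self):
        px = np.zeros((5, 5), dtype=bool)
        px[1, 1] = px[2, 2] = px[3, 3] = True
        total, _ = branch_lengths(binary_mask(px), imagej_parity=True)
        assert total == pytest.approx(3.0)

    def test_additive_over_components(self):
        a = np.zeros((10, 20), dtype=bool)
        a[2, 2:9] = True
        b = np.zeros((10, 20), dtype=bool)
        b[7, 4:17] = True
        t_a, _ = branch_lengths(binary_mask(a))
        t_b, _ = branch_lengths(binary_mask(b))
        t_ab, _ = branch_lengths(binary_mask(a | b))
        assert t_ab == pytest.approx(t_a + t_b)

    def test_deleting_branch_points_never_increases_length(self):
        px = np.zeros((9, 9), dtype=bool)
        px[4, 1:8] = True
        px[1:8, 4] = True
        from nmjmorph.presynaptic import _chamfer_length_px, _neighbor_counts

        counts = _neighbor_counts(px)
        segments = px & ~(px & (counts >= 3))
        assert _chamfer_length_px(segments, context=px) <= _chamfer_length_px(px)


class TestComplexity:
    @pytest.mark.parametrize(
        "branches,points,length,expected",
        [(10, 10, 100.0, 2.0), (1, 1, 100.0, 0.0)],
    )
    def test_formula(self, branches, points, length, expected):
        assert complexity(branches, points, length) == pytest.approx(expected)

    def test_zero_factor_missing(self):
        assert complexity(1, 0, 5.0) is None
        assert complexity(0, 3, 5.0) is None
        assert complexity(2, 1, 0.0) is None


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 5000))
def test_skeleton_subset_of_mask(seed):
    rng = np.random.default_rng(seed)
    px = rng.random((16, 16)) < 0.55
    if not px.any():
        return
    skel = skeletonize(binary_mask(px))
    assert (skel.pixels & ~px).sum() == 0


def test_skeleton_stats_consistency():
    px = np.zeros((20, 40), dtype=bool)
    px[10, 3:35] = True
    px[3:10, 12] = True
    px[10:17, 24] = True
    stats = skeleton_stats(binary_mask(px, 0.1))
    assert stats.average_branch_length_um == pytest.approx(
        stats.total_branch_length_um / stats.n_terminal_branches
    )
    assert stats.complexity == pytest.approx(
        math.log10(
            stats.n_terminal_branches
            * stats.n_branch_points
            * stats.total_branch_length_um
            / 100.0
        )
    )
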
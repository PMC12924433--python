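"""Multi-slice alignment and the cross-slice graph."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spotfuse import (
    SliceStack,
    SpotDataset,
    align_horizontal,
    align_vertical,
    build_graph,
    cross_slice_graph,
    edge_spots,
)
from spotfuse.align import stack_z_coordinates


def _grid_slice(side=3, spacing=100.0, shift=(0.0, 0.0), slice_id="s0", genes=4):
    n = side * side
    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float) * spacing
    coords += np.asarray(shift)
    rng = np.random.default_rng(0)
    return SpotDataset(
        counts=rng.integers(0, 5, (n, genes)).astype(float),
        gene_ids=[f"g{j}" for j in range(genes)],
        spot_ids=[f"{slice_id}_spot{i}" for i in range(n)],
        coords=coords,
        slice_id=slice_id,
        spot_spacing=spacing,
    )


class TestEdgeSpots:
    def test_vertical_mode_takes_all_spots(self):
        ds = _grid_slice()
        assert edge_spots(ds, mode="vertical").tolist() == list(range(9))

    def test_rightmost_spots(self):
        ds = _grid_slice()
        idx = edge_spots(ds, mode="horizontal", side="right", tol=50.0)
        assert sorted(ds.coords[idx, 0]) == [200.0] * 3

    def test_leftmost_spots(self):
        ds = _grid_slice()
        idx = edge_spots(ds, mode="horizontal", side="left", tol=50.0)
        assert sorted(ds.coords[idx, 0]) == [0.0] * 3

    def test_single_spot_any_side(self):
        ds = SpotDataset(
            counts=np.ones((1, 2)), gene_ids=["a", "b"], spot_ids=["s"],
            coords=np.array([[5.0, 5.0]]), spot_spacing=1.0,
        )
        for side in ("left", "right", "all"):
            assert edge_spots(ds, mode="horizontal", side=side).tolist() == [0]


class TestVerticalAlignment:
    def test_translated_copy_realigned_to_reference(self):
        s1 = _grid_slice(slice_id="a")
        s2 = _grid_slice(shift=(5.0, -3.0), slice_id="b")
        stack = SliceStack([s1, s2], thickness=10.0, separations=[0.0])
        align_vertical(stack)
        a = stack.aligned_coords
        np.testing.assert_allclose(a[:9, :2], s1.coords, atol=1e-12)
        np.testing.assert_allclose(a[9:, :2], s1.coords, atol=1e-12)

    def test_identical_slices_zero_bias(self):
        s1 = _grid_slice(slice_id="a")
        s2 = _grid_slice(slice_id="b")
        stack = SliceStack([s1, s2])
        align_vertical(stack)
        np.testing.assert_array_equal(
            stack.aligned_coords[9:, :2], s2.coords
        )

    def test_reference_slice_untouched(self):
        s1 = _grid_slice(slice_id="a")
        before = s1.coords.copy()
        s2 = _grid_slice(shift=(123.0, 45.0), slice_id="b")
        stack = SliceStack([s1, s2])
        align_vertical(stack)
        np.testing.assert_array_equal(s1.coords, before)
        np.testing.assert_array_equal(stack.aligned_coords[:9, :2], before)

    def test_z_values_thickness_plus_separations(self):
        z = stack_z_coordinates(3, thickness=10.0, lam=1.0, separations=[300.0, 300.0])
        np.testing.assert_allclose(z, [0.0, 310.0, 620.0])

    @settings(max_examples=50, deadline=None)
    @given(
        st.integers(min_value=1, max_value=8),
        st.floats(min_value=0.1, max_value=100.0),
        st.floats(min_value=0.0, max_value=10.0),
        st.lists(st.floats(min_value=0.0, max_value=1000.0), min_size=7, max_size=7),
    )
    def test_z_formula_property(self, s, d, lam, seps):
        z = stack_z_coordinates(s, d, lam, seps[: s - 1])
        assert z[0] == 0.0
        for i in range(2, s + 1):
            assert z[i - 1] == pytest.approx(
                (i - 1) * d + lam * sum(seps[: i - 1]), rel=1e-12
            )

    def test_random_rigid_translations_recovered(self):
        rng = np.random.default_rng(0)
        base = _grid_slice(side=5, slice_id="ref")
        slices = [base] + [
            _grid_slice(
                side=5, shift=tuple(rng.uniform(-500, 500, 2)), slice_id=f"s{i}"
            )
            for i in range(1, 4)
        ]
        stack = SliceStack(slices)
        align_vertical(stack)
        for i in range(4):
            np.testing.assert_allclose(
                stack.aligned_coords[i * 25 : (i + 1) * 25, :2],
                base.coords,
                atol=1e-9,
            )


class TestHorizontalAlignment:
    def test_constructed_shift_arithmetic(self):
        # S1 x in [0, 10], S2 x in [100, 110]: dx = 10 - 100 = -90
        s1 = _grid_slice(side=2, spacing=10.0, slice_id="a")
        s2 = _grid_slice(side=2, spacing=10.0, shift=(100.0, 0.0), slice_id="b")
        merged = align_horizontal(s1, s2)
        right_half = merged.coords[4:]
        assert right_half[:, 0].min() == pytest.approx(10.0)
        assert merged.coords[:4].tolist() == s1.coords.tolist()

    def test_already_abutting_slices_unmoved(self):
        s1 = _grid_slice(side=2, spacing=10.0, slice_id="a")
        s2 = _grid_slice(side=2, spacing=10.0, shift=(10.0, 0.0), slice_id="b")
        merged = align_horizontal(s1, s2)
        np.testing.assert_allclose(merged.coords[4:], s2.coords)

    def test_chaining_three_slices_grows_extent(self):
        s1 = _grid_slice(side=2, spacing=10.0, slice_id="a")
        s2 = _grid_slice(side=2, spacing=10.0, shift=(55.0, 3.0), slice_id="b")
        s3 = _grid_slice(side=2, spacing=10.0, shift=(-40.0, -7.0), slice_id="c")
        m12 = align_horizontal(s1, s2)
        m123 = align_horizontal(m12, s3)
        assert m123.n_spots == 12
        extent12 = m12.coords[:, 0].max() - m12.coords[:, 0].min()
        extent123 = m123.coords[:, 0].max() - m123.coords[:, 0].min()
        assert extent123 > extent12  # x-extent grows monotonically
        # each appended slice abuts the running max-x of the merged entity
        assert m123.coords[8:, 0].min() == pytest.approx(m12.coords[:, 0].max())

    def test_y_bias_uses_edge_means(self):
        s1 = _grid_slice(side=3, spacing=10.0, slice_id="a")
        s2 = _grid_slice(side=3, spacing=10.0, shift=(100.0, 42.0), slice_id="b")
        merged = align_horizontal(s1, s2)
        # equal-shaped edges: y offset fully removed
        np.testing.assert_allclose(
            sorted(merged.coords[9:, 1]), sorted(s1.coords[:, 1]), atol=1e-9
        )

    def test_duplicate_ids_suffixed(self):
        s1 = _grid_slice(side=2, slice_id="a")
        s2 = _grid_slice(side=2, slice_id="a")  # same ids on purpose
        s2.slice_id = "b"
        merged = align_horizontal(s1, s2)
        assert len(set(merged.spot_ids)) == 8


class TestCrossSliceGraph:
    def test_matches_3d_brute_force_and_links_counterparts(self):
        s1 = _grid_slice(slice_id="a")
        s2 = _grid_slice(slice_id="b")
        stack = SliceStack([s1, s2], thickness=10.0, separations=[0.0])
        align_vertical(stack)
        g = cross_slice_graph(stack, radius=15.0)
        coords = stack.aligned_coords
        n = len(coords)
        A = g.dense()
        for i in range(n):
            for j in range(n):
                expected = 1 if (
                    i == j or np.linalg.norm(coords[i] - coords[j]) < 15.0
                ) else 0
                assert A[i, j] == expected
        # each spot's only cross-slice neighbor is its vertical counterpart
        for i in range(9):
            assert A[i, 9 + i] == 1
            assert A[i, 9:].sum() == 1

    def test_single_slice_equals_2d_graph(self):
        s1 = _grid_slice(slice_id="a")
        stack = SliceStack([s1])
        g3 = cross_slice_graph(stack, radius=150.0)
        g2 = build_graph(s1.coords, radius=150.0, spacing=100.0)
        np.testing.assert_array_equal(g3.dense(), g2.dense())

    def test_large_gap_warns_no_cross_edges(self):
        s1 = _grid_slice(slice_id="a")
        s2 = _grid_slice(slice_id="b")
        stack = SliceStack([s1, s2], thickness=1500.0, separations=[0.0])
        align_vertical(stack)
        with pytest.warns(UserWarning, match="no cross-slice edges"):
            g = cross_slice_graph(stack, radius=150.0)
        A = g.dense()
        assert A[:9, 9:].sum() == 0


def test_stack_validation():
    s1 = _grid_slice()
    with pytest.raises(ValueError, match="separation"):
        SliceStack([s1, s1], separations=[1.0, 2.0])
    with pytest.raises(ValueError, match="mode"):
        SliceStack([s1], mode="diagonal")
    with pytest.raises(ValueError, match="2 slices"):
        align_vertical(SliceStack([s1]))
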
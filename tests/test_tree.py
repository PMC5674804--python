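"""Summarization index: culling, structure, sampling, whittling, and the
exact-budget viewport query checked against linear-scan oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mzlod.model import MsPoint, PointSet, ViewWindow
from mzlod.tree import (
    BuildConfig,
    SummaryQuery,
    brute_force_query,
    build_tree,
    cull_points,
    jump_window,
    load_index,
    sample_node,
    save_index,
    whittle,
)

from conftest import grid_points, random_windows, sort_oracle_top_n


class TestCulling:
    def test_sub_threshold_point_is_noise(self):
        points = [MsPoint(0, 500.0, 10.0, 0.5), MsPoint(1, 501.0, 10.0, 2.0)]
        kept = cull_points(points, 1.0)
        assert [p.id for p in kept] == [1]

    def test_floor_boundary_is_inclusive(self):
        kept = cull_points([MsPoint(0, 500.0, 10.0, 1.0)], 1.0)
        assert len(kept) == 1

    def test_empty_input(self):
        assert len(cull_points(PointSet(), 1.0)) == 0

    def test_known_truth_count_on_synthetic_set(self):
        """1000 points of which exactly 400 sit below the floor -> 600 kept."""
        rng = np.random.default_rng(5)
        low = rng.uniform(0.1, 0.95, 400)
        high = rng.uniform(1.0, 100.0, 600)
        inten = np.concatenate([low, high])
        rng.shuffle(inten)
        ps = PointSet(np.arange(1000), rng.uniform(400, 1600, 1000),
                      rng.uniform(0, 600, 1000), inten)
        oracle = int(np.sum(ps.intensity >= 1.0))  # independent linear scan
        assert oracle == 600
        assert len(cull_points(ps, 1.0)) == 600

    def test_order_preserved(self, small_cloud):
        points, _, _ = small_cloud
        kept = cull_points(points, 1.0)
        assert np.all(np.diff(np.searchsorted(points.ids, kept.ids)) > 0)


class TestStructure:
    def test_empty_build_queries_empty(self):
        idx = build_tree(PointSet(), BuildConfig())
        q = SummaryQuery(ViewWindow(0, 1e6, 0, 1e6), 100)
        assert idx.query(q) == []

    def test_leaves_partition_the_culled_input(self, dense_cloud):
        points, _ = dense_cloud
        cfg = BuildConfig(leaf_capacity=64)
        idx = build_tree(points, cfg)
        culled = cull_points(points, cfg.intensity_floor)

        leaf_rows = []

        def collect(node):
            if node.is_leaf:
                leaf_rows.append(node.leaf_rows)
            for child in node.children:
                collect(child)

        collect(idx.root)
        all_rows = np.concatenate(leaf_rows)
        assert all_rows.size == len(culled)
        assert np.array_equal(np.sort(all_rows), np.arange(len(culled)))

    def test_root_bounds_are_the_tight_bounding_box(self, dense_cloud):
        points, _ = dense_cloud
        idx = build_tree(points, BuildConfig())
        culled = cull_points(points, 1.0)
        b = idx.bounds
        assert b.mz_min == culled.mz.min() and b.mz_max == culled.mz.max()
        assert b.rt_min == culled.rt.min() and b.rt_max == culled.rt.max()

    def test_child_bounds_nest_inside_parents(self, dense_cloud):
        points, _ = dense_cloud
        idx = build_tree(points, BuildConfig(leaf_capacity=64))

        def check(node):
            for child in node.children:
                assert child.bounds.mz_min >= node.bounds.mz_min
                assert child.bounds.mz_max <= node.bounds.mz_max
                assert child.bounds.rt_min >= node.bounds.rt_min
                assert child.bounds.rt_max <= node.bounds.rt_max
                check(child)

        check(idx.root)

    def test_samples_reference_descendant_leaf_points(self, dense_cloud):
        points, _ = dense_cloud
        idx = build_tree(points, BuildConfig(leaf_capacity=64, sample_size=32))

        def leaf_rows_of(node):
            if node.is_leaf:
                return set(node.leaf_rows.tolist())
            out = set()
            for child in node.children:
                out |= leaf_rows_of(child)
            return out

        def check(node):
            descendants = leaf_rows_of(node)
            assert set(node.sample.tolist()) <= descendants
            assert node.sample.size <= idx.config.sample_size
            for child in node.children:
                check(child)

        check(idx.root)


class TestSampling:
    def test_underfull_children_are_all_referenced(self):
        ps = grid_points(5, 2)  # 10 points
        ids = sample_node([ps], S=256, seed=0)
        assert sorted(ids) == list(range(10))

    def test_top_s_matches_full_sort_oracle(self):
        rng = np.random.default_rng(17)
        ps = PointSet(np.arange(1000), rng.uniform(400, 1600, 1000),
                      rng.uniform(0, 600, 1000), rng.uniform(1, 1e5, 1000))
        ids = sample_node([ps], S=256, seed=0)
        oracle = sort_oracle_top_n(ps.to_points(), 256)
        assert ids == [p.id for p in oracle]

    def test_intensity_tie_breaks_on_ascending_mz_rt_id(self):
        points = [
            MsPoint(3, 502.0, 10.0, 7.0),
            MsPoint(1, 501.0, 10.0, 7.0),
            MsPoint(0, 501.0, 12.0, 7.0),
            MsPoint(2, 500.0, 99.0, 9.0),
        ]
        ids = sample_node([PointSet.from_points(points)], S=2, seed=0)
        # 9.0 wins outright; the 7.0 tie resolves to the smallest (mz, rt, id)
        assert ids == [2, 1]


class TestWhittle:
    def test_identity_when_budget_equals_supply(self):
        points = grid_points(3, 3).to_points()
        assert sorted(p.id for p in whittle(points, 9)) == list(range(9))

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(29)
        ps = PointSet(np.arange(500), rng.uniform(400, 1600, 500),
                      rng.uniform(0, 600, 500), rng.uniform(1, 1e4, 500))
        got = whittle(ps, 50)
        assert got == sort_oracle_top_n(ps.to_points(), 50)

    def test_all_equal_intensities_take_smallest_triples(self):
        ps = grid_points(4, 4, intensity=np.ones(16))
        got = whittle(ps, 5)
        oracle = sorted(ps.to_points(), key=lambda p: (p.mz, p.rt, p.id))[:5]
        assert got == oracle

    def test_overdraw_is_a_contract_violation(self):
        with pytest.raises(ValueError):
            whittle(grid_points(2, 2), 5)


class TestBruteForce:
    def test_full_window_returns_everything(self, dense_cloud):
        points, _ = dense_cloud
        w = ViewWindow(points.mz.min(), points.mz.max(),
                       points.rt.min(), points.rt.max())
        assert len(brute_force_query(points, w)) == len(points)

    def test_degenerate_window_uses_closed_bounds(self):
        p = MsPoint(0, 500.0, 10.0, 5.0)
        w = ViewWindow(500.0, 500.0, 0.0, 100.0)
        assert brute_force_query([p], w) == [p]

    def test_count_matches_per_point_filter(self, dense_cloud):
        points, _ = dense_cloud
        rng = np.random.default_rng(31)
        for w in random_windows(rng, 10):
            expected = sum(1 for p in points if w.contains(p.mz, p.rt))
            assert len(brute_force_query(points, w)) == expected


@pytest.fixture(scope="module")
def dense_index(dense_cloud):
    points, _ = dense_cloud
    return build_tree(points, BuildConfig(leaf_capacity=128, sample_size=256))


class TestQuery:
    def test_disjoint_window_is_empty(self, dense_index):
        b = dense_index.bounds
        w = ViewWindow(b.mz_max + 10, b.mz_max + 20, b.rt_min, b.rt_max)
        assert dense_index.query(SummaryQuery(w, 100)) == []

    def test_zero_budget_is_empty(self, dense_index):
        assert dense_index.query(SummaryQuery(dense_index.bounds, 0)) == []

    def test_oracle_equivalence_over_random_windows(self, dense_index):
        """50 random windows: generous budgets return exactly the
        brute-force in-window set; tight budgets return exactly n points,
        all in-window, all real, equal to the sort oracle's top-n."""
        rng = np.random.default_rng(37)
        culled = dense_index.points
        all_ids = set(culled.ids.tolist())
        for w in random_windows(rng, 50):
            supply = brute_force_query(culled, w)
            # n >= supply: exact set equality with the linear-scan oracle
            got = dense_index.query(SummaryQuery(w, len(supply) + 10))
            assert sorted(p.id for p in got) == sorted(p.id for p in supply)
            # n < supply: the whittling rule's sort oracle
            if len(supply) > 5:
                n = len(supply) // 2
                got = dense_index.query(SummaryQuery(w, n))
                assert len(got) == n
                assert all(w.contains(p.mz, p.rt) for p in got)
                assert {p.id for p in got} <= all_ids
                assert got == sort_oracle_top_n(supply, n)

    def test_exact_budget_and_leaf_shortfall(self, dense_index):
        rng = np.random.default_rng(41)
        for w in random_windows(rng, 25):
            supply = len(brute_force_query(dense_index.points, w))
            for n in (0, 1, supply // 2, supply, supply + 7):
                got = dense_index.query(SummaryQuery(w, n))
                assert len(got) == min(n, supply)

    def test_monotone_detail(self, dense_index):
        rng = np.random.default_rng(43)
        for w in random_windows(rng, 10):
            small = {p.id for p in dense_index.query(SummaryQuery(w, 50))}
            large = {p.id for p in dense_index.query(SummaryQuery(w, 200))}
            assert small <= large

    def test_determinism_across_rebuilds(self, dense_cloud):
        points, _ = dense_cloud
        cfg = BuildConfig(leaf_capacity=100, sample_size=64, seed=9)
        q = SummaryQuery(ViewWindow(450, 900, 50, 400), 333)
        first = build_tree(points, cfg).query(q)
        second = build_tree(points, cfg).query(q)
        assert first == second


class TestJumpWindow:
    def test_forced_example(self):
        w = jump_window(ViewWindow(400, 500, 10, 20), 1000.0)
        assert w == ViewWindow(950.0, 1050.0, 10.0, 20.0)

    def test_jump_to_current_center_is_identity(self):
        w = ViewWindow(400, 500, 10, 20)
        assert jump_window(w, 450.0) == w

    @given(mz0=st.floats(1, 3000), width=st.floats(0.001, 500),
           target=st.floats(0.01, 4000),
           rt0=st.floats(0, 1e4), rtw=st.floats(0, 1e3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_width_and_rt_preserved(self, mz0, width, target, rt0, rtw):
        w = ViewWindow(mz0, mz0 + width, rt0, rt0 + rtw)
        jumped = jump_window(w, target)
        assert jumped.mz_width == pytest.approx(w.mz_width, rel=1e-9, abs=1e-9)
        assert (jumped.rt_min, jumped.rt_max) == (w.rt_min, w.rt_max)
        assert (jumped.mz_min + jumped.mz_max) / 2 == pytest.approx(target, rel=1e-9)

    def test_non_positive_target_rejected(self):
        with pytest.raises(ValueError):
            jump_window(ViewWindow(400, 500, 0, 10), 0.0)


class TestPersistence:
    def test_save_load_round_trip_preserves_queries(self, dense_cloud, tmp_path):
        points, _ = dense_cloud
        idx = build_tree(points, BuildConfig(leaf_capacity=200, seed=3))
        path = tmp_path / "map.idx"
        save_index(idx, path)
        loaded = load_index(path)
        assert loaded.config == idx.config
        rng = np.random.default_rng(47)
        for w in random_windows(rng, 5):
            q = SummaryQuery(w, 123)
            assert loaded.query(q) == idx.query(q)

    def test_identical_inputs_give_byte_identical_index_files(
            self, dense_cloud, tmp_path):
        points, _ = dense_cloud
        cfg = BuildConfig(seed=5)
        a, b = tmp_path / "a.idx", tmp_path / "b.idx"
        save_index(build_tree(points, cfg), a)
        save_index(build_tree(points, cfg), b)
        assert a.read_bytes() == b.read_bytes()

    def test_garbage_file_is_rejected(self, tmp_path):
        bad = tmp_path / "bad.idx"
        bad.write_bytes(b"not an index")
        with pytest.raises(ValueError):
            load_index(bad)
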
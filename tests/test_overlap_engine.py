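import numpy as np
import pytest

from rankoverlap import hyperstat as hs
from rankoverlap.overlap_engine import (
    build_cursor,
    build_frame,
    evaluate_coordinates,
    lattice_counts,
    move_cursor,
    render_map,
)
from rankoverlap.ranked_io import QUADRANTS, RankedList

from conftest import naive_overlap, naive_two_sided, random_ranked_pair


class TestCursor:
    def test_hand_counted_example(self):
        # a_order=[g1..g5] as indexes 0..4; b_order=[g3,g5,g1,g2,g4]
        cur = build_cursor([0, 1, 2, 3, 4], [2, 4, 0, 1, 3], 5)
        assert move_cursor(cur, 3, 2) == 1  # only g3
        assert move_cursor(cur, 5, 5) == 5
        assert move_cursor(cur, 0, 3) == 0

    def test_build_errors(self):
        with pytest.raises(ValueError):
            build_cursor([0, 1], [0, 1, 2], 3)
        cur = build_cursor(list(range(130)), list(range(130)), 130)
        assert cur.words_a.size == 3  # ceil(130/64) words

    def test_out_of_range_move(self):
        cur = build_cursor([0, 1, 2], [2, 1, 0], 3)
        with pytest.raises(ValueError):
            cur.move(4, 0)

    def test_random_walks_match_naive_sets(self, rng):
        """Incremental counts equal naive set intersection over long
        random walks, including backward moves."""
        for n in (65, 257, 500):
            a_order = rng.permutation(n)
            b_order = rng.permutation(n)
            cur = build_cursor(a_order, b_order, n)
            for _ in range(300):
                i = int(rng.integers(0, n + 1))
                j = int(rng.integers(0, n + 1))
                got = cur.move(i, j)
                assert got == naive_overlap(a_order, b_order, i, j)

    def test_path_independence(self, rng):
        n = 200
        a_order = rng.permutation(n)
        b_order = rng.permutation(n)
        target = (137, 61)
        results = []
        for seed in range(5):
            g = np.random.default_rng(seed)
            cur = build_cursor(a_order, b_order, n)
            for _ in range(10):
                cur.move(int(g.integers(0, n + 1)), int(g.integers(0, n + 1)))
            results.append(cur.move(*target))
        assert len(set(results)) == 1

    def test_popcount_matches_prefix_lengths(self, rng):
        n = 150
        cur = build_cursor(rng.permutation(n), rng.permutation(n), n)
        for (i, j) in [(10, 140), (75, 75), (0, 1), (150, 0)]:
            cur.move(i, j)
            assert cur.popcounts() == (i, j)


class TestLatticeCounts:
    def test_matches_cursor_on_random_lattices(self, rng):
        a, b = random_ranked_pair(120, seed=3)
        frame = build_frame(a, b, QUADRANTS["dd"])
        ci = np.array([5, 17, 30, frame.max_i])
        cj = np.array([3, 20, frame.max_j])
        counts = lattice_counts(frame, ci, cj)
        cur = build_cursor(frame.order_a(), frame.order_b(), frame.n)
        for x, i in enumerate(ci):
            for y, j in enumerate(cj):
                assert counts[x, y] == cur.move(int(i), int(j))


class TestCoordinateEvaluator:
    def test_bulk_and_cursor_paths_agree(self, rng):
        """The vectorized dominance count used for large batches equals
        the incremental cursor count coordinate for coordinate."""
        from rankoverlap.overlap_engine import CoordinateEvaluator

        a, b = random_ranked_pair(300, seed=11)
        frame = build_frame(a, b, QUADRANTS["dd"])
        coords = np.column_stack([
            rng.integers(1, frame.max_i + 1, 200),
            rng.integers(1, frame.max_j + 1, 200),
        ])
        bulk = CoordinateEvaluator(frame).counts(coords)
        cur = build_cursor(frame.order_a(), frame.order_b(), frame.n)
        for k in range(coords.shape[0]):
            assert bulk[k] == cur.move(int(coords[k, 0]), int(coords[k, 1]))


class TestEvaluateCoordinates:
    def test_identical_lists_diagonal(self):
        labels = np.array([f"g{k}" for k in range(20)], dtype=object)
        vals = np.linspace(-1, 1, 20)
        a = RankedList(labels=labels, values=vals)
        b = RankedList(labels=labels, values=vals.copy())
        frame = build_frame(a, b, QUADRANTS["dd"])
        coords = [(i, i) for i in range(1, frame.max_i + 1)]
        from rankoverlap.overlap_engine import CoordinateEvaluator

        ev = CoordinateEvaluator(frame)
        c, _, _ = ev.signed_logp(np.array(coords))
        assert np.array_equal(c, np.arange(1, frame.max_i + 1))

    def test_brute_force_all_cells_random_pair(self):
        """Every cell of a 20-feature dd map matches naive set counting
        plus the independent tail oracle."""
        a, b = random_ranked_pair(20, seed=9)
        q = QUADRANTS["dd"]
        frame = build_frame(a, b, q)
        coords = [
            (i, j)
            for i in range(1, frame.max_i + 1)
            for j in range(1, frame.max_j + 1)
        ]
        got = evaluate_coordinates(a, b, q, coords)
        la = frame.labels[np.argsort(frame.pos_a)]
        lb = frame.labels[np.argsort(frame.pos_b)]
        for (i, j), slp in zip(coords, got):
            c = naive_overlap(la, lb, i, j)
            lp, sign = naive_two_sided(c, i, j, frame.n)
            assert slp.log_p == pytest.approx(lp, abs=1e-9)
            assert slp.sign == sign

    def test_out_of_bounds_rejected(self, small_pair):
        a, b = small_pair
        with pytest.raises(ValueError, match="bounds"):
            evaluate_coordinates(a, b, QUADRANTS["dd"], [(0, 1)])


class TestRenderMap:
    def test_lattice_includes_final_coordinate(self, small_pair):
        a, b = small_pair
        m = render_map(a, b, resolution=7)
        assert m.coords_a[-1] == a.n and m.coords_b[-1] == b.n

    def test_resolution_independent_at_shared_coords(self, small_pair):
        a, b = small_pair
        m1 = render_map(a, b, resolution=6)
        m2 = render_map(a, b, resolution=12)
        shared = np.intersect1d(m1.coords_a, m2.coords_a)
        for s in shared:
            x1 = np.where(m1.coords_a == s)[0][0]
            x2 = np.where(m2.coords_a == s)[0][0]
            for t in np.intersect1d(m1.coords_b, m2.coords_b):
                y1 = np.where(m1.coords_b == t)[0][0]
                y2 = np.where(m2.coords_b == t)[0][0]
                assert m1.cells_log_p[x1, y1] == pytest.approx(
                    m2.cells_log_p[x2, y2], abs=1e-12
                )

    def test_identical_lists_strongest_on_diagonal(self):
        labels = np.array([f"g{k:03d}" for k in range(100)], dtype=object)
        vals = np.linspace(-1, 1, 100)
        a = RankedList(labels=labels, values=vals)
        b = RankedList(labels=labels, values=vals.copy())
        m = render_map(a, b, resolution=10)
        z = m.cells_log_p
        k = np.unravel_index(z.argmin(), z.shape)
        assert k[0] == k[1]  # minimum on the main diagonal
        mid = len(m.coords_a) // 2
        assert abs(k[0] - mid) <= 1  # near the list centres

    def test_reversed_lists_negative_antidiagonal(self):
        labels = np.array([f"g{k:03d}" for k in range(100)], dtype=object)
        vals = np.linspace(-1, 1, 100) + 0.001  # avoid exact zero
        a = RankedList(labels=labels, values=vals)
        b = RankedList(labels=labels, values=-vals)
        m = render_map(a, b, resolution=10)
        z = m.cells_log_p
        k = np.unravel_index(z.argmin(), z.shape)
        assert m.cells_sign[k] == -1
        # antidiagonal: strongest cell has coords summing to ~n
        assert abs(int(m.coords_a[k[0]]) + int(m.coords_b[k[1]]) - 100) <= 20

    def test_rejects_tiny_resolution(self, small_pair):
        a, b = small_pair
        with pytest.raises(ValueError):
            render_map(a, b, resolution=1)

    def test_tsv_export_roundtrip(self, small_pair, tmp_path):
        import pandas as pd

        a, b = small_pair
        m = render_map(a, b, resolution=5)
        out = tmp_path / "map.tsv"
        m.to_tsv(out)
        df = pd.read_csv(out, sep="\t", index_col=0)
        assert df.shape == m.cells_log_p.shape
        assert np.allclose(df.to_numpy(), m.signed_neglog())
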
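"""Grid model, raster I/O, focal means, screening, Moran's I, distances."""

import numpy as np
import pytest

import landconnect as lc
from landconnect.grid import circular_footprint


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

class TestRasterIO:
    def test_round_trip_preserves_values_geometry_and_nodata(self, tmp_path):
        vals = np.array([[1.5, np.nan, 3.0], [0.25, -2.0, 1e-7], [7.0, 8.0, 9.0]])
        g = lc.Grid(vals, cell_size=100.0, origin=(500.0, 900.0))
        path = tmp_path / "g.asc"
        lc.write_raster(g, path)
        back = lc.read_raster(path)
        assert back.shape == g.shape
        assert back.cell_size == g.cell_size
        assert back.origin == g.origin
        np.testing.assert_array_equal(back.mask, g.mask)
        np.testing.assert_array_equal(back.values[g.mask], g.values[g.mask])

    def test_non_square_cells_rejected(self, tmp_path):
        path = tmp_path / "bad.asc"
        path.write_text(
            "ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\ndx 50\ndy 100\n"
            "NODATA_value -9999\n1 2\n3 4\n"
        )
        with pytest.raises(ValueError, match="non-square"):
            lc.read_raster(path)

    def test_geometry_mismatch_names_both_geometries(self):
        a = lc.Grid(np.zeros((4, 4)), 100.0)
        b = lc.Grid(np.zeros((4, 5)), 100.0)
        with pytest.raises(ValueError, match=r"\(4, 4\).*\(4, 5\)"):
            a.assert_same_geometry(b)

    def test_stack_requires_shared_geometry(self):
        a = lc.Grid(np.zeros((4, 4)), 100.0)
        b = lc.Grid(np.zeros((4, 4)), 200.0)
        with pytest.raises(ValueError, match="geometry mismatch"):
            lc.Stack({"a": a, "b": b})


# ---------------------------------------------------------------------------
# focal means
# ---------------------------------------------------------------------------

class TestFocalMean:
    def test_constant_grid_stays_constant_any_radius(self):
        g = lc.Grid(np.full((12, 12), 3.25), 100.0)
        for r in (100.0, 250.0, 500.0):
            out = lc.focal_mean_circular(g, r)
            np.testing.assert_allclose(out.values, 3.25)

    def test_radius_one_cell_gives_von_neumann_window(self):
        # cells whose centres lie within 100 m on a 100 m grid: centre + 4
        fp = circular_footprint(100.0, 100.0)
        assert fp.sum() == 5
        assert fp[1, 1] and fp[0, 1] and fp[2, 1] and fp[1, 0] and fp[1, 2]

    def test_single_pixel_spreads_as_fifth(self):
        v = 10.0
        arr = np.zeros((9, 9))
        arr[4, 4] = v
        out = lc.focal_mean_circular(lc.Grid(arr, 100.0), 100.0)
        assert out.values[4, 4] == pytest.approx(v / 5)
        assert out.values[4, 5] == pytest.approx(v / 5)
        assert out.values[3, 4] == pytest.approx(v / 5)
        assert out.values[2, 4] == 0.0

    def test_window_cardinality_monotone_in_radius(self):
        sizes = [circular_footprint(r, 100.0).sum() for r in np.linspace(50, 2000, 25)]
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))

    def test_tiny_radius_returns_identity_with_warning(self):
        g = lc.Grid(np.arange(16.0).reshape(4, 4), 100.0)
        with pytest.warns(UserWarning, match="below half a cell"):
            out = lc.focal_mean_circular(g, 10.0)
        np.testing.assert_array_equal(out.values, g.values)

    def test_edge_windows_shrink_not_pad(self):
        # mean of available cells only: corner of a constant field unchanged
        g = lc.Grid(np.full((6, 6), 2.0), 100.0)
        out = lc.focal_mean_circular(g, 200.0)
        assert out.values[0, 0] == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# Pearson screening
# ---------------------------------------------------------------------------

def _stack_from_columns(cols: dict) -> lc.Stack:
    n = len(next(iter(cols.values())))
    side = int(np.sqrt(n))
    return lc.Stack(
        {k: lc.Grid(np.asarray(v, float).reshape(side, side), 100.0) for k, v in cols.items()}
    )


class TestPearsonScreen:
    def test_duplicate_variable_drops_exactly_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=64)
        retained, corr = lc.pearson_screen(
            _stack_from_columns({"a": x, "b": x.copy(), "c": rng.normal(size=64)})
        )
        assert len(retained) == 2 and "c" in retained
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_orthogonal_variables_all_retained(self):
        rng = np.random.default_rng(1)
        cols = {f"v{i}": rng.normal(size=100) for i in range(4)}
        retained, _ = lc.pearson_screen(_stack_from_columns(cols))
        assert retained == list(cols)

    def test_greedy_pass_matches_hand_evaluation(self):
        # one pair above the cut; the member with larger mean |r| to the
        # others goes, per a hand-run single greedy pass on the same matrix
        rng = np.random.default_rng(2)
        z = rng.normal(size=400)
        e = rng.normal(size=400)
        x1 = z
        x2 = 0.95 * z + np.sqrt(1 - 0.95 ** 2) * e  # r(1,2) ~ 0.95
        x3 = 0.5 * x2 + np.sqrt(1 - 0.25) * rng.normal(size=400)  # ties x2 to x3
        stack = _stack_from_columns({"x1": x1, "x2": x2, "x3": x3})
        arr = np.corrcoef(np.stack([x1, x2, x3]))
        assert abs(arr[0, 1]) > 0.8 and abs(arr[0, 2]) < 0.8 and abs(arr[1, 2]) < 0.8
        # hand rule: drop whichever of {x1, x2} has larger mean |r| to others
        mean1 = (abs(arr[0, 1]) + abs(arr[0, 2])) / 2
        mean2 = (abs(arr[0, 1]) + abs(arr[1, 2])) / 2
        expected_drop = "x1" if mean1 > mean2 else "x2"
        retained, _ = lc.pearson_screen(stack)
        assert expected_drop not in retained
        assert len(retained) == 2

    def test_zero_variance_flagged_and_retained(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="zero variance"):
            retained, _ = lc.pearson_screen(
                _stack_from_columns({"flat": np.ones(64), "x": rng.normal(size=64)})
            )
        assert "flat" in retained


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

def brute_force_moran(values, weights):
    """Independent double-loop evaluation of the Moran's I formula."""
    x = np.asarray(values, float)
    n = len(x)
    z = x - x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                num += weights[i, j] * z[i] * z[j]
                s0 += weights[i, j]
    return (n / s0) * num / (z ** 2).sum()


class TestMoransI:
    def test_checkerboard_rook_weights_gives_minus_one(self):
        # 2x2 lattice, rook adjacency weight 1, alternating values
        w = np.array(
            [[0, 1, 1, 0], [1, 0, 0, 1], [1, 0, 0, 1], [0, 1, 1, 0]], float
        )
        res = lc.morans_i_from_weights([1.0, 0.0, 0.0, 1.0], w)
        assert res.I == pytest.approx(-1.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(7)
        n = 25
        x = rng.poisson(3, size=n).astype(float)
        pts = rng.uniform(0, 1000, size=(n, 2))
        d = np.hypot(pts[:, 0, None] - pts[None, :, 0], pts[:, 1, None] - pts[None, :, 1])
        with np.errstate(divide="ignore"):
            w = 1.0 / d
        np.fill_diagonal(w, 0.0)
        res = lc.morans_i_from_weights(x, w)
        assert res.I == pytest.approx(brute_force_moran(x, w), rel=1e-9)

    def test_constant_counts_degenerate_status_no_crash(self):
        w = np.ones((4, 4)) - np.eye(4)
        res = lc.morans_i_from_weights([2.0, 2.0, 2.0, 2.0], w)
        assert res.status == "degenerate"
        assert np.isnan(res.I)

    def test_random_patterns_calibrated_under_null(self):
        # ~95% of random point patterns should give |z| < 1.96
        ok = 0
        geometry = lc.Grid(np.zeros((50, 50)), 100.0, origin=(0.0, 5000.0))
        for seed in range(100):
            rng = np.random.default_rng(seed)
            xy = np.column_stack(
                [rng.uniform(0, 5000, 150), rng.uniform(0, 5000, 150)]
            )
            res = lc.morans_i(lc.OccurrenceSet(xy), geometry, aggregation_cell=1000.0)
            if res.status == "ok" and abs(res.z_score) < 1.96:
                ok += 1
        assert ok >= 90

    def test_requires_two_occupied_cells(self):
        geometry = lc.Grid(np.zeros((10, 10)), 100.0, origin=(0.0, 1000.0))
        pts = lc.OccurrenceSet(np.array([[50.0, 950.0], [55.0, 945.0]]))
        with pytest.raises(ValueError, match="occupied aggregation cells"):
            lc.morans_i(pts, geometry, aggregation_cell=1000.0)


# ---------------------------------------------------------------------------
# Euclidean distance
# ---------------------------------------------------------------------------

class TestEuclideanDistance:
    def test_feature_orthogonal_and_diagonal_distances(self):
        arr = np.zeros((5, 5))
        arr[2, 2] = 1
        d = lc.euclidean_distance(lc.Grid(arr, 100.0))
        assert d.values[2, 2] == 0.0
        assert d.values[2, 3] == pytest.approx(100.0)
        assert d.values[3, 3] == pytest.approx(141.42, abs=0.01)

    def test_matches_brute_force_nearest_feature(self):
        rng = np.random.default_rng(11)
        arr = (rng.random((20, 20)) < 0.05).astype(float)
        arr[0, 0] = 1  # ensure a feature
        g = lc.Grid(arr, 100.0)
        d = lc.euclidean_distance(g)
        feats = np.argwhere(arr == 1)
        for r in range(20):
            for c in range(20):
                brute = np.min(np.hypot(feats[:, 0] - r, feats[:, 1] - c)) * 100.0
                assert d.values[r, c] == pytest.approx(brute, rel=1e-9)

    def test_no_features_is_an_error(self):
        with pytest.raises(ValueError, match="no feature cells"):
            lc.euclidean_distance(lc.Grid(np.zeros((4, 4)), 100.0))
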
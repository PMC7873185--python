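"""Landscape metric unit and property tests against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import LineString

from traitscape.landscape import (
    CLASS_NAMES,
    GRASSLAND,
    CROP,
    WOODLAND,
    HedgerowNetwork,
    LandUseMap,
    compute_landscape_variables,
    grassland_amount,
    grassland_isolation,
    hedgerow_amount,
    hedgerow_isolation,
    mean_patch_area,
    patch_count,
    predictor_correlations,
    shannon_diversity,
)


def make_map(grid, cell=10.0):
    return LandUseMap(np.asarray(grid, dtype=int), cell)


# ---------------------------------------------------------------------------
# independent oracles


def floodfill_patch_count(grid, connectivity):
    """Brute-force component labelling by BFS, independent of scikit-image."""
    grid = np.asarray(grid)
    seen = np.zeros(grid.shape, dtype=bool)
    if connectivity == 1:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if dr or dc]
    count = 0
    for r0 in range(grid.shape[0]):
        for c0 in range(grid.shape[1]):
            if seen[r0, c0]:
                continue
            count += 1
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < grid.shape[0]
                        and 0 <= cc < grid.shape[1]
                        and not seen[rr, cc]
                        and grid[rr, cc] == grid[r, c]
                    ):
                        seen[rr, cc] = True
                        stack.append((rr, cc))
    return count


def unionfind_network_count(segments, snap_tol):
    """Union-find over pairwise shapely distance tests."""
    lines = [LineString(s) for s in segments]
    parent = list(range(len(lines)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            touch = (
                lines[i].distance(lines[j]) <= snap_tol
                if snap_tol > 0
                else lines[i].intersects(lines[j])
            )
            if touch:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(len(lines))})


# ---------------------------------------------------------------------------
# Shannon diversity


class TestShannon:
    def test_single_class_is_zero(self):
        assert shannon_diversity(make_map(np.full((20, 20), CROP))) == 0.0

    def test_two_equal_classes(self):
        grid = np.zeros((10, 10), dtype=int)
        grid[:5] = CROP
        assert shannon_diversity(make_map(grid)) == pytest.approx(math.log(2))

    def test_matches_direct_summation(self):
        # proportions 0.5 / 0.3 / 0.2 on a 10x10 grid
        grid = np.full((10, 10), GRASSLAND)
        grid.ravel()[:30] = CROP
        grid.ravel()[30:50] = WOODLAND
        expected = -(0.5 * math.log(0.5) + 0.3 * math.log(0.3) + 0.2 * math.log(0.2))
        assert shannon_diversity(make_map(grid)) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_bounded_by_log_classes_present(self, seed):
        g = np.random.default_rng(seed).integers(0, 7, size=(12, 12))
        h = shannon_diversity(make_map(g))
        n_present = len(np.unique(g))
        assert 0.0 <= h <= math.log(n_present) + 1e-12


# ---------------------------------------------------------------------------
# mean patch area / configurational heterogeneity


class TestMeanPatchArea:
    def test_uniform_map_single_patch(self):
        m = make_map(np.full((10, 10), WOODLAND))
        mpa, het = mean_patch_area(m)
        assert mpa == m.window_area
        assert het == pytest.approx(-math.log(m.window_area))

    def test_checkerboard_4conn_equals_cell_area(self):
        grid = np.indices((8, 8)).sum(axis=0) % 2
        m = make_map(grid)
        mpa, _ = mean_patch_area(m, connectivity=1)
        assert mpa == pytest.approx(m.cell_size**2)

    def test_splitting_a_patch_decreases_mpa(self):
        grid = np.full((9, 9), GRASSLAND)
        grid[:, 4] = CROP  # one grassland block -> two, plus a crop stripe
        whole = np.full((9, 9), GRASSLAND)
        whole[0, 4] = CROP
        assert mean_patch_area(make_map(grid))[0] < mean_patch_area(make_map(whole))[0]

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_floodfill_oracle_and_area_identity(self, seed):
        g = np.random.default_rng(seed).integers(0, 4, size=(10, 10))
        m = make_map(g)
        n = patch_count(m, connectivity=2)
        assert n == floodfill_patch_count(g, connectivity=2)
        mpa, _ = mean_patch_area(m)
        assert mpa * n == pytest.approx(m.window_area, rel=1e-12)


# ---------------------------------------------------------------------------
# grassland amount and isolation


class TestGrassland:
    def test_amount_extremes_and_count(self):
        assert grassland_amount(make_map(np.full((5, 5), GRASSLAND))) == 100.0
        assert grassland_amount(make_map(np.full((5, 5), CROP))) == 0.0
        grid = np.full((40, 25), CROP)
        grid.ravel()[:250] = GRASSLAND  # 250 of 1000 cells
        assert grassland_amount(make_map(grid)) == 25.0
        m = make_map(grid)
        assert grassland_amount(m) + 100.0 * np.mean(m.grid != GRASSLAND) == 100.0

    def test_three_cell_gap_is_30m(self):
        grid = np.full((3, 9), CROP)
        grid[:, 0] = GRASSLAND
        grid[:, 4:] = GRASSLAND  # columns 1-3 empty: 3-cell gap on a 10 m grid
        assert grassland_isolation(make_map(grid)) == pytest.approx(30.0)

    def test_diagonal_gap_distance(self):
        # two single-cell patches separated diagonally by one cell
        grid = np.full((5, 5), CROP)
        grid[0, 0] = GRASSLAND
        grid[2, 2] = GRASSLAND
        d = grassland_isolation(make_map(grid), connectivity=1)
        assert d == pytest.approx(math.sqrt(2) * 10.0)

    def test_corner_contact_4conn_distance_zero(self):
        grid = np.full((4, 4), CROP)
        grid[0, 0] = GRASSLAND
        grid[1, 1] = GRASSLAND  # distinct patches under 4-connectivity
        assert grassland_isolation(make_map(grid), connectivity=1) == 0.0

    def test_single_patch_missing(self):
        grid = np.full((5, 5), CROP)
        grid[2, 2] = GRASSLAND
        assert math.isnan(grassland_isolation(make_map(grid)))

    def test_exhaustive_cell_pair_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            grid = np.where(rng.random((8, 8)) < 0.2, GRASSLAND, CROP)
            m = make_map(grid)
            got = grassland_isolation(m, connectivity=1)
            # oracle: per-patch min over all boundary-to-boundary box distances
            from traitscape.landscape import _patch_boundary_geometries

            geoms = _patch_boundary_geometries(grid == GRASSLAND, 10.0, 1)
            if len(geoms) < 2:
                assert math.isnan(got)
                continue
            nearest = []
            for i, gi in enumerate(geoms):
                nearest.append(
                    min(gi.distance(gj) for j, gj in enumerate(geoms) if j != i)
                )
            assert got == pytest.approx(float(np.mean(nearest)))


# ---------------------------------------------------------------------------
# hedgerows


class TestHedgerows:
    def test_amount(self):
        assert hedgerow_amount(HedgerowNetwork(np.empty((0, 2, 2)))) == 0.0
        one = HedgerowNetwork([[[0, 0], [100, 0]]])
        assert hedgerow_amount(one) == pytest.approx(100.0)

    def test_amount_matches_per_segment_sum(self, rng):
        segs = rng.uniform(0, 1000, size=(40, 2, 2))
        net = HedgerowNetwork(segs)
        expected = sum(
            math.hypot(x2 - x1, y2 - y1) for (x1, y1), (x2, y2) in segs
        )
        assert hedgerow_amount(net) == pytest.approx(expected)

    def test_isolation_cases(self):
        assert hedgerow_isolation(HedgerowNetwork(np.empty((0, 2, 2)))) == 0
        crossing = HedgerowNetwork([[[0, 0], [10, 10]], [[0, 10], [10, 0]]])
        assert hedgerow_isolation(crossing) == 1
        t_junction_plus_far = HedgerowNetwork(
            [
                [[0, 0], [100, 0]],
                [[50, 0], [50, 80]],  # T onto the first
                [[500, 500], [600, 500]],
            ]
        )
        assert hedgerow_isolation(t_junction_plus_far) == 2

    def test_component_count_matches_unionfind_oracle(self, rng):
        for trial in range(10):
            n = int(rng.integers(2, 25))
            pts = rng.uniform(0, 500, size=(n, 2, 2))
            net = HedgerowNetwork(pts)
            for tol in (0.0, 25.0):
                assert hedgerow_isolation(net, snap_tol=tol) == unionfind_network_count(
                    pts, tol
                )

    def test_touching_segment_never_increases_count(self, rng):
        base = rng.uniform(0, 500, size=(12, 2, 2))
        before = hedgerow_isolation(HedgerowNetwork(base), snap_tol=1.0)
        # new segment starting on an existing endpoint
        extra = np.concatenate(
            [base, [[base[0, 1], base[0, 1] + np.array([37.0, 11.0])]]]
        )
        after = hedgerow_isolation(HedgerowNetwork(extra), snap_tol=1.0)
        assert after <= before
        assert before <= len(base)


# ---------------------------------------------------------------------------
# predictor table and correlation screen


class TestPredictors:
    def test_correlation_screen(self, default_study):
        corr, flags = predictor_correlations(
            default_study.landscape_vars, year="current"
        )
        assert np.allclose(np.diag(corr.to_numpy()), 1.0, equal_nan=True)
        for a, b, rho in flags:
            assert abs(rho) > 0.87

    def test_anticorrelated_pair_flagged(self):
        import pandas as pd

        x = np.arange(8.0)
        df = pd.DataFrame(
            {
                "year": "current",
                "window": [f"w{i}" for i in range(8)],
                "a": x,
                "b": -x,
                "c": np.random.default_rng(0).normal(size=8),
            }
        )
        corr, flags = predictor_correlations(df, columns=("a", "b", "c"))
        assert corr.loc["a", "b"] == pytest.approx(-1.0)
        assert ("a", "b", corr.loc["a", "b"]) in [
            (f[0], f[1], pytest.approx(f[2])) for f in flags
        ] or any(f[:2] == ("a", "b") for f in flags)

    def test_matches_manual_rank_oracle(self):
        import pandas as pd

        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "year": "current",
                "window": [f"w{i}" for i in range(5)],
                "a": rng.normal(size=5),
                "b": rng.normal(size=5),
            }
        )
        corr, _ = predictor_correlations(df, columns=("a", "b"))

        def ranks(v):
            order = np.argsort(v)
            r = np.empty(len(v))
            r[order] = np.arange(1, len(v) + 1)
            return r

        ra, rb = ranks(df["a"].to_numpy()), ranks(df["b"].to_numpy())
        manual = np.corrcoef(ra, rb)[0, 1]
        assert corr.loc["a", "b"] == pytest.approx(manual, abs=1e-12)

    def test_constant_predictor_reported_missing(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "year": "current",
                "window": list("abcde"),
                "a": [1.0, 2, 3, 4, 5],
                "b": [2.0, 2, 2, 2, 2],
            }
        )
        corr, flags = predictor_correlations(df, columns=("a", "b"))
        assert math.isnan(corr.loc["a", "b"])
        assert not flags

    def test_variable_table_invariants(self, default_study):
        lv = default_study.landscape_vars
        assert set(lv["year"]) == set(default_study.config.years)
        assert lv["grassland_amount"].between(0, 100).all()
        assert (lv["compositional_heterogeneity"] >= 0).all()
        iso = lv["hedgerow_isolation"].dropna()
        assert (iso >= 1).all() and (iso == iso.astype(int)).all()
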
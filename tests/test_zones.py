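"""Grid enumeration, direction-aware selection, overlap and tetrahedron export."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from coda24.composition import PARTS, close, geometric_mean_composition
from coda24.regression import CovariateSpec, fit_compositional_model
from coda24.zones import (
    MAASTRICHT_FOOTPRINT,
    GridFootprint,
    compute_footprint,
    enumerate_grid,
    export_tetrahedron_coords,
    overlap_zone,
    rank_and_select,
    zone_summary,
)

from conftest import random_composition
from test_regression import SIMPLE_SPEC, make_linear_data


def brute_force_count(fp: GridFootprint) -> int:
    """Independent nested-loop enumeration oracle."""
    step = int(fp.step)
    count = 0
    for a in range(int(fp.lower[0]), int(fp.upper[0]) + 1, step):
        for b in range(int(fp.lower[1]), int(fp.upper[1]) + 1, step):
            for c in range(int(fp.lower[2]), int(fp.upper[2]) + 1, step):
                for d in range(int(fp.lower[3]), int(fp.upper[3]) + 1, step):
                    e = 1440 - a - b - c - d
                    if int(fp.lower[4]) <= e <= int(fp.upper[4]):
                        count += 1
    return count


class TestEnumerateGrid:
    def test_single_point_footprint(self):
        fp = GridFootprint(lower=(500, 300, 100, 60, 480), upper=(500, 300, 100, 60, 480))
        grid = enumerate_grid(fp)
        assert grid.shape == (1, 5)
        np.testing.assert_allclose(grid[0], [500, 300, 100, 60, 480])

    def test_small_footprint_against_nested_loop_oracle(self):
        fp = GridFootprint(
            lower=(100, 100, 100, 100, 980), upper=(120, 120, 120, 120, 1040)
        )
        grid = enumerate_grid(fp)
        assert grid.shape[0] == brute_force_count(fp)
        assert np.all(grid.sum(axis=1) == 1440)

    def test_random_footprints_match_oracle(self, rng):
        for _ in range(50):
            lo = rng.integers(1, 20, 5) * 10
            width = rng.integers(0, 8, 5) * 10
            hi = lo + width
            # force feasibility by widening the last part around the residual
            resid = 1440 - int(lo[:4].sum())
            lo[4] = max(10, min(resid - 40, 1200))
            hi[4] = lo[4] + 120
            if lo.sum() > 1440 or hi.sum() < 1440:
                continue
            fp = GridFootprint(lower=tuple(map(float, lo)), upper=tuple(map(float, hi)))
            grid = enumerate_grid(fp)
            assert grid.shape[0] == brute_force_count(fp)
            if grid.shape[0]:
                assert np.all(grid.sum(axis=1) == 1440)
                for k in range(5):
                    assert grid[:, k].min() >= fp.lower[k]
                    assert grid[:, k].max() <= fp.upper[k]

    def test_lexicographic_order(self):
        fp = GridFootprint(lower=(100, 100, 100, 100, 980), upper=(120, 120, 120, 120, 1040))
        grid = enumerate_grid(fp)
        keys = [tuple(row[:4]) for row in grid]
        assert keys == sorted(keys)

    def test_infeasible_footprint_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            GridFootprint(lower=(600, 400, 200, 200, 200), upper=(700, 500, 300, 300, 300))

    def test_off_lattice_bounds_rejected(self):
        with pytest.raises(ValueError):
            GridFootprint(lower=(105, 100, 100, 100, 900), upper=(200, 200, 200, 200, 1100))


class TestFootprint:
    def test_identical_sample_degenerate_bounds(self):
        comp = close([560, 250, 60, 50, 520])
        sample = np.tile(comp, (150, 1))
        fp = compute_footprint(sample)
        np.testing.assert_allclose(fp.lower, fp.upper)
        np.testing.assert_allclose(fp.lower, np.round(comp / 10) * 10)

    def test_brackets_generating_centre(self, cohort):
        table, truth = cohort
        fp = compute_footprint(table)
        centre = geometric_mean_composition(table)
        for k in range(5):
            assert fp.lower[k] <= centre[k] <= fp.upper[k]

    def test_nearest_step_rounding(self):
        rng = np.random.default_rng(3)
        sample = random_composition(rng, n=500)
        fp = compute_footprint(sample, step=10)
        for v in (*fp.lower, *fp.upper):
            assert v % 10 == 0

    def test_small_sample_warns(self, rng):
        sample = random_composition(rng, n=20)
        with pytest.warns(UserWarning, match="unstable"):
            compute_footprint(sample)


@pytest.fixture(scope="module")
def grid_and_fits():
    rng = np.random.default_rng(99)
    df = make_linear_data(rng, n=600, beta=(0.5, -0.2, 0.1, -0.3), noise_sd=0.5)
    fit = fit_compositional_model(df, "y", SIMPLE_SPEC)
    fp = GridFootprint(lower=(340, 100, 30, 10, 380), upper=(800, 470, 140, 140, 640))
    grid = enumerate_grid(fp)
    return df, fit, fp, grid


class TestRankAndSelect:
    def test_fraction_one_returns_everything(self, grid_and_fits):
        _, fit, _, grid = grid_and_fits
        sel = rank_and_select(fit, grid, fraction=1.0)
        assert sel.shape[0] == grid.shape[0]

    def test_k_is_ceiling(self, grid_and_fits):
        _, fit, _, grid = grid_and_fits
        sel = rank_and_select(fit, grid, fraction=0.05)
        assert sel.shape[0] == math.ceil(0.05 * grid.shape[0])

    def test_mvpa_rewarding_model_selects_max_mvpa_corner(self, rng):
        """A model whose only signal favours MVPA keeps the max-MVPA point."""
        comps = random_composition(rng, n=400)
        df = pd.DataFrame(comps, columns=list(PARTS))
        df["age"] = rng.normal(60, 8, 400)
        df["sex"] = rng.choice(["F", "M"], 400)
        # outcome decreases as mvpa-vs-sleep balance increases
        from coda24.composition import ilr_transform
        df["y"] = -ilr_transform(comps)[:, 3]
        fit = fit_compositional_model(df, "y", SIMPLE_SPEC)
        fp = GridFootprint(lower=(340, 100, 30, 10, 380), upper=(800, 470, 140, 140, 640))
        grid = enumerate_grid(fp)
        sel = rank_and_select(fit, grid, fraction=0.05, direction="lower")
        assert sel[:, 3].max() == grid[:, 3].max()

    def test_direction_flip(self, grid_and_fits):
        _, fit, _, grid = grid_and_fits
        lo = rank_and_select(fit, grid, fraction=0.02, direction="lower")
        hi = rank_and_select(fit, grid, fraction=0.02, direction="higher")
        from coda24.composition import ilr_transform
        score = lambda g: (ilr_transform(g) @ fit.ilr_params).mean()
        assert score(lo) < score(hi)

    def test_invalid_fraction(self, grid_and_fits):
        _, fit, _, grid = grid_and_fits
        with pytest.raises(ValueError):
            rank_and_select(fit, grid, fraction=0.0)
        with pytest.raises(ValueError):
            rank_and_select(fit, grid, fraction=1.5)

    def test_selection_invariant_to_lead_part(self, grid_and_fits):
        from coda24.composition import CANONICAL_BASIS, reorder_basis
        df, _, _, grid = grid_and_fits
        sels = []
        for lead in ("sitting", "mvpa"):
            fit = fit_compositional_model(df, "y", SIMPLE_SPEC,
                                          reorder_basis(CANONICAL_BASIS, lead))
            sels.append(rank_and_select(fit, grid, fraction=0.03))
        np.testing.assert_allclose(sels[0], sels[1], atol=1e-9)

    def test_centre_moves_to_corner_as_fraction_shrinks(self, grid_and_fits):
        """Monotone-optimum recovery: smaller fractions concentrate at the corner."""
        _, fit, _, grid = grid_and_fits
        sitting_centres = []
        for frac in (0.5, 0.2, 0.05, 0.01):
            sel = rank_and_select(fit, grid, frac, direction="lower")
            sitting_centres.append(zone_summary(sel).centre[0])
        # beta1 > 0 and direction 'lower': less sitting is better
        assert all(np.diff(sitting_centres) < 0)


class TestZoneSummary:
    def test_single_composition(self):
        sel = np.array([[520.0, 260.0, 70.0, 50.0, 540.0]])
        rep = zone_summary(sel)
        np.testing.assert_allclose(rep.centre_rounded, sel[0])
        assert rep.ranges[0] == (520.0, 520.0)

    def test_two_compositions_hand_calculation(self):
        a = np.array([700.0, 300.0, 100.0, 60.0, 280.0])
        b = np.array([500.0, 400.0, 80.0, 100.0, 360.0])
        rep = zone_summary(np.vstack([a, b]))
        expected = close(np.sqrt(a * b))
        np.testing.assert_allclose(rep.centre, expected, atol=1e-9)
        np.testing.assert_allclose(rep.centre_rounded, np.round(expected / 10) * 10)
        assert rep.ranges[0] == (500.0, 700.0)

    def test_full_grid_ranges_equal_footprint(self, grid_and_fits):
        _, _, fp, grid = grid_and_fits
        rep = zone_summary(grid)
        for k in range(5):
            assert rep.ranges[k] == (fp.lower[k], fp.upper[k])

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            zone_summary(np.empty((0, 5)))


class TestOverlap:
    def test_identical_fits_overlap_at_start_fraction(self, grid_and_fits):
        _, fit, _, grid = grid_and_fits
        zones = overlap_zone({"a": fit, "b": fit}, grid,
                             {"a": "lower", "b": "lower"})
        assert zones.overlap_fraction == 0.05
        np.testing.assert_allclose(
            np.sort(zones.overlap_set, axis=0),
            np.sort(zones.selected["a"], axis=0),
        )

    def test_overlap_subset_of_each_selection(self, grid_and_fits, rng):
        df, fit, _, grid = grid_and_fits
        df2 = df.copy()
        df2["y"] = df2["y"] + rng.normal(0, 0.3, len(df2))
        fit2 = fit_compositional_model(df2, "y", SIMPLE_SPEC)
        zones = overlap_zone({"a": fit, "b": fit2}, grid, {"a": "lower", "b": "lower"})
        assert zones.overlap_fraction is not None
        from coda24.zones import _rows_as_keys
        okeys = set(_rows_as_keys(zones.overlap_set))
        for o, sel in zones.selected_at_overlap.items():
            assert okeys <= set(_rows_as_keys(sel))

    def test_opposing_gradients_escalate_or_report_empty(self, grid_and_fits, rng):
        df, fit, _, grid = grid_and_fits
        df_flip = df.copy()
        df_flip["y"] = -df_flip["y"]
        fit_flip = fit_compositional_model(df_flip, "y", SIMPLE_SPEC)
        zones = overlap_zone({"a": fit, "b": fit_flip}, grid,
                             {"a": "lower", "b": "lower"})
        if zones.overlap_fraction is None:
            assert zones.overlap is None
            assert zones.pairwise_diagnostics is not None
            assert {"outcome_a", "outcome_b"} <= set(zones.pairwise_diagnostics.columns)
        else:
            assert zones.overlap_fraction > 0.05

    def test_minimal_fraction_recorded(self, grid_and_fits, rng):
        """The recorded fraction is the first non-empty one in the schedule."""
        df, fit, _, grid = grid_and_fits
        df_flip = df.copy()
        df_flip["y"] = -df_flip["y"]
        fit_flip = fit_compositional_model(df_flip, "y", SIMPLE_SPEC)
        zones = overlap_zone({"a": fit, "b": fit_flip}, grid,
                             {"a": "lower", "b": "higher"},
                             start_fraction=0.01, max_fraction=0.10)
        # direction-flipped duplicate ranks identically: non-empty immediately
        assert zones.overlap_fraction == 0.01

    def test_needs_two_outcomes(self, grid_and_fits):
        _, fit, _, grid = grid_and_fits
        with pytest.raises(ValueError):
            overlap_zone({"a": fit}, grid, {"a": "lower"})


class TestTetrahedron:
    def test_corner_and_centroid(self):
        sleep = 480.0
        corner = np.array([[960.0, 1e-9, 1e-9, 1e-9, sleep]])
        centroid = np.array([[240.0, 240.0, 240.0, 240.0, sleep]])
        out = export_tetrahedron_coords({"s": np.vstack([corner, centroid])})
        xyz = out[["x", "y", "z"]].to_numpy()
        v0 = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        np.testing.assert_allclose(xyz[np.argmax(out["sitting"])], v0, atol=1e-6)
        np.testing.assert_allclose(xyz[np.argmin(out["sitting"])], 0.0, atol=1e-12)

    def test_points_inside_tetrahedron(self, grid_and_fits):
        _, fit, _, grid = grid_and_fits
        sel = rank_and_select(fit, grid, fraction=0.05)
        out = export_tetrahedron_coords({"sel": sel})
        w = out[list(PARTS)[:4]].to_numpy()
        w = w / w.sum(axis=1, keepdims=True)
        assert np.all(w >= 0) and np.all(w <= 1)
        assert np.all(out["in_sel"])
        assert np.allclose(out["sleeping"], 480.0)

    def test_nearest_sleep_level_warning(self):
        pts = np.array([[500.0, 300.0, 100.0, 100.0, 440.0]])
        with pytest.warns(UserWarning, match="nearest"):
            out = export_tetrahedron_coords({"s": pts}, sleep_fixed=480.0)
        assert len(out) == 1


def test_reference_footprint_enumerates_printed_count():
    grid = enumerate_grid(MAASTRICHT_FOOTPRINT)
    assert grid.shape[0] == 142938
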
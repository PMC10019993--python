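"""Grid construction, coverage metrics and trial summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roachloop import arena_metrics as am
from roachloop.report import load_fixture_tables


def lattice_count_bruteforce(resolution: int) -> int:
    """Independent integer-arithmetic enumeration of interior lattice points."""
    count = 0
    for j in range(-resolution, resolution + 1):
        for k in range(-resolution, resolution + 1):
            if j * j + k * k < resolution * resolution:
                count += 1
    return count


class TestGrid:
    @pytest.mark.parametrize("resolution,expected", [(1, 1), (2, 9), (100, 31397)])
    def test_interior_count(self, resolution, expected):
        assert am.generate_grid(resolution).grid_area == expected

    @pytest.mark.parametrize("resolution", [1, 3, 7, 10, 17, 33])
    def test_matches_bruteforce_enumeration(self, resolution):
        g = am.generate_grid(resolution)
        assert g.grid_area == lattice_count_bruteforce(resolution)

    def test_rejects_bad_resolution(self):
        with pytest.raises(ValueError):
            am.generate_grid(0)


class TestMinDistanceField:
    def test_single_point_route(self, grid100):
        field = am.min_distance_field(np.array([[0.0, 0.0]]), grid100)
        pts = grid100.interior_points
        idx = np.flatnonzero((pts[:, 0] == 0.05) & (pts[:, 1] == 0.0))[0]
        assert field[idx] == pytest.approx(0.05, abs=1e-15)

    def test_zero_on_route_points(self, grid100):
        traj = np.array([[0.25, 0.25], [-0.5, 0.1]])
        field = am.min_distance_field(traj, grid100)
        pts = grid100.interior_points
        for x, y in traj:
            idx = np.flatnonzero((pts[:, 0] == x) & (pts[:, 1] == y))[0]
            assert field[idx] == 0.0

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(3)
        traj = rng.uniform(-0.7, 0.7, (100, 2))
        grid = am.generate_grid(20)
        field = am.min_distance_field(traj, grid)
        pts = grid.interior_points
        brute = np.array([min(np.hypot(px - x, py - y) for x, y in traj)
                          for px, py in pts])
        np.testing.assert_allclose(field, brute, rtol=0, atol=1e-12)

    def test_empty_trajectory_rejected(self, grid100):
        with pytest.raises(ValueError):
            am.min_distance_field(np.empty((0, 2)), grid100)


class TestSearchRate:
    def test_stationary_center_strict_count(self, grid100):
        """A stationary route reaches exactly the lattice points with
        j²+k² strictly below (0.1·resolution)² — 305 of them."""
        oracle = sum(1 for j in range(-10, 11) for k in range(-10, 11)
                     if j * j + k * k < 100)
        field = am.min_distance_field(np.array([[0.0, 0.0]]), grid100)
        count = am.searched_grid_count(field, 0.1)
        assert count == oracle == 305
        assert am.search_rate(count, grid100) == pytest.approx(305 / 31397)

    def test_full_coverage_and_zero(self, grid100):
        assert am.search_rate(grid100.grid_area, grid100) == 1.0
        assert am.search_rate(0, grid100) == 0.0
        with pytest.raises(ValueError):
            am.search_rate(grid100.grid_area + 1, grid100)

    def test_monotone_under_extension(self, grid100):
        rng = np.random.default_rng(11)
        traj = rng.uniform(-0.9, 0.9, (50, 2))
        prev_count, prev_len = 0, 0.0
        for m in (10, 25, 50):
            field = am.min_distance_field(traj[:m], grid100)
            count = am.searched_grid_count(field)
            d = am.path_length(traj[:m])
            assert count >= prev_count and d >= prev_len
            prev_count, prev_len = count, d

    def test_rotation_near_invariance(self, grid100):
        rng = np.random.default_rng(5)
        traj = rng.uniform(-0.8, 0.8, (200, 2))
        base = am.search_rate(am.searched_grid_count(
            am.min_distance_field(traj, grid100)), grid100)
        for angle in rng.uniform(0, 2 * np.pi, 3):
            c, s = np.cos(angle), np.sin(angle)
            rot = traj @ np.array([[c, -s], [s, c]]).T
            eps = am.search_rate(am.searched_grid_count(
                am.min_distance_field(rot, grid100)), grid100)
            assert abs(eps - base) <= 0.02


class TestOccupancyAndDistance:
    def test_rate_examples(self):
        origin = np.zeros((5, 2))
        assert am.central_peripheral_rates(origin) == (1.0, 0.0)
        ring = np.column_stack([np.full(4, 0.95), np.zeros(4)])
        assert am.central_peripheral_rates(ring) == (0.0, 1.0)
        half = np.array([[0.5, 0], [0.5, 0], [0.95, 0], [0.95, 0]])
        c_r, p_r = am.central_peripheral_rates(half)
        assert c_r == 0.5 and p_r == 0.5

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 0.999), min_size=1, max_size=40))
    def test_rates_sum_to_one(self, radii):
        traj = np.column_stack([radii, np.zeros(len(radii))])
        c_r, p_r = am.central_peripheral_rates(traj)
        assert c_r + p_r == 1.0

    def test_path_length(self):
        assert am.path_length([[0, 0], [0.3, 0.4]]) == pytest.approx(0.5)
        square = [[0, 0], [0.2, 0], [0.2, 0.2], [0, 0.2], [0, 0]]
        assert am.path_length(square) == pytest.approx(0.8)
        with pytest.warns(UserWarning):
            assert am.path_length([[0.1, 0.1]]) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10 ** 6))
    def test_path_at_least_end_to_end(self, seed):
        rng = np.random.default_rng(seed)
        traj = rng.uniform(-1, 1, (8, 2))
        chord = np.hypot(*(traj[-1] - traj[0]))
        assert am.path_length(traj) >= chord - 1e-12


class TestTimes:
    def test_stop_time_examples(self):
        assert am.stop_time(np.zeros(100), 7) == pytest.approx(420.0)
        assert am.stop_time(np.ones(100), 7) == 0.0
        assert am.stop_time([0] * 50 + [1] * 50, 7) == pytest.approx(210.0)

    def test_stimulation_time_examples(self):
        assert am.stimulation_time(np.zeros(50), 7) == 0.0
        flags = np.zeros(100); flags[:1] = 1
        assert am.stimulation_time(flags, 7) == pytest.approx(4.2)
        assert am.stimulation_time(np.ones(10), 7) == pytest.approx(420.0)

    def test_stop_plus_move_is_trial_duration(self):
        rng = np.random.default_rng(0)
        states = rng.integers(0, 2, 777)
        t_s = am.stop_time(states, 7)
        t_move = am.stop_time(1 - states, 7)
        assert t_s + t_move == pytest.approx(420.0, abs=1e-9)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            am.stop_time([0, 1, 2], 7)


class TestSummaries:
    def test_per_animal_means_match_published(self):
        free, stim = load_fixture_tables()
        fs = am.summarize_trials(free)
        assert round(fs.loc["C2", "stop_time"], 2) == 210.95
        assert round(fs.loc["C3", "stop_time"], 2) == 142.56
        assert round(fs.loc["C3", "search_rate"], 2) == 0.48
        assert round(fs.loc["C3", "distance"], 2) == 36.40
        ss = am.summarize_trials(stim)
        assert round(ss.loc["C3", "stimulation_time"], 1) == 4.6
        assert round(stim["stimulation_time"].mean(), 1) == 3.4

    def test_improvement_identity_and_doubling(self):
        free, _ = load_fixture_tables()
        s = am.summarize_trials(free)
        same = am.improvement_stats(s, s)
        for v in same["mean_change_pct"].values():
            assert v == pytest.approx(0.0, abs=1e-12)
        doubled = free.copy()
        doubled["distance"] *= 2
        d = am.improvement_stats(s, am.summarize_trials(doubled))
        assert d["mean_change_pct"]["distance"] == pytest.approx(100.0)

    def test_stop_time_reduction_is_78_percent(self):
        free, stim = load_fixture_tables()
        imp = am.improvement_stats(am.summarize_trials(free),
                                   am.summarize_trials(stim))
        per_animal = imp["per_animal_change_pct"]["stop_time"]
        assert [round(-per_animal[a], 1) for a in ("C1", "C2", "C3")] == \
            [76.3, 94.8, 61.9]
        assert imp["headline"]["stop_time_reduction_pct"] == 78

    def test_zero_baseline_excluded_with_warning(self):
        free, stim = load_fixture_tables()
        free = free.assign(stimulation_time=0.0)  # free trials: no bursts
        with pytest.warns(UserWarning, match="zero free-condition mean"):
            imp = am.improvement_stats(am.summarize_trials(free),
                                       am.summarize_trials(stim))
        assert imp["per_animal_change_pct"]["stimulation_time"] == {}
        assert "stimulation_time" not in imp["mean_change_pct"]
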
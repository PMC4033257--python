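import numpy as np
import pytest

from gazelearn.observers import (INHIBITION_DECAY, make_yoke,
                                 select_next_fixation, simulate_random_observer,
                                 simulate_saliency_observer, step_inhibition)
from gazelearn.saliency import CELL_PX, GRID_H, GRID_W
from gazelearn.synthetic_gaze import GazeRecord, GazeStyleParams, generate_gaze


def _record(xs, ys, durs):
    return GazeRecord("ref", x=xs, y=ys, duration_ms=durs)


class TestMakeYoke:
    def test_375ms_is_11_frames(self):
        yoke = make_yoke(_record([0, 10], [0, 10], [375.0, 375.0]))
        assert yoke.durations_frames.tolist() == [11, 11]

    def test_single_frame_floor(self):
        yoke = make_yoke(_record([0, 10], [0, 10], [100.0 / 3.0, 5.0]))
        assert yoke.durations_frames.tolist() == [1, 1]

    def test_345_distance(self):
        yoke = make_yoke(_record([0, 3], [0, 4], [100, 100]))
        assert yoke.distances_px.tolist() == [5.0]

    def test_requires_two_fixations(self):
        with pytest.raises(ValueError):
            make_yoke(GazeRecord("r", x=[1], y=[1], duration_ms=[100]))


class TestInhibition:
    def test_peak_decays_ten_percent_per_frame(self):
        inhib = np.zeros((GRID_H, GRID_W))
        smap = np.ones((GRID_H, GRID_W))
        out = step_inhibition(inhib, (240.0, 180.0), smap, add=True)
        assert out.max() == pytest.approx(1.0 * INHIBITION_DECAY)

    def test_geometric_decay_closed_form(self):
        inhib = np.zeros((GRID_H, GRID_W))
        inhib[15, 20] = 1.0
        k = 7
        for _ in range(k):
            inhib = step_inhibition(inhib)
        assert inhib[15, 20] == pytest.approx(0.9 ** k)

    def test_zero_saliency_adds_nothing(self):
        inhib = np.zeros((GRID_H, GRID_W))
        out = step_inhibition(inhib, (100.0, 100.0), np.zeros((GRID_H, GRID_W)),
                              add=True)
        assert np.allclose(out, 0.0)

    def test_never_negative(self):
        inhib = np.zeros((GRID_H, GRID_W))
        smap = np.random.default_rng(0).random((GRID_H, GRID_W))
        for i in range(20):
            inhib = step_inhibition(inhib, (i * 20.0, i * 15.0), smap,
                                    add=(i % 3 == 0))
            assert np.all(inhib >= 0)


class TestSelectNextFixation:
    def test_closest_distance_wins(self, rng):
        fixmap = np.zeros((GRID_H, GRID_W))
        # three high cells in row 15 at distances ~50/60/70 px from current
        current = (5.5, 185.5)  # centre of cell (15, 0)
        for col in (4, 5, 6):
            fixmap[15, col] = 1.0  # centres at distances 48, 60, 72 px
        pick = select_next_fixation(fixmap, current, 59.0, rng)
        assert pick == (5 * CELL_PX + 5.5, 15 * CELL_PX + 5.5)

    def test_zero_distance_returns_own_cell(self, rng):
        fixmap = np.zeros((GRID_H, GRID_W))
        fixmap[10, 10] = 5.0
        current = (10 * CELL_PX + 5.5, 10 * CELL_PX + 5.5)
        assert select_next_fixation(fixmap, current, 0.0, rng) == current

    def test_coin_toss_on_exact_ties(self):
        """Two candidates exactly equidistant-in-error are each chosen
        about half the time (binomial test of the coin toss, alpha 0.001)."""
        from scipy.stats import binomtest

        fixmap = np.zeros((GRID_H, GRID_W))
        fixmap[15, 10] = 1.0
        fixmap[15, 20] = 1.0
        current = (15 * CELL_PX + 5.5, 15 * CELL_PX + 5.5)  # midway in x
        rng = np.random.default_rng(77)
        n = 10_000
        left = sum(select_next_fixation(fixmap, current, 60.0, rng)[0]
                   < current[0] for _ in range(n))
        assert binomtest(left, n, 0.5).pvalue > 1e-3

    def test_degenerate_flat_map_still_returns_cell(self, rng):
        pick = select_next_fixation(np.ones((GRID_H, GRID_W)), (240.0, 180.0),
                                    50.0, rng)
        assert 0 <= pick[0] < GRID_W * CELL_PX
        assert 0 <= pick[1] < GRID_H * CELL_PX


@pytest.fixture(scope="module")
def yokes(display):
    records = [generate_gaze(GazeStyleParams.infant_like(seed=s,
                                                         n_fixations=25),
                             display) for s in range(20)]
    return [(r, make_yoke(r, display.frame_ms)) for r in records]


class TestYokedSimulations:
    def test_saliency_observer_yoking_exact(self, smaps, yokes, display):
        for s, (ref, yoke) in enumerate(yokes):
            sim = simulate_saliency_observer(smaps, yoke, seed=s)
            assert sim.n_fixations == ref.n_fixations
            assert (sim.x[0], sim.y[0]) == yoke.first_xy
            assert np.array_equal(make_yoke(sim, display.frame_ms).durations_frames,
                                  yoke.durations_frames)

    def test_random_observer_yoking_exact(self, yokes, display):
        for s, (ref, yoke) in enumerate(yokes):
            sim = simulate_random_observer(yoke, display, seed=s)
            assert sim.n_fixations == ref.n_fixations
            assert (sim.x[0], sim.y[0]) == yoke.first_xy
            assert np.allclose(sim.shift_distances(), yoke.distances_px)
            assert np.all((sim.x >= 0) & (sim.x < display.width_px))
            assert np.all((sim.y >= 0) & (sim.y < display.height_px))

    def test_single_fixation_yoke(self, smaps):
        from gazelearn.observers import YokeSpec
        yoke = YokeSpec(first_xy=(100.0, 100.0), durations_frames=[5],
                        distances_px=[])
        sim = simulate_saliency_observer(smaps, yoke, seed=0)
        assert sim.n_fixations == 1

    def test_random_angles_uniform_from_center(self, display):
        """10k single hops from the display centre (where no draw is ever
        rejected): chi-square uniformity over 12 angular bins, alpha 0.01."""
        from scipy.stats import chisquare
        from gazelearn.observers import YokeSpec

        yoke = YokeSpec(first_xy=(240.0, 180.0), durations_frames=[1, 1],
                        distances_px=[50.0])
        angles = np.empty(10_000)
        for s in range(angles.size):
            sim = simulate_random_observer(yoke, display, seed=s)
            angles[s] = np.arctan2(sim.y[1] - sim.y[0], sim.x[1] - sim.x[0])
        counts, _ = np.histogram(angles, bins=12, range=(-np.pi, np.pi))
        assert chisquare(counts).pvalue > 0.01

    def test_infeasible_distance_clipped_with_warning(self, display):
        from gazelearn.observers import YokeSpec
        yoke = YokeSpec(first_xy=(0.0, 0.0), durations_frames=[1, 1],
                        distances_px=[10_000.0])
        with pytest.warns(UserWarning):
            sim = simulate_random_observer(yoke, display, seed=0)
        assert 0 <= sim.x[1] < display.width_px
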
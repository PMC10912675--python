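import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myoscore.classifier import ScoreTrajectory
from myoscore.config import PipelineConfig
from myoscore.metrics import (
    detect_high_stable,
    detect_onset,
    differentiation_duration,
    fusion_coupling,
    longest_run,
    score_time_correlation,
    terminal_time,
    timings_frame,
)


def oracle_longest_run(values, predicate):
    """Exhaustive O(n^2) enumeration of all qualifying runs."""
    best = None
    n = len(values)
    for i in range(n):
        for j in range(i, n):
            if all(predicate(v) for v in values[i : j + 1]):
                if best is None or (j - i) > (best[1] - best[0]):
                    best = (i, j)
    return best


def _traj(scores, t0=4.0, dt=0.5, cell_id="c"):
    scores = np.asarray(scores, dtype=float)
    return ScoreTrajectory(cell_id, t0 + dt * np.arange(len(scores)), scores)


class TestLongestRun:
    def test_known_example(self):
        vals = [0.25, 0.25, 0.5, 0.25, 0.25, 0.25]
        assert longest_run(vals, lambda v: 0.2 <= v <= 0.3) == (3, 5)

    def test_no_qualifying_value(self):
        assert longest_run([0.9, 0.9], lambda v: v < 0.5) is None

    def test_tie_broken_to_earliest(self):
        vals = [1, 1, 0, 1, 1, 0]
        assert longest_run(vals, lambda v: v == 1) == (0, 1)

    def test_agrees_with_exhaustive_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 40))
            vals = rng.choice(np.round(np.linspace(0, 1, 21), 2), size=n)
            pred = lambda v: 0.2 <= v <= 0.3
            assert longest_run(vals, pred) == oracle_longest_run(list(vals), pred)

    @given(st.lists(st.integers(min_value=0, max_value=3), max_size=60))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_oracle_equivalence_property(self, vals):
        pred = lambda v: v == 1
        assert longest_run(vals, pred) == oracle_longest_run(vals, pred)


class TestTimingEstimators:
    def test_onset_is_last_point_of_band_run(self):
        st = _traj([0.25] * 5 + [0.8] * 5, t0=4.0, dt=0.5)
        assert detect_onset(st) == pytest.approx(4.0 + 4 * 0.5)

    def test_onset_none_when_never_in_band(self):
        assert detect_onset(_traj([0.9] * 6)) is None

    def test_high_stable_is_first_point_of_band_run(self):
        st = _traj([0.1] * 3 + [0.75] * 6)
        assert detect_high_stable(st) == pytest.approx(st.t_hours[3])

    def test_high_stable_none_for_flat_half(self):
        assert detect_high_stable(_traj([0.5] * 8)) is None

    def test_terminal_threshold_is_strict(self):
        assert terminal_time(_traj([0.78] * 6)) is None

    def test_terminal_picks_longest_run_start(self):
        st = _traj([0.9] * 3 + [0.5] + [0.9] * 5)
        assert terminal_time(st) == pytest.approx(st.t_hours[4])

    def test_duration_is_difference(self):
        st = _traj([0.25] * 4 + [0.5] * 2 + [0.75] * 4, t0=10.0, dt=1.1)
        onset = detect_onset(st)
        high = detect_high_stable(st)
        assert differentiation_duration(st) == pytest.approx(high - onset)

    def test_duration_none_when_onset_missing(self):
        assert differentiation_duration(_traj([0.75] * 6)) is None

    def test_duration_none_when_high_precedes_onset(self):
        st = _traj([0.75] * 4 + [0.25] * 4)
        assert differentiation_duration(st) is None

    def test_estimators_shift_with_uniform_time_shift(self, rng):
        scores = np.concatenate([
            rng.uniform(0.2, 0.3, 6), rng.uniform(0.4, 0.6, 3),
            rng.uniform(0.7, 0.8, 5), rng.uniform(0.85, 1.0, 6),
        ])
        a = _traj(scores, t0=4.0)
        b = _traj(scores, t0=9.5)
        for f in (detect_onset, detect_high_stable, terminal_time):
            assert f(b) == pytest.approx(f(a) + 5.5)

    def test_band_estimators_match_oracle_on_noisy_trajectories(self, rng):
        cfg = PipelineConfig()
        for _ in range(100):
            scores = np.round(rng.uniform(0, 1, int(rng.integers(5, 60))), 2)
            st = _traj(scores)
            run = oracle_longest_run(list(scores), lambda v: 0.7 <= v <= 0.8)
            expected = None if run is None else st.t_hours[run[0]]
            got = detect_high_stable(st, cfg)
            assert (got is None and expected is None) or got == pytest.approx(expected)


class TestCorrelationAndCoupling:
    def test_increasing_scores_give_rho_one(self):
        st = _traj(np.linspace(0.1, 0.9, 20), t0=7.5, dt=0.25)
        rho, p = score_time_correlation(st)
        assert rho == pytest.approx(1.0)

    def test_decreasing_scores_give_rho_minus_one(self):
        st = _traj(np.linspace(0.9, 0.1, 20), t0=7.5, dt=0.25)
        assert score_time_correlation(st)[0] == pytest.approx(-1.0)

    def test_too_few_points_in_window_flagged(self):
        st = _traj([0.5, 0.6], t0=20.0)
        assert score_time_correlation(st) is None

    def test_null_scores_have_near_zero_mean_rho(self, rng):
        rhos = []
        for _ in range(300):
            st = _traj(rng.uniform(0, 1, 25), t0=7.5, dt=0.3)
            rhos.append(score_time_correlation(st)[0])
        se = np.std(rhos) / np.sqrt(len(rhos))
        assert abs(np.mean(rhos)) < 3 * se + 1e-12

    def test_exact_gap_gives_perfect_correlation(self):
        timings = pd.DataFrame(
            dict(cell_id=[f"c{i}" for i in range(10)], terminal_h=np.linspace(10, 16, 10))
        )
        fusion = pd.DataFrame(
            dict(cell_id=timings.cell_id, fusion_time_hours=timings.terminal_h + 3.0)
        )
        rep = fusion_coupling(timings, fusion)
        assert rep["pearson_r"] == pytest.approx(1.0)
        assert rep["gap_median_h"] == pytest.approx(3.0)

    def test_independent_times_have_small_correlation(self, rng):
        n = 500
        timings = pd.DataFrame(
            dict(cell_id=[f"c{i}" for i in range(n)], terminal_h=rng.normal(13, 2, n))
        )
        fusion = pd.DataFrame(
            dict(cell_id=timings.cell_id, fusion_time_hours=rng.normal(16, 2, n))
        )
        assert abs(fusion_coupling(timings, fusion)["pearson_r"]) < 0.15

    def test_insufficient_pairs_raise(self):
        timings = pd.DataFrame(dict(cell_id=["a", "b"], terminal_h=[1.0, 2.0]))
        fusion = pd.DataFrame(dict(cell_id=["a", "b"], fusion_time_hours=[4.0, 5.0]))
        with pytest.raises(ValueError):
            fusion_coupling(timings, fusion)

    def test_timings_frame_columns(self):
        df = timings_frame([_traj(np.linspace(0.05, 0.95, 40), t0=4.0, dt=0.25)])
        assert {"cell_id", "onset_h", "high_stable_h", "duration_h", "terminal_h", "rho_time"} <= set(df.columns)
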
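import numpy as np
import pandas as pd
import pytest

from myoscore.config import PipelineConfig
from myoscore.tracks import (
    CellTrack,
    IntegrityError,
    SchemaError,
    TrackSet,
    estimate_frame_offsets,
    inject_drift,
    quantify_actin_window,
    read_tracks,
    register_tracks,
    write_tracks,
)


def _toy_csv(tmp_path, rows, name="tracks.csv", columns=None):
    columns = columns or ["cell_id", "frame", "x_um", "y_um"]
    path = tmp_path / name
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    return path


class TestReadWrite:
    def test_round_trip_preserves_tracks(self, tmp_path, small_experiment):
        ts, _ = small_experiment
        out = tmp_path / "rt.csv"
        write_tracks(ts, out)
        back = read_tracks(out, ts.config)
        assert len(back) == len(ts)
        orig = ts.by_id()
        for tr in back:
            o = orig[tr.cell_id]
            assert np.array_equal(tr.frames, o.frames)
            np.testing.assert_allclose(tr.xy_um, o.xy_um, atol=1e-9)
            np.testing.assert_allclose(tr.t_hours, o.t_hours, atol=1e-9)
            np.testing.assert_allclose(tr.actin_stats, o.actin_stats, atol=1e-9)
            assert tr.condition == o.condition

    def test_two_cells_three_frames(self, tmp_path):
        rows = [["a", f, float(f), 0.0] for f in range(3)]
        rows += [["b", f, 0.0, float(f)] for f in range(3)]
        ts = read_tracks(_toy_csv(tmp_path, rows))
        assert len(ts) == 2
        assert all(tr.n_frames == 3 for tr in ts)

    def test_shuffled_rows_parse_identically(self, tmp_path, rng):
        rows = [["a", f, float(f), 2.0 * f] for f in range(5)]
        rows += [["b", f, -1.0 * f, 0.5] for f in range(5)]
        sorted_ts = read_tracks(_toy_csv(tmp_path, rows, "sorted.csv"))
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        shuf_ts = read_tracks(_toy_csv(tmp_path, shuffled, "shuffled.csv"))
        for a, b in zip(sorted_ts, shuf_ts):
            assert a.cell_id == b.cell_id
            np.testing.assert_array_equal(a.xy_um, b.xy_um)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = _toy_csv(
            tmp_path, [["a", 0, 1.0]], columns=["cell_id", "frame", "y_um"]
        )
        with pytest.raises(SchemaError, match="x_um"):
            read_tracks(path)

    def test_duplicate_cell_frame_is_integrity_error(self, tmp_path):
        rows = [["a", 0, 0.0, 0.0], ["a", 0, 1.0, 1.0]]
        with pytest.raises(IntegrityError):
            read_tracks(_toy_csv(tmp_path, rows))

    def test_t_hours_derived_from_frame_interval(self, tmp_path):
        ts = read_tracks(
            _toy_csv(tmp_path, [["a", f, 0.0, 0.0] for f in range(3)]),
            PipelineConfig(frame_interval_min=30),
        )
        np.testing.assert_allclose(ts.tracks[0].t_hours, [0.0, 0.5, 1.0])


def _static_tracks(n_cells=4, n_frames=6, rng=None):
    rng = rng or np.random.default_rng(0)
    tracks = []
    for i in range(n_cells):
        pos = np.tile(rng.uniform(0, 100, 2), (n_frames, 1))
        tracks.append(
            CellTrack(
                cell_id=f"c{i}",
                frames=np.arange(n_frames),
                t_hours=np.arange(n_frames) / 12,
                xy_um=pos,
            )
        )
    return TrackSet(tracks)


class TestRegistration:
    def test_stationary_cells_give_zero_offsets(self):
        offsets = estimate_frame_offsets(_static_tracks())
        np.testing.assert_allclose(offsets, 0.0, atol=1e-12)

    def test_injected_rigid_drift_is_recovered(self):
        drifted = inject_drift(_static_tracks(), (1.0, 0.0))
        offsets = estimate_frame_offsets(drifted)
        expected = np.column_stack([np.arange(6, dtype=float), np.zeros(6)])
        np.testing.assert_allclose(offsets, expected, atol=1e-9)

    def test_single_moving_cell_reads_as_drift(self):
        track = CellTrack(
            "only",
            np.arange(4),
            np.arange(4) / 12,
            np.column_stack([2.0 * np.arange(4), np.zeros(4)]),
        )
        offsets = estimate_frame_offsets(TrackSet([track]))
        np.testing.assert_allclose(offsets[:, 0], [0, 2, 4, 6])

    def test_zero_offsets_are_identity(self):
        ts = _static_tracks()
        reg = register_tracks(ts, np.zeros((6, 2)))
        for a, b in zip(ts, reg):
            np.testing.assert_array_equal(a.xy_um, b.xy_um)

    def test_drift_round_trip_recovers_positions(self):
        ts = _static_tracks()
        drifted = inject_drift(ts, (0.7, -0.3))
        reg = register_tracks(drifted, estimate_frame_offsets(drifted))
        for a, b in zip(ts, reg):
            np.testing.assert_allclose(a.xy_um, b.xy_um, atol=1e-9)

    def test_registration_preserves_pairwise_distances(self, rng):
        ts = _static_tracks(rng=rng)
        offsets = rng.normal(size=(6, 2))
        reg = register_tracks(ts, offsets)
        for f in range(6):
            orig = np.array([tr.xy_um[f] for tr in ts])
            new = np.array([tr.xy_um[f] for tr in reg])
            d0 = np.linalg.norm(orig[:, None] - orig[None, :], axis=-1)
            d1 = np.linalg.norm(new[:, None] - new[None, :], axis=-1)
            np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_offsets_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            register_tracks(_static_tracks(), np.zeros((3, 2)))


class TestActinWindow:
    def test_uniform_image(self):
        cfg = PipelineConfig()
        img = np.full((200, 200), 7.0)
        assert quantify_actin_window(img, (40.0, 40.0), cfg) == (7, 7, 7, 7, 0)

    def test_three_by_three_window_brute_force(self):
        # window side = round(3 / 1) = 3 px over values 1..9
        cfg = PipelineConfig(pixel_size_um=1.0, actin_window_um=3.0)
        img = np.arange(1.0, 10.0).reshape(3, 3)
        got = quantify_actin_window(img, (1.0, 1.0), cfg)
        vals = np.arange(1.0, 10.0)
        assert got == (1.0, 9.0, 5.0, 5.0, pytest.approx(vals.std()))

    def test_border_window_is_clipped(self):
        cfg = PipelineConfig(pixel_size_um=1.0, actin_window_um=5.0)
        img = np.arange(100.0).reshape(10, 10)
        got = quantify_actin_window(img, (0.0, 0.0), cfg)
        clipped = img[0:3, 0:3]  # half = 2, center (0, 0)
        assert got[0] == clipped.min()
        assert got[2] == pytest.approx(clipped.mean())

    def test_center_outside_image_raises(self):
        with pytest.raises(ValueError):
            quantify_actin_window(np.zeros((10, 10)), (100.0, 0.0), PipelineConfig(pixel_size_um=1.0))

    def test_order_statistics_invariant_on_random_images(self, rng):
        cfg = PipelineConfig(pixel_size_um=1.0, actin_window_um=7.0)
        for _ in range(25):
            img = rng.normal(size=(30, 30))
            c = tuple(rng.uniform(0, 29, 2))
            mn, mx, mean, med, sd = quantify_actin_window(img, c, cfg)
            assert mn <= med <= mx
            assert mn <= mean <= mx
            assert sd >= 0
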
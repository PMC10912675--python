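"""Simple single-cell measurements and their single-feature classifiers.

These baselines discriminate experimental conditions from one scalar
readout per temporal segment (local density, speed, mean actin,
actin derivative, migration persistence, or all four core readouts
together). They serve as the comparison point for the dynamics
classifiers: a baseline can separate conditions without producing a
monotone per-cell differentiation trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .classifier import (
    ModelBundle,
    ScoreTrajectory,
    evaluate,
    predict_scores,
    train_classifier,
)
from .config import PipelineConfig
from .metrics import score_time_correlation
from .segments import TemporalSegment, make_segments
from .tracks import CellTrack, TrackSet

MEASUREMENTS = ("local_density", "speed", "actin_mean", "actin_derivative", "persistence")
#: the four core readouts entering the combined baseline
CORE_MEASUREMENTS = ("local_density", "speed", "actin_mean", "persistence")


@dataclass
class SimpleSeries:
    """One cell's per-frame series of a simple measurement."""

    cell_id: str
    measurement: str
    t_hours: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.t_hours = np.asarray(self.t_hours, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t_hours.shape != self.values.shape:
            raise ValueError("misaligned simple series")


def local_density(
    ts: TrackSet, config: Optional[PipelineConfig] = None
) -> Dict[str, SimpleSeries]:
    """Per frame, the number of OTHER cells within the density radius
    (inclusive boundary, self excluded). Expects registered tracks.

    Conditions are imaged in separate cultures, so neighbours are counted
    within each condition group independently.
    """
    config = config or ts.config
    conditions = {tr.condition for tr in ts.tracks}
    if len(conditions) > 1:
        out: Dict[str, SimpleSeries] = {}
        for cond in sorted(conditions):
            out.update(local_density(ts.by_condition(cond), config))
        return out
    r = config.density_radius_um
    n_frames = ts.n_frames_max
    # gather per-frame positions with track/row bookkeeping
    counts = {tr.cell_id: np.zeros(tr.n_frames) for tr in ts.tracks}
    frame_members: List[List[Tuple[str, int]]] = [[] for _ in range(n_frames)]
    frame_pos: List[List[np.ndarray]] = [[] for _ in range(n_frames)]
    for tr in ts.tracks:
        for i, f in enumerate(tr.frames):
            frame_members[int(f)].append((tr.cell_id, i))
            frame_pos[int(f)].append(tr.xy_um[i])
    for f in range(n_frames):
        members = frame_members[f]
        if len(members) < 2:
            continue
        pts = np.vstack(frame_pos[f])
        tree = cKDTree(pts)
        n_within = tree.query_ball_point(pts, r, return_length=True)
        for (cid, i), n in zip(members, n_within):
            counts[cid][i] = n - 1  # exclude self
    return {
        tr.cell_id: SimpleSeries(tr.cell_id, "local_density", tr.t_hours, counts[tr.cell_id])
        for tr in ts.tracks
    }


def speed_series(track: CellTrack, config: Optional[PipelineConfig] = None) -> SimpleSeries:
    """Per-step displacement magnitude in µm per frame, stamped at the step's
    end frame."""
    if track.n_frames < 2:
        raise ValueError("need >= 2 frames for speed")
    d = np.diff(track.xy_um, axis=0)
    v = np.hypot(d[:, 0], d[:, 1])
    return SimpleSeries(track.cell_id, "speed", track.t_hours[1:], v)


def persistence(track: CellTrack, window_frames: int) -> SimpleSeries:
    """Net displacement over path length per sliding window (stamped at the
    window's end frame). 1 means straight-line migration; 0/0 is defined
    as 0 (a cell that never moved)."""
    if window_frames < 2:
        raise ValueError("persistence window must span >= 2 frames")
    if track.n_frames < window_frames:
        return SimpleSeries(track.cell_id, "persistence", np.empty(0), np.empty(0))
    d = np.diff(track.xy_um, axis=0)
    step_len = np.hypot(d[:, 0], d[:, 1])
    w = window_frames - 1  # steps per window
    csum = np.concatenate([[0.0], np.cumsum(step_len)])
    path = csum[w:] - csum[:-w]
    net = np.hypot(
        track.xy_um[w:, 0] - track.xy_um[:-w, 0],
        track.xy_um[w:, 1] - track.xy_um[:-w, 1],
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(path > 0, net / path, 0.0)
    return SimpleSeries(track.cell_id, "persistence", track.t_hours[w:], np.clip(p, 0.0, 1.0))


def actin_derivative(track: CellTrack, config: Optional[PipelineConfig] = None) -> SimpleSeries:
    """First difference of the mean actin intensity, in units per hour."""
    config = config or PipelineConfig()
    if track.actin_stats is None:
        raise ValueError(f"track {track.cell_id} has no actin statistics")
    dt_h = config.frame_interval_min / 60.0
    dv = np.diff(track.actin_stats[:, 2]) / dt_h
    return SimpleSeries(track.cell_id, "actin_derivative", track.t_hours[1:], dv)


def _measurement_lookup(
    ts: TrackSet, measurement: str, config: PipelineConfig
) -> Dict[str, SimpleSeries]:
    if measurement == "local_density":
        return local_density(ts, config)
    out = {}
    for tr in ts.tracks:
        if measurement == "speed":
            out[tr.cell_id] = speed_series(tr, config)
        elif measurement == "actin_mean":
            if tr.actin_stats is None:
                raise ValueError(f"track {tr.cell_id} has no actin statistics")
            out[tr.cell_id] = SimpleSeries(
                tr.cell_id, "actin_mean", tr.t_hours, tr.actin_stats[:, 2]
            )
        elif measurement == "actin_derivative":
            out[tr.cell_id] = actin_derivative(tr, config)
        elif measurement == "persistence":
            out[tr.cell_id] = persistence(tr, config.segment_len_frames)
        else:
            raise ValueError(f"unknown measurement {measurement!r}")
    return out


def segment_measurement_matrix(
    ts: TrackSet,
    segments: Sequence[TemporalSegment],
    measurements: Sequence[str],
    config: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Mean of each measurement within each temporal segment.

    Rows align with ``segments``; one column per measurement.
    """
    config = config or ts.config
    lookups = {m: _measurement_lookup(ts, m, config) for m in measurements}
    cols: Dict[str, np.ndarray] = {}
    for m in measurements:
        lk = lookups[m]
        vals = np.empty(len(segments))
        for i, s in enumerate(segments):
            ser = lk[s.cell_id]
            in_win = (ser.t_hours >= s.t_start_h - 1e-9) & (ser.t_hours <= s.t_end_h + 1e-9)
            vals[i] = float(ser.values[in_win].mean()) if in_win.any() else 0.0
        cols[f"{m}__segment_mean"] = vals
    index = pd.MultiIndex.from_arrays(
        [[s.cell_id for s in segments], [s.start_frame for s in segments]],
        names=["cell_id", "start_frame"],
    )
    return pd.DataFrame(cols, index=index)


@dataclass
class BaselineReport:
    """A simple-measurement classifier with its evaluation."""

    measurement: str
    bundle: ModelBundle
    metrics: Dict[str, float]
    rho_by_cell: pd.Series  # per-cell Spearman(score, time) in the diff window


def simple_classifier(
    train_ts: TrackSet,
    train_labeled: Sequence[TemporalSegment],
    test_ts: TrackSet,
    test_labeled: Sequence[TemporalSegment],
    measurement: str = "local_density",
    config: Optional[PipelineConfig] = None,
    seed: int = 0,
) -> BaselineReport:
    """Train and evaluate a single-measurement (or all-four) classifier.

    The feature is the mean of the measurement within each temporal
    segment; ``measurement="all"`` combines the four core readouts. The
    report carries the held-out metrics and the per-cell score-time
    Spearman distribution of the test set's differentiating cells, for a
    side-by-side monotonicity comparison with the dynamics classifiers.
    """
    config = config or train_ts.config
    names = list(CORE_MEASUREMENTS) if measurement == "all" else [measurement]

    fm_train = segment_measurement_matrix(train_ts, train_labeled, names, config)
    y_train = np.array([s.label for s in train_labeled])
    bundle = train_classifier(
        fm_train, y_train, mode=f"baseline:{measurement}", seed=seed, select=False
    )

    fm_test = segment_measurement_matrix(test_ts, test_labeled, names, config)
    y_test = np.array([s.label for s in test_labeled])
    metrics = evaluate(bundle, fm_test, y_test)

    # per-cell score trajectories of differentiating test cells
    diff_tracks = test_ts.by_condition("ERKi")
    segs = make_segments(diff_tracks, config)
    fm_all = segment_measurement_matrix(diff_tracks, segs, names, config)
    scores = predict_scores(bundle, fm_all)
    t_end = np.array([s.t_end_h for s in segs])
    ids = np.array([s.cell_id for s in segs])
    rhos = {}
    for cid in dict.fromkeys(ids):
        m = ids == cid
        if m.sum() < 2:
            continue  # single segment: correlation undefined, flagged by omission
        st = ScoreTrajectory(cid, t_end[m], scores[m], "ERKi")
        rho = score_time_correlation(st, config)
        if rho is not None:
            rhos[cid] = rho[0]
    return BaselineReport(
        measurement=measurement,
        bundle=bundle,
        metrics=metrics,
        rho_by_cell=pd.Series(rhos, name=f"rho_{measurement}"),
    )
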
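"""Temporal segmentation of tracks and training-label assignment.

A temporal segment is a fixed-length sliding window of one track
(default 31 frames = 2.5 h at 5-minute sampling, lag 1 frame). Each
segment carries a per-step displacement series (30 entries at the
default length) and, when available, the five-channel actin statistics
series (31 entries).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .tracks import CellTrack, TrackSet

logger = logging.getLogger(__name__)

LABEL_DIFF = "differentiated"
LABEL_UNDIFF = "undifferentiated"

#: conditions whose segments may receive a positive / negative label
POSITIVE_CONDITION = "ERKi"
NEGATIVE_CONDITION = "DMSO"


@dataclass
class TemporalSegment:
    """One fixed-length window of one track."""

    cell_id: str
    condition: str
    start_frame: int
    end_frame: int  # inclusive
    t_start_h: float
    t_end_h: float
    motility_series: np.ndarray  # (L-1, 2) per-step displacements
    actin_series: Optional[np.ndarray]  # (L, 5) or None
    label: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end_frame - self.start_frame + 1


def make_segments(
    ts: TrackSet, config: Optional[PipelineConfig] = None
) -> List[TemporalSegment]:
    """Partition every track into overlapping fixed-length segments.

    A track of N frames yields N - L + 1 segments at lag
    ``segment_lag_frames`` = 1 (general lag: floor((N - L) / lag) + 1).
    Tracks shorter than L are skipped with a warning; a track with an
    internal frame gap is an error (gaps are not interpolated).
    """
    config = config or ts.config
    L = config.segment_len_frames
    lag = config.segment_lag_frames
    out: List[TemporalSegment] = []
    for tr in ts.tracks:
        if not tr.is_gap_free():
            raise ValueError(f"track {tr.cell_id} has internal frame gaps")
        if tr.n_frames < L:
            logger.warning(
                "track %s shorter than segment length (%d < %d); skipped",
                tr.cell_id,
                tr.n_frames,
                L,
            )
            continue
        disp = np.diff(tr.xy_um, axis=0)  # (N-1, 2)
        for k in range(0, tr.n_frames - L + 1, lag):
            actin = tr.actin_stats[k : k + L] if tr.actin_stats is not None else None
            out.append(
                TemporalSegment(
                    cell_id=tr.cell_id,
                    condition=tr.condition,
                    start_frame=int(tr.frames[k]),
                    end_frame=int(tr.frames[k + L - 1]),
                    t_start_h=float(tr.t_hours[k]),
                    t_end_h=float(tr.t_hours[k + L - 1]),
                    motility_series=disp[k : k + L - 1],
                    actin_series=actin,
                )
            )
    return out


def assign_training_labels(
    segments: Sequence[TemporalSegment],
    first_fusion_time_h: Optional[float] = None,
    config: Optional[PipelineConfig] = None,
) -> List[TemporalSegment]:
    """Label segments for classifier training; return the labeled subset.

    Differentiating-condition (ERKi) cells receive one "differentiated"
    segment each: the segment spanning the label window — by default the
    2.5 h ending at ``first_fusion_time_h`` when given, otherwise the
    fixed ``config.label_window_hours``. Control (DMSO) cells are tiled
    with non-overlapping "undifferentiated" segments across the whole
    experiment. Perturbation conditions are never labeled. Input segments
    are not mutated; labeled copies are returned.
    """
    config = config or PipelineConfig()
    if first_fusion_time_h is not None:
        win_end = first_fusion_time_h
        win_start = win_end - config.segment_len_hours
    else:
        win_start, win_end = config.label_window_hours

    span_start = min(s.t_start_h for s in segments)
    span_end = max(s.t_end_h for s in segments)
    if win_end < span_start or win_start > span_end:
        raise ValueError(
            f"label window [{win_start}, {win_end}] h outside imaging span "
            f"[{span_start:.2f}, {span_end:.2f}] h"
        )

    half_dt = 0.5 * config.frame_interval_min / 60.0
    labeled: List[TemporalSegment] = []

    # positives: per differentiating cell, the single segment matching the window
    best: Dict[str, TemporalSegment] = {}
    for s in segments:
        if s.condition != POSITIVE_CONDITION:
            continue
        if abs(s.t_start_h - win_start) <= half_dt and s.t_end_h <= win_end + half_dt:
            prev = best.get(s.cell_id)
            if prev is None or abs(s.t_start_h - win_start) < abs(prev.t_start_h - win_start):
                best[s.cell_id] = s
    for s in best.values():
        labeled.append(
            TemporalSegment(
                **{**s.__dict__, "label": LABEL_DIFF}
            )
        )

    # negatives: non-overlapping tiling of each control track
    next_free: Dict[str, int] = {}
    for s in segments:
        if s.condition != NEGATIVE_CONDITION:
            continue
        if s.start_frame >= next_free.get(s.cell_id, -1):
            labeled.append(TemporalSegment(**{**s.__dict__, "label": LABEL_UNDIFF}))
            next_free[s.cell_id] = s.end_frame + 1
    return labeled


def segments_to_frame(segments: Sequence[TemporalSegment]) -> pd.DataFrame:
    """Long-format table of segments (series serialized as ;-joined floats)."""
    rows = []
    for s in segments:
        rows.append(
            dict(
                cell_id=s.cell_id,
                condition=s.condition,
                start_frame=s.start_frame,
                end_frame=s.end_frame,
                t_start_h=s.t_start_h,
                t_end_h=s.t_end_h,
                label=s.label if s.label is not None else "",
                dx=";".join(f"{v:.9g}" for v in s.motility_series[:, 0]),
                dy=";".join(f"{v:.9g}" for v in s.motility_series[:, 1]),
                actin=(
                    ";".join(f"{v:.9g}" for v in s.actin_series.ravel())
                    if s.actin_series is not None
                    else ""
                ),
            )
        )
    return pd.DataFrame(rows)


def write_segments(segments: Sequence[TemporalSegment], path: str | Path) -> None:
    segments_to_frame(segments).to_csv(path, index=False)


def read_segments(path: str | Path) -> List[TemporalSegment]:
    df = pd.read_csv(path, keep_default_na=False)
    out: List[TemporalSegment] = []
    for _, r in df.iterrows():
        dx = np.fromstring(r["dx"], sep=";")
        dy = np.fromstring(r["dy"], sep=";")
        actin = None
        if r["actin"]:
            flat = np.fromstring(r["actin"], sep=";")
            actin = flat.reshape(-1, 5)
        out.append(
            TemporalSegment(
                cell_id=str(r["cell_id"]),
                condition=str(r["condition"]),
                start_frame=int(r["start_frame"]),
                end_frame=int(r["end_frame"]),
                t_start_h=float(r["t_start_h"]),
                t_end_h=float(r["t_end_h"]),
                motility_series=np.column_stack([dx, dy]),
                actin_series=actin,
                label=str(r["label"]) or None,
            )
        )
    return out
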
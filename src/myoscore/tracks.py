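"""Track tables: containers, CSV I/O, drift registration, actin windows.

The import surface targets the CSV exports of interactive tracking tools
(Mastodon, Imaris): one row per (cell, frame) with positions in
micrometres and optional per-frame actin-window statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import PipelineConfig

logger = logging.getLogger(__name__)

CONDITIONS = ("ERKi", "DMSO", "p38i", "ERKi_p38i", "custom")

#: actin-window statistic channels, in canonical column order
ACTIN_CHANNELS = ("min", "max", "mean", "median", "std")

_REQUIRED_COLUMNS = ("cell_id", "frame", "x_um", "y_um")
_ACTIN_COLUMNS = tuple(f"actin_{c}" for c in ACTIN_CHANNELS)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class IntegrityError(ValueError):
    """An input table violates a structural invariant."""


@dataclass
class SimCellTruth:
    """Simulator ground truth for one cell (all times in hours)."""

    onset_h: Optional[float] = None
    terminal_h: Optional[float] = None
    fusion_h: Optional[float] = None


@dataclass
class CellTrack:
    """One cell's trajectory.

    ``frames`` are 0-based and strictly increasing; ``t_hours`` counts from
    treatment time. ``actin_stats``, when present, is an (n_frames, 5)
    array in :data:`ACTIN_CHANNELS` order.
    """

    cell_id: str
    frames: np.ndarray  # (n,) int
    t_hours: np.ndarray  # (n,) float
    xy_um: np.ndarray  # (n, 2) float
    condition: str = "custom"
    actin_stats: Optional[np.ndarray] = None  # (n, 5)
    fusion_time_hours: Optional[float] = None
    truth: Optional[SimCellTruth] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.t_hours = np.asarray(self.t_hours, dtype=float)
        self.xy_um = np.asarray(self.xy_um, dtype=float)
        n = len(self.frames)
        if self.t_hours.shape != (n,) or self.xy_um.shape != (n, 2):
            raise IntegrityError(f"track {self.cell_id}: misaligned arrays")
        if n > 1:
            if not np.all(np.diff(self.frames) > 0):
                raise IntegrityError(f"track {self.cell_id}: frames not strictly increasing")
            if not np.all(np.diff(self.t_hours) > 0):
                raise IntegrityError(f"track {self.cell_id}: t_hours not strictly increasing")
        if self.actin_stats is not None:
            self.actin_stats = np.asarray(self.actin_stats, dtype=float)
            if self.actin_stats.shape != (n, 5):
                raise IntegrityError(
                    f"track {self.cell_id}: actin_stats not aligned with frames"
                )
        if self.condition not in CONDITIONS:
            raise IntegrityError(
                f"track {self.cell_id}: unknown condition {self.condition!r}"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def is_gap_free(self) -> bool:
        return self.n_frames < 2 or bool(np.all(np.diff(self.frames) == 1))


@dataclass
class TrackSet:
    """A collection of tracks sharing one pipeline configuration."""

    tracks: List[CellTrack]
    config: PipelineConfig = field(default_factory=PipelineConfig)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [t.cell_id for t in self.tracks]
        if len(set(ids)) != len(ids):
            raise IntegrityError("duplicate cell_id in TrackSet")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def by_id(self) -> Dict[str, CellTrack]:
        return {t.cell_id: t for t in self.tracks}

    def by_condition(self, condition: str) -> "TrackSet":
        return TrackSet(
            [t for t in self.tracks if t.condition == condition],
            config=self.config,
            provenance=self.provenance,
        )

    @property
    def n_frames_max(self) -> int:
        return max((int(t.frames[-1]) + 1 for t in self.tracks), default=0)


def read_tracks(path: str | Path, config: Optional[PipelineConfig] = None) -> TrackSet:
    """Read a track CSV into a :class:`TrackSet`.

    Required columns: cell_id, frame, x_um, y_um. Optional: t_hours
    (derived from frame index when absent), condition, actin_min/.../std.
    Rows may arrive in any order; they are sorted by (cell_id, frame).
    """
    config = config or PipelineConfig()
    df = pd.read_csv(path)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    if df.duplicated(subset=["cell_id", "frame"]).any():
        dup = df[df.duplicated(subset=["cell_id", "frame"])].iloc[0]
        raise IntegrityError(
            f"duplicate (cell_id, frame) = ({dup['cell_id']}, {dup['frame']})"
        )
    df = df.sort_values(["cell_id", "frame"], kind="mergesort")
    has_t = "t_hours" in df.columns
    has_actin = all(c in df.columns for c in _ACTIN_COLUMNS)
    has_cond = "condition" in df.columns

    tracks: List[CellTrack] = []
    for cell_id, g in df.groupby("cell_id", sort=True):
        frames = g["frame"].to_numpy(dtype=np.int64)
        t = (
            g["t_hours"].to_numpy(dtype=float)
            if has_t
            else frames * (config.frame_interval_min / 60.0)
        )
        xy = g[["x_um", "y_um"]].to_numpy(dtype=float)
        actin = g[list(_ACTIN_COLUMNS)].to_numpy(dtype=float) if has_actin else None
        cond = str(g["condition"].iloc[0]) if has_cond else "custom"
        tracks.append(
            CellTrack(
                cell_id=str(cell_id),
                frames=frames,
                t_hours=t,
                xy_um=xy,
                condition=cond,
                actin_stats=actin,
            )
        )
    return TrackSet(tracks, config=config, provenance=str(path))


def write_tracks(ts: TrackSet, path: str | Path) -> None:
    """Write a TrackSet to the track-CSV dialect read by :func:`read_tracks`."""
    rows = []
    for tr in ts.tracks:
        rec: Dict[str, np.ndarray] = {
            "cell_id": np.repeat(tr.cell_id, tr.n_frames),
            "frame": tr.frames,
            "t_hours": tr.t_hours,
            "x_um": tr.xy_um[:, 0],
            "y_um": tr.xy_um[:, 1],
            "condition": np.repeat(tr.condition, tr.n_frames),
        }
        if tr.actin_stats is not None:
            for j, c in enumerate(_ACTIN_COLUMNS):
                rec[c] = tr.actin_stats[:, j]
        rows.append(pd.DataFrame(rec))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_fusion_annotations(path: str | Path) -> pd.DataFrame:
    """Read a per-cell fusion-time table (columns cell_id, fusion_time_hours)."""
    df = pd.read_csv(path)
    for col in ("cell_id", "fusion_time_hours"):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    df["cell_id"] = df["cell_id"].astype(str)
    return df[["cell_id", "fusion_time_hours"]]


def attach_fusion_annotations(ts: TrackSet, fusion: pd.DataFrame) -> None:
    """Set fusion_time_hours on matching tracks in place."""
    lookup = dict(zip(fusion["cell_id"].astype(str), fusion["fusion_time_hours"]))
    for tr in ts.tracks:
        if tr.cell_id in lookup:
            tr.fusion_time_hours = float(lookup[tr.cell_id])


def read_offsets(path: str | Path) -> np.ndarray:
    """Read precomputed registration offsets (columns frame, dx_um, dy_um)."""
    df = pd.read_csv(path)
    for col in ("frame", "dx_um", "dy_um"):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    df = df.sort_values("frame")
    return df[["dx_um", "dy_um"]].to_numpy(dtype=float)


def estimate_frame_offsets(ts: TrackSet) -> np.ndarray:
    """Estimate per-frame stage-drift offsets from the tracks themselves.

    For each adjacent frame pair the offset increment is the median
    displacement over all cells present in both frames (robust to a
    minority of fast movers); increments are accumulated from frame 0, so
    ``offset[0] == (0, 0)`` and ``offset[k]`` is the cumulative drift of
    frame k relative to frame 0. Returns an (n_frames, 2) array.
    """
    n_frames = ts.n_frames_max
    if n_frames < 2:
        raise ValueError("need at least 2 frames to estimate offsets")
    # per frame: positions keyed by cell
    pos_by_frame: List[Dict[str, np.ndarray]] = [dict() for _ in range(n_frames)]
    for tr in ts.tracks:
        for i, f in enumerate(tr.frames):
            pos_by_frame[int(f)][tr.cell_id] = tr.xy_um[i]
    increments = np.zeros((n_frames, 2))
    for k in range(1, n_frames):
        shared = pos_by_frame[k].keys() & pos_by_frame[k - 1].keys()
        if not shared:
            raise ValueError(f"no cells shared between frames {k - 1} and {k}")
        disp = np.array([pos_by_frame[k][c] - pos_by_frame[k - 1][c] for c in shared])
        increments[k] = np.median(disp, axis=0)
    return np.cumsum(increments, axis=0)


def register_tracks(ts: TrackSet, offsets: np.ndarray) -> TrackSet:
    """Subtract per-frame offsets from every position; other fields unchanged."""
    offsets = np.asarray(offsets, dtype=float)
    n_frames = ts.n_frames_max
    if offsets.shape != (n_frames, 2):
        raise ValueError(
            f"offsets shape {offsets.shape} does not match frame count {n_frames}"
        )
    out = []
    for tr in ts.tracks:
        xy = tr.xy_um - offsets[tr.frames]
        out.append(replace(tr, xy_um=xy))
    return TrackSet(out, config=ts.config, provenance=ts.provenance)


def inject_drift(ts: TrackSet, drift_per_frame_um: Tuple[float, float]) -> TrackSet:
    """Add a rigid per-frame drift to every track (test/benchmark helper)."""
    d = np.asarray(drift_per_frame_um, dtype=float)
    out = []
    for tr in ts.tracks:
        xy = tr.xy_um + tr.frames[:, None] * d[None, :]
        out.append(replace(tr, xy_um=xy))
    return TrackSet(out, config=ts.config, provenance=ts.provenance)


def quantify_actin_window(
    frame_image: np.ndarray,
    center_um: Tuple[float, float],
    config: PipelineConfig,
) -> Tuple[float, float, float, float, float]:
    """Five summary statistics of intensity in a square window around a nucleus.

    The window side in pixels is ``round(actin_window_um / pixel_size_um)``
    (69 px at the defaults), centred on the nucleus pixel; windows
    extending past the image border are clipped, not discarded.

    Returns (min, max, mean, median, std) over the window's pixels.
    """
    img = np.asarray(frame_image)
    if img.ndim != 2:
        raise ValueError("frame_image must be 2D")
    h, w = img.shape
    cx = int(round(center_um[0] / config.pixel_size_um))
    cy = int(round(center_um[1] / config.pixel_size_um))
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"window center ({cx}, {cy}) px outside image {img.shape}")
    side = int(round(config.actin_window_um / config.pixel_size_um))
    half = side // 2
    x0, x1 = max(0, cx - half), min(w, cx + half + 1)
    y0, y1 = max(0, cy - half), min(h, cy + half + 1)
    win = img[y0:y1, x0:x1]
    if win.size == 0:
        raise ValueError("empty actin quantification window")
    return (
        float(win.min()),
        float(win.max()),
        float(win.mean()),
        float(np.median(win)),
        float(win.std()),
    )
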
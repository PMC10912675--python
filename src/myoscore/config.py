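"""Shared pipeline configuration.

All spatial quantities are in micrometres, times in hours unless a field
name says otherwise. Time zero is the moment of treatment; imaging
typically starts later (the track tables carry absolute ``t_hours``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Tuple

import yaml


@dataclass
class PipelineConfig:
    """Constants shared by every pipeline stage.

    Parameters
    ----------
    frame_interval_min
        Minutes between consecutive frames.
    pixel_size_um
        Micrometres per pixel of the raw images (used only when
        quantifying actin windows from images).
    segment_len_frames
        Frames per temporal segment. 31 frames at 5-minute sampling span
        2.5 h including both endpoints; the per-segment displacement
        series then has 30 entries.
    segment_lag_frames
        Frames between consecutive segment starts (1 = fully overlapping
        sliding windows).
    actin_window_um
        Side of the square actin quantification window around a nucleus.
    density_radius_um
        Neighbourhood radius for the local-density baseline.
    onset_band
        Differentiation-score band whose longest run defines onset (the
        run's last time point).
    high_band
        Score band whose longest run defines the high stable point (the
        run's first time point).
    terminal_threshold
        Scores strictly above this define terminal differentiation (first
        point of the longest supra-threshold run).
    diff_window_hours
        Time window over which score-vs-time monotonicity (Spearman) is
        evaluated.
    label_window_hours
        Fixed fallback window for the "differentiated" training label when
        no first-fusion anchor is supplied.
    alpha
        Significance level for feature selection and RFT inference.
    rft_sigma_frames
        Gaussian smoothing width (in frames) applied to score
        trajectories before random-field inference.
    seed
        Seed for every stochastic pipeline stage (forest training,
        Monte-Carlo cluster inference).
    """

    frame_interval_min: float = 5.0
    pixel_size_um: float = 0.462
    segment_len_frames: int = 31
    segment_lag_frames: int = 1
    actin_window_um: float = 32.0
    density_radius_um: float = 50.0
    onset_band: Tuple[float, float] = (0.2, 0.3)
    high_band: Tuple[float, float] = (0.7, 0.8)
    terminal_threshold: float = 0.78
    diff_window_hours: Tuple[float, float] = (7.5, 14.5)
    label_window_hours: Tuple[float, float] = (12.3, 14.8)
    alpha: float = 0.05
    rft_sigma_frames: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.segment_len_frames < 2:
            raise ValueError("segment_len_frames must be >= 2")
        if not (1 <= self.segment_lag_frames <= self.segment_len_frames):
            raise ValueError("segment_lag_frames must be in [1, segment_len_frames]")
        if self.actin_window_um <= 0 or self.density_radius_um <= 0:
            raise ValueError("window/radius must be positive")
        for name in ("onset_band", "high_band", "diff_window_hours", "label_window_hours"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be a nondecreasing interval")
        if not (self.onset_band[1] < self.high_band[0] < self.terminal_threshold <= 1.0):
            raise ValueError(
                "bands must be ordered: onset_band max < high_band min < terminal_threshold <= 1"
            )
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.rft_sigma_frames < 0:
            raise ValueError("rft_sigma_frames must be nonnegative")

    @property
    def frame_interval_h(self) -> float:
        return self.frame_interval_min / 60.0

    @property
    def segment_len_hours(self) -> float:
        """Time spanned by one segment (first to last frame)."""
        return (self.segment_len_frames - 1) * self.frame_interval_h

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for k, v in data.items():
            if isinstance(v, tuple):
                data[k] = list(v)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for k, v in data.items():
            if isinstance(v, list):
                data[k] = tuple(v)
        return cls(**data)
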
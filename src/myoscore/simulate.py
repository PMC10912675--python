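"""Synthetic two-condition live-imaging experiments.

Generates tracked-cell tables with the statistical structure the scoring
pipeline assumes: a differentiating condition (ERKi-like) in which each
cell slows down, becomes more persistent and up-regulates its actin
signal across an individual [onset, terminal] transition and then fuses
~3 h after terminal differentiation, and a proliferating control
(DMSO-like) with permanently undifferentiated dynamics, flat actin and
ongoing cell divisions that drive local density up over time.

Motion is a persistent random walk: per frame the heading receives a
Gaussian increment with state-dependent width, and the step length is
Gaussian around a state-dependent mean speed. Motility parameters
interpolate linearly between the undifferentiated and differentiated
values across each cell's own transition, making the transition gradual
rather than switch-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .tracks import CellTrack, SimCellTruth, TrackSet


@dataclass
class SimConfig:
    """Generative parameters of the synthetic experiment.

    Speeds are mean step speeds in µm/min; heading widths are the per-frame
    standard deviation of the heading increment in radians; all times in
    hours. Imaging runs from ``imaging_start_h`` for ``duration_hours``.
    """

    n_cells_per_condition: int = 150
    duration_hours: float = 21.5
    imaging_start_h: float = 1.5
    frame_interval_min: float = 5.0
    field_um: Tuple[float, float] = (1500.0, 1500.0)
    speed_undiff_um_min: float = 0.8
    speed_diff_um_min: float = 0.3
    heading_sigma_undiff: float = 1.2
    heading_sigma_diff: float = 0.4
    onset_mean_h: float = 11.0
    onset_sd_h: float = 2.0
    duration_mean_h: float = 3.5
    duration_sd_h: float = 1.0
    actin_base: float = 100.0
    actin_fold: float = 1.8
    actin_noise_cv: float = 0.05
    fusion_gap_mean_h: float = 3.0
    fusion_gap_sd_h: float = 0.75
    division_rate_per_cell_h: float = 0.03
    daughter_offset_um: float = 12.0
    step_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_condition < 1:
            raise ValueError("n_cells_per_condition must be >= 1")
        if min(self.speed_undiff_um_min, self.speed_diff_um_min) <= 0:
            raise ValueError("speeds must be positive")
        for name in (
            "onset_sd_h",
            "duration_sd_h",
            "fusion_gap_sd_h",
            "actin_noise_cv",
            "division_rate_per_cell_h",
            "heading_sigma_undiff",
            "heading_sigma_diff",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.onset_mean_h + self.duration_mean_h >= self.imaging_end_h:
            raise ValueError("mean transition must complete inside the imaging window")

    @property
    def imaging_end_h(self) -> float:
        return self.imaging_start_h + self.duration_hours

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_hours * 60.0 / self.frame_interval_min)) + 1

    @property
    def times_h(self) -> np.ndarray:
        return self.imaging_start_h + np.arange(self.n_frames) * (
            self.frame_interval_min / 60.0
        )


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment.

    ``per_cell`` has columns cell_id, condition, onset_h, terminal_h,
    fusion_h (NaN where undefined); ``state`` maps cell_id to the per-frame
    differentiation state in [0, 1].
    """

    per_cell: pd.DataFrame
    state: Dict[str, np.ndarray] = field(default_factory=dict)


def _reflect(x: np.ndarray, hi: float) -> np.ndarray:
    """Fold coordinates into [0, hi] (reflective boundary)."""
    period = 2.0 * hi
    x = np.mod(x, period)
    return hi - np.abs(x - hi)


def _walk(
    rng: np.random.Generator,
    start: np.ndarray,
    speed_um_min: np.ndarray,
    heading_sigma: np.ndarray,
    dt_min: float,
    field_um: Tuple[float, float],
    step_cv: float,
) -> np.ndarray:
    """Persistent random walk with per-frame motion parameters.

    ``speed_um_min`` and ``heading_sigma`` have one entry per step
    (n_frames - 1). Returns (n_frames, 2) positions.
    """
    n_steps = len(speed_um_min)
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    theta = theta0 + np.cumsum(rng.standard_normal(n_steps) * heading_sigma)
    mean_step = speed_um_min * dt_min
    steps = np.clip(mean_step * (1.0 + step_cv * rng.standard_normal(n_steps)), 0.0, None)
    d = np.column_stack([steps * np.cos(theta), steps * np.sin(theta)])
    pos = start[None, :] + np.vstack([np.zeros(2), np.cumsum(d, axis=0)])
    pos[:, 0] = _reflect(pos[:, 0], field_um[0])
    pos[:, 1] = _reflect(pos[:, 1], field_um[1])
    return pos


def _actin_stats(
    rng: np.random.Generator, mean: np.ndarray, cv: float
) -> np.ndarray:
    """Five consistent window statistics (min,max,mean,median,std) per frame."""
    n = len(mean)
    m = mean * (1.0 + cv * rng.standard_normal(n))
    m = np.clip(m, 1e-6, None)
    std = m * np.clip(0.10 + 0.01 * rng.standard_normal(n), 0.01, None)
    amin = np.clip(m * (0.78 + 0.02 * rng.standard_normal(n)), 0.0, None)
    amax = m * (1.25 + 0.03 * rng.standard_normal(n))
    amed = m * (0.97 + 0.01 * rng.standard_normal(n))
    amax = np.maximum(amax, np.maximum(m, amed) + 1e-9)
    amin = np.minimum(amin, np.minimum(m, amed) - 1e-9)
    return np.column_stack([amin, amax, m, amed, std])


def _sigmoid_actin(sim: SimConfig, t: np.ndarray, onset: float, duration: float) -> np.ndarray:
    """Mean actin curve: logistic rise from base to base*fold across the transition."""
    # slope puts ~90% of the rise inside [onset, onset + duration]
    k = 2.0 * np.log(9.0) / max(duration, 1e-6)
    center = onset + duration / 2.0
    frac = 1.0 / (1.0 + np.exp(-k * (t - center)))
    return sim.actin_base * (1.0 + (sim.actin_fold - 1.0) * frac)


def simulate_experiment(sim: SimConfig) -> Tuple[TrackSet, SimTruth]:
    """Generate one two-condition experiment.

    Returns the track table (conditions "ERKi" and "DMSO") and the ground
    truth. Identical ``sim`` (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(sim.seed)
    t = sim.times_h
    n_frames = sim.n_frames
    frames = np.arange(n_frames, dtype=np.int64)
    dt_min = sim.frame_interval_min
    dt_h = dt_min / 60.0

    tracks: List[CellTrack] = []
    truth_rows: List[dict] = []
    states: Dict[str, np.ndarray] = {}

    # --- differentiating condition -------------------------------------
    for i in range(sim.n_cells_per_condition):
        cid = f"ERKi_{i:04d}"
        onset = float(
            np.clip(rng.normal(sim.onset_mean_h, sim.onset_sd_h), sim.imaging_start_h + 0.5, None)
        )
        duration = float(np.clip(rng.normal(sim.duration_mean_h, sim.duration_sd_h), 0.5, None))
        terminal = onset + duration
        fusion = terminal + float(
            np.clip(rng.normal(sim.fusion_gap_mean_h, sim.fusion_gap_sd_h), 0.1, None)
        )
        state = np.clip((t - onset) / duration, 0.0, 1.0)
        states[cid] = state

        # motion parameters per step (state at the step's starting frame)
        s = state[:-1]
        speed = sim.speed_undiff_um_min + (sim.speed_diff_um_min - sim.speed_undiff_um_min) * s
        sigma = sim.heading_sigma_undiff + (sim.heading_sigma_diff - sim.heading_sigma_undiff) * s
        fused = t[:-1] >= fusion
        speed = np.where(fused, 0.02, speed)
        start = rng.uniform([0.0, 0.0], list(sim.field_um))
        xy = _walk(rng, start, speed, sigma, dt_min, sim.field_um, sim.step_cv)

        actin_mean = _sigmoid_actin(sim, t, onset, duration)
        actin = _actin_stats(rng, actin_mean, sim.actin_noise_cv)

        truth = SimCellTruth(onset_h=onset, terminal_h=terminal, fusion_h=fusion)
        fusion_obs = fusion if fusion <= sim.imaging_end_h else None
        tracks.append(
            CellTrack(
                cell_id=cid,
                frames=frames,
                t_hours=t,
                xy_um=xy,
                condition="ERKi",
                actin_stats=actin,
                fusion_time_hours=fusion_obs,
                truth=truth,
            )
        )
        truth_rows.append(
            dict(cell_id=cid, condition="ERKi", onset_h=onset, terminal_h=terminal, fusion_h=fusion)
        )

    # --- proliferating control ------------------------------------------
    # queue of (cell_id, start_frame, start_xy); daughters may divide again
    n_daughters = 0
    queue: List[Tuple[str, int, np.ndarray]] = []
    for i in range(sim.n_cells_per_condition):
        queue.append((f"DMSO_{i:04d}", 0, rng.uniform([0.0, 0.0], list(sim.field_um))))
    while queue:
        cid, f0, start = queue.pop(0)
        n_sub = n_frames - f0
        if n_sub < 2:
            continue
        n_steps = n_sub - 1
        speed = np.full(n_steps, sim.speed_undiff_um_min)
        sigma = np.full(n_steps, sim.heading_sigma_undiff)
        xy = _walk(rng, start, speed, sigma, dt_min, sim.field_um, sim.step_cv)
        actin_mean = np.full(n_sub, sim.actin_base)
        actin = _actin_stats(rng, actin_mean, sim.actin_noise_cv)
        sub_frames = frames[f0:]
        tracks.append(
            CellTrack(
                cell_id=cid,
                frames=sub_frames,
                t_hours=t[f0:],
                xy_um=xy,
                condition="DMSO",
                actin_stats=actin,
                truth=SimCellTruth(),
            )
        )
        states[cid] = np.zeros(n_sub)
        truth_rows.append(
            dict(cell_id=cid, condition="DMSO", onset_h=np.nan, terminal_h=np.nan, fusion_h=np.nan)
        )
        # division events: Poisson process over the track's lifetime
        if sim.division_rate_per_cell_h > 0:
            tau = t[f0]
            while True:
                tau += rng.exponential(1.0 / sim.division_rate_per_cell_h)
                if tau >= t[-1] - dt_h:
                    break
                fd = int(np.ceil((tau - sim.imaging_start_h) / dt_h))
                fd = min(max(fd, f0 + 1), n_frames - 1)
                phi = rng.uniform(0.0, 2.0 * np.pi)
                dpos = sim.daughter_offset_um * np.array([np.cos(phi), np.sin(phi)])
                child = xy[fd - f0] + dpos
                child[0] = _reflect(child[:1], sim.field_um[0])[0]
                child[1] = _reflect(child[1:], sim.field_um[1])[0]
                n_daughters += 1
                queue.append((f"{cid}.d{n_daughters:04d}", fd, child))

    truth = SimTruth(per_cell=pd.DataFrame(truth_rows), state=states)
    cfg = PipelineConfig(frame_interval_min=sim.frame_interval_min)
    return TrackSet(tracks, config=cfg, provenance=f"simulate_experiment(seed={sim.seed})"), truth


def render_actin_frames(
    ts: TrackSet,
    sim: SimConfig,
    pixel_size_um: Optional[float] = None,
    blob_sigma_um: float = 8.0,
    background: float = 10.0,
    background_noise_sd: float = 1.0,
    frames: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Render per-frame intensity images of Gaussian blobs at cell positions.

    Each cell contributes an isotropic Gaussian (sigma ``blob_sigma_um``)
    whose peak amplitude equals the cell's generative actin mean at that
    frame, on top of uniform background with Gaussian noise. A fixture for
    the window-quantification path; not a microscopy simulation.
    """
    px = pixel_size_um if pixel_size_um is not None else ts.config.pixel_size_um
    w_px = int(round(sim.field_um[0] / px))
    h_px = int(round(sim.field_um[1] / px))
    sigma_px = blob_sigma_um / px
    if min(sim.field_um) < 4.0 * blob_sigma_um:
        raise ValueError("field too small to support the blob footprint")
    frame_ids = np.arange(sim.n_frames) if frames is None else np.asarray(frames)
    rng = np.random.default_rng(sim.seed if seed is None else seed)
    stack = np.empty((len(frame_ids), h_px, w_px), dtype=np.float32)
    support = int(np.ceil(4.0 * sigma_px))
    for out_i, f in enumerate(frame_ids):
        img = background + background_noise_sd * rng.standard_normal((h_px, w_px))
        for tr in ts.tracks:
            idx = np.searchsorted(tr.frames, f)
            if idx >= tr.n_frames or tr.frames[idx] != f:
                continue
            if tr.actin_stats is None:
                raise ValueError(f"track {tr.cell_id} carries no actin means")
            amp = tr.actin_stats[idx, 2]
            cx = tr.xy_um[idx, 0] / px
            cy = tr.xy_um[idx, 1] / px
            x0, x1 = max(0, int(cx) - support), min(w_px, int(cx) + support + 1)
            y0, y1 = max(0, int(cy) - support), min(h_px, int(cy) + support + 1)
            if x0 >= x1 or y0 >= y1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            img[y0:y1, x0:x1] += amp * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma_px**2)
            )
        stack[out_i] = img
    return stack
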
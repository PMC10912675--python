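"""Single-cell state timing from differentiation-score trajectories.

All timing estimators are run-length rules on the score trajectory:

* onset — last time point of the longest run of scores inside the onset
  band (default [0.2, 0.3], inclusive);
* high stable point — first time point of the longest run inside the
  high band (default [0.7, 0.8], inclusive);
* differentiation duration — high stable point minus onset;
* terminal differentiation — first time point of the longest run of
  scores strictly above the terminal threshold (default 0.78); the
  longest-run rule discards isolated score peaks.

Ties between equal-length runs are broken toward the earliest run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import ScoreTrajectory
from .config import PipelineConfig

logger = logging.getLogger(__name__)


@dataclass
class StateTiming:
    """Per-cell timing estimates (hours; None where undefined)."""

    cell_id: str
    onset_h: Optional[float] = None
    high_stable_h: Optional[float] = None
    duration_h: Optional[float] = None
    terminal_h: Optional[float] = None
    rho_time: Optional[float] = None
    rho_p: Optional[float] = None


def longest_run(
    values: Sequence[float], predicate: Callable[[float], bool]
) -> Optional[Tuple[int, int]]:
    """(start, end) indices (inclusive) of the longest run where ``predicate``
    holds; earliest run wins ties; None if no value qualifies."""
    best: Optional[Tuple[int, int]] = None
    best_len = 0
    start: Optional[int] = None
    values = list(values)
    for i, v in enumerate(values):
        if predicate(v):
            if start is None:
                start = i
        else:
            if start is not None and i - start > best_len:
                best, best_len = (start, i - 1), i - start
            start = None
    if start is not None and len(values) - start > best_len:
        best = (start, len(values) - 1)
    return best


def _longest_run_mask(mask: np.ndarray) -> Optional[Tuple[int, int]]:
    return longest_run(mask.astype(bool), lambda v: bool(v))


def detect_onset(st: ScoreTrajectory, config: Optional[PipelineConfig] = None) -> Optional[float]:
    """Onset: last time of the longest run of scores inside the onset band."""
    config = config or PipelineConfig()
    lo, hi = config.onset_band
    run = _longest_run_mask((st.scores >= lo) & (st.scores <= hi))
    return float(st.t_hours[run[1]]) if run else None


def detect_high_stable(
    st: ScoreTrajectory, config: Optional[PipelineConfig] = None
) -> Optional[float]:
    """High stable point: first time of the longest run inside the high band."""
    config = config or PipelineConfig()
    lo, hi = config.high_band
    run = _longest_run_mask((st.scores >= lo) & (st.scores <= hi))
    return float(st.t_hours[run[0]]) if run else None


def differentiation_duration(
    st: ScoreTrajectory, config: Optional[PipelineConfig] = None
) -> Optional[float]:
    """Hours between onset and the high stable point; None if either is
    missing or the high run precedes the onset run."""
    onset = detect_onset(st, config)
    high = detect_high_stable(st, config)
    if onset is None or high is None:
        return None
    if high < onset:
        logger.info("cell %s: high stable run precedes onset run; duration undefined", st.cell_id)
        return None
    return high - onset


def terminal_time(
    st: ScoreTrajectory, config: Optional[PipelineConfig] = None
) -> Optional[float]:
    """Terminal differentiation: first time of the longest run of scores
    strictly above the terminal threshold."""
    config = config or PipelineConfig()
    run = _longest_run_mask(st.scores > config.terminal_threshold)
    return float(st.t_hours[run[0]]) if run else None


def score_time_correlation(
    st: ScoreTrajectory, config: Optional[PipelineConfig] = None
) -> Optional[Tuple[float, float]]:
    """Spearman (rho, p) between score and time inside the differentiation
    window; None (flagged) with fewer than 3 points in the window."""
    config = config or PipelineConfig()
    lo, hi = config.diff_window_hours
    m = (st.t_hours >= lo) & (st.t_hours <= hi)
    if m.sum() < 3:
        logger.info("cell %s: <3 score points in the correlation window", st.cell_id)
        return None
    with warnings.catch_warnings():
        # constant trajectories are mapped to (0, 1) below
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        res = stats.spearmanr(st.t_hours[m], st.scores[m])
    rho = float(res.statistic)
    if not np.isfinite(rho):  # constant scores: no monotone association
        return (0.0, 1.0)
    return (rho, float(res.pvalue))


def state_timing(st: ScoreTrajectory, config: Optional[PipelineConfig] = None) -> StateTiming:
    """All timing estimates for one trajectory."""
    rho = score_time_correlation(st, config)
    return StateTiming(
        cell_id=st.cell_id,
        onset_h=detect_onset(st, config),
        high_stable_h=detect_high_stable(st, config),
        duration_h=differentiation_duration(st, config),
        terminal_h=terminal_time(st, config),
        rho_time=rho[0] if rho else None,
        rho_p=rho[1] if rho else None,
    )


def timings_frame(
    trajectories: Sequence[ScoreTrajectory], config: Optional[PipelineConfig] = None
) -> pd.DataFrame:
    """StateTiming table for a batch of trajectories."""
    rows = [state_timing(st, config).__dict__ for st in trajectories]
    return pd.DataFrame(rows)


def fusion_coupling(
    timings: pd.DataFrame, fusion: pd.DataFrame
) -> Dict[str, float]:
    """Couple terminal-differentiation estimates to annotated fusion times.

    ``timings`` needs columns cell_id and terminal_h; ``fusion`` needs
    cell_id and fusion_time_hours. Returns the per-cell gap median,
    Pearson r and p between terminal and fusion times, and D'Agostino
    K-squared normality p-values for the terminal, fusion and gap
    distributions.
    """
    merged = timings.merge(
        fusion.rename(columns={"fusion_time_hours": "fusion_h"}), on="cell_id"
    ).dropna(subset=["terminal_h", "fusion_h"])
    n = len(merged)
    if n < 3:
        raise ValueError(f"need >= 3 cells with both terminal and fusion times (got {n})")
    term = merged["terminal_h"].to_numpy(dtype=float)
    fus = merged["fusion_h"].to_numpy(dtype=float)
    gap = fus - term
    r, p = stats.pearsonr(term, fus)

    def _norm_p(x: np.ndarray) -> float:
        if len(x) < 8 or np.ptp(x) == 0:  # normaltest needs n >= 8
            return float("nan")
        return float(stats.normaltest(x).pvalue)

    return dict(
        n_cells=float(n),
        gap_median_h=float(np.median(gap)),
        terminal_median_h=float(np.median(term)),
        fusion_median_h=float(np.median(fus)),
        pearson_r=float(r),
        pearson_p=float(p),
        normality_p_terminal=_norm_p(term),
        normality_p_fusion=_norm_p(fus),
        normality_p_gap=_norm_p(gap),
    )
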
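"""End-to-end study driver: simulate, train, score, and summarize.

Bundles the full synthetic-study workflow — generate independent train
and test experiments, train the state classifiers, score the test
trajectories and derive timing/monotonicity summaries — so that scripts
and analyses run the identical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import (
    ModelBundle,
    ScoreTrajectory,
    evaluate,
    score_trajectories,
    train_classifier,
)
from .config import PipelineConfig
from .features import extract_feature_matrix
from .segments import assign_training_labels, make_segments
from .simulate import SimConfig, SimTruth, simulate_experiment
from .tracks import TrackSet

ALL_MODES = ("motility", "actin", "combined")


@dataclass
class StudyResult:
    """Everything produced by one synthetic train/test study."""

    config: PipelineConfig
    ts_train: TrackSet
    ts_test: TrackSet
    truth_train: SimTruth
    truth_test: SimTruth
    labeled_train: list
    labeled_test: list
    bundles: Dict[str, ModelBundle]
    heldout_metrics: Dict[str, Dict[str, float]]
    trajectories: Dict[str, List[ScoreTrajectory]]

    def diff_trajectories(self, mode: str) -> List[ScoreTrajectory]:
        return [st for st in self.trajectories[mode] if st.condition == "ERKi"]

    def control_trajectories(self, mode: str, min_len: int = 3) -> List[ScoreTrajectory]:
        return [
            st
            for st in self.trajectories[mode]
            if st.condition == "DMSO" and len(st) >= min_len
        ]


def run_study(
    n_cells: int = 150,
    seed: int = 0,
    modes: Sequence[str] = ALL_MODES,
    config: Optional[PipelineConfig] = None,
    sim_kwargs: Optional[dict] = None,
) -> StudyResult:
    """Run the full synthetic study: independent train/test experiments,
    classifier training per mode, and test-set score trajectories.

    Train and test seeds are derived from ``seed`` so the two experiments
    never share randomness.
    """
    config = config or PipelineConfig(seed=seed)
    kw = dict(sim_kwargs or {})
    kw["n_cells_per_condition"] = n_cells
    seed_train = (2 * seed + 1) % (2**31)
    seed_test = (2 * seed + 2) % (2**31)
    ts_train, truth_train = simulate_experiment(SimConfig(**kw, seed=seed_train))
    ts_test, truth_test = simulate_experiment(SimConfig(**kw, seed=seed_test))
    labeled_train = assign_training_labels(make_segments(ts_train, config), config=config)
    labeled_test = assign_training_labels(make_segments(ts_test, config), config=config)
    y_train = np.array([s.label for s in labeled_train])
    y_test = np.array([s.label for s in labeled_test])

    bundles: Dict[str, ModelBundle] = {}
    heldout: Dict[str, Dict[str, float]] = {}
    trajs: Dict[str, List[ScoreTrajectory]] = {}
    for mode in modes:
        fm_train = extract_feature_matrix(labeled_train, mode)
        bundle = train_classifier(fm_train, y_train, mode=mode, seed=seed, config=config)
        heldout[mode] = evaluate(bundle, extract_feature_matrix(labeled_test, mode), y_test)
        trajs[mode] = score_trajectories(bundle, ts_test, config)
        bundles[mode] = bundle
    return StudyResult(
        config=config,
        ts_train=ts_train,
        ts_test=ts_test,
        truth_train=truth_train,
        truth_test=truth_test,
        labeled_train=labeled_train,
        labeled_test=labeled_test,
        bundles=bundles,
        heldout_metrics=heldout,
        trajectories=trajs,
    )


def timing_recovery(study: StudyResult, mode: str = "motility") -> Dict[str, float]:
    """Compare estimated per-cell timings against the simulator's truth.

    Returns medians of absolute onset/terminal errors, the median
    estimated duration, the median estimated-terminal-to-true-fusion gap,
    and the Pearson correlation between estimated terminal and true
    fusion times, over the test experiment's differentiating cells.
    """
    from .metrics import timings_frame

    tim = timings_frame(study.diff_trajectories(mode), study.config).set_index("cell_id")
    truth = study.truth_test.per_cell.set_index("cell_id").loc[tim.index]
    onset_err = (tim["onset_h"] - truth["onset_h"]).abs()
    term_err = (tim["terminal_h"] - truth["terminal_h"]).abs()
    gap = truth["fusion_h"] - tim["terminal_h"]
    ok = tim["terminal_h"].notna()
    r, p = stats.pearsonr(tim.loc[ok, "terminal_h"], truth.loc[ok, "fusion_h"])
    return dict(
        onset_abs_err_median_h=float(onset_err.median()),
        terminal_abs_err_median_h=float(term_err.median()),
        duration_median_h=float(tim["duration_h"].median()),
        fusion_gap_median_h=float(gap.median()),
        pearson_terminal_fusion=float(r),
        n_cells=int(len(tim)),
        frac_onset_defined=float(tim["onset_h"].notna().mean()),
        frac_terminal_defined=float(tim["terminal_h"].notna().mean()),
    )


def monotonicity_summary(study: StudyResult, mode: str) -> Dict[str, float]:
    """Median per-cell Spearman(score, time) in the differentiation window,
    for differentiating and control cells of the test experiment."""
    from .metrics import timings_frame

    diff = timings_frame(study.diff_trajectories(mode), study.config)
    ctrl = timings_frame(study.control_trajectories(mode), study.config)
    return dict(
        rho_median_diff=float(diff["rho_time"].median()),
        rho_median_control=float(ctrl["rho_time"].median()),
        n_diff=int(diff["rho_time"].notna().sum()),
        n_control=int(ctrl["rho_time"].notna().sum()),
    )
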
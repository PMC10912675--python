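"""Random-forest state classifiers and differentiation-score trajectories.

The classifier's class probability for the "differentiated" class — the
fraction of trees voting for it — is used directly as a continuous
differentiation score in [0, 1]. No probability calibration is applied:
the downstream estimators rely on the score's monotonicity along a
cell's transition, not on its linearity.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .config import PipelineConfig
from .features import ByFeatureSelector, extract_feature_matrix, segment_metadata
from .segments import LABEL_DIFF, TemporalSegment, make_segments
from .tracks import CellTrack, TrackSet

#: default hyperparameter grid: the optima reported for the motility and
#: actin models plus their cross-combinations as neighbours
DEFAULT_GRID: Dict[str, list] = {
    "max_depth": [12, 20],
    "min_samples_leaf": [1],
    "n_estimators": [100, 200],
}


@dataclass
class ScoreTrajectory:
    """Per-cell time-indexed differentiation scores.

    One score per lag-1 temporal segment, timestamped at the segment's
    final frame (the time the score becomes available).
    """

    cell_id: str
    t_hours: np.ndarray
    scores: np.ndarray
    condition: str = "custom"

    def __post_init__(self) -> None:
        self.t_hours = np.asarray(self.t_hours, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.t_hours.shape != self.scores.shape:
            raise ValueError("t_hours and scores misaligned")
        if len(self.t_hours) > 1 and not np.all(np.diff(self.t_hours) > 0):
            raise ValueError("trajectory times must be strictly increasing")
        if len(self.scores) and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)


class DifferentiationStateClassifier(BaseEstimator, ClassifierMixin):
    """Grid-searched random forest over selected temporal features.

    fit(X, y) takes a feature matrix (DataFrame from
    :func:`myoscore.features.extract_feature_matrix`) and binary labels
    (1/"differentiated" = positive). Feature selection
    (Mann-Whitney U + Benjamini-Yekutieli) runs inside fit; the forest's
    hyperparameters are chosen by grid search maximizing cross-validated
    ROC AUC with stratified folds, then refit on all data.

    Fitted attributes: ``selector_``, ``selected_features_``, ``forest_``,
    ``best_params_``, ``cv_auc_``, ``classes_``.
    """

    def __init__(
        self,
        mode: str = "combined",
        param_grid: Optional[Dict[str, list]] = None,
        cv_folds: int = 5,
        alpha: float = 0.05,
        select: bool = True,
        seed: int = 0,
    ):
        self.mode = mode
        self.param_grid = param_grid
        self.cv_folds = cv_folds
        self.alpha = alpha
        self.select = select
        self.seed = seed

    @staticmethod
    def _binarize(y) -> np.ndarray:
        y = np.asarray(y)
        if y.dtype.kind in "UOS":
            return (y == LABEL_DIFF).astype(int)
        return y.astype(int)

    def fit(self, X: pd.DataFrame, y) -> "DifferentiationStateClassifier":
        X = pd.DataFrame(X)
        yb = self._binarize(y)
        if len(np.unique(yb)) != 2:
            raise ValueError("both classes must be present for training")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if np.bincount(yb).min() < self.cv_folds:
            raise ValueError(
                "stratification error: a class has fewer samples than cv folds"
            )
        if self.select:
            self.selector_ = ByFeatureSelector(alpha=self.alpha).fit(X, yb)
            Xs = self.selector_.transform(X)
            if Xs.shape[1] == 0:  # nothing survives FDR: fall back to all features
                Xs = X
                self.selector_ = None
        else:
            self.selector_ = None
            Xs = X
        self.selected_features_ = list(Xs.columns)

        grid = self.param_grid if self.param_grid is not None else DEFAULT_GRID
        cv = StratifiedKFold(n_splits=self.cv_folds, shuffle=True, random_state=self.seed)
        search = GridSearchCV(
            RandomForestClassifier(random_state=self.seed),
            param_grid=grid,
            scoring="roc_auc",
            cv=cv,
            n_jobs=1,
            refit=True,
        )
        search.fit(Xs.values, yb)
        self.forest_ = search.best_estimator_
        self.best_params_ = dict(search.best_params_)
        self.cv_auc_ = float(search.best_score_)
        self.classes_ = self.forest_.classes_
        self.n_training_per_class_ = {
            int(c): int(n) for c, n in zip(*np.unique(yb, return_counts=True))
        }
        return self

    def _select(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        missing = [c for c in self.selected_features_ if c not in X.columns]
        if missing:
            raise ValueError(f"missing feature column {missing[0]!r}")
        return X[self.selected_features_].values

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.forest_.predict_proba(self._select(X))

    def predict_score(self, X: pd.DataFrame) -> np.ndarray:
        """Differentiation score: probability of the positive class."""
        proba = self.predict_proba(X)
        pos = int(np.where(self.classes_ == 1)[0][0])
        return proba[:, pos]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.forest_.predict(self._select(X))

    @property
    def feature_importances_(self) -> np.ndarray:
        return self.forest_.feature_importances_


@dataclass
class ModelBundle:
    """A trained classifier plus the metadata needed to reuse it."""

    model: DifferentiationStateClassifier
    mode: str
    selected_features: List[str]
    metadata: Dict[str, object] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "ModelBundle":
        return joblib.load(path)


def _config_hash(config: Optional[PipelineConfig]) -> str:
    payload = json.dumps(
        (config or PipelineConfig()).__dict__, sort_keys=True, default=str
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def train_classifier(
    fm: pd.DataFrame,
    y,
    mode: str = "combined",
    grid: Optional[Dict[str, list]] = None,
    cv_folds: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
    select: bool = True,
    config: Optional[PipelineConfig] = None,
) -> ModelBundle:
    """Train a state classifier on a labeled feature matrix."""
    model = DifferentiationStateClassifier(
        mode=mode, param_grid=grid, cv_folds=cv_folds, alpha=alpha, select=select, seed=seed
    ).fit(fm, y)
    meta = dict(
        config_hash=_config_hash(config),
        seed=seed,
        counts_per_class=model.n_training_per_class_,
        best_params=model.best_params_,
        cv_auc=model.cv_auc_,
    )
    return ModelBundle(model=model, mode=mode, selected_features=model.selected_features_, metadata=meta)


def predict_scores(bundle: ModelBundle, fm: pd.DataFrame) -> np.ndarray:
    """Differentiation score per feature-matrix row."""
    return bundle.model.predict_score(fm)


def score_trajectories(
    bundle: ModelBundle,
    ts: TrackSet,
    config: Optional[PipelineConfig] = None,
) -> List[ScoreTrajectory]:
    """Score every track of a set in one batched pass.

    Tracks shorter than the segment length yield empty trajectories.
    """
    config = config or ts.config
    segments = make_segments(ts, config)
    cond = {t.cell_id: t.condition for t in ts.tracks}
    if not segments:
        return [ScoreTrajectory(t.cell_id, [], [], t.condition) for t in ts.tracks]
    fm = extract_feature_matrix(segments, bundle.mode)
    scores = predict_scores(bundle, fm)
    t_end = np.array([s.t_end_h for s in segments])
    ids = np.array([s.cell_id for s in segments])
    # segments are emitted per track in time order: locate contiguous blocks
    change = np.flatnonzero(ids[1:] != ids[:-1]) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [len(ids)]])
    blocks = {ids[a]: (a, b) for a, b in zip(starts, stops)}
    out: List[ScoreTrajectory] = []
    for tr in ts.tracks:
        a, b = blocks.get(tr.cell_id, (0, 0))
        out.append(
            ScoreTrajectory(tr.cell_id, t_end[a:b], scores[a:b], cond[tr.cell_id])
        )
    return out


def score_trajectory(
    bundle: ModelBundle,
    track: CellTrack,
    config: Optional[PipelineConfig] = None,
) -> ScoreTrajectory:
    """Score one track: one score per lag-1 segment, stamped at segment end."""
    config = config or PipelineConfig()
    ts = TrackSet([track], config=config)
    return score_trajectories(bundle, ts, config)[0]


def evaluate(bundle: ModelBundle, fm: pd.DataFrame, y) -> Dict[str, float]:
    """Binary metrics (AUC by score ranking; others at threshold 0.5)."""
    yb = DifferentiationStateClassifier._binarize(y)
    if len(np.unique(yb)) < 2:
        raise ValueError("AUC undefined: evaluation set has a single class")
    s = predict_scores(bundle, fm)
    pred = (s >= 0.5).astype(int)
    return dict(
        auc=float(roc_auc_score(yb, s)),
        accuracy=float(accuracy_score(yb, pred)),
        precision=float(precision_score(yb, pred, zero_division=0)),
        recall=float(recall_score(yb, pred, zero_division=0)),
    )


def auc_over_time(
    bundle: ModelBundle,
    ts: TrackSet,
    config: Optional[PipelineConfig] = None,
    positive_condition: str = "ERKi",
    negative_condition: str = "DMSO",
) -> pd.DataFrame:
    """AUC of condition discrimination at each segment-end time.

    At each time, the AUC is computed over all segments ending there with
    the experimental condition as ground truth; times where only one
    condition is present are omitted.
    """
    config = config or ts.config
    segments = [
        s
        for s in make_segments(ts, config)
        if s.condition in (positive_condition, negative_condition)
    ]
    if not segments:
        return pd.DataFrame(columns=["t_hours", "auc", "n"])
    fm = extract_feature_matrix(segments, bundle.mode)
    scores = predict_scores(bundle, fm)
    meta = segment_metadata(segments)
    meta["score"] = scores
    meta["y"] = (meta["condition"] == positive_condition).astype(int)
    rows = []
    for t, g in meta.groupby("t_end_h", sort=True):
        if g["y"].nunique() < 2:
            continue
        rows.append(dict(t_hours=float(t), auc=float(roc_auc_score(g["y"], g["score"])), n=len(g)))
    return pd.DataFrame(rows)


def feature_importance(bundle: ModelBundle) -> List[Tuple[str, float]]:
    """Impurity-based importances, descending (they sum to 1)."""
    if not hasattr(bundle.model, "forest_"):
        raise ValueError("model is not fitted")
    imp = bundle.model.feature_importances_
    pairs = sorted(zip(bundle.selected_features, imp), key=lambda kv: -kv[1])
    return [(name, float(v)) for name, v in pairs]
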
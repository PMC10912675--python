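"""Temporal feature catalog and FDR-controlled feature selection.

Each temporal segment contributes one fixed-length series per channel
(motility: dx, dy displacement components; actin: the five window
statistics). A fixed, explicitly named catalog of 30 scalar features is
computed per channel — descriptive statistics, change/derivative
summaries, autocorrelations, peak and run-length counts, linear trend,
and a complexity estimate — giving stable column names of the form
``<channel>__<feature>``. The catalog is deliberately explicit rather
than delegated to an external feature library so that column names and
values are reproducible across environments.

Feature selection tests each feature's class association with a
two-sample Mann–Whitney U test and keeps the features surviving the
Benjamini–Yekutieli step-up procedure, which controls the false
discovery rate under arbitrary dependence between features.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .segments import TemporalSegment

MODES = ("motility", "actin", "combined")

MOTILITY_CHANNELS = ("dx", "dy")
ACTIN_FEATURE_CHANNELS = (
    "actin_min",
    "actin_max",
    "actin_mean",
    "actin_median",
    "actin_std",
)

AUTOCORR_LAGS = (1, 2, 5, 10)
QUANTILES = (0.1, 0.25, 0.75, 0.9)

FEATURE_NAMES: Tuple[str, ...] = (
    "mean",
    "std",
    "median",
    "minimum",
    "maximum",
    "skewness",
    "kurtosis",
    "abs_energy",
    "mean_abs_change",
    "mean_change",
    "variance_first_diff",
    *(f"autocorr_lag_{l}" for l in AUTOCORR_LAGS),
    "n_peaks_support_3",
    "longest_run_above_mean",
    "longest_run_below_mean",
    "count_above_mean",
    "trend_slope",
    "trend_stderr",
    "complexity_ce",
    *(f"quantile_{int(q * 100):02d}" for q in QUANTILES),
    "first_loc_max",
    "last_loc_max",
    "first_loc_min",
    "last_loc_min",
)


def _longest_runs(mask: np.ndarray) -> np.ndarray:
    """Longest run of True per row of a boolean (n, T) matrix."""
    n, T = mask.shape
    run = np.zeros(n, dtype=np.int64)
    best = np.zeros(n, dtype=np.int64)
    for t in range(T):
        run = (run + 1) * mask[:, t]
        np.maximum(best, run, out=best)
    return best


def catalog_features(X: np.ndarray) -> Dict[str, np.ndarray]:
    """Compute the full catalog for a batch of series.

    Parameters
    ----------
    X : (n_series, T) array
        One series per row; T >= 2.

    Returns
    -------
    dict
        Feature name -> (n_series,) values, in :data:`FEATURE_NAMES` order.
        All values are finite: undefined quantities on degenerate series
        (constant series, short series vs. autocorrelation lag) are
        imputed as 0.
    """
    X = np.asarray(X, dtype=float)
    n, T = X.shape
    if T < 2:
        raise ValueError("series must have length >= 2")
    mu = X.mean(axis=1)
    sd = X.std(axis=1)
    diff = np.diff(X, axis=1)
    out: Dict[str, np.ndarray] = {}
    out["mean"] = mu
    out["std"] = sd
    out["median"] = np.median(X, axis=1)
    out["minimum"] = X.min(axis=1)
    out["maximum"] = X.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant rows trigger scipy's precision warning; they are imputed below
        warnings.simplefilter("ignore", RuntimeWarning)
        sk = stats.skew(X, axis=1, bias=True)
        ku = stats.kurtosis(X, axis=1, bias=True)
    out["skewness"] = np.where(np.isfinite(sk), sk, 0.0)
    out["kurtosis"] = np.where(np.isfinite(ku), ku, 0.0)
    out["abs_energy"] = np.einsum("ij,ij->i", X, X)
    out["mean_abs_change"] = np.abs(diff).mean(axis=1)
    out["mean_change"] = (X[:, -1] - X[:, 0]) / (T - 1)
    out["variance_first_diff"] = diff.var(axis=1) if T > 2 else np.zeros(n)

    var = sd**2
    xc = X - mu[:, None]
    for lag in AUTOCORR_LAGS:
        if T < lag + 2:
            out[f"autocorr_lag_{lag}"] = np.zeros(n)
            continue
        num = np.einsum("ij,ij->i", xc[:, :-lag], xc[:, lag:]) / (T - lag)
        with np.errstate(invalid="ignore", divide="ignore"):
            ac = num / var
        out[f"autocorr_lag_{lag}"] = np.where(var > 0, ac, 0.0)

    # peaks with support 3: strictly above the 3 left neighbours, at least
    # as high as the 3 right neighbours (a flat top counts its left edge)
    if T >= 7:
        peak = np.ones((n, T - 6), dtype=bool)
        center = X[:, 3 : T - 3]
        for k in range(1, 4):
            peak &= center > X[:, 3 - k : T - 3 - k]
            peak &= center >= X[:, 3 + k : T - 3 + k]
        out["n_peaks_support_3"] = peak.sum(axis=1).astype(float)
    else:
        out["n_peaks_support_3"] = np.zeros(n)

    above = X > mu[:, None]
    below = X < mu[:, None]
    out["longest_run_above_mean"] = _longest_runs(above).astype(float)
    out["longest_run_below_mean"] = _longest_runs(below).astype(float)
    out["count_above_mean"] = above.sum(axis=1).astype(float)

    t = np.arange(T, dtype=float)
    tc = t - t.mean()
    stt = float((tc**2).sum())
    slope = (xc @ tc) / stt
    resid = xc - slope[:, None] * tc[None, :]
    if T > 2:
        sse = np.einsum("ij,ij->i", resid, resid)
        stderr = np.sqrt(np.clip(sse, 0.0, None) / ((T - 2) * stt))
    else:
        stderr = np.zeros(n)
    out["trend_slope"] = slope
    out["trend_stderr"] = stderr
    out["complexity_ce"] = np.sqrt(np.einsum("ij,ij->i", diff, diff))

    qs = np.quantile(X, QUANTILES, axis=1)
    for qi, q in enumerate(QUANTILES):
        out[f"quantile_{int(q * 100):02d}"] = qs[qi]

    denom = float(T - 1)
    out["first_loc_max"] = X.argmax(axis=1) / denom
    out["last_loc_max"] = (T - 1 - X[:, ::-1].argmax(axis=1)) / denom
    out["first_loc_min"] = X.argmin(axis=1) / denom
    out["last_loc_min"] = (T - 1 - X[:, ::-1].argmin(axis=1)) / denom
    return out


def _channel_matrices(
    segments: Sequence[TemporalSegment], mode: str
) -> Dict[str, np.ndarray]:
    """Stack per-segment series into one (n_segments, T) matrix per channel."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    chans: Dict[str, np.ndarray] = {}
    if mode in ("motility", "combined"):
        mot = np.stack([s.motility_series for s in segments])  # (n, L-1, 2)
        chans["dx"] = mot[:, :, 0]
        chans["dy"] = mot[:, :, 1]
    if mode in ("actin", "combined"):
        missing = [s.cell_id for s in segments if s.actin_series is None]
        if missing:
            raise ValueError(
                f"actin features requested but segments of {missing[0]} carry no actin series"
            )
        act = np.stack([s.actin_series for s in segments])  # (n, L, 5)
        for j, name in enumerate(ACTIN_FEATURE_CHANNELS):
            chans[name] = act[:, :, j]
    return chans


def extract_feature_matrix(
    segments: Sequence[TemporalSegment], mode: str = "combined"
) -> pd.DataFrame:
    """Feature matrix for a batch of segments.

    Rows are indexed by (cell_id, start_frame); columns are
    ``<channel>__<feature>`` in a fixed, reproducible order. All values
    are finite.
    """
    if len(segments) == 0:
        raise ValueError("no segments given")
    chans = _channel_matrices(segments, mode)
    cols: Dict[str, np.ndarray] = {}
    for chan, X in chans.items():
        feats = catalog_features(X)
        for fname in FEATURE_NAMES:
            cols[f"{chan}__{fname}"] = feats[fname]
    index = pd.MultiIndex.from_arrays(
        [[s.cell_id for s in segments], [s.start_frame for s in segments]],
        names=["cell_id", "start_frame"],
    )
    return pd.DataFrame(cols, index=index)


def extract_features(segment: TemporalSegment, mode: str = "combined") -> pd.Series:
    """Feature record for a single segment (one row of the batch catalog)."""
    return extract_feature_matrix([segment], mode).iloc[0]


def segment_metadata(segments: Sequence[TemporalSegment]) -> pd.DataFrame:
    """Per-segment metadata aligned with :func:`extract_feature_matrix` rows."""
    return pd.DataFrame(
        dict(
            cell_id=[s.cell_id for s in segments],
            condition=[s.condition for s in segments],
            start_frame=[s.start_frame for s in segments],
            t_end_h=[s.t_end_h for s in segments],
            label=[s.label for s in segments],
        )
    )


def feature_pvalues(fm: pd.DataFrame, y: np.ndarray) -> pd.Series:
    """Per-feature two-sample Mann-Whitney U p-values (class 1 vs class 0)."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("feature selection needs exactly two classes")
    a = fm.values[y == classes[0]]
    b = fm.values[y == classes[1]]
    if min(len(a), len(b)) < 2:
        raise ValueError("need at least 2 samples per class")
    res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
    p = np.asarray(res.pvalue, dtype=float)
    p[~np.isfinite(p)] = 1.0  # degenerate (constant) features carry no signal
    return pd.Series(p, index=fm.columns)


def select_features(fm: pd.DataFrame, y: np.ndarray, alpha: float = 0.05) -> List[str]:
    """Names of features surviving Benjamini-Yekutieli FDR control at ``alpha``.

    The returned order follows the input column order (deterministic).
    ``alpha = 0`` selects nothing.
    """
    if alpha <= 0:
        return []
    p = feature_pvalues(fm, y)
    reject, _, _, _ = multipletests(p.values, alpha=alpha, method="fdr_by")
    return [c for c, r in zip(fm.columns, reject) if r]


class SegmentFeatureExtractor(BaseEstimator, TransformerMixin):
    """Stateless transformer: temporal segments -> feature matrix.

    Parameters
    ----------
    mode : {"motility", "actin", "combined"}
        Which channels enter the catalog.
    """

    def __init__(self, mode: str = "combined"):
        self.mode = mode

    def fit(self, X: Sequence[TemporalSegment], y=None) -> "SegmentFeatureExtractor":
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.n_features_out_ = len(FEATURE_NAMES) * (
            {"motility": 2, "actin": 5, "combined": 7}[self.mode]
        )
        return self

    def transform(self, X: Sequence[TemporalSegment]) -> pd.DataFrame:
        return extract_feature_matrix(X, self.mode)


class ByFeatureSelector(BaseEstimator, TransformerMixin):
    """Feature selector: Mann-Whitney U tests + Benjamini-Yekutieli FDR.

    Fitted attributes: ``pvalues_`` (per input column), ``support_``
    (boolean mask) and ``selected_features_`` (surviving column names).
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y) -> "ByFeatureSelector":
        X = pd.DataFrame(X)
        self.pvalues_ = feature_pvalues(X, np.asarray(y))
        self.selected_features_ = select_features(X, np.asarray(y), self.alpha)
        self.support_ = np.asarray(
            [c in set(self.selected_features_) for c in X.columns]
        )
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        missing = [c for c in self.selected_features_ if c not in X.columns]
        if missing:
            raise ValueError(f"missing feature column {missing[0]!r}")
        return X[self.selected_features_]
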
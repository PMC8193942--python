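"""Statistical summary feature set (76 named features per trial).

The feature vector summarizes one trial's oculomotor events and raw
channels in six families:

* fixation (9): count and the 8 distribution statistics of durations,
* saccade (20): count, duration and amplitude statistics, inter-saccade
  angle mean/sd, fixation:saccade time ratio,
* blink (9): count and duration statistics,
* pupil (5): mean/sd/median/min/max of the combined (two-eye mean) diameter,
* vergence (23): statistics of the horizontal disparity v(t) = left_x -
  right_x over the whole trial, during fixations only, and of successive
  sample-pair absolute differences (distance-dependent vergence features
  that would need screen/eye geometry are deliberately absent),
* spatial dispersion (10): minimal-enclosing-circle radius of the valid gaze
  points, total scanpath length, and the 8 gaze-speed statistics.

The 8 distribution statistics are mean, standard deviation, median, minimum,
maximum, range, kurtosis and skewness (population definitions; kurtosis is
excess kurtosis).  Undefined statistics over empty or degenerate event sets
are set to 0 — the corresponding count feature carries the information that
the set was empty.

The module also hosts z-score normalization fitted on training data only,
ANOVA-F / mutual-information feature ranking, and the (estimator, k)
grid selection over {10,...,70} top-ranked features by five-fold CV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import clone
from sklearn.feature_selection import f_classif, mutual_info_classif
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .events import OculomotorEvents, detect_events, EventConfig
from .gaze_io import Trial, DataError
from .geometry import minimal_enclosing_circle

__all__ = [
    "FEATURE_NAMES",
    "SummaryFeatureVector",
    "SelectionConfig",
    "extract_features",
    "extract_feature_table",
    "zscore_fit_apply",
    "rank_features",
    "select_best_feature_set",
]

_STAT8 = ["mean", "sd", "median", "min", "max", "range", "kurt", "skew"]
_STAT7 = ["mean", "sd", "median", "min", "max", "range", "skew"]
_STAT5 = ["mean", "sd", "median", "min", "max"]


def _schema() -> list[str]:
    names: list[str] = []
    names.append("fix_count")
    names += [f"fix_dur_{s}" for s in _STAT8]
    names.append("sacc_count")
    names += [f"sacc_dur_{s}" for s in _STAT8]
    names += [f"sacc_amp_{s}" for s in _STAT8]
    names += ["sacc_angle_mean", "sacc_angle_sd", "fix_sacc_ratio"]
    names.append("blink_count")
    names += [f"blink_dur_{s}" for s in _STAT8]
    names += [f"pupil_{s}" for s in _STAT5]
    names += [f"verg_{s}" for s in _STAT8]
    names += [f"verg_fix_{s}" for s in _STAT8]
    names += [f"verg_pair_{s}" for s in _STAT7]
    names += ["mec_radius", "path_length"]
    names += [f"vel_{s}" for s in _STAT8]
    return names


#: canonical, ordered schema — the single source of truth (exactly 76 names)
FEATURE_NAMES: tuple[str, ...] = tuple(_schema())
assert len(FEATURE_NAMES) == 76 and len(set(FEATURE_NAMES)) == 76


@dataclass
class SummaryFeatureVector:
    values: np.ndarray  # aligned with FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (76,):
            raise ValueError("feature vector must have exactly 76 entries")
        if not np.isfinite(self.values).all():
            raise ValueError("feature vector must be finite")

    @property
    def names(self) -> tuple[str, ...]:
        return FEATURE_NAMES

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(FEATURE_NAMES))

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])


def _dist_stats(x: np.ndarray, stats: Sequence[str]) -> list[float]:
    """Distribution statistics with the undefined->0 policy."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    out = []
    for s in stats:
        if len(x) == 0:
            out.append(0.0)
            continue
        if s == "mean":
            v = x.mean()
        elif s == "sd":
            v = x.std() if len(x) > 1 else 0.0
        elif s == "median":
            v = float(np.median(x))
        elif s == "min":
            v = x.min()
        elif s == "max":
            v = x.max()
        elif s == "range":
            v = x.max() - x.min()
        elif s in ("kurt", "skew"):
            # population moments; near-constant samples trip scipy's
            # precision warning and the undefined->0 policy covers them
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore", RuntimeWarning)
                if len(x) > 1:
                    v = (sps.kurtosis(x, fisher=True, bias=True)
                         if s == "kurt" else sps.skew(x, bias=True))
                else:
                    v = 0.0
        else:  # pragma: no cover
            raise KeyError(s)
        out.append(float(v) if np.isfinite(v) else 0.0)
    return out


def extract_features(trial: Trial, events: OculomotorEvents
                     ) -> SummaryFeatureVector:
    """The canonical 76-entry summary vector for one trial."""
    rec = trial.recording
    if not rec.valid.any():
        raise DataError(f"trial {trial.trial_id} has no valid samples")
    vals: list[float] = []

    fix_dur = np.array([f.duration for f in events.fixations])
    vals.append(float(len(events.fixations)))
    vals += _dist_stats(fix_dur, _STAT8)

    sacc = events.saccades
    sacc_dur = np.array([s.duration for s in sacc])
    sacc_amp = np.array([s.amplitude for s in sacc])
    vals.append(float(len(sacc)))
    vals += _dist_stats(sacc_dur, _STAT8)
    vals += _dist_stats(sacc_amp, _STAT8)
    # angles between consecutive saccade direction vectors
    angles = []
    for a, b in zip(sacc, sacc[1:]):
        u = np.array([a.end_x - a.start_x, a.end_y - a.start_y])
        v = np.array([b.end_x - b.start_x, b.end_y - b.start_y])
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu > 0 and nv > 0:
            angles.append(float(np.arccos(np.clip(u @ v / (nu * nv), -1, 1))))
    vals += _dist_stats(np.array(angles), ["mean", "sd"])
    total_sacc = sacc_dur.sum()
    vals.append(float(fix_dur.sum() / total_sacc) if total_sacc > 0 else 0.0)

    blink_dur = np.array([b.duration for b in events.blinks])
    vals.append(float(len(events.blinks)))
    vals += _dist_stats(blink_dur, _STAT8)

    valid = rec.valid
    pupil = 0.5 * (rec.left_pupil + rec.right_pupil)
    vals += _dist_stats(pupil[valid], _STAT5)

    verg = (rec.left_x - rec.right_x)[valid]
    vals += _dist_stats(verg, _STAT8)
    fix_mask = np.zeros(rec.n_samples, dtype=bool)
    for f in events.fixations:
        i0 = int(np.searchsorted(rec.timestamps, f.onset))
        i1 = int(np.searchsorted(rec.timestamps, f.offset))
        fix_mask[i0:i1] = True
    vals += _dist_stats((rec.left_x - rec.right_x)[valid & fix_mask], _STAT8)
    vals += _dist_stats(np.abs(np.diff(verg)), _STAT7)

    gx, gy = rec.mean_gaze()
    pts = np.column_stack([gx[valid], gy[valid]])
    (_, _), radius = minimal_enclosing_circle(pts)
    vals.append(float(radius))
    # scanpath length and speed over valid consecutive samples only
    both = valid[:-1] & valid[1:]
    step = np.hypot(np.diff(gx), np.diff(gy))[both]
    vals.append(float(step.sum()))
    dt = np.diff(rec.timestamps)[both]
    speed = step / dt if len(step) else np.empty(0)
    vals += _dist_stats(speed, _STAT8)

    return SummaryFeatureVector(np.array(vals))


def extract_feature_table(trials: Sequence[Trial],
                          events: Sequence[OculomotorEvents] | None = None,
                          event_config: EventConfig | None = None
                          ) -> pd.DataFrame:
    """Feature table: one row per trial, metadata + 76 feature columns."""
    rows = []
    for i, trial in enumerate(trials):
        ev = events[i] if events is not None else detect_events(trial,
                                                                event_config)
        fv = extract_features(trial, ev)
        row = {
            "trial_id": trial.trial_id,
            "participant_id": trial.participant_id,
            "task_id": trial.task_id,
            "condition": trial.condition,
        }
        row.update(zip(FEATURE_NAMES, fv.values))
        rows.append(row)
    return pd.DataFrame(rows)


def zscore_fit_apply(train: pd.DataFrame, test: pd.DataFrame | None = None):
    """Z-score normalization fitted on the training table only.

    Returns ``(train_z, test_z, scaler)``; zero-variance features map to 0
    everywhere.  Population (ddof=0) standard deviation.
    """
    if len(train) == 0:
        raise DataError("empty training table")
    scaler = StandardScaler().fit(train.to_numpy(dtype=float))
    train_z = pd.DataFrame(scaler.transform(train.to_numpy(dtype=float)),
                           columns=train.columns, index=train.index)
    test_z = None
    if test is not None:
        test_z = pd.DataFrame(scaler.transform(test.to_numpy(dtype=float)),
                              columns=test.columns, index=test.index)
    return train_z, test_z, scaler


def rank_features(table: pd.DataFrame, labels, estimator: str = "anova",
                  seed: int = 0) -> tuple[list[str], np.ndarray]:
    """Rank features by ANOVA F or k-NN mutual information, descending.

    Undefined scores (constant features) are set to 0; ties are broken by
    the canonical column order.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise DataError("feature ranking requires both classes")
    X = table.to_numpy(dtype=float)
    if estimator == "anova":
        with np.errstate(invalid="ignore", divide="ignore"):
            scores, _ = f_classif(X, y)
    elif estimator == "mutual_information":
        scores = mutual_info_classif(X, y, n_neighbors=3, random_state=seed)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    scores = np.nan_to_num(np.asarray(scores, dtype=float), nan=0.0,
                           posinf=0.0, neginf=0.0)
    order = np.argsort(-scores, kind="stable")
    return [table.columns[i] for i in order], scores[order]


@dataclass
class SelectionConfig:
    estimator: str = "anova"   # anova | mutual_information
    k: int = 30
    folds: int = 5

    def __post_init__(self) -> None:
        if not 1 <= self.k <= len(FEATURE_NAMES):
            raise ValueError("k must be in [1, 76]")


GRID_KS = (10, 20, 30, 40, 50, 60, 70)
GRID_ESTIMATORS = ("anova", "mutual_information")


def _cv_accuracy(X: pd.DataFrame, y: np.ndarray, classifier,
                 estimator: str, k: int, folds, seed: int) -> float:
    accs = []
    for tr_idx, te_idx in folds:
        Xtr, Xte = X.iloc[tr_idx], X.iloc[te_idx]
        ytr, yte = y[tr_idx], y[te_idx]
        Xtr_z, Xte_z, _ = zscore_fit_apply(Xtr, Xte)
        names, _ = rank_features(Xtr_z, ytr, estimator, seed=seed)
        cols = names[:k]
        model = clone(classifier)
        model.fit(Xtr_z[cols].to_numpy(), ytr)
        accs.append(float(np.mean(model.predict(Xte_z[cols].to_numpy()) == yte)))
    return float(np.mean(accs))


def select_best_feature_set(table: pd.DataFrame, labels, classifier,
                            folds: int = 5, seed: int = 0):
    """Pick the best (estimator, k) for one classifier by five-fold CV.

    All 14 combinations are scored on identical fold splits; ranking and
    normalization are fitted inside each training fold.  Returns
    ``(SelectionConfig, accuracy, grid_table)``.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < folds:
        raise DataError(f"need at least {folds} trials per class")
    X = table[list(FEATURE_NAMES)] if set(FEATURE_NAMES) <= set(table.columns) \
        else table
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_list = list(splitter.split(X, y))
    records = []
    for est in GRID_ESTIMATORS:
        for k in GRID_KS:
            acc = _cv_accuracy(X, y, classifier, est, k, fold_list, seed)
            records.append({"estimator": est, "k": k, "accuracy": acc})
    grid = pd.DataFrame(records)
    best = grid.loc[grid["accuracy"].idxmax()]
    cfg = SelectionConfig(estimator=str(best["estimator"]), k=int(best["k"]),
                          folds=folds)
    return cfg, float(best["accuracy"]), grid
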
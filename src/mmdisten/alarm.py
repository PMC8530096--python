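"""Seizure alarm rule and prediction/classification performance metrics.

Classification quality is the usual confusion-matrix arithmetic (accuracy,
sensitivity, specificity) plus a rank-based ROC AUC.  Prediction quality is
measured on the alarm stream: the false-alarm rate ``R_fa = N_fa / H_t``
(alarms per hour), the prediction rate ``R_p = N_p / N_t`` (fraction of
seizures preceded by an alarm within the horizon), and the average
prediction time ``T_avg = T_p / N_p`` (minutes of warning).

The alarm rule compares a running mean of the predicted-feature stream
``P_F`` against the mean seizure feature ``S_F`` (the mean entropy of ictal
epochs).  Two comparators are available: ``"as-printed"`` fires whenever
``mean(S_F) >= running mean(P_F)``, and ``"crossing-up"`` fires when the
running mean rises through a fraction of ``mean(S_F)`` from below.  A
refractory period suppresses repeat alarms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .pipeline import EpochFeatureTable

__all__ = [
    "ConfusionCounts",
    "AlarmConfig",
    "PredictionPerformance",
    "UndefinedMetricError",
    "classification_metrics",
    "roc_auc",
    "seizure_threshold",
    "run_alarm",
    "prediction_performance",
]


class UndefinedMetricError(ZeroDivisionError):
    """A rate with a zero denominator was requested."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def classification_metrics(cc: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity and specificity from confusion counts."""
    if cc.total == 0:
        raise UndefinedMetricError("accuracy undefined: no observations")
    if cc.TP + cc.FN == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive observations")
    if cc.TN + cc.FP == 0:
        raise UndefinedMetricError("specificity undefined: no negative observations")
    return {
        "accuracy": (cc.TP + cc.TN) / cc.total,
        "sensitivity": cc.TP / (cc.TP + cc.FN),
        "specificity": cc.TN / (cc.TN + cc.FP),
    }


def roc_auc(scores: Sequence[float], truth: Sequence[int]) -> float:
    """Area under the ROC curve (rank/Mann-Whitney estimator).

    ``truth`` holds binary labels with 1 the positive class (by convention
    ictal-vs-rest when derived from three-state probabilities).
    """
    truth = np.asarray(truth)
    if np.unique(truth).size < 2:
        raise ValueError("ROC AUC needs both classes present in truth")
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


def seizure_threshold(ictal_features: EpochFeatureTable) -> float:
    """Mean seizure feature S_F: the mean entropy over all ictal epochs,
    pooled across scales."""
    labs = np.asarray(ictal_features.labels)
    rows = ictal_features.features[labs == "ictal"]
    if rows.size == 0:
        raise ValueError("no ictal epochs: cannot form the seizure feature mean")
    return float(rows.mean())


@dataclass(frozen=True)
class AlarmConfig:
    """Decision rule for the alarm stream."""

    seizure_feature_mean: float
    comparator: str = "as-printed"
    evaluation_window_epochs: int = 6
    refractory_min: float = 30.0
    crossing_fraction: float = 1.0  # crossing-up threshold as a fraction of S_F mean

    def __post_init__(self) -> None:
        if self.comparator not in ("as-printed", "crossing-up"):
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.evaluation_window_epochs < 1:
            raise ValueError("evaluation window must be >= 1 epoch")
        if self.refractory_min < 0:
            raise ValueError("refractory period must be >= 0")


def run_alarm(
    feature_stream: Sequence[float],
    cfg: AlarmConfig,
    epoch_length_s: float = 10.0,
    start_times_s: Sequence[float] | None = None,
) -> list[float]:
    """Causal alarm scan over a time-ordered predicted-feature stream.

    At step ``k`` the mean of the last ``evaluation_window_epochs`` stream
    values (fewer while the window fills) is compared against the seizure
    feature mean; a firing comparator emits an alarm at that step's time and
    silences further alarms for ``refractory_min`` minutes.  Returns alarm
    times in seconds.
    """
    stream = np.asarray(feature_stream, dtype=float)
    if stream.size == 0:
        raise ValueError("feature stream is empty")
    if start_times_s is None:
        times = np.arange(stream.size) * epoch_length_s
    else:
        times = np.asarray(start_times_s, dtype=float)
        if times.size != stream.size:
            raise ValueError("start_times_s length must match the stream")
    w = cfg.evaluation_window_epochs
    thr = cfg.seizure_feature_mean
    cross = cfg.crossing_fraction * thr
    alarms: list[float] = []
    silenced_until = -np.inf
    prev_mean: float | None = None
    for k in range(stream.size):
        running = float(stream[max(0, k - w + 1) : k + 1].mean())
        if cfg.comparator == "as-printed":
            fire = thr >= running
        else:  # crossing-up
            fire = running >= cross and (prev_mean is None or prev_mean < cross)
        prev_mean = running
        if fire and times[k] >= silenced_until:
            alarms.append(float(times[k]))
            silenced_until = times[k] + cfg.refractory_min * 60.0
    return alarms


@dataclass(frozen=True)
class PredictionPerformance:
    """Alarm-stream aggregates and the derived rates of a prediction run."""

    N_fa: int
    H_t: float
    N_p: int
    N_t: int
    T_p: float  # summed prediction lead time, minutes
    N_detect: int = 0  # alarms inside ictal intervals (detections, not predictions)

    @property
    def R_fa(self) -> float:
        """False alarms per hour."""
        if self.H_t <= 0:
            raise UndefinedMetricError("R_fa undefined: zero total hours")
        return self.N_fa / self.H_t

    @property
    def R_p(self) -> float:
        """Fraction of seizures predicted."""
        if self.N_t <= 0:
            raise UndefinedMetricError("R_p undefined: no seizures")
        return self.N_p / self.N_t

    @property
    def T_avg(self) -> float:
        """Mean prediction lead time in minutes."""
        if self.N_p == 0:
            raise UndefinedMetricError("T_avg undefined: no predicted seizures")
        return self.T_p / self.N_p

    def to_dict(self) -> dict:
        return {
            "N_fa": self.N_fa,
            "H_t": self.H_t,
            "N_p": self.N_p,
            "N_t": self.N_t,
            "T_p_min": self.T_p,
            "N_detect": self.N_detect,
            "R_fa_per_hour": self.R_fa if self.H_t > 0 else None,
            "R_p": self.R_p if self.N_t > 0 else None,
            "T_avg_min": self.T_avg if self.N_p > 0 else None,
        }


def prediction_performance(
    alarms_s: Sequence[float],
    seizure_onsets_s: Sequence[float],
    horizon_min: float,
    total_hours: float,
    seizure_offsets_s: Sequence[float] | None = None,
) -> PredictionPerformance:
    """Score an alarm stream against true seizure onsets.

    A seizure counts as predicted when at least one alarm falls within
    ``horizon_min`` minutes before its onset; the earliest such alarm sets
    that seizure's prediction time.  An alarm inside an annotated seizure
    (when offsets are given) is a detection — neither predictive nor false.
    Every remaining alarm is a false alarm.  Each alarm is classified
    exactly once.
    """
    if total_hours <= 0:
        raise ValueError(f"total_hours must be > 0, got {total_hours}")
    onsets = np.sort(np.asarray(seizure_onsets_s, dtype=float))
    offsets = None
    if seizure_offsets_s is not None:
        order = np.argsort(np.asarray(seizure_onsets_s, dtype=float))
        offsets = np.asarray(seizure_offsets_s, dtype=float)[order]
    horizon_s = horizon_min * 60.0
    earliest: dict[int, float] = {}
    n_false = 0
    n_detect = 0
    for t in sorted(float(a) for a in alarms_s):
        # predictive? match to the first upcoming onset within the horizon
        matched = False
        for i, onset in enumerate(onsets):
            if onset - horizon_s <= t < onset:
                earliest.setdefault(i, t)
                matched = True
                break
        if matched:
            continue
        if offsets is not None and any(
            onsets[i] <= t < offsets[i] for i in range(len(onsets))
        ):
            n_detect += 1
            continue
        n_false += 1
    t_p_min = sum((onsets[i] - t) / 60.0 for i, t in earliest.items())
    return PredictionPerformance(
        N_fa=n_false,
        H_t=float(total_hours),
        N_p=len(earliest),
        N_t=len(onsets),
        T_p=float(t_p_min),
        N_detect=n_detect,
    )
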
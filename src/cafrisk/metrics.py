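"""Evaluation stack for scored binary classifiers.

Threshold confusion metrics (PRE/SEN/SPE/ACC/F1), ranking metrics (ROC-AUC,
PR-AUC as average precision), decision-curve analysis (net benefit across
decision thresholds), and calibration (equal-width reliability bins plus the
Brier score).  Score-vs-threshold comparison is inclusive (``score >= t``)
throughout for internal consistency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "MetricReport",
    "DCACurve",
    "CalibrationReport",
    "confusion_metrics",
    "roc_auc",
    "pr_auc",
    "decision_curve",
    "calibration",
    "HIGH_BENEFIT_BAND",
]

# Decision-threshold band over which the deployed model is expected to add
# clinical net benefit (reported as a highlighted sub-range of the DCA grid).
HIGH_BENEFIT_BAND = (0.22, 0.76)


def _check_scored(y, scores) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    if y.size == 0:
        raise ValueError("y must be non-empty")
    if y.shape != scores.shape:
        raise ValueError("y and scores must have the same length")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("y must be binary 0/1")
    if np.any(~np.isfinite(scores)):
        raise ValueError("scores must be finite")
    return y.astype(int), scores


@dataclass
class MetricReport:
    tp: int
    fp: int
    fn: int
    tn: int
    pre: float
    sen: float
    spe: float
    acc: float
    f1: float
    roc_auc: float | None = None
    pr_auc: float | None = None
    degenerate: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        d = {
            "counts": {"TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn},
            "PRE": self.pre, "SEN": self.sen, "SPE": self.spe,
            "ACC": self.acc, "F1": self.f1,
        }
        if self.roc_auc is not None:
            d["ROC_AUC"] = self.roc_auc
        if self.pr_auc is not None:
            d["PR_AUC"] = self.pr_auc
        if self.degenerate:
            d["degenerate"] = list(self.degenerate)
        return d


def confusion_metrics(y, scores, threshold: float = 0.5) -> MetricReport:
    """Confusion-matrix metrics at a fixed decision threshold.

    Empty-denominator ratios (e.g. precision with no predicted positives)
    return 0 and are flagged in ``degenerate``.
    """
    y, scores = _check_scored(y, scores)
    pred = scores >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    degenerate = []

    def ratio(num, den, name):
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    sen = ratio(tp, tp + fn, "SEN")
    spe = ratio(tn, tn + fp, "SPE")
    pre = ratio(tp, tp + fp, "PRE")
    acc = (tp + tn) / len(y)
    f1 = ratio(2 * pre * sen, pre + sen, "F1")
    return MetricReport(tp=tp, fp=fp, fn=fn, tn=tn, pre=pre, sen=sen, spe=spe,
                        acc=acc, f1=f1, degenerate=tuple(degenerate))


def roc_auc(y, scores) -> float:
    """ROC-AUC: the Mann-Whitney concordance probability, ties counted 1/2."""
    y, scores = _check_scored(y, scores)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC-AUC needs both outcome classes")
    return float(roc_auc_score(y, scores))


def pr_auc(y, scores) -> float:
    """PR-AUC as average precision (step-wise integration, no interpolation)."""
    y, scores = _check_scored(y, scores)
    if y.sum() == 0:
        raise ValueError("PR-AUC needs at least one positive")
    return float(average_precision_score(y, scores))


@dataclass
class DCACurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray
    prevalence: float

    def band_mean(self, lo: float = HIGH_BENEFIT_BAND[0], hi: float = HIGH_BENEFIT_BAND[1]) -> float:
        """Mean model net benefit over a threshold sub-range."""
        m = (self.thresholds >= lo) & (self.thresholds <= hi)
        if not m.any():
            raise ValueError("band contains no grid thresholds")
        return float(self.nb_model[m].mean())

    def to_dict(self) -> dict:
        return {
            "thresholds": [float(v) for v in self.thresholds],
            "nb_model": [float(v) for v in self.nb_model],
            "nb_all": [float(v) for v in self.nb_all],
            "nb_none": [float(v) for v in self.nb_none],
            "prevalence": self.prevalence,
        }


def decision_curve(y, scores, thresholds: Sequence[float] | None = None) -> DCACurve:
    """Decision-curve analysis.

    Net benefit of the model at threshold pt is TP/N - FP/N * pt/(1-pt) with
    positives called at ``score >= pt``; treat-all and treat-none reference
    strategies are included.
    """
    y, scores = _check_scored(y, scores)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    t = np.asarray(thresholds, dtype=float)
    if np.any(t <= 0.0) or np.any(t >= 1.0):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    prev = float(y.mean())
    odds = t / (1.0 - t)
    pred = scores[None, :] >= t[:, None]
    tp = np.sum(pred & (y == 1)[None, :], axis=1)
    fp = np.sum(pred & (y == 0)[None, :], axis=1)
    nb_model = tp / n - fp / n * odds
    nb_all = prev - (1.0 - prev) * odds
    return DCACurve(thresholds=t, nb_model=nb_model, nb_all=nb_all,
                    nb_none=np.zeros_like(t), prevalence=prev)


@dataclass
class CalibrationReport:
    bin_edges: np.ndarray
    bin_mean_pred: np.ndarray
    bin_obs_rate: np.ndarray
    bin_n: np.ndarray
    brier: float

    def to_dict(self) -> dict:
        return {
            "bin_edges": [float(v) for v in self.bin_edges],
            "bin_mean_pred": [None if np.isnan(v) else float(v) for v in self.bin_mean_pred],
            "bin_obs_rate": [None if np.isnan(v) else float(v) for v in self.bin_obs_rate],
            "bin_n": [int(v) for v in self.bin_n],
            "brier": self.brier,
        }


def calibration(y, scores, n_bins: int = 10) -> CalibrationReport:
    """Reliability diagram over equal-width probability bins plus Brier score.

    Bins are [0, 1/n_bins), ..., [(n_bins-1)/n_bins, 1.0] (last bin closed);
    empty bins report NaN means.  Brier = mean (score - outcome)^2.
    """
    y, scores = _check_scored(y, scores)
    if np.any(scores < 0) or np.any(scores > 1):
        raise ValueError("scores must lie in [0, 1] for calibration")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.minimum((scores * n_bins).astype(int), n_bins - 1)
    mean_pred = np.full(n_bins, np.nan)
    obs_rate = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        m = idx == b
        counts[b] = int(m.sum())
        if counts[b]:
            mean_pred[b] = float(scores[m].mean())
            obs_rate[b] = float(y[m].mean())
    brier = float(np.mean((scores - y) ** 2))
    return CalibrationReport(bin_edges=edges, bin_mean_pred=mean_pred,
                             bin_obs_rate=obs_rate, bin_n=counts, brier=brier)
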
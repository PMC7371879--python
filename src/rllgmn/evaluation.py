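"""Threshold selection, confusion-matrix metrics, and cross-validation.

The decision score of a case is the class-2 ("deterioration") posterior at
the final step of its window.  The positive threshold is chosen by ROC
analysis of the learning data only: the candidate maximizing Youden's
J = sensitivity + specificity - 1, ties broken toward the smaller threshold
(which favours sensitivity).  Cases with score >= threshold are called
positive.

Cross-validation holds out one group (a patient or an event) per fold,
trains on the rest, selects the threshold on the training folds only, and
scores the held-out group; decisions are pooled into a single report per
repeat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ModelShape, posterior_sequence
from .exceptions import InvalidParameterError
from .preprocess import FeatureSequence, NormalizationSpec, WindowSpec, make_windows
from .training import TrainingConfig, TrainingResult, train

logger = logging.getLogger(__name__)

__all__ = [
    "ScoredCase",
    "ConfusionMatrix",
    "EvalReport",
    "roc_curve",
    "auc_score",
    "select_threshold",
    "confusion_and_metrics",
    "score_sequences",
    "loo_cross_validation",
    "horizon_sweep",
    "CVResult",
]


@dataclass(frozen=True)
class ScoredCase:
    case_id: str
    truth: int  # class in {1, 2}
    score: float  # class-2 posterior at the final step

    def __post_init__(self):
        if self.truth not in (1, 2):
            raise InvalidParameterError("truth must be 1 (normal) or 2 (event)")
        if not 0.0 <= self.score <= 1.0:
            raise InvalidParameterError("score must lie in [0, 1]")


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise InvalidParameterError("counts must be non-negative")
        if self.total < 1:
            raise InvalidParameterError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * (self.TP + self.TN) / self.total

    @property
    def sensitivity_pct(self) -> float | None:
        pos = self.TP + self.FN
        return None if pos == 0 else 100.0 * self.TP / pos

    @property
    def specificity_pct(self) -> float | None:
        neg = self.TN + self.FP
        return None if neg == 0 else 100.0 * self.TN / neg


@dataclass
class EvalReport:
    """Confusion counts, the three headline percentages, AUC and threshold.

    Percentages are stored at full precision; ``summary()`` rounds to the
    1-decimal display convention.  Ratios with an empty denominator are
    ``None``, never NaN.
    """

    confusion: ConfusionMatrix
    threshold: float | None = None
    auc: float | None = None
    decisions: list[dict] = field(default_factory=list)

    @property
    def accuracy_pct(self) -> float:
        return self.confusion.accuracy_pct

    @property
    def sensitivity_pct(self) -> float | None:
        return self.confusion.sensitivity_pct

    @property
    def specificity_pct(self) -> float | None:
        return self.confusion.specificity_pct

    def summary(self) -> dict:
        rnd = lambda v: None if v is None else round(v, 1)
        return {
            "TP": self.confusion.TP,
            "TN": self.confusion.TN,
            "FP": self.confusion.FP,
            "FN": self.confusion.FN,
            "accuracy_pct": rnd(self.accuracy_pct),
            "sensitivity_pct": rnd(self.sensitivity_pct),
            "specificity_pct": rnd(self.specificity_pct),
            "auc": None if self.auc is None else round(self.auc, 3),
            "threshold": self.threshold,
        }


def _split_scores(cases: Sequence[ScoredCase]):
    pos = np.array([c.score for c in cases if c.truth == 2])
    neg = np.array([c.score for c in cases if c.truth == 1])
    if len(pos) == 0 or len(neg) == 0:
        raise InvalidParameterError("ROC analysis needs both classes present")
    return pos, neg


def roc_curve(cases: Sequence[ScoredCase]):
    """ROC points over the unique observed scores, plus the AUC.

    Returns ``(points, auc)`` where points is a list of (threshold, FPR, TPR)
    in decreasing threshold order, prefixed by the empty operating point
    (threshold above every score).  Decision rule: score >= threshold is
    positive.  AUC is the trapezoidal area, identical to the Mann-Whitney
    rank statistic with ties credited 1/2.
    """
    pos, neg = _split_scores(cases)
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    points = [(np.inf, 0.0, 0.0)]
    for th in thresholds:
        tpr = float(np.mean(pos >= th))
        fpr = float(np.mean(neg >= th))
        points.append((float(th), fpr, tpr))
    fprs = np.array([p[1] for p in points])
    tprs = np.array([p[2] for p in points])
    auc = float(np.trapezoid(tprs, fprs))
    return points, auc


def auc_score(cases: Sequence[ScoredCase]) -> float:
    return roc_curve(cases)[1]


def select_threshold(cases: Sequence[ScoredCase]) -> float:
    """Threshold maximizing Youden's J; ties resolved to the smallest value."""
    points, _ = roc_curve(cases)
    best_th, best_j = None, -np.inf
    for th, fpr, tpr in points[1:]:
        j = tpr - fpr
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and th < best_th):
            best_th, best_j = th, j
    return float(best_th)


def confusion_and_metrics(
    cases: Sequence[ScoredCase], threshold: float, auc: float | None = None
) -> EvalReport:
    """Apply ``score >= threshold`` and tabulate counts and percentages."""
    tp = tn = fp = fn = 0
    decisions = []
    for c in cases:
        positive = c.score >= threshold
        if c.truth == 2:
            tp += positive
            fn += not positive
        else:
            fp += positive
            tn += not positive
        decisions.append(
            {"case_id": c.case_id, "truth": c.truth,
             "score": c.score, "decision": 2 if positive else 1}
        )
    if auc is None:
        try:
            auc = auc_score(cases)
        except InvalidParameterError:
            auc = None
    return EvalReport(
        confusion=ConfusionMatrix(TP=int(tp), TN=int(tn), FP=int(fp), FN=int(fn)),
        threshold=float(threshold),
        auc=auc,
        decisions=decisions,
    )


def score_sequences(seqs: Sequence[FeatureSequence], weights) -> list[ScoredCase]:
    """Final-step class-2 posterior of each sequence as its decision score."""
    out = []
    for i, fs in enumerate(seqs):
        post = posterior_sequence(fs.x, weights)
        cid = fs.record_id or f"case-{i}"
        if fs.window_end is not None:
            cid = f"{cid}@{fs.window_end:g}"
        score = float(min(1.0, max(0.0, post[-1, 1])))  # guard float round-off
        out.append(ScoredCase(case_id=cid, truth=int(fs.label), score=score))
    return out


@dataclass
class CVResult:
    reports: list[EvalReport]          # one pooled report per repeat
    mean_accuracy_pct: float
    fold_details: list[dict]
    unit: str
    seeds: list[int]

    @property
    def report(self) -> EvalReport:
        """Pooled confusion report of the last repeat."""
        return self.reports[-1]


def _group_key(fs: FeatureSequence, unit: str) -> str:
    if unit == "patient":
        return fs.group or fs.record_id
    return fs.record_id


def loo_cross_validation(
    cohort: Sequence[FeatureSequence],
    shape: ModelShape,
    cfg: TrainingConfig | None = None,
    unit: str = "event",
    repeats: int = 1,
    seeds: Sequence[int] | None = None,
) -> CVResult:
    """Leave-one-group-out cross-validation with learning-set thresholding.

    ``unit`` chooses the held-out group: "patient" (all of a patient's
    windows) or "event" (one record/segment).  Each repeat re-trains every
    fold from a different seed; the mean accuracy across repeats and the
    pooled report of each repeat are returned.  The threshold is always
    selected on the training folds, never on held-out cases.
    """
    if cfg is None:
        cfg = TrainingConfig()
    if unit not in ("patient", "event"):
        raise InvalidParameterError("unit must be 'patient' or 'event'")
    groups = sorted({_group_key(fs, unit) for fs in cohort})
    if len(groups) < 2:
        raise InvalidParameterError("need at least 2 groups for cross-validation")
    labels = {fs.label for fs in cohort}
    if labels != {1, 2}:
        raise InvalidParameterError("cohort must contain both classes")
    if seeds is None:
        seeds = [int(cfg.seed) + 1000 * r for r in range(repeats)]
    seeds = [int(s) for s in seeds]
    if len(seeds) != repeats:
        raise InvalidParameterError("seeds must have one entry per repeat")

    reports: list[EvalReport] = []
    fold_details: list[dict] = []
    accs: list[float] = []
    for rep, seed in enumerate(seeds):
        pooled: list[ScoredCase] = []
        pooled_decisions: list[dict] = []
        for gi, g in enumerate(groups):
            train_set = [fs for fs in cohort if _group_key(fs, unit) != g]
            test_set = [fs for fs in cohort if _group_key(fs, unit) == g]
            if {fs.label for fs in train_set} != {1, 2}:
                logger.warning("fold %s: training fold lacks a class; skipped", g)
                continue
            fold_cfg = TrainingConfig(
                learning_rate=cfg.learning_rate, max_epochs=cfg.max_epochs,
                tol=cfg.tol, restarts=cfg.restarts, init_range=cfg.init_range,
                seed=(seed + gi) % (2**31), pin_unit=cfg.pin_unit,
            )
            result = train(train_set, shape, fold_cfg)
            theta = select_threshold(score_sequences(train_set, result.weights))
            held = score_sequences(test_set, result.weights)
            fold_report = confusion_and_metrics(held, theta, auc=None)
            pooled.extend(held)
            pooled_decisions.extend(fold_report.decisions)
            fold_details.append(
                {"repeat": rep, "group": g, "threshold": theta,
                 "final_J": result.final_losses[result.best_restart],
                 "n_test": len(test_set)}
            )
        if not pooled:
            raise InvalidParameterError("every fold was skipped; cannot evaluate")
        tp = sum(d["truth"] == 2 and d["decision"] == 2 for d in pooled_decisions)
        fn = sum(d["truth"] == 2 and d["decision"] == 1 for d in pooled_decisions)
        fp = sum(d["truth"] == 1 and d["decision"] == 2 for d in pooled_decisions)
        tn = sum(d["truth"] == 1 and d["decision"] == 1 for d in pooled_decisions)
        try:
            pooled_auc = auc_score(pooled)
        except InvalidParameterError:
            pooled_auc = None
        report = EvalReport(
            confusion=ConfusionMatrix(TP=tp, TN=tn, FP=fp, FN=fn),
            threshold=None, auc=pooled_auc, decisions=pooled_decisions,
        )
        reports.append(report)
        accs.append(report.accuracy_pct)
    return CVResult(
        reports=reports,
        mean_accuracy_pct=float(np.mean(accs)),
        fold_details=fold_details,
        unit=unit,
        seeds=list(seeds),
    )


def horizon_sweep(
    records: Sequence,
    events: dict[str, list[float]],
    P_values: Sequence[float],
    spec: WindowSpec,
    norm: NormalizationSpec,
    shape: ModelShape,
    cfg: TrainingConfig | None = None,
    unit: str = "event",
    repeats: int = 1,
) -> pd.DataFrame:
    """Re-label and re-evaluate the cohort for each prediction horizon P.

    Returns a table with one row per P: ``P, TP, TN, FN, FP, accuracy_pct``
    (pooled counts of the last repeat, mean accuracy across repeats).
    """
    rows = []
    for P in P_values:
        sp = spec.with_horizon(P)
        cohort: list[FeatureSequence] = []
        for rec in records:
            rid = getattr(rec, "record_id", "rri")
            cohort.extend(make_windows(rec, sp, norm, events.get(rid)))
        cv = loo_cross_validation(cohort, shape, cfg, unit=unit, repeats=repeats)
        cm = cv.report.confusion
        rows.append(
            {"P": P, "TP": cm.TP, "TN": cm.TN, "FN": cm.FN, "FP": cm.FP,
             "accuracy_pct": cv.mean_accuracy_pct}
        )
    return pd.DataFrame(rows)
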
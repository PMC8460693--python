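"""Voxel-wise evaluation: ROC/AUC, MCC, balanced accuracy, bootstrap CIs.

Voxels are pooled across test cases for the global ROC curve, matching how
the segmentation methods are compared on the whole test set.  Confidence
intervals use the percentile bootstrap, resampling test *cases* (the patient
analogue) with replacement -- voxels within one lung are strongly correlated,
so they are never the resampling unit.  The default is 1e5 resamples at the
95% level.  Paired differences (method A minus method B) are computed on the
same resample so the interval reflects the within-case pairing; the
difference is called significant when the interval excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import sklearn.metrics as _skm

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "BootstrapResult",
    "UndefinedStatisticError",
    "confusion",
    "mcc",
    "balanced_accuracy",
    "roc_curve",
    "optimal_threshold",
    "bootstrap_ci",
    "paired_difference_ci",
]


class UndefinedStatisticError(ValueError):
    """Raised by a statistic that is undefined on a bootstrap resample."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


@dataclass(frozen=True)
class RocCurve:
    """Pooled-voxel ROC curve: descending thresholds, trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class BootstrapResult:
    point: float
    ci_low: float
    ci_high: float
    n_resamples: int
    level: float
    resample_unit: str
    seed: int
    significant: bool | None = None  # set for paired differences: 0 outside CI

    def as_dict(self) -> dict:
        d = {
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_resamples": self.n_resamples,
            "level": self.level,
        }
        if self.significant is not None:
            d["significant"] = self.significant
        return d


def confusion(pred_mask, truth_mask, region) -> ConfusionCounts:
    """Confusion counts restricted to ``region`` voxels.

    Arguments may be :class:`~perfseg3d.volio.BinaryMask` or plain boolean
    arrays sharing one grid.
    """
    pred = np.asarray(getattr(pred_mask, "data", pred_mask), bool)
    truth = np.asarray(getattr(truth_mask, "data", truth_mask), bool)
    reg = np.asarray(getattr(region, "data", region), bool)
    if not (pred.shape == truth.shape == reg.shape):
        raise ValueError(
            f"grid mismatch: pred {pred.shape}, truth {truth.shape}, region {reg.shape}"
        )
    if not reg.any():
        raise ValueError("evaluation region is empty")
    p = pred[reg]
    t = truth[reg]
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    tp, fp, fn, tn = float(c.tp), float(c.fp), float(c.fn), float(c.tn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def balanced_accuracy(c: ConfusionCounts) -> float:
    """(sensitivity + specificity) / 2, with 0/0 class rates treated as 0."""
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.0
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else 0.0
    return (sens + spec) / 2.0


def _check_two_classes(truth: np.ndarray) -> None:
    if truth.all() or not truth.any():
        raise ValueError("ROC requires both classes in the truth labels")


def roc_curve(scores, truth) -> RocCurve:
    """ROC over pooled voxels; prediction is positive when score >= threshold.

    Thresholds are the unique score values (ties grouped) plus a sentinel
    above the maximum; AUC is the trapezoidal area.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    truth = np.asarray(truth, bool).ravel()
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have the same length")
    _check_two_classes(truth)
    fpr, tpr, thr = _skm.roc_curve(truth, scores, drop_intermediate=False)
    auc = float(_skm.auc(fpr, tpr))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def optimal_threshold(scores, truth, criterion: str = "balanced_accuracy"):
    """Threshold (score >= t is positive) maximising the criterion.

    Candidates are the unique score values plus an all-negative sentinel;
    ties are broken toward the LOWER threshold (the more sensitive operating
    point).  Returns ``(threshold, achieved_value)``.
    """
    if criterion != "balanced_accuracy":
        raise ValueError(f"unsupported criterion: {criterion}")
    scores = np.asarray(scores, dtype=np.float64).ravel()
    truth = np.asarray(truth, bool).ravel()
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have the same length")
    _check_two_classes(truth)
    # candidates are the unique score values; ranking uses the integer
    # statistic tp*N - fp*P (equivalent to balanced accuracy), so ties are
    # exact and break toward the lower threshold
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = truth[order]
    last = np.r_[np.flatnonzero(np.diff(s) != 0), s.size - 1]
    cum_tp = np.cumsum(t)[last].astype(np.int64)
    cum_fp = np.cumsum(~t)[last].astype(np.int64)
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    key = cum_tp * n_neg - cum_fp * n_pos
    idx = np.flatnonzero(key == key.max())[-1]  # descending -> lowest threshold
    bal = (cum_tp[idx] / n_pos + 1.0 - cum_fp[idx] / n_neg) / 2.0
    return float(s[last][idx]), float(bal)


def _resample_indices(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, n, size=n)


def _bootstrap_draws(
    cases: Sequence,
    statistics: Sequence[Callable],
    n_resamples: int,
    seed: int,
    max_redraw_factor: int = 100,
) -> np.ndarray:
    n = len(cases)
    if n < 2:
        raise ValueError("bootstrap needs at least 2 cases")
    rng = np.random.default_rng(seed)
    draws = np.empty((n_resamples, len(statistics)), dtype=np.float64)
    budget = max_redraw_factor * n_resamples
    used = 0
    i = 0
    while i < n_resamples:
        if used >= budget:
            raise RuntimeError(
                "too many bootstrap resamples were undefined; "
                f"gave up after {used} draws"
            )
        used += 1
        idx = _resample_indices(rng, n)
        sample = [cases[j] for j in idx]
        try:
            vals = [float(stat(sample)) for stat in statistics]
        except UndefinedStatisticError:
            continue
        if any(not np.isfinite(v) for v in vals):
            continue
        draws[i] = vals
        i += 1
    return draws


def bootstrap_ci(
    cases: Sequence,
    statistic: Callable,
    n_resamples: int = 100_000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapResult:
    """Percentile bootstrap CI for ``statistic`` computed over a case multiset.

    ``statistic`` receives a list of case data objects (whatever the caller
    chooses to carry per case) and returns a float.  Resamples on which the
    statistic raises :class:`UndefinedStatisticError` or returns a non-finite
    value (e.g. a single-class resample) are redrawn, up to a documented cap
    of 100x ``n_resamples`` total draws, after which an error is raised.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    point = float(statistic(list(cases)))
    draws = _bootstrap_draws(cases, [statistic], n_resamples, seed)[:, 0]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return BootstrapResult(
        point=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_resamples=n_resamples,
        level=level,
        resample_unit="case",
        seed=seed,
    )


def paired_difference_ci(
    cases: Sequence,
    stat_a: Callable,
    stat_b: Callable,
    n_resamples: int = 100_000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap CI for ``stat_a - stat_b`` with both evaluated on each resample.

    The point estimate is the mean of the resampled differences, and the
    difference is flagged significant when 0 lies outside the interval.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    draws = _bootstrap_draws(cases, [stat_a, stat_b], n_resamples, seed)
    diffs = draws[:, 0] - draws[:, 1]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha])
    return BootstrapResult(
        point=float(diffs.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_resamples=n_resamples,
        level=level,
        resample_unit="case",
        seed=seed,
        significant=bool(not (lo <= 0.0 <= hi)),
    )
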
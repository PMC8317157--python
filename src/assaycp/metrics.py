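"""Efficiency, calibration and concordance metrics for conformal models.

Validity is monitored with calibration curves (empirical accuracy vs the
requested confidence); a strategy is flagged invalid when its accuracy
falls clearly below the diagonal at any gridpoint (one-sided — an
overconservative model is still valid). Efficiency is measured with
observed fuzziness for classification (mean summed p-value of the
non-true classes) and the median prediction-interval width at a fixed
confidence for regression. Replicated experiments are summarized with
t-distribution confidence intervals, and paired old/new measurements of
the same compounds with a concordance summary (label retention, signed
differences, regression slope).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .conformal import PredictionInterval
from .io import Qualifier, UNDETERMINED, _label_value, ic50_to_pic50

DEFAULT_CONFIDENCE_GRID = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))
DEFAULT_VALIDITY_TOLERANCE = 0.025


def observed_fuzziness(p_values: dict[str, np.ndarray], true_labels) -> float:
    """Mean summed p-value of the non-true classes; smaller is better.

    Confidence-independent classification efficiency: for each test
    compound, sum the p-values of every class other than the true one,
    then average. Bounded by [0, #classes − 1].
    """
    truths = np.asarray(true_labels)
    n = len(truths)
    if n == 0:
        raise ValueError("no examples")
    for label in np.unique(truths):
        if label not in p_values:
            raise KeyError(f"true label {label!r} missing from the p-value map")
    total = np.zeros(n, dtype=float)
    for c, p in p_values.items():
        p = np.atleast_1d(np.asarray(p, dtype=float))
        total += np.where(truths == c, 0.0, p)
    return float(np.mean(total))


def median_interval_width(intervals: PredictionInterval, confidence: float) -> float:
    """Median interval width (pIC50 units) at the stated confidence."""
    if len(intervals.width) == 0:
        raise ValueError("no intervals")
    if not np.isclose(intervals.confidence, confidence):
        raise ValueError(
            f"intervals computed at confidence {intervals.confidence}, "
            f"asked for {confidence}"
        )
    return float(np.median(intervals.width))


@dataclass
class CalibrationCurve:
    """Empirical accuracy per requested confidence gridpoint."""

    confidence: np.ndarray
    accuracy: np.ndarray
    per_class: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if self.confidence.shape != self.accuracy.shape:
            raise ValueError("grid and accuracy shapes differ")


def classification_calibration_curve(
    p_values: dict[str, np.ndarray],
    truths,
    grid=DEFAULT_CONFIDENCE_GRID,
    count_empty_as_error: bool = True,
) -> CalibrationCurve:
    """Accuracy(c) = fraction of prediction sets at confidence c containing
    the true label; per-class (Mondrian) accuracies are included.

    An empty prediction set counts as an error by default (the truth is
    not part of it); ``count_empty_as_error=False`` counts it as correct
    instead.
    """
    truths = np.asarray(truths)
    grid = np.asarray(grid, dtype=float)
    p_true = np.zeros(len(truths), dtype=float)
    for c, p in p_values.items():
        p_true = np.where(truths == c, np.atleast_1d(np.asarray(p, float)), p_true)
    acc = np.empty_like(grid)
    per_class: dict[str, np.ndarray] = {c: np.empty_like(grid) for c in p_values}
    for i, conf in enumerate(grid):
        eps = 1.0 - conf
        hit = p_true > eps
        if not count_empty_as_error:
            stack = np.vstack(
                [np.atleast_1d(np.asarray(p, float)) for p in p_values.values()]
            )
            hit = hit | np.all(stack <= eps, axis=0)
        acc[i] = float(np.mean(hit))
        for c in p_values:
            mask = truths == c
            per_class[c][i] = float(np.mean(hit[mask])) if np.any(mask) else np.nan
    return CalibrationCurve(grid, acc, per_class)


def regression_calibration_curve(
    model, X, truths, grid=DEFAULT_CONFIDENCE_GRID
) -> CalibrationCurve:
    """Accuracy(c) = fraction of intervals at confidence c containing the
    true value. ``model`` is anything with an ``interval_grid(X, grid)`` or
    ``predict_interval(X, c)`` method; unbounded intervals always contain
    the truth."""
    truths = np.asarray(truths, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if hasattr(model, "interval_grid"):
        by_conf = model.interval_grid(X, grid)
        acc = np.array(
            [float(np.mean(by_conf[float(c)].contains(truths))) for c in grid]
        )
    else:
        acc = np.array(
            [
                float(np.mean(model.predict_interval(X, float(c)).contains(truths)))
                for c in grid
            ]
        )
    return CalibrationCurve(grid, acc)


def validity_flag(
    curve: CalibrationCurve, tolerance: float = DEFAULT_VALIDITY_TOLERANCE
) -> str:
    """"invalid" iff accuracy(c) < c − tolerance at any gridpoint.

    One-sided by design: accuracy above the diagonal (overconservatism)
    never invalidates a model.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    below = curve.accuracy < (curve.confidence - tolerance)
    return "invalid" if bool(np.any(below)) else "valid"


def replicate_ci(values, level: float = 0.95):
    """Mean and t-distribution confidence interval over replicate values.

    Returns ``(mean, lower, upper)`` with
    ``mean ± t_{(1+level)/2, n−1} · sd/√n``; requires n ≥ 2.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least two replicate values")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    t_crit = float(scipy.stats.t.ppf(0.5 + level / 2.0, df=n - 1))
    half = t_crit * sd / np.sqrt(n)
    return mean, mean - half, mean + half


def concordance_summary(
    old_ic50_um,
    new_ic50_um,
    threshold_um: float = 10.0,
    old_qualifiers=None,
    new_qualifiers=None,
) -> dict:
    """Agreement summary for compounds measured in both assays.

    Returns label retention at the activity threshold, mean/median signed
    differences (old − new, both μM and pIC50 scale), the least-squares
    slope/intercept of new-vs-old pIC50, and an informational paired
    t-test on pIC50. Difference statistics need ≥ 2 exact (qualifier-free)
    pairs; otherwise they are omitted with a notice.
    """
    old = np.asarray(old_ic50_um, dtype=float)
    new = np.asarray(new_ic50_um, dtype=float)
    if old.shape != new.shape:
        raise ValueError("paired measurements must align")
    n = old.size
    oq = list(old_qualifiers) if old_qualifiers is not None else [Qualifier.EXACT] * n
    nq = list(new_qualifiers) if new_qualifiers is not None else [Qualifier.EXACT] * n

    old_labels = np.array([_label_value(v, q, threshold_um) for v, q in zip(old, oq)])
    new_labels = np.array([_label_value(v, q, threshold_um) for v, q in zip(new, nq)])
    determinate = (old_labels != UNDETERMINED) & (new_labels != UNDETERMINED)
    retention = (
        float(np.mean(old_labels[determinate] == new_labels[determinate]))
        if np.any(determinate)
        else np.nan
    )

    exact = np.array(
        [q1 is Qualifier.EXACT and q2 is Qualifier.EXACT for q1, q2 in zip(oq, nq)]
    )
    out = {
        "n_pairs": int(n),
        "n_exact_pairs": int(np.sum(exact)),
        "retention": retention,
    }
    if int(np.sum(exact)) < 2:
        out["notice"] = "fewer than 2 exact pairs; difference statistics omitted"
        return out
    o, w = old[exact], new[exact]
    p_old, p_new = ic50_to_pic50(o), ic50_to_pic50(w)
    slope, intercept = np.polyfit(p_old, p_new, 1)
    t_stat, p_val = scipy.stats.ttest_rel(p_old, p_new)
    out.update(
        mean_diff_um=float(np.mean(o - w)),
        median_diff_um=float(np.median(o - w)),
        mean_diff_pic50=float(np.mean(p_old - p_new)),
        median_diff_pic50=float(np.median(p_old - p_new)),
        slope=float(slope),
        intercept=float(intercept),
        paired_t=float(t_stat),
        paired_t_pvalue=float(p_val),
    )
    return out
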
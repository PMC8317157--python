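"""Data-composition strategies for modeling across an assay transition.

Six ways of combining the legacy dataset ``A_old`` with the accumulating
new-assay dataset ``A_new`` into conformal predictors:

================  ========================  =============================
name              proper training set       calibration set
================  ========================  =============================
CCP_new           A_new (9/10 folds)        A_new (1/10 fold)
CCP_old           A_old (9/10 folds)        A_old (1/10 fold)
CCP_pool          pooled (9/10 folds)       pooled (1/10 fold)
ICP_old_new       all of A_old              all of A_new
CCP_AT            A_new folds ∪ all A_old   A_new (1/10 fold)
CCP_AT2           A_old (9/10 folds)        A_old fold ∪ all A_new
================  ========================  =============================

CCP strategies train k independent ICPs with shifted folds and aggregate
the k predictions by the median (per-class p-values for classification,
componentwise interval bounds for regression). Calibration sets consist
exclusively of new-assay data for CCP_new, CCP_AT and ICP_old_new — these
are the strategies whose calibration is exchangeable with new-assay test
compounds and hence theoretically guaranteed valid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conformal import (
    CalibrationError,
    IcpClassifier,
    IcpRegressor,
    LearnerConfig,
    PredictionInterval,
    PredictionSet,
    conformal_quantile,
    fit_icp_classifier,
    fit_icp_regressor,
)
from .io import ACTIVE, CLASSIFICATION, NONACTIVE, REGRESSION, LabeledDataset

STRATEGIES = ("CCP_new", "CCP_old", "CCP_pool", "ICP_old_new", "CCP_AT", "CCP_AT2")

#: strategies whose calibration rows are exclusively new-assay data
EXCHANGEABLE_CALIBRATION = frozenset({"CCP_new", "CCP_AT", "ICP_old_new"})


def calibration_all_new(name: str) -> bool:
    """Whether a strategy calibrates exclusively on new-assay data."""
    if name not in STRATEGIES:
        raise ValueError(f"unknown strategy {name!r}; valid: {', '.join(STRATEGIES)}")
    return name in EXCHANGEABLE_CALIBRATION


def _shuffled_folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """k near-equal folds as shuffled contiguous blocks of a permutation."""
    perm = rng.permutation(n)
    return [np.sort(block) for block in np.array_split(perm, k)]


def _check_min_calibration(name: str, calib: LabeledDataset) -> None:
    if calib.n < 1:
        raise CalibrationError(f"{name}: empty calibration fold")
    if calib.task == CLASSIFICATION:
        for c in (ACTIVE, NONACTIVE):
            if not np.any(calib.y == c):
                raise CalibrationError(
                    f"{name}: calibration fold has no class {c!r} examples"
                )


def compose(
    name: str,
    A_old: LabeledDataset | None,
    A_new: LabeledDataset | None,
    k: int = 10,
    seed: int = 0,
) -> list[tuple[LabeledDataset, LabeledDataset]]:
    """Build the (proper, calibration) pairs of a strategy.

    Returns one pair for ICP_old_new and k pairs for the CCP strategies.
    Refuses (``CalibrationError``) when a Mondrian calibration fold would
    lack a class entirely, mirroring the removal of CCP_new/CCP_AT at very
    small new-assay sizes.
    """
    if name not in STRATEGIES:
        raise ValueError(f"unknown strategy {name!r}; valid: {', '.join(STRATEGIES)}")
    rng = np.random.default_rng(seed)

    def need(ds, which):
        if ds is None or ds.n == 0:
            raise ValueError(f"{name} requires a non-empty {which} dataset")
        return ds

    pairs: list[tuple[LabeledDataset, LabeledDataset]] = []
    if name == "ICP_old_new":
        old = need(A_old, "A_old")
        new = need(A_new, "A_new")
        _check_min_calibration(name, new)
        return [(old, new)]

    if name in ("CCP_new", "CCP_old", "CCP_pool"):
        if name == "CCP_new":
            base = need(A_new, "A_new")
        elif name == "CCP_old":
            base = need(A_old, "A_old")
        else:
            base = LabeledDataset.concat([need(A_old, "A_old"), need(A_new, "A_new")])
        folds = _shuffled_folds(base.n, k, rng)
        for i in range(k):
            calib = base.subset(folds[i])
            proper_idx = np.concatenate([folds[j] for j in range(k) if j != i])
            _check_min_calibration(name, calib)
            pairs.append((base.subset(proper_idx), calib))
        return pairs

    if name == "CCP_AT":
        new = need(A_new, "A_new")
        old = need(A_old, "A_old")
        folds = _shuffled_folds(new.n, k, rng)
        for i in range(k):
            calib = new.subset(folds[i])
            _check_min_calibration(name, calib)
            rest = np.concatenate([folds[j] for j in range(k) if j != i])
            proper = LabeledDataset.concat([new.subset(rest), old])
            pairs.append((proper, calib))
        return pairs

    # CCP_AT2
    old = need(A_old, "A_old")
    new = need(A_new, "A_new")
    folds = _shuffled_folds(old.n, k, rng)
    for i in range(k):
        calib = LabeledDataset.concat([old.subset(folds[i]), new])
        _check_min_calibration(name, calib)
        rest = np.concatenate([folds[j] for j in range(k) if j != i])
        pairs.append((old.subset(rest), calib))
    return pairs


# ---------------------------------------------------------------------------
# median aggregation
# ---------------------------------------------------------------------------


def aggregate_p_values(p_lists, median_rule: str = "midpoint"):
    """Median per-class p-value over k ICP predictions.

    ``p_lists`` is a sequence of per-ICP dicts {class: p-array}; all dicts
    must share classes and array lengths. With even k the default takes the
    midpoint of the two central order statistics; ``median_rule="lower"``
    takes the lower one.
    """
    p_lists = list(p_lists)
    if not p_lists:
        raise ValueError("no p-values to aggregate")
    classes = tuple(p_lists[0])
    for d in p_lists:
        if tuple(d) != classes:
            raise ValueError("ragged per-class p-value inputs")
    out = {}
    for c in classes:
        stack = np.vstack([np.atleast_1d(np.asarray(d[c], float)) for d in p_lists])
        if stack.ndim != 2 or len({len(np.atleast_1d(d[c])) for d in p_lists}) != 1:
            raise ValueError("ragged p-value arrays")
        out[c] = _median(stack, median_rule)
    return out


def _median(stack: np.ndarray, rule: str) -> np.ndarray:
    if rule == "midpoint":
        return np.median(stack, axis=0)
    if rule == "lower":
        k = stack.shape[0]
        return np.sort(stack, axis=0)[(k - 1) // 2]
    raise ValueError(f"unknown median rule {rule!r}")


def aggregate_intervals(intervals, median_rule: str = "midpoint") -> PredictionInterval:
    """Componentwise median of k prediction intervals at one confidence.

    Lower bound = median of lower bounds, upper = median of uppers; a
    single unbounded member among many finite ones therefore does not blow
    up the aggregate.
    """
    intervals = list(intervals)
    if not intervals:
        raise ValueError("no intervals to aggregate")
    confs = {iv.confidence for iv in intervals}
    if len(confs) != 1:
        raise ValueError("intervals computed at mixed confidence levels")
    lowers = np.vstack([iv.lower for iv in intervals])
    uppers = np.vstack([iv.upper for iv in intervals])
    lo = _median(lowers, median_rule)
    hi = _median(uppers, median_rule)
    if np.any(lo > hi):
        raise AssertionError("degenerate aggregated interval (lower > upper)")
    return PredictionInterval((lo + hi) / 2.0, (hi - lo) / 2.0, intervals[0].confidence)


# ---------------------------------------------------------------------------
# fitted strategy models
# ---------------------------------------------------------------------------


@dataclass
class StrategyModel:
    """One or k fitted ICPs plus the median aggregation rule."""

    name: str
    task: str
    icps: list
    median_rule: str = "midpoint"

    @property
    def k(self) -> int:
        return len(self.icps)

    # -- classification -----------------------------------------------------

    def predict_p_values(self, X) -> dict[str, np.ndarray]:
        if self.task != CLASSIFICATION:
            raise ValueError("p-values are a classification output")
        return aggregate_p_values(
            [icp.predict_p_values(X) for icp in self.icps], self.median_rule
        )

    def predict_set(self, X, confidence: float) -> PredictionSet:
        if not 0.0 < confidence < 1.0:
            raise ValueError("confidence must lie in (0, 1)")
        return PredictionSet(self.predict_p_values(X))

    # -- regression ---------------------------------------------------------

    def predict_interval(self, X, confidence: float) -> PredictionInterval:
        if self.task != REGRESSION:
            raise ValueError("intervals are a regression output")
        return aggregate_intervals(
            [icp.predict_interval(X, confidence) for icp in self.icps],
            self.median_rule,
        )

    def interval_grid(self, X, confidences) -> dict[float, PredictionInterval]:
        """Aggregated intervals at several confidences, predicting once."""
        preds = [icp.point_predictions(X) for icp in self.icps]
        out = {}
        for conf in confidences:
            members = []
            for icp, (y_hat, sigma) in zip(self.icps, preds):
                a_star, _ = conformal_quantile(
                    icp.calib_alphas, conf, icp.interpolate
                )
                members.append(PredictionInterval(y_hat, a_star * sigma, conf))
            out[float(conf)] = aggregate_intervals(members, self.median_rule)
        return out


def fit_strategy(
    name: str,
    A_old: LabeledDataset | None,
    A_new: LabeledDataset | None,
    cfg: LearnerConfig | None = None,
    k: int = 10,
    seed: int = 0,
    beta: float = 0.01,
    interpolate_p: bool = True,
    interpolate_quantile: bool = False,
    median_rule: str = "midpoint",
) -> StrategyModel:
    """Compose and fit a strategy; Mondrian calibration for classification.

    Each member ICP gets a learner seed derived from ``seed`` and its fold
    index so that refitting with the same inputs is deterministic.
    """
    cfg = cfg or LearnerConfig()
    pairs = compose(name, A_old, A_new, k=k, seed=seed)
    task = pairs[0][0].task
    icps = []
    for i, (proper, calib) in enumerate(pairs):
        member_cfg = LearnerConfig(
            cost=cfg.cost,
            svr_epsilon=cfg.svr_epsilon,
            tol=cfg.tol,
            max_iter=cfg.max_iter,
            seed=(int(seed) * 1009 + i) % (2**31),
        )
        if task == CLASSIFICATION:
            icps.append(
                fit_icp_classifier(proper, calib, member_cfg, interpolate=interpolate_p)
            )
        else:
            icps.append(
                fit_icp_regressor(
                    proper, calib, member_cfg, beta=beta,
                    interpolate=interpolate_quantile,
                )
            )
    return StrategyModel(name=name, task=task, icps=icps, median_rule=median_rule)
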
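"""Replicated, seeded evaluation of assay-transition strategies.

The study design: for each replicate (its own deterministic seed derived
from the base seed), the full new-assay dataset is shuffled and split into
``cv_folds`` cross-validation folds. Each held-out fold is the test set —
testing is always on new-assay data only. For each (n_old, n_new) cell of
the size grid, n_new records are sampled from the remaining new-assay
training split and n_old from the full old-assay dataset; every strategy
is fitted on those identical samples and evaluated on the identical test
fold, so results are comparable across strategies and sizes. A strategy
that refuses a cell (e.g. a Mondrian calibration fold without both
classes) is recorded as a skipped row, never silently dropped.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conformal import CalibrationError, LearnerConfig
from .io import CLASSIFICATION, LabeledDataset
from .metrics import (
    DEFAULT_CONFIDENCE_GRID,
    DEFAULT_VALIDITY_TOLERANCE,
    classification_calibration_curve,
    median_interval_width,
    observed_fuzziness,
    replicate_ci,
    validity_flag,
    CalibrationCurve,
)
from .strategies import STRATEGIES, fit_strategy


@dataclass
class StudyConfig:
    """Configuration of a replicated cross-validated strategy study."""

    task: str
    strategies: tuple = STRATEGIES
    n_old_grid: tuple = (300, 1000, 3000)
    n_new_grid: tuple = (30, 100, 300)
    cv_folds: int = 10
    replicates: int = 10
    k: int = 10
    confidence: float = 0.8
    confidence_grid: tuple = DEFAULT_CONFIDENCE_GRID
    base_seed: int = 1
    learner: LearnerConfig = field(default_factory=LearnerConfig)
    beta: float = 0.01
    interpolate_p: bool = True
    interpolate_quantile: bool = False
    median_rule: str = "midpoint"
    validity_tolerance: float = DEFAULT_VALIDITY_TOLERANCE

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")
        unknown = [s for s in self.strategies if s not in STRATEGIES]
        if unknown:
            raise ValueError(
                f"unknown strategy name(s) {unknown}; valid: {', '.join(STRATEGIES)}"
            )

    def config_hash(self) -> str:
        payload = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(self).items()
            if k != "learner"
        }
        payload["learner"] = vars(self.learner)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class StudyResult:
    """Long per-(strategy, sizes, replicate, fold) records plus curves."""

    results: pd.DataFrame
    curves: pd.DataFrame
    config: StudyConfig

    def aggregate(self) -> pd.DataFrame:
        return aggregate_study(self.results)


def _derived_seed(*entropy) -> int:
    return int(
        np.random.SeedSequence([int(e) for e in entropy]).generate_state(1)[0]
        % (2**31)
    )


def run_study(cfg: StudyConfig, A_old: LabeledDataset, A_new: LabeledDataset) -> StudyResult:
    """Execute the replicated cross-validated study."""
    if A_new.task != cfg.task or A_old.task != cfg.task:
        raise ValueError("dataset tasks must match the study task")
    rows: list[dict] = []
    curve_rows: list[dict] = []
    grid = np.asarray(cfg.confidence_grid, dtype=float)

    for r in range(cfg.replicates):
        shuffle_rng = np.random.default_rng(_derived_seed(cfg.base_seed, r, 1))
        perm = shuffle_rng.permutation(A_new.n)
        folds = np.array_split(perm, cfg.cv_folds)
        for f in range(cfg.cv_folds):
            test_idx = np.sort(folds[f])
            pool_idx = np.sort(
                np.concatenate([folds[j] for j in range(cfg.cv_folds) if j != f])
            )
            test = A_new.subset(test_idx)
            cp_seed = _derived_seed(cfg.base_seed, r, f, 2)
            for n_new in cfg.n_new_grid:
                for n_old in cfg.n_old_grid:
                    cell = dict(
                        task=cfg.task,
                        n_old=int(n_old),
                        n_new=int(n_new),
                        replicate=r,
                        fold=f,
                        n_test=int(test.n),
                    )
                    if n_new > len(pool_idx) or n_old > A_old.n:
                        for strat in cfg.strategies:
                            rows.append(
                                dict(
                                    strategy=strat,
                                    **cell,
                                    status="skipped",
                                    reason="requested size exceeds available data",
                                )
                            )
                        continue
                    samp_rng = np.random.default_rng(
                        _derived_seed(cfg.base_seed, r, f, n_new, n_old, 3)
                    )
                    sub_new = A_new.subset(
                        samp_rng.choice(pool_idx, size=n_new, replace=False)
                    )
                    sub_old = A_old.subset(
                        samp_rng.choice(A_old.n, size=n_old, replace=False)
                    )
                    for strat in cfg.strategies:
                        rows_before = len(rows)
                        try:
                            model = fit_strategy(
                                strat,
                                sub_old,
                                sub_new,
                                cfg=cfg.learner,
                                k=cfg.k if strat != "ICP_old_new" else 1,
                                seed=cp_seed,
                                beta=cfg.beta,
                                interpolate_p=cfg.interpolate_p,
                                interpolate_quantile=cfg.interpolate_quantile,
                                median_rule=cfg.median_rule,
                            )
                        except (CalibrationError, ValueError) as exc:
                            rows.append(
                                dict(
                                    strategy=strat,
                                    **cell,
                                    status="skipped",
                                    reason=str(exc),
                                )
                            )
                            continue
                        record = dict(strategy=strat, **cell, status="ok", reason="")
                        curve = _evaluate(
                            model, test, cfg, record
                        )
                        rows.append(record)
                        for conf, acc in zip(curve.confidence, curve.accuracy):
                            curve_rows.append(
                                dict(
                                    strategy=strat,
                                    n_old=int(n_old),
                                    n_new=int(n_new),
                                    replicate=r,
                                    fold=f,
                                    confidence=float(conf),
                                    accuracy=float(acc),
                                )
                            )
                        assert len(rows) == rows_before + 1
    results = pd.DataFrame(rows)
    curves = pd.DataFrame(curve_rows)
    return StudyResult(results=results, curves=curves, config=cfg)


def _evaluate(model, test: LabeledDataset, cfg: StudyConfig, record: dict) -> CalibrationCurve:
    grid = np.asarray(cfg.confidence_grid, dtype=float)
    if cfg.task == CLASSIFICATION:
        p = model.predict_p_values(test.X)
        curve = classification_calibration_curve(p, test.y, grid)
        p_true = np.zeros(test.n)
        for c, arr in p.items():
            p_true = np.where(test.y == c, arr, p_true)
        record["of"] = observed_fuzziness(p, test.y)
        record["accuracy"] = float(np.mean(p_true > 1.0 - cfg.confidence))
        record["width"] = np.nan
        record["coverage"] = np.nan
    else:
        confs = sorted(set(float(c) for c in grid) | {float(cfg.confidence)})
        by_conf = model.interval_grid(test.X, confs)
        iv = by_conf[float(cfg.confidence)]
        record["of"] = np.nan
        record["accuracy"] = np.nan
        record["width"] = median_interval_width(iv, cfg.confidence)
        record["coverage"] = float(np.mean(iv.contains(test.y.astype(float))))
        curve = CalibrationCurve(
            grid,
            np.array(
                [
                    float(np.mean(by_conf[float(c)].contains(test.y.astype(float))))
                    for c in grid
                ]
            ),
        )
    record["validity"] = validity_flag(curve, cfg.validity_tolerance)
    return curve


_METRIC_COLUMNS = ("of", "width", "coverage", "accuracy")


def aggregate_study(results: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Aggregate per-fold records to per-cell means with t-based CIs.

    Folds are averaged within each replicate first; the confidence
    interval is computed over the replicate means. Cells with fewer than
    two successful replicates get NaN interval bounds.
    """
    ok = results[results["status"] == "ok"]
    out_rows = []
    for (strat, n_old, n_new), grp in ok.groupby(["strategy", "n_old", "n_new"]):
        row = dict(strategy=strat, n_old=n_old, n_new=n_new)
        row["n_replicates"] = grp["replicate"].nunique()
        for metric in _METRIC_COLUMNS:
            per_rep = grp.groupby("replicate")[metric].mean().dropna()
            if len(per_rep) == 0:
                row[f"{metric}_mean"] = np.nan
                row[f"{metric}_lo"] = np.nan
                row[f"{metric}_hi"] = np.nan
            elif len(per_rep) == 1:
                row[f"{metric}_mean"] = float(per_rep.iloc[0])
                row[f"{metric}_lo"] = np.nan
                row[f"{metric}_hi"] = np.nan
            else:
                mean, lo, hi = replicate_ci(per_rep.to_numpy(), level)
                row[f"{metric}_mean"] = mean
                row[f"{metric}_lo"] = lo
                row[f"{metric}_hi"] = hi
        row["invalid_fraction"] = float(np.mean(grp["validity"] == "invalid"))
        out_rows.append(row)
    skipped = results[results["status"] == "skipped"]
    for (strat, n_old, n_new), grp in skipped.groupby(["strategy", "n_old", "n_new"]):
        already = any(
            r["strategy"] == strat and r["n_old"] == n_old and r["n_new"] == n_new
            for r in out_rows
        )
        if not already:
            out_rows.append(
                dict(
                    strategy=strat,
                    n_old=n_old,
                    n_new=n_new,
                    n_replicates=0,
                    status="skipped",
                    reason=grp["reason"].iloc[0],
                )
            )
    return pd.DataFrame(out_rows)
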
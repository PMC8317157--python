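"""Inductive conformal predictors for QSAR endpoints.

Two predictor types are provided:

* Mondrian binary classification — nonconformity is the negative signed
  distance to a linear SVM decision surface, calibrated per class so that
  validity holds class-conditionally even on imbalanced data.
* Normalized regression — nonconformity is the absolute residual scaled by
  a per-compound error estimate, α = |y − ŷ| / (exp(μ̂) + β), where ŷ comes
  from a scoring model and μ̂ from an error model trained on log absolute
  residuals (the "LogNormalized" measure of Papadopoulos & Haralambous).

p-values and interval quantiles can optionally be linearly interpolated
between the calibration order statistics, which matters for small
calibration sets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from sklearn.svm import LinearSVC, LinearSVR

from .io import ACTIVE, CLASSIFICATION, NONACTIVE, REGRESSION, LabeledDataset

#: additive guard inside the error-model log target, ln(|y − ŷ| + LOG_GUARD)
LOG_GUARD = 1e-6
#: clip range for predicted log errors before exponentiation
_MU_CLIP = 30.0


class CalibrationError(ValueError):
    """A calibration set is empty or too small to calibrate with."""


@dataclass
class LearnerConfig:
    """Hyperparameters of the underlying linear SVM learners.

    Defaults follow a LIBLINEAR setup tuned for sparse signature-count
    descriptors: cost 0.25, ε-SVR tube 0.01, termination tolerance 0.001.
    The solver types are L2-regularized L2-loss (primal for classification,
    dual for regression).
    """

    cost: float = 0.25
    svr_epsilon: float = 0.01
    tol: float = 1e-3
    max_iter: int = 100000
    seed: int = 0

    def make_classifier(self):
        return LinearSVC(
            C=self.cost,
            loss="squared_hinge",
            dual=False,
            tol=self.tol,
            max_iter=self.max_iter,
        )

    def make_regressor(self):
        return LinearSVR(
            C=self.cost,
            epsilon=self.svr_epsilon,
            loss="squared_epsilon_insensitive",
            dual=True,
            tol=self.tol,
            max_iter=self.max_iter,
            random_state=int(self.seed) % (2**31),
        )


# ---------------------------------------------------------------------------
# nonconformity measures
# ---------------------------------------------------------------------------


def classification_nonconformity(f_value, label):
    """Nonconformity of a decision value toward a class.

    ``f_value`` is oriented so that positive means active-like; the measure
    is the negative distance to the hyperplane for the hypothesised class:
    α(x, A) = −f(x) and α(x, N) = +f(x).
    """
    f = np.asarray(f_value, dtype=float)
    if label == ACTIVE:
        out = -f
    elif label == NONACTIVE:
        out = +f
    else:
        raise ValueError(f"unknown class {label!r}")
    return float(out) if np.isscalar(f_value) else out


def regression_nonconformity(y, y_hat, mu_hat, beta=0.01):
    """Normalized regression nonconformity α = |y − ŷ| / (exp(μ̂) + β)."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    mu = np.clip(np.asarray(mu_hat, dtype=float), -_MU_CLIP, _MU_CLIP)
    out = np.abs(y - y_hat) / (np.exp(mu) + beta)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# p-values and conformal quantiles
# ---------------------------------------------------------------------------


def p_value(test_alpha, calib_alphas, interpolate: bool = True):
    """Conformal p-value(s) of test nonconformity scores.

    Without interpolation this is the counting rule
    ``p = (#{α_i ≥ α_test} + 1) / (n + 1)`` with ties counted as ≥.
    With interpolation, p is piecewise linear between the counting-rule
    values at the sorted calibration scores, equal to 1 below the smallest
    score and to 1/(n+1) above the largest; the interpolated value never
    falls below the counting rule, so validity is preserved.
    """
    calib = np.sort(np.asarray(calib_alphas, dtype=float))
    n = calib.size
    if n == 0:
        raise CalibrationError("empty calibration set")
    t = np.asarray(test_alpha, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if not interpolate:
        count_ge = n - np.searchsorted(calib, t, side="left")
        p = (count_ge + 1.0) / (n + 1.0)
    else:
        first = np.searchsorted(calib, calib, side="left")
        knot_p = (n - first + 1.0) / (n + 1.0)
        p = np.interp(t, calib, knot_p, left=1.0, right=1.0 / (n + 1.0))
    return float(p[0]) if scalar else p


def conformal_quantile(calib_alphas, confidence: float, interpolate: bool = False):
    """Calibration-score quantile α* used for interval construction.

    The conformal index is ``⌈confidence · (n+1)⌉``; without interpolation
    α* is that order statistic, with interpolation α* interpolates linearly
    between adjacent order statistics at the fractional index
    ``confidence · (n+1)``. If the index exceeds n the interval is
    unbounded: returns ``(inf, False)``; otherwise ``(α*, True)``.
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    calib = np.sort(np.asarray(calib_alphas, dtype=float))
    n = calib.size
    if n == 0:
        raise CalibrationError("empty calibration set")
    q = confidence * (n + 1)
    if not interpolate:
        k = math.ceil(q)
        if k > n:
            return math.inf, False
        return float(calib[k - 1]), True
    if q >= n:
        return math.inf, False
    if q <= 1.0:
        return float(calib[0] * q), True
    k0 = math.floor(q)
    frac = q - k0
    return float(calib[k0 - 1] + frac * (calib[k0] - calib[k0 - 1])), True


# ---------------------------------------------------------------------------
# prediction containers
# ---------------------------------------------------------------------------


@dataclass
class PredictionSet:
    """Per-class conformal p-values for a batch of test compounds."""

    p_values: dict[str, np.ndarray]

    @property
    def classes(self):
        return tuple(self.p_values)

    @property
    def n(self) -> int:
        return len(next(iter(self.p_values.values())))

    def included(self, epsilon: float) -> dict[str, np.ndarray]:
        """Boolean inclusion masks per class at significance ε: p_c > ε."""
        return {c: p > epsilon for c, p in self.p_values.items()}

    def contains(self, truths, epsilon: float) -> np.ndarray:
        """Whether the set at significance ε contains each true label."""
        truths = np.asarray(truths)
        out = np.zeros(self.n, dtype=bool)
        for c, p in self.p_values.items():
            out |= (truths == c) & (p > epsilon)
        return out

    def set_sizes(self, epsilon: float) -> np.ndarray:
        inc = self.included(epsilon)
        return np.sum([m.astype(int) for m in inc.values()], axis=0)


@dataclass
class PredictionInterval:
    """Symmetric conformal intervals ŷ ± h at one confidence level."""

    midpoint: np.ndarray
    half_width: np.ndarray
    confidence: float

    def __post_init__(self) -> None:
        self.midpoint = np.atleast_1d(np.asarray(self.midpoint, dtype=float))
        self.half_width = np.atleast_1d(np.asarray(self.half_width, dtype=float))
        if np.any(self.half_width < 0):
            raise ValueError("negative interval half-width")

    @property
    def lower(self) -> np.ndarray:
        return self.midpoint - self.half_width

    @property
    def upper(self) -> np.ndarray:
        return self.midpoint + self.half_width

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def is_finite(self) -> np.ndarray:
        return np.isfinite(self.half_width)

    def contains(self, truths) -> np.ndarray:
        truths = np.asarray(truths, dtype=float)
        return (truths >= self.lower) & (truths <= self.upper)


# ---------------------------------------------------------------------------
# fitted predictors
# ---------------------------------------------------------------------------


def _require_disjoint(proper: LabeledDataset, calib: LabeledDataset) -> None:
    # cheap identity check: identical row content passed as both halves
    if proper.n == calib.n and proper.X.shape == calib.X.shape:
        same_x = (proper.X != calib.X).nnz == 0
        if same_x and np.array_equal(proper.y, calib.y):
            raise ValueError("proper training and calibration sets must be disjoint")


@dataclass
class IcpClassifier:
    """A fitted Mondrian inductive conformal classifier."""

    model: object
    calib_alphas: dict[str, np.ndarray]
    learner: LearnerConfig
    interpolate: bool = True

    def decision_values(self, X) -> np.ndarray:
        """Signed distance to the hyperplane, positive = active-like."""
        return np.asarray(self.model.decision_function(X), dtype=float)

    def predict_p_values(self, X) -> dict[str, np.ndarray]:
        f = self.decision_values(X)
        out = {}
        for c, alphas in self.calib_alphas.items():
            if alphas.size == 0:
                raise CalibrationError(f"empty calibration set for class {c!r}")
            out[c] = np.atleast_1d(
                p_value(classification_nonconformity(f, c), alphas, self.interpolate)
            )
        return out

    def predict_set(self, X, epsilon: float | None = None, confidence: float | None = None) -> PredictionSet:
        if epsilon is None:
            if confidence is None:
                raise ValueError("give either epsilon or confidence")
            epsilon = 1.0 - confidence
        if not 0.0 < epsilon < 1.0:
            raise ValueError("significance must lie in (0, 1)")
        return PredictionSet(self.predict_p_values(X))


def fit_icp_classifier(
    proper: LabeledDataset,
    calib: LabeledDataset,
    cfg: LearnerConfig | None = None,
    model=None,
    interpolate: bool = True,
) -> IcpClassifier:
    """Fit the scoring SVM on the proper set and calibrate per class.

    The active class is mapped to the positive side of the decision
    function. Both classes must appear in the proper training set and at
    least once each in the calibration set (Mondrian requirement).
    """
    cfg = cfg or LearnerConfig()
    if proper.task != CLASSIFICATION or calib.task != CLASSIFICATION:
        raise ValueError("classification datasets required")
    if calib.n < 1:
        raise CalibrationError("calibration set is empty")
    _require_disjoint(proper, calib)
    classes = (ACTIVE, NONACTIVE)
    for c in classes:
        if not np.any(proper.y == c):
            raise ValueError(f"class {c!r} absent from the proper training set")
        if not np.any(calib.y == c):
            raise CalibrationError(f"class {c!r} absent from the calibration set")
    model = model if model is not None else cfg.make_classifier()
    y_bin = (proper.y == ACTIVE).astype(int)
    model.fit(proper.X, y_bin)
    f_cal = np.asarray(model.decision_function(calib.X), dtype=float)
    calib_alphas = {
        c: np.asarray(
            classification_nonconformity(f_cal[calib.y == c], c), dtype=float
        )
        for c in classes
    }
    return IcpClassifier(model, calib_alphas, cfg, interpolate)


@dataclass
class IcpRegressor:
    """A fitted normalized inductive conformal regressor."""

    model: object
    error_model: object
    calib_alphas: np.ndarray
    beta: float
    learner: LearnerConfig
    interpolate: bool = False

    def point_predictions(self, X):
        y_hat = np.asarray(self.model.predict(X), dtype=float)
        mu = np.clip(
            np.asarray(self.error_model.predict(X), dtype=float), -_MU_CLIP, _MU_CLIP
        )
        sigma = np.exp(mu) + self.beta
        return y_hat, sigma

    def predict_interval(self, X, confidence: float) -> PredictionInterval:
        """Interval ŷ ± α*·(exp(μ̂)+β); unbounded if the conformal index
        exceeds the calibration size (half-width = inf, flagged via
        ``is_finite``)."""
        y_hat, sigma = self.point_predictions(X)
        alpha_star, _finite = conformal_quantile(
            self.calib_alphas, confidence, self.interpolate
        )
        return PredictionInterval(y_hat, alpha_star * sigma, confidence)


def fit_icp_regressor(
    proper: LabeledDataset,
    calib: LabeledDataset,
    cfg: LearnerConfig | None = None,
    beta: float = 0.01,
    interpolate: bool = False,
) -> IcpRegressor:
    """Fit scoring and error models on the proper set, calibrate on calib.

    The error model is trained on ln(|y − ŷ| + δ) of the proper-set
    residuals (δ guards exact fits), so exp(μ̂) estimates the expected
    absolute error of the scoring model for a compound.
    """
    cfg = cfg or LearnerConfig()
    if proper.task != REGRESSION or calib.task != REGRESSION:
        raise ValueError("regression datasets required")
    if calib.n < 1:
        raise CalibrationError("calibration set is empty")
    _require_disjoint(proper, calib)
    y_proper = proper.y.astype(float)
    model = cfg.make_regressor()
    model.fit(proper.X, y_proper)
    resid = np.abs(y_proper - model.predict(proper.X))
    error_model = cfg.make_regressor()
    error_model.fit(proper.X, np.log(resid + LOG_GUARD))
    y_hat_cal = np.asarray(model.predict(calib.X), dtype=float)
    mu_cal = np.asarray(error_model.predict(calib.X), dtype=float)
    alphas = regression_nonconformity(calib.y.astype(float), y_hat_cal, mu_cal, beta)
    return IcpRegressor(model, error_model, np.asarray(alphas, float), beta, cfg, interpolate)


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------


def _linear_state(model) -> dict:
    return {
        "coef": np.asarray(model.coef_).tolist(),
        "intercept": np.asarray(model.intercept_).tolist(),
        "classes": getattr(model, "classes_", np.array([])).tolist(),
    }


def _restore_linear(state: dict, maker):
    model = maker()
    model.coef_ = np.asarray(state["coef"], dtype=float)
    model.intercept_ = np.asarray(state["intercept"], dtype=float)
    if state.get("classes"):
        model.classes_ = np.asarray(state["classes"])
    model.n_features_in_ = model.coef_.shape[-1]
    return model


def save_icp(icp, path) -> None:
    """Save a fitted ICP as a JSON bundle (calibration scores verbatim)."""
    if isinstance(icp, IcpClassifier):
        payload = {
            "kind": "classifier",
            "model": _linear_state(icp.model),
            "calib_alphas": {c: a.tolist() for c, a in icp.calib_alphas.items()},
            "interpolate": icp.interpolate,
            "learner": vars(icp.learner),
        }
    elif isinstance(icp, IcpRegressor):
        payload = {
            "kind": "regressor",
            "model": _linear_state(icp.model),
            "error_model": _linear_state(icp.error_model),
            "calib_alphas": icp.calib_alphas.tolist(),
            "beta": icp.beta,
            "interpolate": icp.interpolate,
            "learner": vars(icp.learner),
        }
    else:
        raise TypeError(f"cannot save {type(icp).__name__}")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_icp(path):
    """Load an ICP saved by :func:`save_icp`."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    cfg = LearnerConfig(**payload["learner"])
    if payload["kind"] == "classifier":
        model = _restore_linear(payload["model"], cfg.make_classifier)
        alphas = {
            c: np.asarray(a, dtype=float) for c, a in payload["calib_alphas"].items()
        }
        return IcpClassifier(model, alphas, cfg, payload["interpolate"])
    model = _restore_linear(payload["model"], cfg.make_regressor)
    err = _restore_linear(payload["error_model"], cfg.make_regressor)
    return IcpRegressor(
        model,
        err,
        np.asarray(payload["calib_alphas"], dtype=float),
        payload["beta"],
        cfg,
        payload["interpolate"],
    )
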
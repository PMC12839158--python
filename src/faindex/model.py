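"""Two-predictor logit diagnostic function, LASSO development, validation.

``published_model`` returns the reported diagnostic function

    logit p = 5.254 - 0.145 * o63bi - 11.544 * c18_ratio,
    p = 1 / (1 + exp(-logit p)),

with the standardized coefficients carried as metadata. ``fit_lasso_logistic``
re-develops such a model from data: features are standardized, an L1 penalty
weight is chosen by stratified cross-validation over a log-spaced path, and
exact zeros are reported as excluded predictors. ``validate`` provides both
stratified k-fold cross-validation (pooled out-of-fold metrics) and the
optimism bootstrap, which refits the full selection procedure inside every
resample.

Classification direction: a sample is called diseased when its logit score
is >= the cut-off. Group means (disease +0.959 vs control -1.28) make this
the only direction consistent with the reported sensitivity/specificity,
even though the cut-off table reuses the "<= cut-off" wording of the
index tables.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .diagnostics import AUCResult, auc_delong

_LOGIT_PREDICTORS = ("o63bi", "c18_ratio")


class DegenerateMetricsError(ValueError):
    """Metrics are undefined because only one outcome class is present."""


class StratificationError(ValueError):
    """Stratified resampling/folding is infeasible for the given labels."""


@dataclass
class LogitModel:
    intercept: float
    coefficients: dict[str, float]
    standardized_coefficients: Optional[dict[str, float]] = None
    standardized_intercept: Optional[float] = None
    standardization: Optional[dict[str, tuple[float, float]]] = None
    excluded: tuple[str, ...] = ()
    separation_flag: bool = False
    lambda_: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "standardized_coefficients": self.standardized_coefficients,
            "standardized_intercept": self.standardized_intercept,
            "standardization": {
                k: list(v) for k, v in (self.standardization or {}).items()
            },
            "excluded": list(self.excluded),
            "separation_flag": self.separation_flag,
            "lambda": self.lambda_,
        }


@dataclass
class Prediction:
    logit_score: float
    probability: float


def published_model() -> LogitModel:
    """The reported two-predictor diagnostic function, constants verbatim.

    The arachidonate elongation ratio (aa_ada) was shrunk to exactly zero
    during selection and is recorded as excluded.
    """
    return LogitModel(
        intercept=5.254,
        coefficients={"o63bi": -0.145, "c18_ratio": -11.544},
        standardized_coefficients={"o63bi": -0.622, "c18_ratio": -1.416,
                                   "aa_ada": 0.000},
        standardized_intercept=-0.147,
        excluded=("aa_ada",),
    )


def predict(model: LogitModel, features: Union[Mapping[str, float], object]) -> Prediction:
    """Score one sample: logit = intercept + sum(beta_j * x_j)."""
    getter = features.get if isinstance(features, Mapping) else None
    logit = model.intercept
    for name, beta in model.coefficients.items():
        if getter is not None:
            value = getter(name)
            if value is None:
                raise KeyError(f"predictor {name!r} missing from features")
        else:
            try:
                value = getattr(features, name)
            except AttributeError:
                raise KeyError(f"predictor {name!r} missing from features") from None
        logit += beta * float(value)
    return Prediction(logit_score=logit, probability=1.0 / (1.0 + math.exp(-logit)))


def predict_scores(model: LogitModel, table: pd.DataFrame) -> np.ndarray:
    """Vectorized logit scores for a feature table (columns = predictors)."""
    missing = [name for name in model.coefficients if name not in table.columns]
    if missing:
        raise KeyError(f"predictors missing from features: {missing}")
    scores = np.full(len(table), model.intercept, dtype=float)
    for name, beta in model.coefficients.items():
        scores += beta * table[name].to_numpy(dtype=float)
    return scores


# ---------------------------------------------------------------------------
# LASSO development
# ---------------------------------------------------------------------------


@dataclass
class LassoConfig:
    """Development-procedure settings.

    ``lambda_`` fixes the penalty weight (0 = unpenalized MLE,
    ``math.inf`` = full shrinkage); when None the weight is chosen by
    stratified ``cv_folds``-fold cross-validation minimizing binomial
    deviance over ``n_lambdas`` log-spaced values, optionally with the
    one-standard-error rule.
    """

    lambda_: Optional[float] = None
    n_lambdas: int = 40
    lambda_min_ratio: float = 1e-4
    cv_folds: int = 10
    one_se: bool = False
    seed: Optional[int] = None
    max_iter: int = 5000


def _fit_l1(Xs: np.ndarray, y: np.ndarray, lam: float, max_iter: int) -> tuple[float, np.ndarray]:
    """L1-penalized logistic fit at glmnet-style weight lam (intercept free)."""
    n = len(y)
    model = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (n * lam), solver="saga", max_iter=max_iter,
        tol=1e-8, random_state=0,
    )
    model.fit(Xs, y)
    return float(model.intercept_[0]), model.coef_[0].copy()


def _fit_mle(Xs: np.ndarray, y: np.ndarray, max_iter: int) -> tuple[float, np.ndarray]:
    model = LogisticRegression(
        C=np.inf, solver="lbfgs", max_iter=max(max_iter, 10000), tol=1e-10
    )
    model.fit(Xs, y)
    return float(model.intercept_[0]), model.coef_[0].copy()


def _deviance(intercept: float, coef: np.ndarray, Xs: np.ndarray, y: np.ndarray) -> float:
    eta = intercept + Xs @ coef
    # -2 log-likelihood / n, numerically stable
    return float(2.0 * np.mean(np.logaddexp(0.0, eta) - y * eta))


def fit_lasso_logistic(
    features: pd.DataFrame,
    labels: Sequence[int],
    config: Optional[LassoConfig] = None,
) -> LogitModel:
    """Develop a penalized logistic model on a feature table.

    Features are centered/scaled before penalization; returned coefficients
    are reported on both the standardized and the original scale. Exact
    zeros are listed in ``excluded``. Constant features are dropped with a
    warning. Apparent complete separation of the fitted scores sets
    ``separation_flag`` (the penalized coefficients are still returned).
    """
    config = config or LassoConfig()
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise DegenerateMetricsError("both outcome classes are required for fitting")

    X = features.to_numpy(dtype=float)
    names = list(features.columns)
    scales = X.std(axis=0)
    constant = scales == 0.0
    if constant.any():
        dropped = [name for name, c in zip(names, constant) if c]
        _warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
        keep = ~constant
        X = X[:, keep]
        names = [name for name, c in zip(names, constant) if not c]
        scales = scales[keep]
    if not names:
        raise ValueError("no non-constant features remain")
    centers = X.mean(axis=0)
    Xs = (X - centers) / scales
    n = len(y)
    prevalence = y.mean()

    if config.lambda_ == math.inf:
        std_intercept = math.log(prevalence / (1.0 - prevalence))
        std_coef = np.zeros(len(names))
        lam = math.inf
    elif config.lambda_ == 0.0:
        std_intercept, std_coef = _fit_mle(Xs, y, config.max_iter)
        lam = 0.0
    else:
        if config.lambda_ is not None:
            lam = config.lambda_
        else:
            lam = _select_lambda(Xs, y, config)
        std_intercept, std_coef = _fit_l1(Xs, y, lam, config.max_iter)

    coefficients = {}
    standardized = {}
    excluded = []
    intercept = std_intercept
    for name, bs, center, scale in zip(names, std_coef, centers, scales):
        standardized[name] = float(bs)
        if bs == 0.0:
            excluded.append(name)
            coefficients[name] = 0.0
        else:
            coefficients[name] = float(bs / scale)
            intercept -= bs * center / scale

    scores = std_intercept + Xs @ std_coef
    separation = bool(scores[y == 1].min() > scores[y == 0].max()) if (
        (y == 1).any() and (y == 0).any()
    ) else False

    return LogitModel(
        intercept=float(intercept),
        coefficients=coefficients,
        standardized_coefficients=standardized,
        standardized_intercept=float(std_intercept),
        standardization={
            name: (float(c), float(s)) for name, c, s in zip(names, centers, scales)
        },
        excluded=tuple(excluded),
        separation_flag=separation,
        lambda_=None if lam == math.inf else float(lam),
    )


def _lambda_path(Xs: np.ndarray, y: np.ndarray, config: LassoConfig) -> np.ndarray:
    n = len(y)
    lambda_max = np.abs(Xs.T @ (y - y.mean())).max() / n
    lambda_max = max(lambda_max, 1e-12)
    return np.geomspace(lambda_max, lambda_max * config.lambda_min_ratio,
                        config.n_lambdas)


def _select_lambda(Xs: np.ndarray, y: np.ndarray, config: LassoConfig) -> float:
    path = _lambda_path(Xs, y, config)
    counts = np.bincount(y.astype(int))
    folds = min(config.cv_folds, counts.min())
    if folds < 2:
        raise StratificationError("too few samples in a class for CV")
    splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                               random_state=config.seed)
    deviances = np.zeros((len(path), folds))
    for fold, (train, test) in enumerate(splitter.split(Xs, y)):
        for i, lam in enumerate(path):
            b0, b = _fit_l1(Xs[train], y[train], lam, config.max_iter)
            deviances[i, fold] = _deviance(b0, b, Xs[test], y[test])
    mean_dev = deviances.mean(axis=1)
    best = int(np.argmin(mean_dev))
    if config.one_se:
        se = deviances.std(axis=1, ddof=1) / math.sqrt(folds)
        threshold = mean_dev[best] + se[best]
        # Largest lambda (most shrinkage) within one SE of the minimum.
        for i in range(len(path)):
            if mean_dev[i] <= threshold:
                best = i
                break
    return float(path[best])


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class ModelMetrics:
    auc: AUCResult
    brier: float
    cox_snell_r2: float
    nagelkerke_r2: float
    calibration_slope: float
    confusion: tuple[int, int, int, int]  # (tn, fp, fn, tp)
    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float
    kappa: float
    mcnemar_p: float
    nir_p: float


def confusion_metrics(tn: int, fp: int, fn: int, tp: int) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, MCC, kappa from a 2x2 table."""
    total = tn + fp + fn + tp
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = ((tp * tn - fp * fn) / mcc_den) if mcc_den else 0.0
    p_obs = accuracy
    p_yes = ((tp + fp) / total) * ((tp + fn) / total)
    p_no = ((tn + fn) / total) * ((tn + fp) / total)
    p_exp = p_yes + p_no
    kappa = (p_obs - p_exp) / (1.0 - p_exp) if p_exp != 1.0 else 0.0
    return {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "mcc": mcc,
        "kappa": kappa,
    }


def _log_likelihood(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1.0 - eps)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _calibration_slope(logit_scores: np.ndarray, y: np.ndarray) -> float:
    """Slope of an unpenalized logistic refit of the outcome on the score."""
    import statsmodels.api as sm

    exog = sm.add_constant(logit_scores)
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            result = sm.GLM(y, exog, family=sm.families.Binomial()).fit()
        return float(result.params[1])
    except Exception:
        return float("nan")


def evaluate(
    predictions: Sequence[Prediction],
    labels: Sequence[int],
    cutoff_logit: float = 0.0,
) -> ModelMetrics:
    """Discrimination, calibration, and classification metrics.

    Classification rule: disease when logit_score >= cutoff_logit.
    McNemar is the exact binomial test on the discordant cells; the
    no-information-rate test is a one-sided exact binomial test of the
    accuracy against the majority-class rate.
    """
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise DegenerateMetricsError("both outcome classes are required")
    probs = np.array([p.probability for p in predictions], dtype=float)
    scores = np.array([p.logit_score for p in predictions], dtype=float)
    if probs.size != y.size:
        raise ValueError("predictions and labels must be aligned")
    n = y.size

    auc = auc_delong(scores[y == 1], scores[y == 0], "disease_high")
    brier = float(np.mean((probs - y) ** 2))
    l1 = _log_likelihood(probs, y)
    l0 = _log_likelihood(np.full(n, y.mean()), y)
    cox_snell = 1.0 - math.exp(2.0 * (l0 - l1) / n)
    nagelkerke = cox_snell / (1.0 - math.exp(2.0 * l0 / n))
    slope = _calibration_slope(scores, y)

    predicted = scores >= cutoff_logit
    tp = int(np.sum(predicted & (y == 1)))
    fp = int(np.sum(predicted & (y == 0)))
    fn = int(np.sum(~predicted & (y == 1)))
    tn = int(np.sum(~predicted & (y == 0)))
    summary = confusion_metrics(tn, fp, fn, tp)

    discordant = fp + fn
    mcnemar_p = (
        stats.binomtest(min(fp, fn), discordant, 0.5).pvalue if discordant else 1.0
    )
    nir = max(y.mean(), 1.0 - y.mean())
    nir_p = stats.binomtest(tp + tn, n, nir, alternative="greater").pvalue

    return ModelMetrics(
        auc=auc,
        brier=brier,
        cox_snell_r2=cox_snell,
        nagelkerke_r2=nagelkerke,
        calibration_slope=slope,
        confusion=(tn, fp, fn, tp),
        accuracy=summary["accuracy"],
        sensitivity=summary["sensitivity"],
        specificity=summary["specificity"],
        mcc=summary["mcc"],
        kappa=summary["kappa"],
        mcnemar_p=float(mcnemar_p),
        nir_p=float(nir_p),
    )


# ---------------------------------------------------------------------------
# Riley feasibility
# ---------------------------------------------------------------------------


@dataclass
class RileyReport:
    n: int
    events: int
    n_params: int
    events_per_parameter: float
    required_n: int
    target_shrinkage: float
    anticipated_cs_r2: float
    passes: bool


def riley_feasibility(
    n: int,
    events: int,
    n_params: int,
    anticipated_cs_r2: float,
    target_shrinkage: float = 0.9,
) -> RileyReport:
    """Shrinkage-based minimum sample size for model development.

    required n = n_params / ((S - 1) * ln(1 - R2_CS / S)) with expected
    shrinkage factor S; also reports events-per-parameter.
    """
    if not 0 < events < n:
        raise ValueError("events must satisfy 0 < events < n")
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    if not 0.0 < anticipated_cs_r2 < target_shrinkage:
        raise ValueError("anticipated_cs_r2 must lie in (0, target_shrinkage)")
    required = n_params / (
        (target_shrinkage - 1.0) * math.log(1.0 - anticipated_cs_r2 / target_shrinkage)
    )
    required_n = math.ceil(required)
    return RileyReport(
        n=n,
        events=events,
        n_params=n_params,
        events_per_parameter=events / n_params,
        required_n=required_n,
        target_shrinkage=target_shrinkage,
        anticipated_cs_r2=anticipated_cs_r2,
        passes=n >= required_n,
    )


# ---------------------------------------------------------------------------
# Internal validation
# ---------------------------------------------------------------------------

_VALIDATED_METRICS = ("auc", "brier", "calibration_slope")


@dataclass
class ValidationReport:
    apparent: dict[str, float]
    cv: dict[str, float]
    optimism: dict[str, float]
    corrected: dict[str, float]
    B: int
    k: int
    seed: Optional[int]


def _score_metrics(scores: np.ndarray, y: np.ndarray) -> dict[str, float]:
    probs = 1.0 / (1.0 + np.exp(-scores))
    auc = auc_delong(scores[y == 1], scores[y == 0], "disease_high").auc
    return {
        "auc": auc,
        "brier": float(np.mean((probs - y) ** 2)),
        "calibration_slope": _calibration_slope(scores, y),
    }


def validate(
    features: pd.DataFrame,
    labels: Sequence[int],
    config: Optional[LassoConfig] = None,
    B: int = 1000,
    k: int = 10,
    seed: Optional[int] = None,
) -> ValidationReport:
    """Stratified k-fold CV plus the optimism bootstrap.

    CV pools out-of-fold logit scores and computes the metrics once on the
    pool. The bootstrap refits the entire development procedure (including
    penalty selection) on each stratified resample; per-resample optimism is
    metric(boot fit on boot sample) - metric(boot fit on original sample),
    and corrected = apparent - mean optimism. With B = 0 the corrected
    metrics equal the apparent metrics.
    """
    config = config or LassoConfig()
    y = np.asarray(labels, dtype=float)
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < k:
        raise StratificationError(
            f"each class needs >= k={k} members for stratified folds"
        )
    rng = np.random.default_rng(seed)

    def develop(X: pd.DataFrame, yy: np.ndarray) -> LogitModel:
        fold_config = LassoConfig(
            lambda_=config.lambda_,
            n_lambdas=config.n_lambdas,
            lambda_min_ratio=config.lambda_min_ratio,
            cv_folds=config.cv_folds,
            one_se=config.one_se,
            seed=int(rng.integers(2**31 - 1)),
            max_iter=config.max_iter,
        )
        return fit_lasso_logistic(X, yy, fold_config)

    full_model = develop(features, y)
    apparent = _score_metrics(predict_scores(full_model, features), y)

    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = np.empty(len(y))
    for train, test in splitter.split(features, y):
        fold_model = develop(features.iloc[train], y[train])
        pooled[test] = predict_scores(fold_model, features.iloc[test])
    cv_metrics = _score_metrics(pooled, y)

    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    optimism_sums = {name: 0.0 for name in _VALIDATED_METRICS}
    for _ in range(B):
        boot_idx = np.concatenate(
            [rng.choice(idx_pos, size=idx_pos.size, replace=True),
             rng.choice(idx_neg, size=idx_neg.size, replace=True)]
        )
        boot_model = develop(features.iloc[boot_idx], y[boot_idx])
        boot_on_boot = _score_metrics(
            predict_scores(boot_model, features.iloc[boot_idx]), y[boot_idx]
        )
        boot_on_orig = _score_metrics(predict_scores(boot_model, features), y)
        for name in _VALIDATED_METRICS:
            optimism_sums[name] += boot_on_boot[name] - boot_on_orig[name]
    optimism = {
        name: (optimism_sums[name] / B if B else 0.0)
        for name in _VALIDATED_METRICS
    }
    corrected = {name: apparent[name] - optimism[name] for name in _VALIDATED_METRICS}
    return ValidationReport(apparent, cv_metrics, optimism, corrected, B, k, seed)
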
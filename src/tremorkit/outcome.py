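"""DBS-outcome modelling: responder binarization, logistic regression with
Wald/likelihood-ratio inference, leave-one-out cross-validated prediction
metrics, and a linear model of the relative amplitude reduction.

Responder rule
--------------
A patient is a *poor* responder when, under stimulation, the residual
kinetic tremor amplitude is still >= 20 mm AND the relative reduction from
baseline is <= 30 %; anything else is a good response.  One table row is
one analysis unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    balanced_accuracy_score,
    confusion_matrix,
    f1_score,
    roc_auc_score,
)

from .io_formats import ParameterError, PipelineConfig

#: default covariates of the outcome model ("preoperative limb kinematics")
DEFAULT_FEATURES = ("peak_kinetic_amplitude_mm", "peak_postural_amplitude_mm",
                    "dominant_kinetic_frequency_hz", "dominant_postural_frequency_hz")


@dataclass
class LogisticFitResult:
    feature_names: list[str]         # "intercept" first
    coefficients: np.ndarray
    odds_ratios: np.ndarray          # exp(coefficients)
    or_ci95: np.ndarray              # (k, 2)
    wald_p: np.ndarray
    model_chi2: float                # LR test vs intercept-only
    model_p: float
    mcfadden_r2: float
    separation: bool = False


@dataclass
class CVMetrics:
    auroc: float
    balanced_accuracy: float
    f1: float
    accuracy: float
    precision: float
    recall: float
    confusion_matrix: np.ndarray     # rows true (good, poor), cols predicted
    n: int


def binarize_response(pre_mm: float, post_mm: float,
                      cfg: PipelineConfig | None = None) -> str:
    """Classify a DBS response as 'good' or 'poor'.

    Poor iff the residual amplitude under stimulation is at least
    ``responder_residual_mm`` (20 mm) AND the relative reduction
    ``(pre - post) / pre`` is at most ``responder_reduction_frac`` (30 %).
    """
    cfg = cfg or PipelineConfig()
    if pre_mm <= 0:
        raise ParameterError("pre_mm must be > 0")
    if post_mm < 0:
        raise ParameterError("post_mm must be >= 0")
    reduction = (pre_mm - post_mm) / pre_mm
    poor = (post_mm >= cfg.responder_residual_mm
            and reduction <= cfg.responder_reduction_frac)
    return "poor" if poor else "good"


def _design(records: pd.DataFrame, features) -> tuple[np.ndarray, np.ndarray]:
    features = list(features)
    missing = [f for f in features if f not in records.columns]
    if missing:
        raise ParameterError(f"missing feature column(s): {missing}")
    X = records[features].to_numpy(dtype=float)
    y = (records["responder"].astype(str) == "poor").to_numpy(dtype=float)
    return X, y


def _check_design(X: np.ndarray, features) -> None:
    Xc = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # name the offending columns by checking each against the rest
        collinear = []
        for j, name in enumerate(features):
            others = np.delete(Xc, j + 1, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                collinear.append(name)
        raise ParameterError(f"singular design; collinear feature(s): {collinear}")


def fit_logistic(records: pd.DataFrame,
                 features=DEFAULT_FEATURES) -> LogisticFitResult:
    """Maximum-likelihood logistic model of poor response on baseline features.

    Reports per-coefficient Wald p-values and 95 % odds-ratio CIs, the
    likelihood-ratio chi-square against the intercept-only model, and
    McFadden's pseudo-R^2 (1 - ll_model / ll_null).  Perfect separation is
    detected and reported (the fit then falls back to a lightly ridge-
    penalised solution, flagged in the result, instead of diverging
    silently).
    """
    features = list(features)
    X, y = _design(records, features)
    n = len(y)
    if n < 10:
        raise ParameterError("need at least 10 records")
    if y.min() == y.max():
        raise ParameterError("both response classes must be present")
    _check_design(X, features)

    Xc = sm.add_constant(X, has_constant="add")
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=Warning)
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True) or \
                np.abs(fit.params).max() > 50:
            raise RuntimeError("suspect separation")
        params = fit.params
        conf = fit.conf_int()
        pvals = fit.pvalues
        llf, llnull = fit.llf, fit.llnull
        chi2, chi2_p = fit.llr, fit.llr_pvalue
    except Exception:
        separation = True
        clf = LogisticRegression(C=1e3, max_iter=5000)
        clf.fit(X, y)
        params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
        conf = np.full((len(params), 2), np.nan)
        pvals = np.full(len(params), np.nan)
        p = np.clip(clf.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
        llf = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        pbar = y.mean()
        llnull = float(n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar)))
        chi2, chi2_p = 2 * (llf - llnull), float("nan")

    mcfadden = float(1.0 - llf / llnull) if llnull != 0 else float("nan")
    return LogisticFitResult(
        feature_names=["intercept"] + features,
        coefficients=np.asarray(params, dtype=float),
        odds_ratios=np.exp(np.asarray(params, dtype=float)),
        or_ci95=np.exp(np.asarray(conf, dtype=float)),
        wald_p=np.asarray(pvals, dtype=float),
        model_chi2=float(chi2), model_p=float(chi2_p),
        mcfadden_r2=mcfadden, separation=separation)


def loocv_evaluate(records: pd.DataFrame,
                   features=DEFAULT_FEATURES) -> CVMetrics:
    """Leave-one-out cross-validated prediction of the responder label.

    Each of the n refits leaves one record out; the held-out predicted
    probabilities are pooled, AUROC computed on the pool, and class
    predictions at 0.5 fill the confusion matrix / balanced accuracy / F1.
    A training fold that ends up single-class (only possible when the
    minority class has one member) predicts the fold's prevalence and a
    warning is issued.
    """
    features = list(features)
    X, y = _design(records, features)
    n = len(y)
    if n < 10:
        raise ParameterError("need at least 10 records")
    if y.min() == y.max():
        raise ParameterError("both response classes must be present")
    probs = np.empty(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            yi = y[mask]
            if yi.min() == yi.max():
                warnings.warn("single-class training fold: predicting prevalence")
                probs[i] = yi.mean()
                continue
            clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=2000)
            clf.fit(X[mask], yi)
            probs[i] = clf.predict_proba(X[i][None, :])[0, 1]
    pred = (probs >= 0.5).astype(float)
    cm = confusion_matrix(y, pred, labels=[0.0, 1.0])
    tn, fp, fn, tp = cm.ravel()
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    return CVMetrics(
        auroc=float(roc_auc_score(y, probs)),
        balanced_accuracy=float(balanced_accuracy_score(y, pred)),
        f1=float(f1_score(y, pred)),
        accuracy=float((pred == y).mean()),
        precision=float(precision), recall=float(recall),
        confusion_matrix=cm, n=n)


@dataclass
class LinearFitResult:
    feature_names: list[str]
    coefficients: np.ndarray
    p_values: np.ndarray
    r_squared: float


def fit_linear_response(records: pd.DataFrame,
                        features=DEFAULT_FEATURES) -> LinearFitResult:
    """OLS of the relative amplitude reduction on baseline features."""
    features = list(features)
    X = records[list(features)].to_numpy(dtype=float)
    yv = records["relative_reduction"].to_numpy(dtype=float)
    if len(yv) < 10:
        raise ParameterError("need at least 10 records")
    _check_design(X, features)
    fit = sm.OLS(yv, sm.add_constant(X, has_constant="add")).fit()
    return LinearFitResult(feature_names=["intercept"] + features,
                           coefficients=np.asarray(fit.params, dtype=float),
                           p_values=np.asarray(fit.pvalues, dtype=float),
                           r_squared=float(fit.rsquared))
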
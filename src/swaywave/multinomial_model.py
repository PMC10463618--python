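"""Multinomial logistic model of group membership on sensorimotor covariates.

The probability that subject i belongs to balance-strategy class k is the
softmax of class-specific linear predictors,

    P(Y_i = k) = exp(b_k0 + b_k . x_i) / sum_j exp(b_j0 + b_j . x_i),

with the reference class (group 3 by default) pinned at zero coefficients.
The (optionally ridge-penalized) log-likelihood is maximized by Newton's
method with step halving, so the iteration trace is monotone.  Wald standard
errors come from the inverse observed information at the optimum; p-values
use the normal approximation and 95% CIs are estimate +/- 1.96 SE.

With few subjects and many predictors the unpenalized MLE sits at or near
(quasi-)separation: coefficients grow without bound and the fit is reported
with ``converged=False`` plus an actionable message, rather than an error,
because that fragility is part of the result.  A small ridge penalty
(``penalty > 0``) restores a finite optimum.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import ParameterError, RankDeficientError, ValidationError

INTERCEPT = "(intercept)"


@dataclass
class ModelFit:
    """Coefficients and Wald inference for each non-reference class."""

    classes: list            # non-reference classes, row order of beta
    reference_class: str
    predictor_names: list    # without intercept
    beta: np.ndarray         # (K-1, p+1); column 0 is the intercept
    se: np.ndarray
    p: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    converged: bool
    message: str
    penalty: float
    n_obs: int
    loglik: float
    loglik_trace: list
    standardize: bool


def _check_rank(X, names):
    # QR with column pivoting exposes which columns are (nearly) dependent
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise RankDeficientError(bad)


def _probs(X, B):
    """Class probabilities, reference class last; overflow-safe softmax."""
    eta = X @ B.T
    eta = np.column_stack([eta, np.zeros(X.shape[0])])
    eta -= eta.max(axis=1, keepdims=True)
    e = np.exp(eta)
    return e / e.sum(axis=1, keepdims=True)


def _penalized_loglik(X, Y, B, penalty):
    P = _probs(X, B)
    Yfull = np.column_stack([Y, 1.0 - Y.sum(axis=1)])
    ll = float(np.sum(Yfull * np.log(np.clip(P, 1e-300, None))))
    if penalty > 0:
        ll -= 0.5 * penalty * float((B[:, 1:] ** 2).sum())
    return ll


def _newton(X, Y, penalty, max_iter=200, tol=1e-8):
    n, p1 = X.shape
    km1 = Y.shape[1]
    B = np.zeros((km1, p1))
    trace = [_penalized_loglik(X, Y, B, penalty)]
    converged = False
    message = "converged"
    for _ in range(max_iter):
        P = _probs(X, B)[:, :km1]
        grad = ((Y - P).T @ X).reshape(-1)
        if penalty > 0:
            pen_grad = penalty * B.copy()
            pen_grad[:, 0] = 0.0
            grad -= pen_grad.reshape(-1)
        H = np.zeros((km1 * p1, km1 * p1))
        for a in range(km1):
            for b in range(km1):
                w = P[:, a] * ((a == b) - P[:, b])
                H[a * p1:(a + 1) * p1, b * p1:(b + 1) * p1] = -(X.T * w) @ X
        if penalty > 0:
            d = np.tile(np.r_[0.0, np.full(p1 - 1, penalty)], km1)
            H -= np.diag(d)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-H, grad)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(-H, grad, rcond=None)
        # step halving keeps the penalized log-likelihood monotone
        ll0 = trace[-1]
        scale = 1.0
        for _ in range(40):
            B_new = B + scale * step.reshape(km1, p1)
            ll1 = _penalized_loglik(X, Y, B_new, penalty)
            if ll1 >= ll0 - 1e-12:
                break
            scale /= 2.0
        else:
            message = "step search stalled"
            break
        B = B_new
        trace.append(ll1)
        if abs(ll1 - ll0) < 1e-12 and np.max(np.abs(grad)) < 1e-4:
            converged = True
            break
    if not converged and message == "converged":
        message = (
            "did not converge (gradient still nonzero); with penalty=0 this "
            "usually indicates quasi/complete separation -- consider penalty > 0"
        )
    if converged and penalty == 0 and np.max(np.abs(B)) > 1e6:
        converged = False
        message = "coefficients diverging; likely separation -- consider penalty > 0"
    return B, H, trace, converged, message


def fit_multinomial(covariates: pd.DataFrame, reference: str = "group3",
                    standardize: bool = False, penalty: float = 0.0,
                    group_col: str = "group", predictors=None,
                    max_iter: int = 200) -> ModelFit:
    """Fit the softmax model of `group_col` on the predictor columns.

    ``covariates`` is one row per subject.  Predictors default to every
    ``x``-numbered column, in numeric order.  ``penalty`` is the ridge
    strength on non-intercept coefficients (0 = pure maximum likelihood).
    """
    if group_col not in covariates.columns:
        raise ValidationError(f"covariates must contain a {group_col!r} column")
    if predictors is None:
        xcols = [c for c in covariates.columns
                 if c.startswith("x") and c[1:].isdigit()]
        predictors = sorted(xcols, key=lambda c: int(c[1:]))
    if not predictors:
        predictors = []
    missing = [c for c in predictors if c not in covariates.columns]
    if missing:
        raise ValidationError(f"missing predictor columns: {', '.join(missing)}")
    sub = covariates[list(predictors) + [group_col]]
    if sub.isna().to_numpy().any():
        raise ValidationError("covariates contain missing values; the model "
                              "requires complete cases")
    if penalty < 0:
        raise ParameterError(f"penalty must be >= 0, got {penalty}")
    y = sub[group_col].astype(str).to_numpy()
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes to fit the model")
    if reference not in classes:
        raise ValidationError(
            f"reference class {reference!r} absent from data (classes: {classes})"
        )
    n = len(y)
    if n <= len(classes):
        raise ValidationError(f"n_obs={n} must exceed the number of classes")
    nonref = [c for c in classes if c != reference]
    Xraw = sub[list(predictors)].to_numpy(dtype=float)
    mu = np.zeros(Xraw.shape[1])
    sd = np.ones(Xraw.shape[1])
    if standardize and Xraw.shape[1]:
        mu = Xraw.mean(axis=0)
        sd = Xraw.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
    Xs = (Xraw - mu) / sd
    X = np.column_stack([np.ones(n), Xs])
    names = [INTERCEPT] + list(predictors)
    _check_rank(X, names)
    Y = np.column_stack([(y == c).astype(float) for c in nonref])

    B, H, trace, converged, message = _newton(X, Y, penalty, max_iter=max_iter)
    if converged and penalty == 0 and trace[-1] > -1e-6:
        # the training labels are fitted perfectly, so the unpenalized MLE
        # sits at infinity and the reported coefficients are arbitrary cutoffs
        converged = False
        message = ("log-likelihood reached zero: complete separation; "
                   "ML estimates are unbounded -- consider penalty > 0")

    # covariance of the estimates: inverse observed (penalized) information
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(-H)
        message += "; information matrix singular, SEs from pseudo-inverse"

    km1, p1 = B.shape
    if standardize:
        # back-transform to raw units: beta_j / sd_j, intercept absorbs means
        A = np.eye(p1)
        A[0, 1:] = -mu / sd
        for j in range(1, p1):
            A[j, j] = 1.0 / sd[j - 1]
        Ablk = np.kron(np.eye(km1), A)
        B = (A @ B.T).T
        cov = Ablk @ cov @ Ablk.T

    se = np.sqrt(np.clip(np.diag(cov), 0, None)).reshape(km1, p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, B / se, np.inf * np.sign(B + (B == 0)))
    p = 2 * stats.norm.sf(np.abs(z))
    ci_low = B - 1.96 * se
    ci_high = B + 1.96 * se
    return ModelFit(
        classes=nonref,
        reference_class=reference,
        predictor_names=list(predictors),
        beta=B,
        se=se,
        p=p,
        ci_low=ci_low,
        ci_high=ci_high,
        converged=converged,
        message=message,
        penalty=penalty,
        n_obs=n,
        loglik=trace[-1],
        loglik_trace=trace,
        standardize=standardize,
    )


def predict_group(fit: ModelFit, covariates) -> tuple:
    """Softmax class probabilities and the modal class for one subject.

    ``covariates`` maps predictor name -> value (dict or pandas Series).
    """
    if isinstance(covariates, pd.Series):
        covariates = covariates.to_dict()
    missing = [c for c in fit.predictor_names if c not in covariates]
    if missing:
        raise ValidationError(f"missing covariates: {', '.join(missing)}")
    x = np.array([1.0] + [float(covariates[c]) for c in fit.predictor_names])
    eta = np.r_[fit.beta @ x, 0.0]
    eta -= eta.max()
    e = np.exp(eta)
    probs_arr = e / e.sum()
    order = fit.classes + [fit.reference_class]
    probs = dict(zip(order, probs_arr))
    return probs, order[int(np.argmax(probs_arr))]


def coefficient_table(fit: ModelFit, contrast: str) -> pd.DataFrame:
    """Coefficient rows for one contrast against the reference class."""
    if contrast == fit.reference_class:
        raise ParameterError("contrast must differ from the reference class")
    if contrast not in fit.classes:
        raise ParameterError(
            f"unknown contrast {contrast!r}; fitted classes: {fit.classes}"
        )
    k = fit.classes.index(contrast)
    return pd.DataFrame(
        {
            "variable": [INTERCEPT] + fit.predictor_names,
            "p_value": fit.p[k],
            "beta": fit.beta[k],
            "se": fit.se[k],
            "ci_low": fit.ci_low[k],
            "ci_high": fit.ci_high[k],
            "significant": fit.p[k] < 0.05,
        }
    )
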
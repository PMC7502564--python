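"""Permutation-based association tests between lesion burden and clinic.

Continuous disability/cognition outcomes are tested with a covariate-
adjusted linear model whose p-value comes from the Freedman-Lane procedure:
fit the nuisance-only model, permute its residuals, add them back to the
nuisance fit, refit the full model and collect the permuted t-statistics of
the predictor of interest.  This keeps the nuisance (age, sex) structure
intact and is robust to non-Gaussian residuals.  Binary outcomes use a
logistic model with a predictor-residual permutation null (residualize the
predictor on the nuisance design, permute those residuals) on the
likelihood-ratio statistic — the Freedman-Lane analogue when the outcome
cannot be decomposed additively.  Families of tests are controlled by
Bonferroni correction; the family size is an explicit input, never inferred.

All p-values use the add-one estimator ``(1 + #{extreme}) / (1 + n_perms)``
and are therefore bounded below by ``1 / (n_perms + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AssociationResult",
    "freedman_lane_lm",
    "perm_logistic",
    "perm_group_diff",
    "adjust_bonferroni",
]


@dataclass(frozen=True)
class AssociationResult:
    outcome: str
    predictor: str
    family: str  # "linear" | "logistic" | "group_diff"
    coefficient: float
    direction: str  # "Positive" | "Negative" | "Zero"
    p_perm: float
    n_perms: int
    n_used: int
    n_dropped: int = 0
    bonferroni_significant: bool | None = None
    family_size: int | None = None
    alpha: float = 0.05
    flags: str = ""


def _direction(coef: float) -> str:
    if coef > 0:
        return "Positive"
    if coef < 0:
        return "Negative"
    return "Zero"


def _build_design(n: int, covariates) -> np.ndarray:
    """Nuisance design Z: intercept plus optional covariate columns."""
    if covariates is None:
        return np.ones((n, 1))
    C = (
        covariates.to_numpy(dtype=float)
        if isinstance(covariates, pd.DataFrame)
        else np.asarray(covariates, dtype=float)
    )
    if C.ndim == 1:
        C = C[:, None]
    return np.column_stack([np.ones(C.shape[0]), C])


def _drop_missing(*arrays):
    ok = np.ones(arrays[0].shape[0], dtype=bool)
    for a in arrays:
        ok &= np.isfinite(a).all(axis=1) if a.ndim == 2 else np.isfinite(a)
    return ok


def _t_stats(W: np.ndarray, Y: np.ndarray, pinv_W: np.ndarray, cxx: float) -> np.ndarray:
    """t-statistic of the first column of W for each column of Y."""
    beta = pinv_W @ Y
    resid = Y - W @ beta
    dof = W.shape[0] - W.shape[1]
    rss = np.sum(resid**2, axis=0)
    scale = np.maximum(np.sum(Y**2, axis=0), 1e-300)
    # (almost) exact fits have no usable error variance: t is +-inf when the
    # predictor coefficient carries signal, 0 when it is itself negligible
    exact = rss <= 1e-12 * scale
    signal = beta[0] ** 2 / cxx > 1e-12 * scale
    sigma2 = rss / dof
    se = np.sqrt(np.maximum(sigma2 * cxx, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[0] / np.where(se == 0, 1.0, se), 0.0)
    t = np.where(exact & signal, np.sign(beta[0]) * np.inf, t)
    return np.where(exact & ~signal, 0.0, t)


def freedman_lane_lm(
    y,
    x,
    covariates=None,
    n_perms: int = 5000,
    seed: int = 0,
    outcome: str = "y",
    predictor: str = "x",
) -> AssociationResult:
    """Freedman-Lane permutation test of ``x`` in ``y ~ x + covariates``.

    Rows with missing values are dropped (counted in the result).  The
    reported coefficient and direction come from the unpermuted full fit.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    Z = _build_design(y.shape[0], covariates)
    ok = _drop_missing(y, x, Z)
    n_drop = int((~ok).sum())
    y, x, Z = y[ok], x[ok], Z[ok]
    n = y.shape[0]
    if n < Z.shape[1] + 2:
        raise ValueError("too few complete observations")
    # collinearity of x with the nuisance design
    gamma, *_ = np.linalg.lstsq(Z, x, rcond=None)
    ex = x - Z @ gamma
    if np.sum(ex**2) <= 1e-12 * max(1.0, np.sum(x**2)):
        raise ValueError("predictor is collinear with the nuisance covariates")

    full = sm.OLS(y, np.column_stack([x, Z])).fit()
    coef = float(full.params[0])

    W = np.column_stack([x, Z])
    pinv_W = np.linalg.pinv(W)
    cxx = float(np.linalg.inv(W.T @ W)[0, 0])
    t_obs = float(_t_stats(W, y[:, None], pinv_W, cxx)[0])

    reduced_beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    yhat_r = Z @ reduced_beta
    e_r = y - yhat_r

    rng = np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((n_perms, n)), axis=1)  # independent permutations
    Ystar = yhat_r[:, None] + e_r[perm_idx].T  # (n, n_perms)
    t_star = _t_stats(W, Ystar, pinv_W, cxx)
    p = (1.0 + float(np.sum(np.abs(t_star) >= np.abs(t_obs) - 1e-12))) / (1.0 + n_perms)
    return AssociationResult(
        outcome, predictor, "linear", coef, _direction(coef), p, n_perms, n, n_drop
    )


# --------------------------------------------------------------------------
# logistic
# --------------------------------------------------------------------------

def _logit_fit(W: np.ndarray, y: np.ndarray, max_iter: int = 100, ridge: float = 1e-8):
    """Newton/IRLS logistic fit; returns (beta, loglik, converged)."""
    n, p = W.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(W @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        w = mu * (1.0 - mu)
        grad = W.T @ (y - mu)
        H = (W * w[:, None]).T @ W + ridge * np.eye(p)
        step = np.linalg.solve(H, grad)
        # step-halving if the likelihood does not improve
        t = 1.0
        while t > 1e-4:
            eta_new = np.clip(W @ (beta + t * step), -30, 30)
            ll_new = float(np.sum(y * eta_new - np.log1p(np.exp(eta_new))))
            if ll_new >= ll:
                break
            t /= 2.0
        beta = beta + t * step
        if abs(ll_new - ll_old) < 1e-10:
            converged = True
            ll = ll_new
            break
        ll_old = ll_new
        ll = ll_new
    return beta, ll, converged


def perm_logistic(
    y_binary,
    x,
    covariates=None,
    n_perms: int = 5000,
    seed: int = 0,
    outcome: str = "y",
    predictor: str = "x",
) -> AssociationResult:
    """Permutation test of ``x`` in a logistic model ``y ~ x + covariates``.

    The null distribution of the likelihood-ratio statistic is built by
    permuting the residuals of ``x`` regressed on the nuisance design and
    refitting.  Complete separation is flagged; the permutation p-value is
    still valid.
    """
    y = np.asarray(y_binary, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    Z = _build_design(y.shape[0], covariates)
    ok = _drop_missing(y, x, Z)
    n_drop = int((~ok).sum())
    y, x, Z = y[ok], x[ok], Z[ok]
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("outcome must be binary 0/1")
    if classes.size < 2:
        raise ValueError("both outcome classes must be present")

    gamma, *_ = np.linalg.lstsq(Z, x, rcond=None)
    xhat = Z @ gamma
    ex = x - xhat
    if np.sum(ex**2) <= 1e-12 * max(1.0, np.sum(x**2)):
        raise ValueError("predictor is collinear with the nuisance covariates")

    _, ll_red, _ = _logit_fit(Z, y)
    beta_full, ll_full, conv = _logit_fit(np.column_stack([x, Z]), y)
    lr_obs = max(0.0, 2.0 * (ll_full - ll_red))
    coef = float(beta_full[0])
    flags = ""
    if not conv or abs(coef) * float(np.std(x)) > 15.0:
        flags = "possible_separation"

    rng = np.random.default_rng(seed)
    lr_null = np.empty(n_perms)
    for i in range(n_perms):
        xs = xhat + ex[rng.permutation(ex.shape[0])]
        _, ll_f, _ = _logit_fit(np.column_stack([xs, Z]), y)
        lr_null[i] = max(0.0, 2.0 * (ll_f - ll_red))
    p = (1.0 + float(np.sum(lr_null >= lr_obs - 1e-12))) / (1.0 + n_perms)
    return AssociationResult(
        outcome, predictor, "logistic", coef, _direction(coef), p, n_perms, y.shape[0],
        n_drop, flags=flags,
    )


# --------------------------------------------------------------------------
# two-group comparison
# --------------------------------------------------------------------------

def perm_group_diff(
    values,
    groups,
    n_perms: int = 5000,
    seed: int = 0,
    n_boot: int = 2000,
    ci_level: float = 0.95,
) -> dict:
    """Permutation test and bootstrap CI for a two-group mean difference.

    Returns ``difference = mean(second group) - mean(first group)`` with
    group order given by sorted labels, a two-sided permutation p-value, and
    a percentile bootstrap confidence interval.
    """
    v = np.asarray(values, dtype=float).ravel()
    g = np.asarray(groups).ravel()
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError("exactly two groups required")
    a, b = v[g == labels[0]], v[g == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    diff = float(b.mean() - a.mean())

    rng = np.random.default_rng(seed)
    null = np.empty(n_perms)
    nb = len(b)
    for i in range(n_perms):
        perm = rng.permutation(v)
        null[i] = perm[:nb].mean() - perm[nb:].mean()
    p = (1.0 + float(np.sum(np.abs(null) >= abs(diff) - 1e-12))) / (1.0 + n_perms)

    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = (
            b[rng.integers(0, len(b), len(b))].mean()
            - a[rng.integers(0, len(a), len(a))].mean()
        )
    lo, hi = np.quantile(boots, [(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
    return {
        "groups": (labels[0], labels[1]),
        "difference": diff,
        "p_perm": p,
        "ci": (float(lo), float(hi)),
        "n": (len(a), len(b)),
    }


def adjust_bonferroni(
    results: list[AssociationResult], m: int, alpha: float = 0.05
) -> list[AssociationResult]:
    """Flag results significant at the Bonferroni-corrected level alpha/m."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    thr = alpha / m
    return [
        replace(r, bonferroni_significant=r.p_perm < thr, family_size=m, alpha=alpha)
        for r in results
    ]
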
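"""Causal-effect estimators: cross-fitted 2SLS second stage, plain 2SLS,
LIML (k-class) and the cross-fitted-instrument comparator CFMR.

All estimators regress a scalar exposure effect with an intercept.  The
2SLS standard error follows the standard instrumental-variable convention:
the error variance is estimated from residuals computed with the *observed*
exposure, Y - b0 - X*beta_hat, not with the first-stage fitted values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["EstimateResult", "CFIResult", "tsls_second_stage", "tsls_full",
           "liml", "cfmr"]


@dataclass
class EstimateResult:
    """A causal-effect estimate with inference summaries."""

    beta_hat: float
    se: float
    pval: float
    ci_low: float
    ci_high: float
    method: str
    n_instruments: int


@dataclass
class CFIResult:
    """Stacked cross-fitted instrument (one polygenic-score column)."""

    folds: list[np.ndarray]
    cfi: np.ndarray
    per_fold_n_selected: list[int]


def _wald_result(beta: float, se: float, df: int, method: str,
                 n_instruments: int) -> EstimateResult:
    tcrit = stats.t.ppf(0.975, df)
    tstat = beta / se if se > 0 else np.inf
    pval = float(2 * stats.t.sf(abs(tstat), df))
    pval = min(max(pval, np.finfo(float).tiny), 1.0)
    return EstimateResult(beta_hat=float(beta), se=float(se), pval=pval,
                          ci_low=float(beta - tcrit * se),
                          ci_high=float(beta + tcrit * se),
                          method=method, n_instruments=n_instruments)


def tsls_second_stage(
    outcome: np.ndarray,
    fitted_exposure: np.ndarray,
    observed_exposure: np.ndarray,
    outcome_binary: bool = False,
    method: str = "2sls",
    n_instruments: int = 1,
) -> EstimateResult:
    """Second-stage regression of the outcome on the fitted exposure.

    Continuous outcome: OLS of Y on [1, X_hat]; the SE uses residuals
    formed with the observed exposure.  Binary outcome: logistic regression
    of Y on [1, X_hat] with a Wald SE (predictor-substitution two-stage
    estimator).
    """
    y = np.asarray(outcome, dtype=float)
    xhat = np.asarray(fitted_exposure, dtype=float)
    x = np.asarray(observed_exposure, dtype=float)
    n = len(y)
    if np.ptp(xhat) == 0:
        raise ValueError("fitted exposure is constant: causal effect not identified")

    if outcome_binary:
        import statsmodels.api as sm
        fit = sm.Logit(y, sm.add_constant(xhat)).fit(disp=0)
        beta, se = fit.params[1], fit.bse[1]
        z = beta / se
        pval = float(2 * stats.norm.sf(abs(z)))
        zc = stats.norm.ppf(0.975)
        return EstimateResult(float(beta), float(se), min(max(pval, np.finfo(float).tiny), 1.0),
                              float(beta - zc * se), float(beta + zc * se),
                              method, n_instruments)

    Z = np.column_stack([np.ones(n), xhat])
    ZtZ = Z.T @ Z
    coef = np.linalg.solve(ZtZ, Z.T @ y)
    b0, beta = coef
    resid = y - b0 - x * beta           # observed-exposure residuals
    sigma2 = float(resid @ resid) / (n - 2)
    var_beta = sigma2 * np.linalg.inv(ZtZ)[1, 1]
    return _wald_result(beta, np.sqrt(var_beta), n - 2, method, n_instruments)


def _first_stage_fitted(x: np.ndarray, Z: np.ndarray) -> np.ndarray:
    D = np.column_stack([np.ones(len(x)), Z])
    coef, *_ = np.linalg.lstsq(D, x, rcond=None)
    return D @ coef


def tsls_full(data, instrument_columns) -> EstimateResult:
    """Standard two-stage least squares using all given instruments."""
    cols = np.asarray(instrument_columns, dtype=int)
    if cols.size == 0:
        raise ValueError("2SLS needs at least one instrument")
    Z = data.genotypes[:, cols]
    if Z.shape[1] >= data.n_samples:
        raise ValueError("more instruments than samples")
    xhat = _first_stage_fitted(data.exposure, Z)
    return tsls_second_stage(data.outcome, xhat, data.exposure,
                             outcome_binary=data.outcome_binary,
                             method="2sls", n_instruments=int(cols.size))


def liml(data, instrument_columns, kappa_override: float | None = None) -> EstimateResult:
    """Limited-information maximum likelihood (k-class) estimator.

    kappa is the smallest eigenvalue of the LIML eigenproblem on the
    centered (Y, X) cross-product matrices with and without the instrument
    projection; forcing ``kappa_override=1`` reproduces 2SLS exactly.
    Continuous outcomes only.
    """
    if data.outcome_binary:
        raise ValueError("LIML assumes a continuous outcome; it is not suitable "
                         "for binary outcomes — use MR-SPLIT or 2SLS with the "
                         "logistic second stage instead")
    cols = np.asarray(instrument_columns, dtype=int)
    if cols.size == 0:
        raise ValueError("LIML needs at least one instrument")
    n = data.n_samples
    # partial out the intercept: center everything
    y = data.outcome - data.outcome.mean()
    x = data.exposure - data.exposure.mean()
    Z = data.genotypes[:, cols]
    Z = Z - Z.mean(axis=0)

    W = np.column_stack([y, x])
    Q, _ = np.linalg.qr(Z)
    PW = Q @ (Q.T @ W)                 # projection of W onto col(Z)
    A = W.T @ W
    B = A - W.T @ PW                   # W' M_Z W
    if kappa_override is None:
        from scipy.linalg import eigvals as geigvals
        kappa = float(np.min(np.real(geigvals(A, B))))
    else:
        kappa = float(kappa_override)

    Px = PW[:, 1]
    denom = float(x @ x - kappa * (x @ x - x @ Px))
    numer = float(x @ y - kappa * (x @ y - Px @ y))
    beta = numer / denom
    resid = y - x * beta
    sigma2 = float(resid @ resid) / (n - 2)
    var_beta = sigma2 / denom
    if var_beta <= 0:
        raise ValueError("k-class variance not positive; instruments too weak")
    return _wald_result(beta, np.sqrt(var_beta), n - 2, "liml", int(cols.size))


def cfmr(
    data,
    k_folds: int = 10,
    selector: str = "lasso",
    sis_keep: int | None = None,
    seed: int = 0,
) -> tuple[EstimateResult, CFIResult]:
    """Cross-fitted MR: one stacked polygenic-score instrument over K folds.

    For each fold, an exposure-prediction model (SIS + LASSO) is trained on
    the complement and its predictions on the fold become the cross-fitted
    instrument there; the stacked instrument is then used in a single-IV
    2SLS on the full sample.  Folds with an empty selection contribute an
    intercept-only (constant) prediction.
    """
    from sklearn.linear_model import LassoCV
    from sklearn.model_selection import KFold

    from .iv_selection import sis_screen

    n = data.n_samples
    if k_folds < 2:
        raise ValueError("k_folds must be at least 2")
    if n < 2 * k_folds:
        raise ValueError(f"need at least {2 * k_folds} samples for {k_folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = [np.sort(f) for f in np.array_split(perm, k_folds)]

    cfi = np.empty(n)
    per_fold_n = []
    any_selected = False
    for k, fold in enumerate(folds):
        train = np.setdiff1d(np.arange(n), fold)
        y_tr = data.exposure[train]
        G_tr = data.genotypes[train]
        keep = min(sis_keep or max(1, len(train) // 2), data.n_snps)
        screened = sis_screen(y_tr, G_tr, keep)
        cv = KFold(5, shuffle=True, random_state=(seed + 7919 * (k + 1)) % (2**31 - 1))
        model = LassoCV(cv=cv, alphas=60, max_iter=5000).fit(G_tr[:, screened], y_tr)
        n_sel = int(np.sum(model.coef_ != 0))
        per_fold_n.append(n_sel)
        if n_sel == 0:
            cfi[fold] = y_tr.mean()
            continue
        any_selected = True
        cfi[fold] = model.predict(data.genotypes[np.ix_(fold, screened)])
    if not any_selected:
        raise ValueError("CFMR: every fold yielded an empty selection")

    xhat = _first_stage_fitted(data.exposure, cfi[:, None])
    est = tsls_second_stage(data.outcome, xhat, data.exposure,
                            outcome_binary=data.outcome_binary,
                            method="cfmr", n_instruments=1)
    return est, CFIResult(folds=folds, cfi=cfi, per_fold_n_selected=per_fold_n)
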
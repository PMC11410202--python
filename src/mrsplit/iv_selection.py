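"""Instrument selection within a half-sample.

The pipeline is: sure-independence screening (marginal-correlation ranking)
to cut the SNP dimension down to at most half the training-sample size,
then a cross-validated LASSO (or a desparsified LASSO with per-coefficient
p-values) to pick instruments and estimate their exposure effects, then a
partial-F statistic per selected instrument to classify it as *major*
(individually strong, partial F above a threshold — 30 by default) or
*weak* (everything else, later merged into a composite instrument).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "IVSelection", "PartialFResult", "sis_screen", "lasso_select",
    "debiased_lasso_select", "partial_f", "partial_f_all", "classify_ivs",
    "select_ivs",
]

DEFAULT_F_THRESHOLD = 30.0


@dataclass
class PartialFResult:
    """Partial-F test of one instrument's added explanatory power.

    ``f_value = ((rss_reduced - rss_full) / p_added) / (rss_full / df)``
    with ``df = n - k_full - 1`` the residual degrees of freedom of the
    full model (``k_full`` predictors plus an intercept).  With a single
    added predictor this equals the squared t-statistic of that predictor
    in the full model.
    """

    f_value: float
    rss_reduced: float
    rss_full: float
    n: int
    k_reduced: int
    p_added: int = 1


@dataclass
class IVSelection:
    """Selected instruments for one training half, with strength labels."""

    half_id: int
    selected: np.ndarray          # indices into the SNP columns
    alpha_hat: np.ndarray         # per-selected-SNP exposure effects
    partial_f: np.ndarray
    major: np.ndarray             # indices (subset of `selected`)
    weak: np.ndarray
    f_threshold: float

    def __post_init__(self) -> None:
        if not (len(self.selected) == len(self.alpha_hat) == len(self.partial_f)):
            raise ValueError("selected, alpha_hat and partial_f must be equally long")
        sel, mw = set(self.selected.tolist()), set(self.major.tolist()) | set(self.weak.tolist())
        if sel != mw or set(self.major.tolist()) & set(self.weak.tolist()):
            raise ValueError("major and weak must partition the selected set")

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def _ols_rss(y: np.ndarray, X: np.ndarray | None) -> float:
    """RSS of an OLS fit of y on [intercept, X]."""
    n = len(y)
    if X is None or X.shape[1] == 0:
        return float(np.sum((y - y.mean()) ** 2))
    Z = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
    r = y - Z @ coef
    return float(r @ r)


def sis_screen(exposure: np.ndarray, genotypes: np.ndarray, keep: int) -> np.ndarray:
    """Rank SNPs by absolute marginal correlation with the exposure.

    Returns the indices of the ``keep`` strongest SNPs, ordered by
    decreasing |correlation| with ties broken by ascending column index.
    Zero-variance columns are excluded from the ranking.
    """
    exposure = np.asarray(exposure, dtype=float)
    G = np.asarray(genotypes, dtype=float)
    n, p = G.shape
    if keep > p:
        raise ValueError(f"keep={keep} exceeds the number of SNPs ({p})")
    sd = G.std(axis=0)
    ok = sd > 0
    if not ok.all():
        logger.warning("sis_screen: excluding %d zero-variance SNP columns",
                       int((~ok).sum()))
    x = exposure - exposure.mean()
    xsd = x.std()
    if xsd == 0:
        raise ValueError("exposure has zero variance")
    Gc = G - G.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(Gc.T @ x) / (n * sd * xsd)
    corr[~ok] = -np.inf
    # stable sort on (-|r|, index) => ties broken by ascending index
    order = np.argsort(-corr, kind="stable")
    order = order[np.isfinite(corr[order])]
    return order[:keep]


def lasso_select(
    exposure: np.ndarray,
    genotypes_screened: np.ndarray,
    seed: int = 0,
    n_alphas: int = 60,
    cv_folds: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """LASSO selection of instruments among pre-screened SNPs.

    The penalty is chosen by K-fold cross-validation (CV-error minimizer)
    with a fold assignment seeded by ``seed`` so the whole pipeline is
    reproducible.  Returns (indices into the screened columns, nonzero
    penalized coefficients); an empty selection is returned, not raised.
    """
    cv = KFold(cv_folds, shuffle=True, random_state=seed % (2**31 - 1))
    model = LassoCV(cv=cv, alphas=n_alphas, max_iter=5000)
    model.fit(np.asarray(genotypes_screened, dtype=float),
              np.asarray(exposure, dtype=float))
    idx = np.flatnonzero(model.coef_)
    return idx, model.coef_[idx]


def debiased_lasso_select(
    exposure: np.ndarray,
    genotypes_screened: np.ndarray,
    p_threshold: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Desparsified-LASSO selection with per-coefficient p-values.

    Debiases the LASSO estimate coefficient-by-coefficient using nodewise
    LASSO residuals z_j (low-dimensional projection): the debiased estimate
    is  b_j = b_j^lasso + z_j'(y - X b^lasso) / (z_j'X_j)  with standard
    error  sigma_hat * ||z_j|| / |z_j'X_j|.  SNPs with two-sided normal
    p-value at most ``p_threshold`` are retained, with their debiased
    effects.  In an orthogonal design the debiased estimate reduces to the
    per-column OLS estimate.
    """
    X = np.asarray(genotypes_screened, dtype=float)
    y = np.asarray(exposure, dtype=float)
    n, p = X.shape
    if p >= n:
        raise ValueError(
            f"screened dimension ({p}) must be below the sample size ({n}); "
            "reduce the SIS keep count")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    base = LassoCV(cv=KFold(5, shuffle=True, random_state=seed % (2**31 - 1)),
                   alphas=40, max_iter=5000).fit(Xc, yc)
    beta = base.coef_
    resid = yc - Xc @ beta
    s = max(int(np.sum(beta != 0)), 0)
    sigma2 = float(resid @ resid) / max(n - s - 1, 1)

    debiased = np.empty(p)
    se = np.empty(p)
    lam_node = base.alpha_
    for j in range(p):
        others = np.delete(np.arange(p), j)
        node = Lasso(alpha=lam_node, max_iter=5000).fit(Xc[:, others], Xc[:, j])
        z = Xc[:, j] - node.predict(Xc[:, others])
        zx = float(z @ Xc[:, j])
        if abs(zx) < 1e-12:           # fully explained column: fall back to raw column
            z = Xc[:, j]
            zx = float(z @ z)
        debiased[j] = beta[j] + float(z @ resid) / zx
        se[j] = np.sqrt(sigma2) * np.linalg.norm(z) / abs(zx)
    pvals = 2 * stats.norm.sf(np.abs(debiased / se))
    idx = np.flatnonzero(pvals <= p_threshold)
    return idx, debiased[idx], pvals[idx]


def partial_f(exposure: np.ndarray, genotypes_selected: np.ndarray,
              target: int) -> PartialFResult:
    """Partial-F statistic for one instrument given the other selected ones.

    Full model: exposure on an intercept plus all selected columns; reduced
    model: the same without the ``target`` column.
    """
    y = np.asarray(exposure, dtype=float)
    Gs = np.asarray(genotypes_selected, dtype=float)
    n, k_full = Gs.shape
    if not 0 <= target < k_full:
        raise ValueError(f"target {target} outside the selected set (0..{k_full - 1})")
    df = n - k_full - 1
    if df <= 0:
        raise ValueError(
            f"too many instruments ({k_full}) for {n} observations in this half")
    rss_full = _ols_rss(y, Gs)
    rss_reduced = _ols_rss(y, np.delete(Gs, target, axis=1))
    rss_reduced = max(rss_reduced, rss_full)  # guard tiny negative round-off
    f = 0.0 if rss_full == 0 else (rss_reduced - rss_full) / (rss_full / df)
    return PartialFResult(f_value=f, rss_reduced=rss_reduced, rss_full=rss_full,
                          n=n, k_reduced=k_full - 1)


def partial_f_all(exposure: np.ndarray, genotypes_selected: np.ndarray) -> np.ndarray:
    """Partial-F values for every column of the selected set at once.

    Exploits the identity F_j = t_j^2, where t_j is column j's t-statistic
    in the full OLS model, so a single factorization replaces one
    reduced-model refit per instrument.  Agrees with :func:`partial_f` to
    numerical precision.
    """
    y = np.asarray(exposure, dtype=float)
    Gs = np.asarray(genotypes_selected, dtype=float)
    n, k_full = Gs.shape
    df = n - k_full - 1
    if df <= 0:
        raise ValueError(
            f"too many instruments ({k_full}) for {n} observations in this half")
    Z = np.column_stack([np.ones(n), Gs])
    gram_inv = np.linalg.pinv(Z.T @ Z)
    coef = gram_inv @ (Z.T @ y)
    r = y - Z @ coef
    s2 = float(r @ r) / df
    var = s2 * np.diag(gram_inv)[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(var > 0, coef[1:] ** 2 / var, 0.0)
    return f


def classify_ivs(
    selected: np.ndarray,
    alpha_hat: np.ndarray,
    f_values: np.ndarray,
    f_threshold: float = DEFAULT_F_THRESHOLD,
    half_id: int = 0,
) -> IVSelection:
    """Split selected instruments into major (F > threshold) and weak."""
    selected = np.asarray(selected)
    f_values = np.asarray(f_values, dtype=float)
    is_major = f_values > f_threshold
    return IVSelection(
        half_id=half_id,
        selected=selected,
        alpha_hat=np.asarray(alpha_hat, dtype=float),
        partial_f=f_values,
        major=selected[is_major],
        weak=selected[~is_major],
        f_threshold=f_threshold,
    )


def select_ivs(
    exposure: np.ndarray,
    genotypes: np.ndarray,
    f_threshold: float = DEFAULT_F_THRESHOLD,
    selector: str = "lasso",
    sis_keep: int | None = None,
    seed: int = 0,
    half_id: int = 0,
) -> IVSelection:
    """Full selection pipeline on one training sample.

    SIS screening keeps ``sis_keep`` SNPs (default: half the training-sample
    size, capped at p), then ``selector`` ("lasso" or "dlasso") picks the
    instruments, then each survivor gets a partial-F value and a major/weak
    label.  An empty selection yields an IVSelection with no instruments.
    """
    y = np.asarray(exposure, dtype=float)
    G = np.asarray(genotypes, dtype=float)
    n, p = G.shape
    if sis_keep is None:
        sis_keep = max(1, n // 2)
    keep = min(sis_keep, p)
    screened = sis_screen(y, G, keep)
    if selector == "lasso":
        loc, alpha_hat = lasso_select(y, G[:, screened], seed=seed)
    elif selector == "dlasso":
        loc, alpha_hat, _ = debiased_lasso_select(y, G[:, screened], seed=seed)
    else:
        raise ValueError(f"unknown selector {selector!r}")
    selected = screened[loc]
    if len(selected) == 0:
        empty = np.array([], dtype=int)
        return IVSelection(half_id, empty, np.array([]), np.array([]),
                           empty, empty, f_threshold)
    # cap at the partial-F degrees-of-freedom limit, keeping strongest effects
    max_k = n - 2
    if len(selected) > max_k:
        top = np.argsort(-np.abs(alpha_hat), kind="stable")[:max_k]
        selected, alpha_hat = selected[top], alpha_hat[top]
    f_values = partial_f_all(y, G[:, selected])
    return classify_ivs(selected, alpha_hat, f_values, f_threshold, half_id)
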
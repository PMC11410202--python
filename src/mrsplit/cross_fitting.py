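"""One random 2-fold split of the MR-SPLIT pipeline.

For each half I_k the instruments are selected on the *other* half, the
weak ones are merged into a signed, L1-normalized composite instrument
evaluated on I_k, and the exposure is regressed on the major instruments
plus the composite within I_k to give cross-fitted exposures.  Stacking the
two halves in original sample order yields X_hat for the full-sample
second-stage regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .estimators import EstimateResult, tsls_second_stage
from .iv_selection import DEFAULT_F_THRESHOLD, IVSelection, select_ivs

logger = logging.getLogger(__name__)

__all__ = ["SplitPlan", "CompositeIV", "SplitResult", "make_split",
           "composite_weights", "build_composite", "fit_first_stage",
           "run_single_split"]


@dataclass
class SplitPlan:
    """A random partition of {0..n-1} into two near-equal halves."""

    seed: int
    i1: np.ndarray
    i2: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.i1) + len(self.i2)
        union = np.union1d(self.i1, self.i2)
        if len(union) != n or not np.array_equal(union, np.arange(n)):
            raise ValueError("i1 and i2 must partition the sample")
        if abs(len(self.i1) - len(self.i2)) > 1:
            raise ValueError("half sizes may differ by at most 1")


@dataclass
class CompositeIV:
    """Weighted sum of weak-instrument dosages, weights from the other half."""

    weights: np.ndarray
    source_half: int
    values: np.ndarray


@dataclass
class SplitResult:
    """Estimate, inference and bookkeeping for one random split."""

    beta_l: float = np.nan
    se_l: float = np.nan
    pval_l: float = np.nan
    n_selected: float = 0.0
    n_major: float = 0.0
    n_weak: float = 0.0
    status: str = "ok"
    fitted_exposure: np.ndarray | None = None
    estimate: EstimateResult | None = None
    selections: tuple[IVSelection, ...] = field(default=())


def make_split(n: int, seed: int) -> SplitPlan:
    """Uniformly random split into halves of size floor(n/2) and n - floor(n/2)."""
    if n < 4:
        raise ValueError(f"need at least 4 samples to split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half = n // 2
    return SplitPlan(seed=seed, i1=np.sort(perm[:half]), i2=np.sort(perm[half:]))


def composite_weights(alpha_hat_weak: np.ndarray) -> np.ndarray:
    """Sign-preserving L1 normalization: w_j = alpha_j / sum_i |alpha_i|."""
    a = np.asarray(alpha_hat_weak, dtype=float)
    if a.size == 0:
        raise ValueError("no weak instruments to weight")
    total = np.abs(a).sum()
    if total == 0:
        raise ValueError("all weak-instrument effects are zero; cannot weight")
    return a / total


def build_composite(
    genotypes_target_half: np.ndarray,
    weak_indices: np.ndarray,
    weights: np.ndarray,
    source_half: int = 0,
) -> CompositeIV:
    """Evaluate the composite instrument on the target half's dosages."""
    G = np.asarray(genotypes_target_half, dtype=float)
    weak_indices = np.asarray(weak_indices, dtype=int)
    if weak_indices.size and weak_indices.max() >= G.shape[1]:
        raise IndexError("weak instrument index outside the genotype matrix")
    if len(weights) != len(weak_indices):
        raise ValueError("one weight per weak instrument required")
    values = G[:, weak_indices] @ np.asarray(weights, dtype=float)
    return CompositeIV(weights=np.asarray(weights, dtype=float),
                       source_half=source_half, values=values)


def fit_first_stage(
    exposure_half: np.ndarray,
    major_columns: np.ndarray | None,
    composite: CompositeIV | None,
) -> np.ndarray:
    """OLS fitted exposure on [intercept, major IVs, composite IV] in one half."""
    y = np.asarray(exposure_half, dtype=float)
    parts = [np.ones(len(y))]
    if major_columns is not None and major_columns.size:
        parts.append(np.asarray(major_columns, dtype=float).reshape(len(y), -1))
    if composite is not None:
        parts.append(composite.values.reshape(-1, 1))
    if len(parts) == 1:
        raise ValueError("first stage needs at least one instrument")
    D = np.column_stack(parts)
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        logger.warning("first stage: rank-deficient design (%d < %d); "
                       "least-squares fit uses the minimum-norm solution",
                       rank, D.shape[1])
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    return D @ coef


def run_single_split(
    data,
    plan: SplitPlan,
    f_threshold: float = DEFAULT_F_THRESHOLD,
    selector: str = "lasso",
    sis_keep: int | None = None,
    refit_alpha: bool = False,
    keep_fitted: bool = False,
) -> SplitResult:
    """Execute one full MR-SPLIT split and return its estimate.

    Selection on each half drives composite construction and first-stage
    fitting on the opposite half; an empty selection on either half marks
    the split ``failed`` (statistical degeneracy, not an exception).
    ``refit_alpha`` replaces the penalized effect estimates with a
    post-selection OLS refit before weighting.
    """
    halves = (plan.i1, plan.i2)
    xhat = np.empty(data.n_samples)
    selections = []
    n_major = n_weak = n_sel = 0.0
    for k, target in enumerate(halves):
        train = halves[1 - k]
        sel = select_ivs(data.exposure[train], data.genotypes[train],
                         f_threshold=f_threshold, selector=selector,
                         sis_keep=sis_keep, seed=plan.seed + 104729 * (k + 1),
                         half_id=k)
        if sel.n_selected == 0:
            logger.info("split seed %d: empty selection on half %d; split failed",
                        plan.seed, 1 - k)
            return SplitResult(status="failed", selections=tuple(selections))
        alpha = sel.alpha_hat
        if refit_alpha:
            Ztr = np.column_stack([np.ones(len(train)),
                                   data.genotypes[np.ix_(train, sel.selected)]])
            coef, *_ = np.linalg.lstsq(Ztr, data.exposure[train], rcond=None)
            alpha = coef[1:]
        weak_mask = np.isin(sel.selected, sel.weak)
        composite = None
        if weak_mask.any():
            w = composite_weights(alpha[weak_mask])
            composite = build_composite(data.genotypes[target],
                                        sel.selected[weak_mask], w,
                                        source_half=1 - k)
        majors = data.genotypes[np.ix_(target, sel.major)] if sel.major.size else None
        xhat[target] = fit_first_stage(data.exposure[target], majors, composite)
        selections.append(sel)
        n_sel += sel.n_selected / 2
        n_major += len(sel.major) / 2
        n_weak += len(sel.weak) / 2

    est = tsls_second_stage(data.outcome, xhat, data.exposure,
                            outcome_binary=data.outcome_binary,
                            method="mr-split",
                            n_instruments=int(round(n_sel)))
    return SplitResult(beta_l=est.beta_hat, se_l=est.se, pval_l=est.pval,
                       n_selected=n_sel, n_major=n_major, n_weak=n_weak,
                       status="ok",
                       fitted_exposure=xhat if keep_fitted else None,
                       estimate=est, selections=tuple(selections))
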
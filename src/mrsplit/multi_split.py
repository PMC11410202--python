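"""Multiple random splits with Cauchy-combination aggregation.

Single-split estimates are sensitive to which samples land in which half,
so the pipeline is repeated over L random splits; per-split p-values are
aggregated with the Cauchy combination rule

    T = sum_l w_l * tan((0.5 - p_l) * pi),    p_combined = 1/2 - arctan(T)/pi,

which is valid under arbitrary dependence between the p-values, and the
aggregated causal estimate is the arithmetic mean of the per-split
estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cross_fitting import SplitResult, make_split, run_single_split
from .iv_selection import DEFAULT_F_THRESHOLD

logger = logging.getLogger(__name__)

__all__ = ["MultiSplitResult", "cauchy_combine", "mr_split"]


@dataclass
class MultiSplitResult:
    """Aggregated result of L random splits."""

    splits: list[SplitResult]
    weights: np.ndarray
    t_cauchy: float
    p_combined: float
    beta_aggregated: float
    n_failed: int

    @property
    def n_successful(self) -> int:
        return len(self.splits) - self.n_failed


def cauchy_combine(
    pvals: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[float, float]:
    """Cauchy combination of (possibly dependent) p-values.

    Weights default to 1/L.  Endpoint p-values are clamped just inside
    (0, 1) because tan((0.5 - p) * pi) is singular there.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    eps = np.finfo(float).tiny
    if np.any((p <= 0) | (p >= 1)):
        logger.warning("cauchy_combine: clamping %d endpoint p-value(s)",
                       int(np.sum((p <= 0) | (p >= 1))))
        p = np.clip(p, eps, 1 - 1e-16)
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != p.size or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be nonnegative and sum to 1")
    t = float(np.sum(w * np.tan((0.5 - p) * np.pi)))
    p_comb = float(0.5 - np.arctan(t) / np.pi)
    return t, min(max(p_comb, eps), 1.0 - 1e-16)


def mr_split(
    data,
    n_splits: int = 50,
    f_threshold: float = DEFAULT_F_THRESHOLD,
    selector: str = "lasso",
    sis_keep: int | None = None,
    master_seed: int = 0,
    min_successful: int | None = None,
    refit_alpha: bool = False,
) -> MultiSplitResult:
    """Run MR-SPLIT over ``n_splits`` random splits and aggregate.

    Split l uses seed ``master_seed + l`` so any single split can be rerun
    in isolation.  Failed splits (empty selection in a half) are excluded
    and the Cauchy weights renormalized over the successes; fewer than
    ``min_successful`` successes (default: min(10, n_splits)) is an error.
    """
    if n_splits < 1:
        raise ValueError("need at least one split")
    if min_successful is None:
        min_successful = min(10, n_splits)
    results: list[SplitResult] = []
    for l in range(n_splits):
        plan = make_split(data.n_samples, master_seed + l)
        res = run_single_split(data, plan, f_threshold=f_threshold,
                               selector=selector, sis_keep=sis_keep,
                               refit_alpha=refit_alpha)
        logger.info("split %d: status=%s n_selected=%.1f n_major=%.1f "
                    "n_weak=%.1f beta=%.4g p=%.3g", l, res.status,
                    res.n_selected, res.n_major, res.n_weak, res.beta_l,
                    res.pval_l)
        results.append(res)
    ok = [r for r in results if r.status == "ok"]
    n_failed = len(results) - len(ok)
    if len(ok) < min_successful:
        raise ValueError(
            f"only {len(ok)}/{n_splits} splits succeeded "
            f"(minimum {min_successful}); the instruments may be too weak")
    weights = np.full(len(ok), 1.0 / len(ok))
    t, p_comb = cauchy_combine(np.array([r.pval_l for r in ok]), weights)
    beta = float(np.mean([r.beta_l for r in ok]))
    return MultiSplitResult(splits=results, weights=weights, t_cauchy=t,
                            p_combined=p_comb, beta_aggregated=beta,
                            n_failed=n_failed)
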
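"""Synthetic one-sample MR data and Monte-Carlo study harnesses.

Generative model
----------------
Independent SNPs with a common minor-allele frequency, dosages
G_ij ~ Binomial(2, maf).  A handful of causal SNPs carry exposure effects;
the ``causal_pattern`` entries are the SNPs' *relative shares of the
genetic variance* (the standard unequal-effects pattern
(0.4, 0.4, 0.1, 0.05, 0.05) and the equal pattern (0.2, ..., 0.2) each sum
to one), so ``alpha_j = omega0 * sqrt(a_j)`` with omega0 calibrated in
closed form so the causal SNPs jointly explain exactly a target fraction
h2 of the exposure variance.  Errors are bivariate normal,

    (e_x, e_y) ~ N(0, sigma2 * [[1, rho], [rho, 1]]),

with rho the confounding correlation, and

    X = G alpha + e_x,        Y = X beta + e_y.

The study harnesses reproduce the method-comparison designs: single-split
MR-SPLIT against half-sample-selection 2SLS/LIML, CFMR comparisons,
major-IV identification tables and split-count stability curves, each at a
configurable replicate count with replicate-level seeds derived from a
master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cross_fitting import make_split, run_single_split
from .data_io import MRData
from .estimators import cfmr, liml, tsls_full
from .iv_selection import select_ivs
from .multi_split import cauchy_combine

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "TruthRecord", "simulate_genotypes", "calibrate_omega0",
           "simulate_dataset", "run_estimator_study", "run_major_iv_study",
           "run_split_count_study"]

SCENARIO_I = (0.4, 0.4, 0.1, 0.05, 0.05)
SCENARIO_II = (0.2, 0.2, 0.2, 0.2, 0.2)

_MOD = 2**31 - 1


@dataclass
class SimConfig:
    """Full generative specification for one synthetic dataset."""

    n: int
    h2: float
    rho: float
    beta: float
    p_snps: int = 300
    maf: float = 0.3
    causal_pattern: tuple[float, ...] = SCENARIO_I
    sigma2: float = 1.0
    causal_placement: str = "fixed-first-k"   # or "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.maf < 0.5:
            raise ValueError("maf must be in (0, 0.5)")
        if not 0 <= self.h2 < 1:
            raise ValueError("h2 must be in [0, 1)")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be below 1")
        if len(self.causal_pattern) > self.p_snps:
            raise ValueError("more causal effects than SNPs")


@dataclass
class TruthRecord:
    """Ground truth accompanying a simulated dataset."""

    alpha: np.ndarray
    beta: float
    causal_indices: np.ndarray
    omega0: float


def simulate_genotypes(n: int, p_snps: int, maf: float,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """Independent additive dosages, each entry Binomial(2, maf)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(2, maf, size=(n, p_snps)).astype(float)


def calibrate_omega0(causal_pattern, maf: float, h2: float,
                     sigma2_x: float = 1.0) -> float:
    """Scale making the causal SNPs explain exactly h2 of the exposure variance.

    Pattern entries a_j are per-SNP shares of the genetic variance, so SNP j
    gets the coefficient ``alpha_j = omega0 * sqrt(a_j)``.  With independent
    Binomial(2, maf) dosages, Var(G alpha) = omega0^2 * sum_j a_j *
    2 maf (1 - maf), and requiring Var(G alpha) / (Var(G alpha) + sigma2_x)
    = h2 gives

        omega0 = sqrt( h2 * sigma2_x / ((1 - h2) * sum_j a_j * 2 maf (1-maf)) ).
    """
    a = np.asarray(causal_pattern, dtype=float)
    if np.any(a < 0):
        raise ValueError("variance shares must be nonnegative")
    if h2 == 0:
        return 0.0
    if not 0 < h2 < 1:
        raise ValueError("h2 must be in [0, 1)")
    denom = (1 - h2) * float(a.sum()) * 2 * maf * (1 - maf)
    if denom == 0:
        raise ValueError("causal pattern must contain a nonzero effect")
    return float(np.sqrt(h2 * sigma2_x / denom))


def simulate_dataset(config: SimConfig) -> tuple[MRData, TruthRecord]:
    """Draw one dataset from the structural model."""
    rng = np.random.default_rng(config.seed)
    G = simulate_genotypes(config.n, config.p_snps, config.maf, rng)
    k = len(config.causal_pattern)
    if config.causal_placement == "random":
        causal = np.sort(rng.choice(config.p_snps, size=k, replace=False))
    elif config.causal_placement == "fixed-first-k":
        causal = np.arange(k)
    else:
        raise ValueError(f"unknown causal_placement {config.causal_placement!r}")
    omega0 = calibrate_omega0(config.causal_pattern, config.maf, config.h2,
                              config.sigma2)
    alpha = np.zeros(config.p_snps)
    alpha[causal] = omega0 * np.sqrt(np.asarray(config.causal_pattern))
    cov = config.sigma2 * np.array([[1.0, config.rho], [config.rho, 1.0]])
    errors = rng.multivariate_normal([0.0, 0.0], cov, size=config.n)
    x = G @ alpha + errors[:, 0]
    y = x * config.beta + errors[:, 1]
    data = MRData(genotypes=G, exposure=x, outcome=y)
    return data, TruthRecord(alpha=alpha, beta=config.beta,
                             causal_indices=causal, omega0=omega0)


def _rep_seed(master_seed: int, cell: int, rep: int) -> int:
    return (master_seed + 1_000_003 * cell + 7_001 * rep) % _MOD


def half_sample_selection(data: MRData, plan, seed: int,
                          selector: str = "lasso") -> np.ndarray:
    """Select instruments on half I1 for estimation on I2 (no F classification)."""
    sel = select_ivs(data.exposure[plan.i1], data.genotypes[plan.i1],
                     selector=selector, seed=seed)
    return sel.selected


def _subset(data: MRData, idx: np.ndarray) -> MRData:
    return MRData(genotypes=data.genotypes[idx], exposure=data.exposure[idx],
                  outcome=data.outcome[idx], outcome_binary=data.outcome_binary,
                  sample_ids=data.sample_ids[idx], snp_ids=data.snp_ids)


def run_estimator_study(
    configs: list[SimConfig] | SimConfig,
    methods=("mrsplit", "2sls", "liml"),
    reps: int = 200,
    master_seed: int = 0,
    f_threshold: float = 30.0,
    cfmr_folds: int = 10,
    mrsplit_splits: int = 1,
    no_split: bool = False,
) -> pd.DataFrame:
    """Monte-Carlo comparison of estimators on a grid of generative settings.

    For each grid cell and replicate, one dataset is drawn and every
    requested method is run on it: single-split MR-SPLIT (``mrsplit_splits``
    splits, Cauchy-aggregated when > 1), 2SLS and LIML with instruments
    selected on one random half and the estimate computed on the other, and
    K-fold CFMR.  ``no_split=True`` switches 2SLS/LIML to whole-sample
    selection *and* estimation, the selection-bias demonstration variant.

    Returns one row per (cell, method) with |bias|*100, mean estimated SE,
    empirical SD, 95%-CI coverage and the rejection rate at 0.05.
    """
    if isinstance(configs, SimConfig):
        configs = [configs]
    rows = []
    for ci, cfg in enumerate(configs):
        per_method: dict[str, list] = {m: [] for m in methods}
        n_failed = {m: 0 for m in methods}
        for rep in range(reps):
            rs = _rep_seed(master_seed, ci, rep)
            data, truth = simulate_dataset(
                SimConfig(**{**cfg.__dict__, "seed": rs}))
            plan = make_split(cfg.n, seed=(rs + 13) % _MOD)
            selected = None
            for m in methods:
                try:
                    if m == "mrsplit":
                        if mrsplit_splits == 1:
                            r = run_single_split(data, plan, f_threshold=f_threshold)
                            if r.status != "ok":
                                n_failed[m] += 1
                                continue
                            est = r.estimate
                        else:
                            from .multi_split import mr_split as _ms
                            mres = _ms(data, n_splits=mrsplit_splits,
                                       f_threshold=f_threshold,
                                       master_seed=(rs + 13) % _MOD)
                            per_method[m].append(
                                (mres.beta_aggregated, np.nan, mres.p_combined,
                                 np.nan, np.nan))
                            continue
                    elif m in ("2sls", "liml"):
                        if no_split:
                            sel = select_ivs(data.exposure, data.genotypes,
                                             seed=(rs + 29) % _MOD)
                            cols, sub = sel.selected, data
                        else:
                            if selected is None:
                                selected = half_sample_selection(
                                    data, plan, seed=(rs + 29) % _MOD)
                            cols, sub = selected, _subset(data, plan.i2)
                        if len(cols) == 0:
                            n_failed[m] += 1
                            continue
                        est = tsls_full(sub, cols) if m == "2sls" else liml(sub, cols)
                    elif m == "cfmr":
                        est, _ = cfmr(data, k_folds=cfmr_folds,
                                      seed=(rs + 41) % _MOD)
                    else:
                        raise ValueError(f"unknown method {m!r}")
                except ValueError:
                    n_failed[m] += 1
                    continue
                per_method[m].append((est.beta_hat, est.se, est.pval,
                                      est.ci_low, est.ci_high))
        for m in methods:
            arr = np.array(per_method[m], dtype=float)
            if arr.size == 0:
                continue
            beta = cfg.beta
            covered = (arr[:, 3] <= beta) & (beta <= arr[:, 4])
            rows.append({
                "h2": cfg.h2, "rho": cfg.rho, "beta": beta, "n": cfg.n,
                "method": m, "reps": len(arr),
                "bias_x100": abs(beta - arr[:, 0].mean()) * 100,
                "mean_beta": arr[:, 0].mean(),
                "est_se": np.nanmean(arr[:, 1]),
                "emp_sd": arr[:, 0].std(ddof=1),
                "coverage": float(np.mean(covered)) if not np.isnan(arr[:, 3]).all() else np.nan,
                "rejection_rate": float(np.mean(arr[:, 2] < 0.05)),
                "n_failed": n_failed[m],
            })
    return pd.DataFrame(rows)


def run_major_iv_study(
    h2_values=(0.15, 0.3, 0.5),
    n_values=(500, 1000, 2000),
    thresholds=(10.0, 30.0, 50.0),
    reps: int = 200,
    master_seed: int = 0,
    p_snps: int = 300,
    maf: float = 0.3,
) -> pd.DataFrame:
    """Major-IV identification rates for the unequal-effects design.

    Per replicate, instruments are selected on one random half-sample
    (SIS + LASSO, as the split pipeline does) and classified by partial F;
    for each threshold the table records the fraction of replicates in
    which each causal SNP is classified major and the mean number of
    major-classified noise SNPs.
    """
    pattern = SCENARIO_I
    k = len(pattern)
    rows = []
    cell = 0
    for h2 in h2_values:
        for n in n_values:
            counts = {thr: np.zeros(k) for thr in thresholds}
            noise = {thr: 0.0 for thr in thresholds}
            for rep in range(reps):
                rs = _rep_seed(master_seed, cell, rep)
                cfg = SimConfig(n=n, h2=h2, rho=0.0, beta=0.0, p_snps=p_snps,
                                maf=maf, causal_pattern=pattern, seed=rs)
                data, truth = simulate_dataset(cfg)
                half = make_split(n, (rs + 3) % _MOD).i1
                sel = select_ivs(data.exposure[half], data.genotypes[half],
                                 seed=(rs + 3) % _MOD)
                for thr in thresholds:
                    major = sel.selected[sel.partial_f > thr]
                    is_causal = np.isin(major, truth.causal_indices)
                    for j, cidx in enumerate(truth.causal_indices):
                        counts[thr][j] += float(cidx in major)
                    noise[thr] += float(np.sum(~is_causal))
            for thr in thresholds:
                row = {"h2": h2, "n": n, "threshold": thr, "reps": reps,
                       "noise_mean": noise[thr] / reps}
                for j in range(k):
                    row[f"snp{j + 1}"] = counts[thr][j] / reps
                rows.append(row)
            cell += 1
    return pd.DataFrame(rows)


def run_split_count_study(
    config: SimConfig,
    split_counts=(10, 30, 50, 80),
    reps: int = 100,
    master_seed: int = 0,
    include_null: bool = True,
    f_threshold: float = 30.0,
) -> pd.DataFrame:
    """Rejection-rate stability as the number of random splits grows.

    For each replicate a single dataset is drawn and ``max(split_counts)``
    splits are run once; the Cauchy-combined p-value for each requested L
    reuses the first L splits, so the curves for different L are computed
    on identical randomness.
    """
    split_counts = sorted(split_counts)
    l_max = split_counts[-1]
    scenarios = [("alt", config.beta)]
    if include_null:
        scenarios.append(("null", 0.0))
    rows = []
    for label, beta in scenarios:
        reject = {L: 0 for L in split_counts}
        n_eval = 0
        for rep in range(reps):
            rs = _rep_seed(master_seed, 17 if label == "null" else 23, rep)
            cfg = SimConfig(**{**config.__dict__, "beta": beta, "seed": rs})
            data, _ = simulate_dataset(cfg)
            pvals = []
            for l in range(l_max):
                plan = make_split(cfg.n, (rs + 31 * l + 7) % _MOD)
                r = run_single_split(data, plan, f_threshold=f_threshold)
                if r.status == "ok":
                    pvals.append(r.pval_l)
            if len(pvals) < min(10, l_max):
                continue
            n_eval += 1
            for L in split_counts:
                sub = pvals[:min(L, len(pvals))]
                _, p = cauchy_combine(np.array(sub))
                reject[L] += int(p < 0.05)
        for L in split_counts:
            rows.append({"scenario": label, "beta": beta, "L": L,
                         "n": config.n, "h2": config.h2, "reps": n_eval,
                         "rejection_rate": reject[L] / max(n_eval, 1)})
    return pd.DataFrame(rows)
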
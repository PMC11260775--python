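"""Sensitivity analyses: heterogeneity, directional pleiotropy, outlier
detection (MR-PRESSO), leave-one-out, and trait-category exclusion runs.

These analyses probe the instrumental-variable assumptions that the point
estimators take for granted: Cochran's Q flags heterogeneity among the
per-SNP ratios, the Egger intercept tests for directional pleiotropy,
MR-PRESSO locates individual pleiotropic outliers by their contribution to
the residual sum of squares, and the category runs re-estimate the effect
after removing instruments annotated with potentially confounding traits.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, MRMethodUnavailable
from .estimators import (EstimatorConfig, MREstimate, MRResults, _ivw_core,
                         ivw, mr_egger, run_all)
from .harmonize import HarmonizedSet


@dataclasses.dataclass
class QResult:
    q: float
    df: int
    pval: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def cochran_q(hset: HarmonizedSet) -> QResult:
    """Cochran's Q over the per-SNP ratio estimates.

    Q = sum_j w_j (theta_j - theta_ivw)^2 with theta_j = Gamma_j/gamma_j and
    w_j = gamma_j^2/se_y_j^2; chi-square with J-1 df under homogeneity.
    """
    if len(hset) < 2:
        raise MRMethodUnavailable("cochran_q requires >= 2 SNPs")
    _, _, q = _ivw_core(hset.gamma, hset.Gamma, hset.se_y)
    df = len(hset) - 1
    return QResult(q, df, float(stats.chi2.sf(q, df)))


# --------------------------------------------------------------------- #
# MR-PRESSO

@dataclasses.dataclass
class PressoResult:
    rss_obs: float
    global_pval: float
    outlier_pvals: pd.Series
    outlier_rsids: set[str]
    beta_all: float
    beta_no_outliers: float
    distortion_coefficient: float
    distortion_pval: float
    distortion_defined: bool
    n_sim: int
    seed: int | None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outlier_pvals"] = {k: float(v) for k, v in self.outlier_pvals.items()}
        return d


def _loo_slopes(gamma: np.ndarray, Gamma: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes for every SNP at once (sums trick).

    Accepts 1-D arrays or (n_sim, J) matrices; operates along the last axis.
    """
    num = w * gamma * Gamma
    den = w * gamma**2
    tot_num = num.sum(axis=-1, keepdims=True)
    tot_den = den.sum(axis=-1, keepdims=True)
    return (tot_num - num) / (tot_den - den)


def mr_presso(
    hset: HarmonizedSet,
    n_sim: int = 1000,
    significance: float = 0.05,
    seed: int | None = None,
) -> PressoResult:
    """Pleiotropy residual-sum-and-outlier analysis.

    *Global test*: the observed residual sum of squares
    RSS = sum_j (Gamma_j - theta_hat(-j) * gamma_j)^2, where theta_hat(-j)
    is the leave-one-out IVW slope, is compared against its parametric null
    distribution obtained by redrawing gamma*_j ~ N(gamma_j, se_x_j^2) and
    Gamma*_j ~ N(theta_hat(-j) gamma_j, se_y_j^2) ``n_sim`` times.

    *Outlier test*: each SNP's squared residual is compared with its own
    simulated distribution; p-values are Bonferroni-multiplied by J and
    SNPs below ``significance`` are flagged.

    *Distortion test*: the percent change of the IVW estimate after outlier
    removal, referenced against the same quantity for random same-sized
    subsets of the non-outlier SNPs.
    """
    j = len(hset)
    if j < 4:
        raise MRMethodUnavailable("mr_presso requires >= 4 SNPs")
    rng = np.random.default_rng(seed)
    gamma, Gamma, se_x, se_y = hset.gamma, hset.Gamma, hset.se_x, hset.se_y
    w = 1.0 / se_y**2

    loo = _loo_slopes(gamma, Gamma, w)
    resid2_obs = (Gamma - loo * gamma) ** 2
    rss_obs = float(resid2_obs.sum())

    g_sim = rng.normal(gamma, se_x, size=(n_sim, j))
    G_sim = rng.normal(loo * gamma, se_y, size=(n_sim, j))
    loo_sim = _loo_slopes(g_sim, G_sim, np.broadcast_to(w, (n_sim, j)))
    resid2_sim = (G_sim - loo_sim * g_sim) ** 2
    rss_sim = resid2_sim.sum(axis=1)

    global_pval = float((1 + (rss_sim >= rss_obs).sum()) / (n_sim + 1))
    raw_p = (1 + (resid2_sim >= resid2_obs[None, :]).sum(axis=0)) / (n_sim + 1)
    adj_p = np.minimum(raw_p * j, 1.0)
    outlier_pvals = pd.Series(adj_p, index=hset.rsids, name="presso_pval")
    outlier_rsids = set(outlier_pvals.index[adj_p < significance])

    beta_all = ivw(hset, model="fixed").beta
    keep = [r for r in hset.rsids if r not in outlier_rsids]
    distortion_defined = bool(outlier_rsids) and (j - len(outlier_rsids)) > 2
    beta_no = beta_all
    distortion = 0.0
    distortion_pval = float("nan")
    if outlier_rsids and len(keep) >= 2:
        beta_no = ivw(hset.subset(keep), model="fixed").beta
        distortion = 100.0 * (beta_no - beta_all) / abs(beta_all) if beta_all != 0 else float("nan")
    if distortion_defined and beta_all != 0:
        k_out = len(outlier_rsids)
        n_null = min(n_sim, 1000)
        null = np.empty(n_null)
        keep_arr = np.array(keep)
        for i in range(n_null):
            removed = rng.choice(keep_arr, size=k_out, replace=False)
            sub = hset.subset([r for r in keep_arr if r not in set(removed)])
            null[i] = 100.0 * (ivw(sub, model="fixed").beta - beta_all) / abs(beta_all)
        distortion_pval = float((1 + (np.abs(null) >= abs(distortion)).sum()) / (n_null + 1))

    return PressoResult(
        rss_obs=rss_obs,
        global_pval=global_pval,
        outlier_pvals=outlier_pvals,
        outlier_rsids=outlier_rsids,
        beta_all=float(beta_all),
        beta_no_outliers=float(beta_no),
        distortion_coefficient=float(distortion),
        distortion_pval=distortion_pval,
        distortion_defined=distortion_defined,
        n_sim=n_sim,
        seed=seed,
    )


# --------------------------------------------------------------------- #
# Leave-one-out and category exclusions

def leave_one_out(hset: HarmonizedSet, model: str = "multiplicative_random") -> pd.DataFrame:
    """IVW re-estimated with each instrument removed in turn."""
    if len(hset) < 3:
        raise MRMethodUnavailable("leave_one_out requires >= 3 SNPs")
    rows = []
    for rsid in hset.rsids:
        e = ivw(hset.exclude([rsid]), model=model)
        rows.append({"rsid_removed": rsid, "beta": e.beta, "se": e.se,
                     "ci_low": e.ci_low, "ci_high": e.ci_high, "pval": e.pval})
    return pd.DataFrame(rows)


@dataclasses.dataclass
class CategoryRun:
    category: str
    mode: str  # 'exclude' or 'keep_only'
    n_snp: int
    results: MRResults | None
    q: QResult | None
    egger_intercept: float | None
    egger_intercept_pval: float | None
    not_estimable: str | None = None

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "mode": self.mode,
            "n_snp": self.n_snp,
            "results": self.results.to_dict() if self.results else None,
            "q": self.q.to_dict() if self.q else None,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_pval": self.egger_intercept_pval,
            "not_estimable": self.not_estimable,
        }


def category_exclusion_analysis(
    hset: HarmonizedSet,
    annotations: Mapping[str, set[str]],
    categories: Iterable[str],
    mode: str = "exclude",
    config: EstimatorConfig | None = None,
    runner=run_all,
) -> dict[str, CategoryRun]:
    """Re-run the full estimator battery on instrument panels reduced by
    trait-category annotation.

    ``mode='exclude'`` drops every instrument annotated with the category
    (probing whether that trait confounds the estimate); ``'keep_only'``
    retains only those instruments (the converse analysis).  Each run uses
    exactly the main analysis code path (``runner``, by default
    :func:`~ivmr.estimators.run_all`) on the reduced panel; a category that
    empties the panel is recorded as not estimable rather than failing.
    """
    if mode not in ("exclude", "keep_only"):
        raise ConfigurationError(f"unknown category mode: {mode}")
    out: dict[str, CategoryRun] = {}
    for cat in categories:
        tagged = {r for r in hset.rsids if cat in annotations.get(r, set())}
        reduced = hset.exclude(tagged) if mode == "exclude" else hset.subset(tagged)
        if len(reduced) == 0:
            out[cat] = CategoryRun(cat, mode, 0, None, None, None, None,
                                   not_estimable="no instruments remain")
            continue
        results = runner(reduced, config)
        q = cochran_q(reduced) if len(reduced) >= 2 else None
        egger_int = egger_int_p = None
        try:
            eg = mr_egger(reduced)
            egger_int = eg.extras["intercept"]
            egger_int_p = eg.extras["intercept_pval"]
        except MRMethodUnavailable:
            pass
        out[cat] = CategoryRun(cat, mode, len(reduced), results, q,
                               egger_int, egger_int_p)
    return out


# --------------------------------------------------------------------- #
# Aggregate report

@dataclasses.dataclass
class SensitivityReport:
    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_pval: float
    presso: PressoResult | None
    loo: pd.DataFrame | None
    category_runs: dict[str, CategoryRun]

    def to_dict(self) -> dict:
        return {
            "q_stat": self.q_stat,
            "q_df": self.q_df,
            "q_pval": self.q_pval,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_pval": self.egger_intercept_pval,
            "presso": self.presso.to_dict() if self.presso else None,
            "loo": self.loo,
            "category_runs": {k: v.to_dict() for k, v in self.category_runs.items()},
        }


def sensitivity_suite(
    hset: HarmonizedSet,
    annotations: Mapping[str, set[str]] | None = None,
    categories: Iterable[str] = (),
    keep_only_categories: Iterable[str] = (),
    presso_n_sim: int = 1000,
    presso_significance: float = 0.05,
    seed: int | None = None,
    config: EstimatorConfig | None = None,
) -> SensitivityReport:
    """Run the full sensitivity battery on a harmonized instrument set."""
    q = cochran_q(hset)
    eg = mr_egger(hset)
    presso = None
    try:
        presso = mr_presso(hset, n_sim=presso_n_sim,
                           significance=presso_significance, seed=seed)
    except MRMethodUnavailable:
        pass
    loo = None
    try:
        loo = leave_one_out(hset)
    except MRMethodUnavailable:
        pass
    runs: dict[str, CategoryRun] = {}
    if annotations is not None:
        runs.update(category_exclusion_analysis(hset, annotations, categories,
                                                mode="exclude", config=config))
        keep_runs = category_exclusion_analysis(hset, annotations,
                                                keep_only_categories,
                                                mode="keep_only", config=config)
        runs.update({f"only_{k}": v for k, v in keep_runs.items()})
    return SensitivityReport(
        q_stat=q.q, q_df=q.df, q_pval=q.pval,
        egger_intercept=eg.extras["intercept"],
        egger_intercept_se=eg.extras["intercept_se"],
        egger_intercept_pval=eg.extras["intercept_pval"],
        presso=presso, loo=loo, category_runs=runs,
    )
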
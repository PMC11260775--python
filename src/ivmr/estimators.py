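"""Causal-effect estimators for two-sample MR on harmonized summary data.

All estimators operate on per-SNP pairs (gamma_j, se_x_j) for the exposure
and (Gamma_j, se_y_j) for the outcome, aligned to a common effect allele.
The causal estimate is reported on the log-odds-per-SD scale together with
the exponentiated odds ratio and a normal-approximation 95% CI.

Implemented methods:

* Wald ratio — per-SNP estimate Gamma/gamma with first-order delta SE;
* IVW — inverse-variance-weighted combination, equivalent to weighted
  regression of Gamma on gamma through the origin, with multiplicative
  random-effects scaling of the SE (under-dispersion clipped at 1);
* MR-Egger — weighted regression with an intercept capturing average
  directional pleiotropy; instruments are oriented so gamma_j > 0 first;
* weighted median — robust to up to 50% of the weight coming from invalid
  instruments; SE by parametric bootstrap;
* weighted mode — consistent when the largest homogeneous cluster of
  ratio estimates is valid; weighted kernel-density argmax with a
  MAD-based bandwidth; SE by parametric bootstrap.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, EmptyInstrumentError, MRMethodUnavailable
from .harmonize import HarmonizedSet

_Z95 = float(stats.norm.ppf(0.975))


@dataclasses.dataclass
class MREstimate:
    """One method's causal estimate on the log-odds-per-SD scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    extras: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if math.isnan(self.ci_low):
            self.ci_low = self.beta - _Z95 * self.se
        if math.isnan(self.ci_high):
            self.ci_high = self.beta + _Z95 * self.se

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_ci_high(self) -> float:
        return math.exp(self.ci_high)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.update(odds_ratio=self.odds_ratio, or_ci_low=self.or_ci_low,
                 or_ci_high=self.or_ci_high)
        return d


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2 * stats.norm.sf(abs(beta) / se))


def _require(hset: HarmonizedSet, n_min: int, method: str) -> None:
    if len(hset) == 0:
        raise EmptyInstrumentError(f"{method}: empty instrument set")
    if len(hset) < n_min:
        raise MRMethodUnavailable(f"{method} requires >= {n_min} SNPs, got {len(hset)}")


# --------------------------------------------------------------------- #
# Wald ratio and IVW

def wald_ratio(pair: pd.Series | dict) -> MREstimate:
    """Per-SNP causal estimate Gamma/gamma with first-order delta-method SE
    se_y/|gamma|."""
    gamma, Gamma, se_y = float(pair["gamma"]), float(pair["Gamma"]), float(pair["se_y"])
    if gamma == 0:
        raise ConfigurationError(f"wald_ratio: gamma is zero for {pair.get('rsid', '?')}")
    beta = Gamma / gamma
    se = se_y / abs(gamma)
    return MREstimate("wald", beta, se, _normal_p(beta, se), n_snp=1,
                      extras={"rsid": pair.get("rsid")})


def _ivw_core(gamma: np.ndarray, Gamma: np.ndarray, se_y: np.ndarray):
    """Closed-form weighted regression through the origin.

    Returns (slope, fixed-effect SE, Q) where Q is Cochran's heterogeneity
    statistic of the per-SNP ratios about the slope.
    """
    w = gamma**2 / se_y**2
    denom = float(w.sum())
    if denom == 0:
        raise EmptyInstrumentError("ivw: zero total weight")
    theta = Gamma / gamma
    slope = float((w * theta).sum() / denom)
    se_fixed = denom ** -0.5
    q = float((w * (theta - slope) ** 2).sum())
    return slope, se_fixed, q


def ivw(hset: HarmonizedSet, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``model='fixed'`` uses the closed-form fixed-effect SE; the default
    ``'multiplicative_random'`` scales it by ``max(1, sqrt(Q/(J-1)))`` so
    that between-instrument heterogeneity widens the interval but
    under-dispersion never narrows it.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ConfigurationError(f"unknown IVW model: {model}")
    _require(hset, 1, "ivw")
    slope, se_fixed, q = _ivw_core(hset.gamma, hset.Gamma, hset.se_y)
    j = len(hset)
    scale = 1.0
    if model == "multiplicative_random" and j >= 2:
        scale = max(1.0, math.sqrt(q / (j - 1)))
    se = se_fixed * scale
    return MREstimate("ivw", slope, se, _normal_p(slope, se), n_snp=j,
                      extras={"q": q, "q_df": j - 1, "model": model,
                              "se_fixed": se_fixed, "re_scale": scale})


# --------------------------------------------------------------------- #
# MR-Egger

def mr_egger(hset: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: weighted least squares of Gamma on gamma with an
    intercept (average directional pleiotropy), weights 1/se_y².

    Instruments are first oriented so every gamma_j > 0; this is the
    conventional orientation that makes the intercept interpretable.  SEs
    use multiplicative random-effects scaling with the residual-based
    heterogeneity statistic on J-2 degrees of freedom, clipped below at 1.
    Slope estimate is returned as the MREstimate; the intercept and its
    SE/p-value ride along in ``extras``.
    """
    _require(hset, 3, "mr_egger")
    gamma, Gamma, se_y = hset.gamma.copy(), hset.Gamma.copy(), hset.se_y
    neg = gamma < 0
    gamma[neg] *= -1
    Gamma[neg] *= -1

    import statsmodels.api as sm

    x = sm.add_constant(gamma, has_constant="add")
    w = 1.0 / se_y**2
    fit = sm.WLS(Gamma, x, weights=w).fit()
    j = len(hset)
    # statsmodels scales bse by sqrt(residual scale); recover fixed-effect SEs
    scale = float(fit.scale)  # = Q_egger / (J - 2)
    se_fixed = fit.bse / math.sqrt(scale) if scale > 0 else fit.bse
    re_scale = max(1.0, math.sqrt(scale))
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    se_int, se_slope = float(se_fixed[0] * re_scale), float(se_fixed[1] * re_scale)

    collinear = bool(np.ptp(gamma) == 0)
    extras = {
        "intercept": intercept,
        "intercept_se": se_int,
        "intercept_pval": _normal_p(intercept, se_int),
        "q_egger": scale * (j - 2),
        "q_df": j - 2,
        "re_scale": re_scale,
    }
    if collinear:
        extras["warning"] = "all instrument strengths equal after orientation; slope ill-determined"
    return MREstimate("egger", slope, se_slope, _normal_p(slope, se_slope),
                      n_snp=j, extras=extras)


# --------------------------------------------------------------------- #
# Weighted median

def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    """Weighted median by linear interpolation of the cumulative weight
    midpoints: sort theta, take S_j - w_j/2 as the plotting position and
    interpolate at probability 0.5."""
    order = np.argsort(theta, kind="mergesort")
    theta = theta[order]
    w = w[order] / w[order].sum()
    p = np.cumsum(w) - w / 2
    return float(np.interp(0.5, p, theta))


def _parametric_resample(hset: HarmonizedSet, n_boot: int, rng: np.random.Generator):
    j = len(hset)
    g = rng.normal(hset.gamma, hset.se_x, size=(n_boot, j))
    G = rng.normal(hset.Gamma, hset.se_y, size=(n_boot, j))
    return g, G


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000,
                    seed: int | None = None) -> MREstimate:
    """Weighted-median estimate over the per-SNP ratios, inverse-variance
    weights ``gamma²/se_y²``; consistent while valid instruments carry more
    than half the weight.  SE from ``n_boot`` parametric-bootstrap
    replicates resampling both study's effects from their sampling
    distributions.
    """
    _require(hset, 3, "weighted_median")
    if n_boot < 2:
        raise ConfigurationError("weighted_median: n_boot must be >= 2")
    theta = hset.Gamma / hset.gamma
    w = hset.gamma**2 / hset.se_y**2
    est = _weighted_median_point(theta, w)

    rng = np.random.default_rng(seed)
    g, G = _parametric_resample(hset, n_boot, rng)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        gb = g[b]
        ok = gb != 0
        reps[b] = _weighted_median_point(G[b][ok] / gb[ok], gb[ok]**2 / hset.se_y[ok]**2)
    se = float(reps.std(ddof=1))
    return MREstimate("weighted_median", est, se, _normal_p(est, se),
                      n_snp=len(hset), extras={"n_boot": n_boot})


# --------------------------------------------------------------------- #
# Weighted mode

def _mode_bandwidth(theta: np.ndarray, phi: float) -> float:
    """Silverman-flavoured robust bandwidth: 0.9 * min(sd, 1.4826*MAD) *
    J^(-1/5), scaled by the user factor phi; MAD of zero falls back to the
    SD so a few duplicated ratios do not collapse the kernel."""
    sd = float(np.std(theta, ddof=1)) if len(theta) > 1 else 0.0
    mad = float(np.median(np.abs(theta - np.median(theta)))) * 1.4826
    s = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
    return phi * 0.9 * s * len(theta) ** (-0.2)


def _mode_point(theta: np.ndarray, w: np.ndarray, phi: float) -> float:
    """Argmax of the weighted Gaussian kernel density of the ratio
    estimates; coarse grid pass refined locally."""
    h = _mode_bandwidth(theta, phi)
    if h == 0:
        return float(theta[0])
    lo, hi = theta.min() - 2 * h, theta.max() + 2 * h

    def density(x: np.ndarray) -> np.ndarray:
        return (w[:, None] * np.exp(-0.5 * ((x[None, :] - theta[:, None]) / h) ** 2)).sum(axis=0)

    grid = np.linspace(lo, hi, 512)
    i = int(np.argmax(density(grid)))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    fine = np.linspace(a, b, 64)
    return float(fine[np.argmax(density(fine))])


def weighted_mode(hset: HarmonizedSet, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int | None = None) -> MREstimate:
    """Mode-based estimate: the weighted kernel-density argmax of the
    per-SNP ratios.  Valid as long as the largest homogeneous cluster of
    instruments is valid, i.e. tolerant of pleiotropy in a majority of SNPs
    provided their biases disagree.  SE by parametric bootstrap.
    """
    _require(hset, 3, "weighted_mode")
    if n_boot < 2:
        raise ConfigurationError("weighted_mode: n_boot must be >= 2")
    theta = hset.Gamma / hset.gamma
    w = hset.gamma**2 / hset.se_y**2
    w = w / w.sum()
    est = _mode_point(theta, w, bandwidth_factor)

    rng = np.random.default_rng(seed)
    g, G = _parametric_resample(hset, n_boot, rng)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        gb = g[b]
        ok = gb != 0
        wb = gb[ok]**2 / hset.se_y[ok]**2
        reps[b] = _mode_point(G[b][ok] / gb[ok], wb / wb.sum(), bandwidth_factor)
    se = float(reps.std(ddof=1))
    return MREstimate("weighted_mode", est, se, _normal_p(est, se),
                      n_snp=len(hset),
                      extras={"n_boot": n_boot, "bandwidth_factor": bandwidth_factor,
                              "bandwidth": _mode_bandwidth(theta, bandwidth_factor)})


# --------------------------------------------------------------------- #
# Batteries-included runner

@dataclasses.dataclass
class EstimatorConfig:
    ivw_model: str = "multiplicative_random"
    n_boot: int = 1000
    bandwidth_factor: float = 1.0
    seed: int | None = None


@dataclasses.dataclass
class MRResults:
    """The four headline estimates, per-method absences with reasons, and
    the per-SNP Wald ratios feeding the single-SNP forest plot."""

    estimates: list[MREstimate]
    absent: dict[str, str]
    single_snp: pd.DataFrame

    def get(self, method: str) -> MREstimate | None:
        for e in self.estimates:
            if e.method == method:
                return e
        return None

    def to_dict(self) -> dict:
        return {
            "estimates": [e.to_dict() for e in self.estimates],
            "absent": self.absent,
            "single_snp": self.single_snp,
        }


def run_all(hset: HarmonizedSet, config: EstimatorConfig | None = None) -> MRResults:
    """Run IVW, MR-Egger, weighted median and weighted mode plus the per-SNP
    Wald ratios.  A method whose minimum-SNP precondition fails is reported
    as absent with the reason; the run itself never fails on that account.
    """
    if len(hset) == 0:
        raise EmptyInstrumentError("run_all: empty instrument set")
    cfg = config or EstimatorConfig()
    seed_seq = np.random.SeedSequence(cfg.seed if cfg.seed is not None else 0)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(2)]

    estimates: list[MREstimate] = []
    absent: dict[str, str] = {}
    runners = [
        ("ivw", lambda: ivw(hset, model=cfg.ivw_model)),
        ("egger", lambda: mr_egger(hset)),
        ("weighted_median", lambda: weighted_median(hset, cfg.n_boot, seeds[0])),
        ("weighted_mode", lambda: weighted_mode(hset, cfg.bandwidth_factor,
                                                cfg.n_boot, seeds[1])),
    ]
    for name, fn in runners:
        try:
            estimates.append(fn())
        except MRMethodUnavailable as exc:
            absent[name] = str(exc)

    rows = []
    for _, pair in hset.pairs.iterrows():
        if pair["gamma"] == 0:
            continue
        e = wald_ratio(pair)
        rows.append({"rsid": pair["rsid"], "beta": e.beta, "se": e.se,
                     "ci_low": e.ci_low, "ci_high": e.ci_high, "pval": e.pval})
    single = pd.DataFrame(rows, columns=["rsid", "beta", "se", "ci_low", "ci_high", "pval"])
    return MRResults(estimates=estimates, absent=absent, single_snp=single)
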
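"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator instantiates the causal diagram behind a two-sample MR study:
per-SNP effects on a continuous exposure (SD units), a causal log-odds
effect theta of the exposure on a binary outcome, and an optional
horizontal-pleiotropy edge delta_j bypassing the exposure for an "invalid"
subset of instruments.  Observed effect sizes are the true values plus
sampling noise at the standard errors implied by the study sizes, so the
generated tables behave statistically like real GWAS output while the
generating truth stays available for calibration checks.

Standard errors use the usual summary-statistic approximations for a
standardized phenotype: se_x = 1/sqrt(2 n x (1-x)) for the quantitative
exposure and se_y = 1/sqrt(2 n_eff x (1-x)) for the binary outcome with
effective size n_eff = 4 / (1/n_case + 1/n_control).

A deterministic accounting fixture (:func:`make_reference_study`) exercises
every pipeline stage: 52 clumpable index SNPs, 48 shared with the outcome,
2 recoverable through planted proxies at r² >= 0.8, 7 ambiguous palindromic
SNPs and 1 incompatible-allele SNP, leaving exactly 42 instruments.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .io import SummaryTable, table_from_frame
from .ld import LDPanel

#: controlled trait-category vocabulary used by the annotation tables
DEFAULT_CATEGORIES = (
    "lipid", "blood", "inflammation", "body_composition", "type_2_diabetes", "other",
)

_NON_PALINDROMIC_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclasses.dataclass
class PleiotropyConfig:
    """Horizontal-pleiotropy regime: a fraction of instruments receive a
    direct outcome effect delta ~ N(mean, sd²); ``balanced`` forces the
    mean to zero."""

    fraction_invalid: float = 0.0
    mean: float = 0.0
    sd: float = 0.0
    balanced: bool = True

    def __post_init__(self):
        if not 0 <= self.fraction_invalid <= 1:
            raise ConfigurationError("fraction_invalid must lie in [0, 1]")


@dataclasses.dataclass
class LDStructure:
    """Panel layout: SNPs are grouped into consecutive blocks of
    ``block_size`` sharing within-block dosage correlation r² ~
    ``within_r2``; blocks land on loci separated by more than the standard
    clumping window so distinct blocks are unlinked."""

    n_individuals: int = 500
    block_size: int = 1
    within_r2: float = 0.9

    def __post_init__(self):
        if self.block_size < 1:
            raise ConfigurationError("block_size must be >= 1")
        if not 0 < self.within_r2 <= 1:
            raise ConfigurationError("within_r2 must lie in (0, 1]")


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for one synthetic two-sample dataset.

    Defaults mirror a large metabolite GWAS (n = 114,999) paired with a
    case-control outcome meta-analysis (9,358 cases / 15,482 controls).
    Instrument effects are drawn from a zero-mean normal truncated away
    from zero; the default scale gives a realistic total variance explained
    of roughly 10% for ~50 instruments.
    """

    n_snp: int = 100
    n_exposure: int = 114_999
    n_case: int = 9_358
    n_control: int = 15_482
    theta: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.08
    gamma_min: float = 0.01
    pleiotropy: PleiotropyConfig = dataclasses.field(default_factory=PleiotropyConfig)
    ld: LDStructure = dataclasses.field(default_factory=LDStructure)
    palindromic_fraction: float = 0.2
    strand_flip_fraction: float = 0.1
    swap_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        for name in ("palindromic_fraction", "strand_flip_fraction", "swap_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not 0 < self.maf_range[0] < self.maf_range[1] <= 0.5:
            raise ConfigurationError("maf_range must satisfy 0 < lo < hi <= 0.5")


@dataclasses.dataclass
class Truth:
    theta: float
    gamma: np.ndarray
    delta: np.ndarray
    valid_mask: np.ndarray
    maf: np.ndarray


@dataclasses.dataclass
class SimulatedStudy:
    exposure: SummaryTable
    outcome: SummaryTable
    panel: LDPanel
    annotations: dict[str, set[str]]
    truth: Truth


def binary_se(maf: np.ndarray | float, n_case: int, n_control: int) -> np.ndarray | float:
    """Per-allele log-odds standard error under the effective-sample-size
    approximation."""
    n_eff = 4.0 / (1.0 / n_case + 1.0 / n_control)
    return 1.0 / np.sqrt(2.0 * n_eff * maf * (1.0 - maf))


def quantitative_se(maf: np.ndarray | float, n: int) -> np.ndarray | float:
    """Per-allele SE for a standardized quantitative trait."""
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, 1e-300, 1.0)


def _truncated_normal(rng, sd: float, minimum: float, size: int) -> np.ndarray:
    """Zero-mean normal draws with |value| >= minimum (rejection)."""
    out = rng.normal(0.0, sd, size)
    while True:
        small = np.abs(out) < minimum
        if not small.any():
            return out
        out[small] = rng.normal(0.0, sd, small.sum())


def _block_positions(n_snp: int, block_size: int, rng) -> tuple[list[str], list[int]]:
    """Place each block on its own locus, >25 Mb from any other block on the
    same chromosome; members of one block sit 10 kb apart."""
    chroms, positions = [], []
    n_blocks = -(-n_snp // block_size)
    for b in range(n_blocks):
        chrom = str(b % 22 + 1)
        base = 20_000_000 + (b // 22) * 30_000_000
        for k in range(block_size):
            idx = b * block_size + k
            if idx >= n_snp:
                break
            chroms.append(chrom)
            positions.append(base + k * 10_000)
    return chroms, positions


def _block_genotypes(maf: np.ndarray, block_size: int, within_r2: float,
                     n_ind: int, rng) -> np.ndarray:
    """Dosage matrix with the requested within-block correlation.

    Each block's first SNP seeds two allele draws; other members copy those
    alleles, re-drawing each with probability 1 - sqrt(within_r2) so the
    expected dosage correlation is sqrt(within_r2) ** 2 = within_r2... the
    expected r is sqrt(within_r2), hence r² ~ within_r2.
    """
    n_snp = len(maf)
    dos = np.empty((n_ind, n_snp))
    mut = 1.0 - np.sqrt(within_r2)
    for start in range(0, n_snp, block_size):
        stop = min(start + block_size, n_snp)
        a1 = rng.random(n_ind) < maf[start]
        a2 = rng.random(n_ind) < maf[start]
        dos[:, start] = a1.astype(float) + a2
        for j in range(start + 1, stop):
            b1, b2 = a1.copy(), a2.copy()
            for b in (b1, b2):
                m = rng.random(n_ind) < mut
                b[m] = rng.random(m.sum()) < maf[j]
            dos[:, j] = b1.astype(float) + b2.astype(float)
    return dos


def simulate_two_sample(config: SimulationConfig) -> SimulatedStudy:
    """Draw one synthetic two-sample study; fully reproducible from
    ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_snp

    maf = rng.uniform(*config.maf_range, size=n)
    gamma = _truncated_normal(rng, config.gamma_sd, config.gamma_min, n)
    se_x = quantitative_se(maf, config.n_exposure)
    beta_x = rng.normal(gamma, se_x)

    plei = config.pleiotropy
    n_invalid = int(round(plei.fraction_invalid * n))
    invalid = np.zeros(n, dtype=bool)
    if n_invalid:
        invalid[rng.choice(n, size=n_invalid, replace=False)] = True
    delta = np.zeros(n)
    mu = 0.0 if plei.balanced else plei.mean
    if n_invalid:
        delta[invalid] = rng.normal(mu, plei.sd, n_invalid)

    se_y = binary_se(maf, config.n_case, config.n_control)
    # pleiotropy is directional relative to the exposure-increasing allele,
    # the frame in which the Egger intercept estimates its mean
    Gamma_true = config.theta * gamma + np.sign(gamma) * delta
    beta_y = rng.normal(Gamma_true, se_y)

    n_outcome = config.n_case + config.n_control
    eaf_x = np.clip(rng.normal(maf, np.sqrt(maf * (1 - maf) / (2 * config.n_exposure))),
                    1e-4, 1 - 1e-4)
    eaf_y = np.clip(rng.normal(maf, np.sqrt(maf * (1 - maf) / (2 * n_outcome))),
                    1e-4, 1 - 1e-4)

    # allele assignment
    n_pal = int(round(config.palindromic_fraction * n))
    pal = np.zeros(n, dtype=bool)
    if n_pal:
        pal[rng.choice(n, size=n_pal, replace=False)] = True
    effect = np.empty(n, dtype=object)
    other = np.empty(n, dtype=object)
    for j in range(n):
        pool = _PALINDROMIC_PAIRS if pal[j] else _NON_PALINDROMIC_PAIRS
        effect[j], other[j] = pool[rng.integers(len(pool))]

    rsids = [f"rs{100001 + j}" for j in range(n)]
    chroms, positions = _block_positions(n, config.ld.block_size, rng)

    exposure_df = pd.DataFrame({
        "rsid": rsids, "chrom": chroms, "pos": positions,
        "effect_allele": effect, "other_allele": other,
        "beta": beta_x, "se": se_x, "pval": _pvals(beta_x, se_x),
        "eaf": eaf_x, "n": config.n_exposure,
    })

    # outcome-side representation quirks: allele swaps and strand recoding
    o_effect, o_other = effect.copy(), other.copy()
    o_beta, o_eaf = beta_y.copy(), eaf_y.copy()
    swap = rng.random(n) < config.swap_fraction
    o_effect[swap], o_other[swap] = o_other[swap].copy(), o_effect[swap].copy()
    o_beta[swap] *= -1
    o_eaf[swap] = 1 - o_eaf[swap]
    flip = (rng.random(n) < config.strand_flip_fraction) & ~pal
    for j in np.nonzero(flip)[0]:
        o_effect[j] = _COMPLEMENT[o_effect[j]]
        o_other[j] = _COMPLEMENT[o_other[j]]

    outcome_df = pd.DataFrame({
        "rsid": rsids, "chrom": chroms, "pos": positions,
        "effect_allele": o_effect, "other_allele": o_other,
        "beta": o_beta, "se": se_y, "pval": _pvals(o_beta, se_y),
        "eaf": o_eaf, "n": n_outcome,
    })

    dosages = pd.DataFrame(
        _block_genotypes(maf, config.ld.block_size, config.ld.within_r2,
                         config.ld.n_individuals, rng),
        columns=rsids,
    )
    meta = pd.DataFrame({"rsid": rsids, "chrom": chroms, "pos": positions,
                         "counted_allele": effect})
    panel = LDPanel.from_genotypes(dosages, meta)

    truth = Truth(theta=config.theta, gamma=gamma, delta=delta,
                  valid_mask=delta == 0, maf=maf)
    return SimulatedStudy(
        exposure=table_from_frame(exposure_df, trait_label="exposure",
                                  n_total=config.n_exposure),
        outcome=table_from_frame(outcome_df, trait_label="outcome", n_total=n_outcome),
        panel=panel,
        annotations={},
        truth=truth,
    )


def annotate_invalid(study: SimulatedStudy, category: str = "lipid") -> dict[str, set[str]]:
    """Annotation table tagging exactly the pleiotropic (invalid)
    instruments with ``category`` — handy for category-exclusion checks."""
    rsids = study.exposure.df["rsid"].to_numpy()
    lookup = {f"rs{100001 + j}": bool(v) for j, v in enumerate(~study.truth.valid_mask)}
    return {r: {category} for r in rsids if lookup.get(r, False)}


# ===================================================================== #
# Deterministic accounting fixture

_FIXTURE_SEED = 7141


def make_reference_study() -> SimulatedStudy:
    """Deterministic end-to-end fixture with a fully known instrument
    accounting.

    The exposure study contains 52 genome-wide-significant, mutually
    unlinked index SNPs (plus clumpable satellites and sub-threshold SNPs
    that the selection stage must discard).  Four index SNPs are absent
    from the outcome study; two of them have planted proxies at r² >= 0.8
    (one of the proxies in anti-phase, so the allele mapping is exercised),
    the other two are unrecoverable.  Among the 50 instruments reaching
    harmonization, 7 are palindromic with MAF >= 0.3 (ambiguous) and 1 has
    irreconcilable alleles, so the final instrument panel holds exactly 42
    SNPs.  Trait-category annotations cover the vocabulary used by the
    exclusion analyses.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    theta = float(np.log(0.92))

    n_idx = 52
    idx_rsids = [f"rs{1001 + i}" for i in range(n_idx)]
    idx_chrom = [str(i % 22 + 1) for i in range(n_idx)]
    idx_pos = [20_000_000 + (i // 22) * 30_000_000 for i in range(n_idx)]

    # allele schedule driving the harmonization accounting
    pal_ambiguous = set(range(0, 7))     # A/T at MAF 0.40 -> dropped
    incompatible = {7}                   # outcome carries a third allele
    pal_inferred = {8, 9}                # A/T at MAF 0.12 -> kept, inferred
    strand_flipped = {10, 11}            # outcome on the other strand
    swapped = {12, 13, 14, 15}           # outcome alleles in reverse order
    missing_from_outcome = {48, 49, 50, 51}
    proxied = {48: "rs4001", 49: "rs4002"}   # recoverable at r² ~ 0.95
    weak_candidate = {50: "rs4003"}          # best candidate only r² ~ 0.3

    maf = rng.uniform(0.10, 0.45, n_idx)
    maf[list(pal_ambiguous)] = 0.40
    maf[list(pal_inferred)] = 0.12

    effect = np.empty(n_idx, dtype=object)
    other = np.empty(n_idx, dtype=object)
    for i in range(n_idx):
        if i in pal_ambiguous or i in pal_inferred:
            effect[i], other[i] = "A", "T"
        else:
            effect[i], other[i] = _NON_PALINDROMIC_PAIRS[int(rng.integers(8))]

    n_exposure, n_case, n_control = 114_999, 9_358, 15_482
    se_x = quantitative_se(maf, n_exposure)
    z = rng.uniform(10.0, 20.0, n_idx) * np.sign(rng.normal(size=n_idx))
    gamma = z * se_x
    beta_x = gamma.copy()  # exposure effects taken at truth (deterministic fixture)
    se_y = binary_se(maf, n_case, n_control)
    delta = rng.normal(0.0, 3.0 * se_y)      # heterogeneity among ratios
    Gamma = theta * gamma + delta

    exp_rows = []
    for i in range(n_idx):
        exp_rows.append({
            "rsid": idx_rsids[i], "chrom": idx_chrom[i], "pos": idx_pos[i],
            "effect_allele": effect[i], "other_allele": other[i],
            "beta": beta_x[i], "se": se_x[i],
            "pval": float(_pvals(np.array([beta_x[i]]), np.array([se_x[i]]))[0]),
            "eaf": maf[i], "n": n_exposure,
        })

    # satellites: clumped away (same window, high LD, larger p)
    sat_rsids = []
    for i in range(10):
        rsid = f"rs{2001 + i}"
        sat_rsids.append(rsid)
        exp_rows.append({
            "rsid": rsid, "chrom": idx_chrom[i], "pos": idx_pos[i] + 50_000,
            "effect_allele": effect[i], "other_allele": other[i],
            "beta": gamma[i] * 0.9, "se": se_x[i], "pval": 1e-9,
            "eaf": maf[i], "n": n_exposure,
        })
    # sub-threshold SNPs: removed by the p < 5e-8 filter
    for i in range(5):
        exp_rows.append({
            "rsid": f"rs{3001 + i}", "chrom": str(i + 1), "pos": 5_000_000,
            "effect_allele": "A", "other_allele": "G",
            "beta": 0.01, "se": 0.004, "pval": 1e-6,
            "eaf": 0.3, "n": n_exposure,
        })

    # ---------------- outcome table ----------------
    n_outcome = n_case + n_control
    out_rows = []
    for i in range(n_idx):
        if i in missing_from_outcome:
            continue
        e, o, b, f = effect[i], other[i], Gamma[i], maf[i]
        if i in incompatible:
            # pick an allele set irreconcilable with the exposure's pair,
            # directly and after strand complement
            exp_set = {effect[i], other[i]}
            comp_set = {_COMPLEMENT[a] for a in exp_set}
            e, o = next((p for p in _NON_PALINDROMIC_PAIRS
                         if set(p) != exp_set and set(p) != comp_set))
        if i in swapped:
            e, o, b, f = o, e, -b, 1 - f
        if i in strand_flipped:
            e, o = _COMPLEMENT[e], _COMPLEMENT[o]
        out_rows.append({
            "rsid": idx_rsids[i], "chrom": idx_chrom[i], "pos": idx_pos[i],
            "effect_allele": e, "other_allele": o,
            "beta": b, "se": se_y[i],
            "pval": float(_pvals(np.array([b]), np.array([se_y[i]]))[0]),
            "eaf": f, "n": n_outcome,
        })

    # proxies for two of the four missing SNPs (rs4002 in anti-phase)
    proxy_meta_rows = []
    for i, proxy in proxied.items():
        b, f = Gamma[i], maf[i]
        anti = proxy == "rs4002"
        if anti:
            b, f = -b, 1 - f
        out_rows.append({
            "rsid": proxy, "chrom": idx_chrom[i], "pos": idx_pos[i] + 10_000,
            "effect_allele": "G", "other_allele": "A",
            "beta": b, "se": se_y[i],
            "pval": float(_pvals(np.array([b]), np.array([se_y[i]]))[0]),
            "eaf": f, "n": n_outcome,
        })
        proxy_meta_rows.append((proxy, idx_chrom[i], idx_pos[i] + 10_000, "G", i, anti))
    # a candidate too weakly linked to rescue rs1051
    i_weak = 50
    out_rows.append({
        "rsid": "rs4003", "chrom": idx_chrom[i_weak], "pos": idx_pos[i_weak] + 10_000,
        "effect_allele": "G", "other_allele": "A",
        "beta": 0.0, "se": se_y[i_weak], "pval": 1.0,
        "eaf": 0.25, "n": n_outcome,
    })

    # ---------------- LD panel ----------------
    n_ind = 400
    dosage_cols: dict[str, np.ndarray] = {}
    meta_rows = []

    def founder(m):
        return (rng.random(n_ind) < m), (rng.random(n_ind) < m)

    alleles_by_idx = {}
    for i in range(n_idx):
        a1, a2 = founder(maf[i])
        alleles_by_idx[i] = (a1, a2)
        dosage_cols[idx_rsids[i]] = a1.astype(float) + a2.astype(float)
        meta_rows.append({"rsid": idx_rsids[i], "chrom": idx_chrom[i],
                          "pos": idx_pos[i], "counted_allele": effect[i]})

    def linked_copy(i, target_r2):
        mut = 1.0 - np.sqrt(target_r2)
        cols = []
        for a in alleles_by_idx[i]:
            b = a.copy()
            m = rng.random(n_ind) < mut
            b[m] = rng.random(int(m.sum())) < maf[i]
            cols.append(b)
        return cols[0].astype(float) + cols[1].astype(float)

    for i in range(10):  # satellites, r² ~ 0.9 with their index SNP
        dosage_cols[sat_rsids[i]] = linked_copy(i, 0.9)
        meta_rows.append({"rsid": sat_rsids[i], "chrom": idx_chrom[i],
                          "pos": idx_pos[i] + 50_000, "counted_allele": effect[i]})
    for proxy, chrom, pos, counted, i, anti in proxy_meta_rows:
        d = linked_copy(i, 0.96)
        if anti:
            d = 2.0 - d
        dosage_cols[proxy] = d
        meta_rows.append({"rsid": proxy, "chrom": chrom, "pos": pos,
                          "counted_allele": counted})
    dosage_cols["rs4003"] = linked_copy(i_weak, 0.3)
    meta_rows.append({"rsid": "rs4003", "chrom": idx_chrom[i_weak],
                      "pos": idx_pos[i_weak] + 10_000, "counted_allele": "G"})

    panel = LDPanel.from_genotypes(pd.DataFrame(dosage_cols),
                                   pd.DataFrame(meta_rows))

    # ---------------- annotations ----------------
    kept_idx = [i for i in range(n_idx)
                if i not in pal_ambiguous and i not in incompatible
                and i not in missing_from_outcome] + list(proxied)
    kept_rsids = sorted(idx_rsids[i] for i in kept_idx)
    schedule = (["lipid"] * 12 + ["blood"] * 10 + ["inflammation"] * 6 +
                ["body_composition"] * 5 + ["type_2_diabetes"] * 4 + ["other"] * 3)
    annotations: dict[str, set[str]] = {}
    for rsid, cat in zip(kept_rsids, schedule):
        annotations.setdefault(rsid, set()).add(cat)

    truth = Truth(theta=theta, gamma=gamma, delta=delta,
                  valid_mask=delta == 0, maf=maf)
    return SimulatedStudy(
        exposure=table_from_frame(pd.DataFrame(exp_rows), trait_label="exposure",
                                  n_total=n_exposure),
        outcome=table_from_frame(pd.DataFrame(out_rows), trait_label="outcome",
                                 n_total=n_outcome),
        panel=panel,
        annotations=annotations,
        truth=truth,
    )
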
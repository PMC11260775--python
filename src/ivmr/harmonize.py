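"""Align exposure and outcome records to a common effect allele.

Two-sample MR requires the per-SNP exposure effect (gamma, SD units) and
outcome effect (Gamma, log-odds units) to refer to the same allele.  The
exposure orientation is never altered; outcome records are swapped,
strand-complemented or frequency-inferred as needed.  Palindromic SNPs
(A/T, C/G) cannot be resolved from alleles alone: orientation is inferred
from effect-allele frequencies when the minor-allele frequency is below the
ambiguity threshold (default 0.3) in both studies, and the SNP is dropped
as ambiguous otherwise.  Every drop and flip is itemized in an audit trail
so that ``input = kept + dropped`` holds by construction.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import SummaryTable
from .ld import LDPanel, ProxyMatch

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PAIR_COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "gamma", "se_x", "Gamma", "se_y", "eaf_x", "eaf_y",
    "is_proxy", "provenance",
]


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


@dataclasses.dataclass
class HarmonizedSet:
    """Aligned instrument set plus a complete audit trail.

    ``pairs`` has one row per retained instrument (columns
    :data:`PAIR_COLUMNS`); ``audit`` has one row per input SNP with its
    action (``kept``/``dropped``) and reason tag.
    """

    pairs: pd.DataFrame
    audit: pd.DataFrame

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def gamma(self) -> np.ndarray:
        return self.pairs["gamma"].to_numpy(float)

    @property
    def se_x(self) -> np.ndarray:
        return self.pairs["se_x"].to_numpy(float)

    @property
    def Gamma(self) -> np.ndarray:
        return self.pairs["Gamma"].to_numpy(float)

    @property
    def se_y(self) -> np.ndarray:
        return self.pairs["se_y"].to_numpy(float)

    @property
    def rsids(self) -> list[str]:
        return list(self.pairs["rsid"])

    def drop_reasons(self) -> dict[str, int]:
        dropped = self.audit[self.audit["action"] == "dropped"]
        return dropped["reason"].value_counts().to_dict()

    def subset(self, keep: Iterable[str]) -> "HarmonizedSet":
        keep = set(keep)
        mask = self.pairs["rsid"].isin(keep)
        return HarmonizedSet(self.pairs[mask].reset_index(drop=True),
                             self.audit[self.audit["rsid"].isin(keep)].reset_index(drop=True))

    def exclude(self, drop: Iterable[str]) -> "HarmonizedSet":
        drop = set(drop)
        return self.subset(set(self.pairs["rsid"]) - drop)

    def write_audit(self, path: str | Path) -> None:
        self.audit.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _oriented(beta: float, eaf: float, flip: bool) -> tuple[float, float]:
    if flip:
        return -beta, (1.0 - eaf) if not math.isnan(eaf) else eaf
    return beta, eaf


def harmonize(
    exposure: SummaryTable,
    outcome: SummaryTable,
    maf_threshold: float = 0.3,
    proxy_rsids: Iterable[str] = (),
) -> HarmonizedSet:
    """Harmonize shared SNPs onto the exposure's effect allele.

    For each exposure SNP also present in the outcome table, in order:

    1. identical allele pair: keep as-is;
    2. alleles swapped: negate the outcome beta, reflect its EAF, keep;
    3. alleles match after strand complement (with or without swap): apply
       the complement (and sign/EAF adjustments), keep;
    4. palindromic pair: infer orientation from EAFs if MAF < ``maf_threshold``
       in both studies (choosing the candidate alignment with concordant
       frequencies), otherwise drop as ambiguous; missing EAF also drops;
    5. anything else: drop as incompatible.

    ``proxy_rsids`` marks instruments whose outcome record came from a proxy
    substitution (see :func:`substitute_proxy`); exposure SNPs with no
    outcome record are dropped with reason ``missing_in_outcome``.
    """
    proxy_rsids = set(proxy_rsids)
    out_by_rsid = {r.rsid: r for r in outcome.df.itertuples(index=False)}

    pairs: list[dict] = []
    audit: list[dict] = []

    def keep(exp, Gamma, se_y, eaf_y, tag):
        pairs.append({
            "rsid": exp.rsid, "chrom": exp.chrom, "pos": exp.pos,
            "effect_allele": exp.effect_allele, "other_allele": exp.other_allele,
            "gamma": exp.beta, "se_x": exp.se, "Gamma": Gamma, "se_y": se_y,
            "eaf_x": exp.eaf, "eaf_y": eaf_y,
            "is_proxy": exp.rsid in proxy_rsids, "provenance": tag,
        })
        audit.append({"rsid": exp.rsid, "action": "kept", "reason": tag})

    def drop(rsid, tag):
        audit.append({"rsid": rsid, "action": "dropped", "reason": tag})

    for exp in exposure.df.itertuples(index=False):
        out = out_by_rsid.get(exp.rsid)
        if out is None:
            drop(exp.rsid, "missing_in_outcome")
            continue

        e1, e2 = exp.effect_allele, exp.other_allele
        o1, o2 = out.effect_allele, out.other_allele

        if _is_palindromic(e1, e2):
            if {o1, o2} != {e1, e2}:
                drop(exp.rsid, "incompatible_alleles")
                continue
            # nominal alignment on allele labels
            Gamma, eaf_y = _oriented(out.beta, out.eaf, flip=(o1 != e1))
            if math.isnan(exp.eaf) or math.isnan(eaf_y):
                drop(exp.rsid, "palindromic_no_eaf")
                continue
            maf_x = min(exp.eaf, 1 - exp.eaf)
            maf_y = min(eaf_y, 1 - eaf_y)
            if maf_x >= maf_threshold or maf_y >= maf_threshold:
                drop(exp.rsid, "palindromic_ambiguous")
                continue
            if (exp.eaf < 0.5) != (eaf_y < 0.5):
                # discordant frequencies: the record is on the other strand,
                # which for a palindrome is equivalent to an allele swap
                Gamma, eaf_y = -Gamma, 1 - eaf_y
            keep(exp, Gamma, out.se, eaf_y, "palindromic_inferred")
            continue

        if {o1, o2} == {e1, e2}:
            flip = o1 != e1
            Gamma, eaf_y = _oriented(out.beta, out.eaf, flip)
            keep(exp, Gamma, out.se, eaf_y, "flipped" if flip else "kept")
            continue

        c1, c2 = _COMPLEMENT[o1], _COMPLEMENT[o2]
        if {c1, c2} == {e1, e2}:
            flip = c1 != e1
            Gamma, eaf_y = _oriented(out.beta, out.eaf, flip)
            tag = "strand_flipped_swapped" if flip else "strand_flipped"
            keep(exp, Gamma, out.se, eaf_y, tag)
            continue

        drop(exp.rsid, "incompatible_alleles")

    pairs_df = pd.DataFrame(pairs, columns=PAIR_COLUMNS)
    audit_df = pd.DataFrame(audit, columns=["rsid", "action", "reason"])
    return HarmonizedSet(pairs_df, audit_df)


def substitute_proxy(
    exposure_record: pd.Series,
    match: ProxyMatch,
    proxy_outcome_record: pd.Series,
    panel: LDPanel,
) -> dict | None:
    """Build an outcome record for a missing instrument from its proxy.

    The proxy's outcome effect is first expressed on the proxy's counted
    allele, transported to the target's counted allele through the LD phase
    sign, and finally restated on the exposure record's alleles so the
    synthesized record harmonizes like a directly-measured one.  Returns the
    record dict, or None when allele bookkeeping cannot be resolved.
    """
    t_counted = panel.counted_allele(match.target)
    p_counted = panel.counted_allele(match.proxy)
    if t_counted is None or p_counted is None:
        return None

    # outcome effect on the proxy's counted allele
    if proxy_outcome_record["effect_allele"] == p_counted:
        b, f = proxy_outcome_record["beta"], proxy_outcome_record["eaf"]
    elif proxy_outcome_record["other_allele"] == p_counted:
        b, f = -proxy_outcome_record["beta"], 1 - proxy_outcome_record["eaf"]
    else:
        return None

    # transport along the LD phase
    if match.sign < 0:
        b, f = -b, 1 - f

    # restate on the exposure record's allele labels
    if exposure_record["effect_allele"] == t_counted:
        beta, eaf = b, f
    elif exposure_record["other_allele"] == t_counted:
        beta, eaf = -b, 1 - f
    else:
        return None

    return {
        "rsid": exposure_record["rsid"],
        "chrom": exposure_record["chrom"],
        "pos": exposure_record["pos"],
        "effect_allele": exposure_record["effect_allele"],
        "other_allele": exposure_record["other_allele"],
        "beta": beta,
        "se": proxy_outcome_record["se"],
        "pval": proxy_outcome_record["pval"],
        "eaf": eaf,
        "n": proxy_outcome_record.get("n", np.nan),
    }


@dataclasses.dataclass
class InstrumentStrength:
    r2_total: float
    f_stat: float
    per_snp_r2: pd.Series
    n: int
    k: int
    formula: str


def instrument_strength(
    exposure: SummaryTable | pd.DataFrame,
    n: int,
    formula: str = "standard",
) -> InstrumentStrength:
    """Variance in the exposure explained by the instruments, and the joint
    F-statistic for instrument strength.

    Per SNP, with beta in SD units and x the minor-allele frequency, the
    variance explained is ``2 * beta^2 * x * (1-x)`` under
    ``formula='standard'``; ``formula='as_printed'`` uses ``beta^2 * x * (1-x)``
    (a variant sometimes quoted without the factor 2).  The joint F is
    ``(R2/k) / ((1-R2)/(n-k-1))`` for k instruments in a sample of n.
    """
    df = exposure.df if isinstance(exposure, SummaryTable) else exposure
    if formula not in ("standard", "as_printed"):
        raise ConfigurationError(f"unknown instrument-strength formula: {formula}")
    missing = df[df["eaf"].isna()]["rsid"].tolist()
    if missing:
        raise ConfigurationError(
            f"eaf required for variance explained; missing for: {', '.join(missing)}"
        )
    maf = np.minimum(df["eaf"].to_numpy(float), 1 - df["eaf"].to_numpy(float))
    factor = 2.0 if formula == "standard" else 1.0
    per = factor * df["beta"].to_numpy(float) ** 2 * maf * (1 - maf)
    per_snp = pd.Series(per, index=df["rsid"].to_numpy(), name="r2")
    r2_total = float(per.sum())
    k = len(df)
    f = f_statistic(r2_total, n, k)
    return InstrumentStrength(r2_total, f, per_snp, n=n, k=k, formula=formula)


def f_statistic(r2_total: float, n: int, k: int) -> float:
    """Joint instrument-strength F for k instruments explaining ``r2_total``
    of the exposure variance in a sample of n."""
    if k == 0 or r2_total <= 0:
        return 0.0
    if r2_total >= 1:
        raise ConfigurationError("r2_total must be < 1")
    return (r2_total / k) / ((1 - r2_total) / (n - k - 1))
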
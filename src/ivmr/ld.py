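"""Linkage disequilibrium against a local reference panel: pairwise r²,
greedy clumping, and proxy-SNP search.

The panel is either (a) an individuals x SNPs allele-dosage matrix (values
0/1/2 counting copies of the SNP's *counted allele*) with per-SNP metadata,
or (b) a table of precomputed r² records with a phase sign.  r² is the
squared Pearson correlation of unphased dosages (composite LD), the quantity
PLINK-style clumping thresholds refer to.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedLDError
from .io import SummaryTable

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ProxyMatch:
    """A substitute SNP in high LD with a missing instrument.

    ``sign`` is the sign of the dosage correlation: +1 means the proxy's
    counted allele travels with the target's counted allele, -1 means it
    travels with the target's other allele.
    """

    target: str
    proxy: str
    r2: float
    sign: int


class LDPanel:
    """Pairwise-LD oracle backed by genotypes or precomputed r² records."""

    def __init__(self, dosages: pd.DataFrame | None, meta: pd.DataFrame | None,
                 r2_records: pd.DataFrame | None = None):
        self._dosages = dosages
        self._r2: dict[tuple[str, str], tuple[float, int]] = {}
        if r2_records is not None:
            for row in r2_records.itertuples(index=False):
                r2 = float(row.r2)
                if not 0.0 <= r2 <= 1.0:
                    raise ConfigurationError(f"r2 out of [0,1] for {row.rsid_a}/{row.rsid_b}")
                sign = int(getattr(row, "sign", 1))
                self._r2[(row.rsid_a, row.rsid_b)] = (r2, sign)
                self._r2[(row.rsid_b, row.rsid_a)] = (r2, sign)
        if meta is not None:
            meta = meta.set_index("rsid", drop=False)
        self.meta = meta

    # ------------------------------------------------------------------ #
    @classmethod
    def from_genotypes(cls, dosages: pd.DataFrame, meta: pd.DataFrame) -> "LDPanel":
        """``dosages``: individuals x SNPs, columns named by rsid, values in
        {0,1,2}; ``meta``: columns rsid, chrom, pos, counted_allele."""
        missing = set(dosages.columns) - set(meta["rsid"])
        if missing:
            raise ConfigurationError(f"panel metadata missing for: {sorted(missing)[:5]}")
        return cls(dosages.astype(float), meta)

    @classmethod
    def from_r2_records(cls, records: pd.DataFrame, meta: pd.DataFrame | None = None) -> "LDPanel":
        """``records``: columns rsid_a, rsid_b, r2 and optional sign."""
        return cls(None, meta, r2_records=records)

    @classmethod
    def read(cls, dosage_path: str | Path, meta_path: str | Path) -> "LDPanel":
        dosages = pd.read_csv(dosage_path, sep="\t")
        meta = pd.read_csv(meta_path, sep="\t", dtype={"rsid": str, "chrom": str})
        return cls.from_genotypes(dosages, meta)

    def write(self, dosage_path: str | Path, meta_path: str | Path) -> None:
        if self._dosages is None:
            raise ConfigurationError("cannot write genotypes for an r²-record panel")
        self._dosages.to_csv(dosage_path, sep="\t", index=False,
                             float_format="%g", lineterminator="\n")
        self.meta.to_csv(meta_path, sep="\t", index=False, lineterminator="\n")

    # ------------------------------------------------------------------ #
    def __contains__(self, rsid: str) -> bool:
        if self._dosages is not None:
            return rsid in self._dosages.columns
        return any(rsid in pair for pair in self._r2)

    def position(self, rsid: str) -> int | None:
        if self.meta is not None and rsid in self.meta.index:
            return int(self.meta.at[rsid, "pos"])
        return None

    def counted_allele(self, rsid: str) -> str | None:
        if self.meta is not None and rsid in self.meta.index:
            return str(self.meta.at[rsid, "counted_allele"])
        return None

    def _corr(self, a: str, b: str) -> float:
        x = self._dosages[a].to_numpy()
        y = self._dosages[b].to_numpy()
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            raise UndefinedLDError(f"monomorphic SNP in r² computation: {a if sx == 0 else b}")
        return float(np.corrcoef(x, y)[0, 1])

    def r2(self, a: str, b: str) -> float:
        """Squared Pearson correlation of dosages; symmetric; r²(a,a)=1."""
        if a == b:
            if a not in self:
                raise UndefinedLDError(f"SNP absent from panel: {a}")
            return 1.0
        if self._dosages is not None:
            if a not in self or b not in self:
                missing = a if a not in self else b
                raise UndefinedLDError(f"SNP absent from panel: {missing}")
            return self._corr(a, b) ** 2
        if (a, b) in self._r2:
            return self._r2[(a, b)][0]
        if a not in self or b not in self:
            missing = a if a not in self else b
            raise UndefinedLDError(f"SNP absent from panel: {missing}")
        return 0.0  # both known, pair unrecorded => unlinked

    def phase_sign(self, a: str, b: str) -> int:
        """Sign of the dosage correlation between the two counted alleles."""
        if a == b:
            return 1
        if self._dosages is not None:
            return 1 if self._corr(a, b) >= 0 else -1
        if (a, b) in self._r2:
            return self._r2[(a, b)][1]
        return 1


def compute_r2(panel: LDPanel, a: str, b: str) -> float:
    """Module-level convenience wrapper around :meth:`LDPanel.r2`."""
    return panel.r2(a, b)


def ld_clump(
    table: SummaryTable,
    panel: LDPanel,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
    missing_policy: str = "drop",
) -> SummaryTable:
    """Greedy p-value-ordered LD clumping.

    Restrict to SNPs with ``pval < p_threshold``; repeatedly promote the
    smallest-p remaining SNP to index status and discard remaining SNPs on
    the same chromosome within ±``window_kb`` whose r² with the index exceeds
    ``r2_threshold``.  Ties on p break by position, then rsid.  SNPs absent
    from the panel are dropped with a warning (``missing_policy='drop'``) or
    treated as unlinked (``'unlinked'``).

    Returns the index SNPs ordered by ascending p.
    """
    if missing_policy not in ("drop", "unlinked"):
        raise ConfigurationError(f"unknown missing_policy: {missing_policy}")
    df = table.df[table.df["pval"] < p_threshold].copy()
    if missing_policy == "drop":
        absent = [r for r in df["rsid"] if r not in panel]
        if absent:
            logger.warning("ld_clump: dropping %d SNP(s) absent from panel: %s",
                           len(absent), ", ".join(absent[:5]))
            df = df[~df["rsid"].isin(absent)]

    df = df.sort_values(["pval", "pos", "rsid"], kind="mergesort").reset_index(drop=True)
    window = window_kb * 1_000
    alive = np.ones(len(df), dtype=bool)
    kept: list[int] = []
    for i in range(len(df)):
        if not alive[i]:
            continue
        kept.append(i)
        alive[i] = False
        chrom, pos, rsid = df.at[i, "chrom"], df.at[i, "pos"], df.at[i, "rsid"]
        for j in np.nonzero(alive)[0]:
            if df.at[j, "chrom"] != chrom or abs(df.at[j, "pos"] - pos) > window:
                continue
            other = df.at[j, "rsid"]
            if other not in panel:  # only reachable under 'unlinked'
                continue
            if panel.r2(rsid, other) > r2_threshold:
                alive[j] = False
    out = df.iloc[kept].reset_index(drop=True)
    return SummaryTable(out, trait_label=table.trait_label, n_total=table.n_total)


def find_proxy(
    panel: LDPanel,
    target: str,
    candidates: Iterable[str],
    min_r2: float = 0.8,
) -> ProxyMatch | None:
    """Best-available proxy for ``target`` among ``candidates``.

    Returns the candidate with maximal r² >= ``min_r2`` (ties broken by
    smaller genomic distance, then lexicographic rsid) with the allele-phase
    sign, or None when nothing qualifies.
    """
    if target not in panel:
        return None
    tpos = panel.position(target)
    best: tuple[float, float, str] | None = None  # (-r2, distance, rsid)
    for cand in candidates:
        if cand == target or cand not in panel:
            continue
        try:
            r2 = panel.r2(target, cand)
        except UndefinedLDError:
            continue
        if r2 < min_r2:
            continue
        cpos = panel.position(cand)
        dist = abs(cpos - tpos) if (tpos is not None and cpos is not None) else np.inf
        key = (-r2, dist, cand)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    r2, _, proxy = -best[0], best[1], best[2]
    return ProxyMatch(target=target, proxy=proxy, r2=r2, sign=panel.phase_sign(target, proxy))
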
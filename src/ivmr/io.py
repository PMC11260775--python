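"""Read, validate and write GWAS summary-statistic tables.

Summary statistics are consumed as tab-separated tables with one row per
SNP.  The internal column standard is::

    rsid  chrom  pos  effect_allele  other_allele  beta  se  pval  eaf  n

``eaf`` and ``n`` are optional; a missing effect-allele frequency is
tolerated at read time and only blocks the downstream steps that need it
(palindromic-strand inference, variance explained).  Other dialects are
adapted through a user-supplied column mapping.

Exposure tables carry per-allele effects in SD units of the exposure;
outcome tables carry log-odds of the (binary) outcome per allele.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, RowValidationError

#: canonical column order of the internal dialect
STANDARD_COLUMNS = (
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
    "eaf",
    "n",
)

_MANDATORY = ("rsid", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pval")

_NUCLEOTIDES = frozenset("ACGT")


def _chrom_sort_key(chrom: str):
    """Numeric chromosomes first in natural order, then X/Y/MT, then others."""
    c = str(chrom).upper().removeprefix("CHR")
    if c.isdigit():
        return (0, int(c), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if c in special:
        return (0, special[c], "")
    return (1, 0, c)


@dataclasses.dataclass
class SummaryTable:
    """Validated per-SNP association records for one trait.

    ``df`` holds one row per SNP in the standard dialect, sorted by
    (chromosome, position) with unique rsids.  ``rejected`` records any rows
    discarded during validation together with the reason, so that
    ``len(input) == len(df) + len(rejected)`` always holds.
    """

    df: pd.DataFrame
    trait_label: str = ""
    n_total: int | None = None
    rejected: pd.DataFrame = dataclasses.field(
        default_factory=lambda: pd.DataFrame(columns=["rsid", "reason"])
    )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def rsids(self) -> pd.Series:
        return self.df["rsid"]

    def record(self, rsid: str) -> pd.Series:
        sub = self.df[self.df["rsid"] == rsid]
        if sub.empty:
            raise KeyError(rsid)
        return sub.iloc[0]

    def subset(self, rsids: Iterable[str]) -> "SummaryTable":
        keep = set(rsids)
        return SummaryTable(
            self.df[self.df["rsid"].isin(keep)].reset_index(drop=True),
            trait_label=self.trait_label,
            n_total=self.n_total,
        )


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw frame into (accepted, rejected-with-reason)."""
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, why: str) -> None:
        fresh = mask & (reasons == "")
        reasons[fresh] = why

    allele_ok = df["effect_allele"].isin(_NUCLEOTIDES) & df["other_allele"].isin(_NUCLEOTIDES)
    flag(~allele_ok, "allele not a single nucleotide")
    flag(df["effect_allele"] == df["other_allele"], "effect allele equals other allele")
    flag(~(df["se"] > 0), "se must be > 0")
    flag(~(df["pval"] > 0) | ~(df["pval"] <= 1), "pval must lie in (0, 1]")
    eaf_bad = df["eaf"].notna() & (~(df["eaf"] > 0) | ~(df["eaf"] < 1))
    flag(eaf_bad, "eaf must lie in (0, 1)")
    flag(~(df["pos"] > 0), "pos must be a positive 1-based coordinate")
    flag(df["rsid"].isna() | (df["rsid"] == ""), "missing rsid")
    flag(df["rsid"].duplicated(keep="first"), "duplicate rsid")

    bad = reasons != ""
    rejected = pd.DataFrame({"rsid": df.loc[bad, "rsid"], "reason": reasons[bad]})
    return df[~bad], rejected.reset_index(drop=True)


def table_from_frame(
    df: pd.DataFrame,
    trait_label: str = "",
    n_total: int | None = None,
    on_invalid: str = "raise",
) -> SummaryTable:
    """Validate a raw frame (already in the standard dialect) into a
    :class:`SummaryTable`.

    ``on_invalid='raise'`` raises :class:`RowValidationError` naming every
    offending rsid; ``'drop'`` rejects those rows and keeps them, with
    reasons, on ``SummaryTable.rejected``.
    """
    df = df.copy()
    for col in ("eaf", "n"):
        if col not in df.columns:
            df[col] = np.nan
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing mandatory column(s): {', '.join(missing)}")

    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    for col in ("beta", "se", "pval", "eaf", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    accepted, rejected = _validate_rows(df)
    if len(rejected) and on_invalid == "raise":
        raise RowValidationError(rejected["rsid"], rejected["reason"])

    accepted = accepted.copy()
    accepted["pos"] = accepted["pos"].astype(np.int64)
    key = accepted["chrom"].map(_chrom_sort_key)
    order = sorted(accepted.index, key=lambda i: (key[i], accepted.at[i, "pos"]))
    accepted = accepted.loc[order, list(STANDARD_COLUMNS)].reset_index(drop=True)
    return SummaryTable(accepted, trait_label=trait_label, n_total=n_total, rejected=rejected)


def read_summary_stats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    trait_label: str = "",
    n_total: int | None = None,
    on_invalid: str = "raise",
) -> SummaryTable:
    """Read a tab-separated summary-statistics file.

    Parameters
    ----------
    path:
        TSV file with a header row.
    dialect:
        Optional mapping ``{standard name -> column name in the file}`` for
        non-standard headers; unmapped standard names are looked up as-is.
    on_invalid:
        ``'raise'`` (default) or ``'drop'``; see :func:`table_from_frame`.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"summary-statistics file not found: {path}")
    raw = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str})
    if dialect:
        rename = {src: std for std, src in dialect.items() if src in raw.columns}
        missing = [std for std, src in dialect.items() if src not in raw.columns]
        if missing:
            raise ConfigurationError(
                f"dialect maps absent column(s): {', '.join(sorted(missing))}"
            )
        raw = raw.rename(columns=rename)
    return table_from_frame(raw, trait_label=trait_label, n_total=n_total, on_invalid=on_invalid)


def write_summary_stats(table: SummaryTable, path: str | Path) -> None:
    """Write a table back to the standard tab-separated dialect
    (deterministic formatting; round-trips through :func:`read_summary_stats`)."""
    table.df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def read_annotations(
    path: str | Path, categories: Iterable[str]
) -> dict[str, set[str]]:
    """Read a SNP -> trait-category annotation table.

    The file has two tab-separated columns ``rsid`` and ``category``, one row
    per SNP-category pair.  Duplicate pairs collapse to one (an association
    reported by several source GWAS counts once).  Category labels must come
    from the declared ``categories`` vocabulary.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"annotation file not found: {path}")
    declared = set(categories)
    try:
        ann = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return {}
    if ann.empty:
        return {}
    if not {"rsid", "category"} <= set(ann.columns):
        raise ConfigurationError("annotation file must have columns 'rsid' and 'category'")
    unknown = sorted(set(ann["category"]) - declared)
    if unknown:
        raise ConfigurationError(
            f"unknown category label(s): {', '.join(unknown)}; declared: {sorted(declared)}"
        )
    out: dict[str, set[str]] = {}
    for rsid, cat in zip(ann["rsid"], ann["category"]):
        out.setdefault(rsid, set()).add(cat)
    return out


def write_annotations(annotations: Mapping[str, set[str]], path: str | Path) -> None:
    rows = [
        {"rsid": rsid, "category": cat}
        for rsid in sorted(annotations)
        for cat in sorted(annotations[rsid])
    ]
    pd.DataFrame(rows, columns=["rsid", "category"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


_ESTIMATE_COLUMNS = ["method", "n_snp", "beta", "se", "or", "or_ci_low", "or_ci_high", "pval"]


def estimates_frame(estimates) -> pd.DataFrame:
    """Flatten a collection of :class:`~ivmr.estimators.MREstimate` into the
    standard 8-column result layout."""
    rows = [
        {
            "method": e.method,
            "n_snp": e.n_snp,
            "beta": e.beta,
            "se": e.se,
            "or": e.odds_ratio,
            "or_ci_low": e.or_ci_low,
            "or_ci_high": e.or_ci_high,
            "pval": e.pval,
        }
        for e in estimates
    ]
    return pd.DataFrame(rows, columns=_ESTIMATE_COLUMNS)


def write_results(estimates, report, out_dir: str | Path) -> dict[str, Path]:
    """Write per-method estimates as a TSV and the full analysis as a
    machine-readable JSON report.

    Output is byte-identical across reruns with identical inputs and seeds.
    Returns the paths written, keyed by artefact name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    est_path = out_dir / "estimates.tsv"
    estimates_frame(estimates).to_csv(
        est_path, sep="\t", index=False, float_format="%.10g", lineterminator="\n"
    )
    paths = {"estimates": est_path}
    if report is not None:
        rep_path = out_dir / "report.json"
        payload = report.to_dict() if hasattr(report, "to_dict") else report
        rep_path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n")
        paths["report"] = rep_path
    return paths


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON-serializable: {type(obj)!r}")
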
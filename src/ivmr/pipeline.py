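"""End-to-end orchestration: select -> clump -> proxy -> harmonize ->
estimate -> sensitivity -> power, with a complete audit trail, a run log
recording every threshold and seed, and the three standard figures.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import plots
from .config import RunConfig
from .errors import ConfigurationError
from .estimators import EstimatorConfig, MRResults, run_all
from .harmonize import (HarmonizedSet, InstrumentStrength, harmonize,
                        instrument_strength, substitute_proxy)
from .io import (SummaryTable, estimates_frame, read_annotations,
                 read_summary_stats, write_results)
from .ld import LDPanel, find_proxy, ld_clump
from .power import PowerQuery, detectable_or, mr_power_binary, power_curve
from .sensitivity import SensitivityReport, cochran_q, sensitivity_suite

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ProxyLog:
    substituted: list[dict]      # target, proxy, r2, sign
    unrecoverable: list[str]     # exposure SNPs with no qualifying proxy


@dataclasses.dataclass
class PipelineResult:
    """Everything one run produces, before and after serialization."""

    index_snps: SummaryTable
    proxy_log: ProxyLog
    hset: HarmonizedSet
    strength: InstrumentStrength
    results: MRResults
    sensitivity: SensitivityReport | None
    power_table: pd.DataFrame
    detectable_or_80: float
    out_dir: Path | None = None


def _proxy_stage(index_snps: SummaryTable, outcome: SummaryTable,
                 panel: LDPanel, min_r2: float) -> tuple[SummaryTable, ProxyLog]:
    """Rescue instruments missing from the outcome study through LD proxies.

    Returns the outcome table augmented with synthesized records (keyed by
    the target rsid) plus a log of substitutions and failures.
    """
    outcome_rsids = set(outcome.df["rsid"])
    missing = [r for r in index_snps.df["rsid"] if r not in outcome_rsids]
    substituted, unrecoverable = [], []
    new_rows = []
    for target in missing:
        match = find_proxy(panel, target, outcome_rsids, min_r2=min_r2)
        if match is None:
            unrecoverable.append(target)
            continue
        rec = substitute_proxy(index_snps.record(target), match,
                               outcome.record(match.proxy), panel)
        if rec is None:
            unrecoverable.append(target)
            continue
        new_rows.append(rec)
        substituted.append({"target": target, "proxy": match.proxy,
                            "r2": match.r2, "sign": match.sign})
    if new_rows:
        df = pd.concat([outcome.df, pd.DataFrame(new_rows)], ignore_index=True)
        outcome = SummaryTable(df, trait_label=outcome.trait_label,
                               n_total=outcome.n_total)
    return outcome, ProxyLog(substituted, unrecoverable)


def run_study(
    exposure: SummaryTable,
    outcome: SummaryTable,
    panel: LDPanel,
    config: RunConfig,
    annotations: dict[str, set[str]] | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs (the file-based
    :func:`run_pipeline` is a thin wrapper around this)."""
    thr = config.thresholds
    est_cfg = EstimatorConfig(
        ivw_model=config.estimators.ivw_model,
        n_boot=config.estimators.n_boot,
        bandwidth_factor=config.estimators.bandwidth_factor,
        seed=config.seed,
    )

    # 1) instrument selection: genome-wide significance + LD clumping
    index_snps = ld_clump(exposure, panel, p_threshold=thr.p_select,
                          r2_threshold=thr.clump_r2,
                          window_kb=thr.clump_window_kb)
    logger.info("selection: %d index SNP(s)", len(index_snps))

    # 2) proxy rescue for instruments missing from the outcome study
    outcome_aug, proxy_log = _proxy_stage(index_snps, outcome, panel,
                                          thr.proxy_min_r2)
    for t in proxy_log.unrecoverable:
        logger.info("proxy: no substitute for %s; instrument dropped", t)

    # 3) allele harmonization
    hset = harmonize(index_snps, outcome_aug, maf_threshold=thr.palindromic_maf,
                     proxy_rsids={s["target"] for s in proxy_log.substituted})
    logger.info("harmonization: %d instrument(s) kept; drops: %s",
                len(hset), hset.drop_reasons())

    # 4) instrument strength
    strength_df = pd.DataFrame({
        "rsid": hset.pairs["rsid"], "beta": hset.pairs["gamma"],
        "eaf": hset.pairs["eaf_x"],
    })
    strength = instrument_strength(strength_df, n=config.n_exposure,
                                   formula=config.strength_formula)

    # 5) causal estimates
    results = run_all(hset, est_cfg)

    # 6) sensitivity battery (needs >= 3 SNPs for the Egger leg)
    sens = None
    if len(hset) >= 3:
        sens = sensitivity_suite(
            hset,
            annotations=annotations if annotations is not None else {},
            categories=config.sensitivity.categories,
            keep_only_categories=config.sensitivity.keep_only_categories,
            presso_n_sim=config.sensitivity.presso_n_sim,
            presso_significance=config.sensitivity.presso_significance,
            seed=config.seed,
            config=est_cfg,
        )
        if config.sensitivity.exclude_proxies_run and hset.pairs["is_proxy"].any():
            non_proxy = hset.pairs.loc[~hset.pairs["is_proxy"], "rsid"]
            reduced = hset.subset(non_proxy)
            from .sensitivity import CategoryRun
            sens.category_runs["proxy"] = CategoryRun(
                "proxy", "exclude", len(reduced),
                run_all(reduced, est_cfg),
                cochran_q(reduced) if len(reduced) >= 2 else None,
                None, None,
            )

    # 7) power
    ps = config.power
    n_outcome = ps.n_case + ps.n_control
    case_fraction = ps.n_case / n_outcome
    r2 = strength.r2_total
    ptab = power_curve(ps.or_grid, n_outcome, case_fraction, r2, ps.alpha)
    det = detectable_or(n_outcome, case_fraction, r2, power=ps.target_power,
                        alpha=ps.alpha)

    return PipelineResult(index_snps=index_snps, proxy_log=proxy_log,
                          hset=hset, strength=strength, results=results,
                          sensitivity=sens, power_table=ptab,
                          detectable_or_80=det)


def _category_or_table(result: PipelineResult, labels: dict[str, str]) -> pd.DataFrame:
    """Main + per-exclusion IVW odds ratios for the cross-analysis forest."""
    rows = []
    ivw_est = result.results.get("ivw")
    if ivw_est is not None:
        rows.append({"label": "Main", "or": ivw_est.odds_ratio,
                     "or_ci_low": ivw_est.or_ci_low, "or_ci_high": ivw_est.or_ci_high})
    if result.sensitivity:
        for cat, run in result.sensitivity.category_runs.items():
            if run.results is None or run.mode != "exclude":
                continue
            e = run.results.get("ivw")
            if e is None:
                continue
            rows.append({"label": labels.get(cat, f"AX:{cat}"), "or": e.odds_ratio,
                         "or_ci_low": e.or_ci_low, "or_ci_high": e.or_ci_high})
    return pd.DataFrame(rows, columns=["label", "or", "or_ci_low", "or_ci_high"])


def _write_outputs(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.paths.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tsv = dict(sep="\t", index=False, float_format="%.10g", lineterminator="\n")

    report = result.sensitivity
    write_results(result.results.estimates, report, out)
    result.hset.write_audit(out / "harmonization_audit.tsv")
    result.results.single_snp.to_csv(out / "single_snp.tsv", **tsv)
    if report is not None and report.loo is not None:
        report.loo.to_csv(out / "leave_one_out.tsv", **tsv)
    result.power_table.to_csv(out / "power_curve.tsv", **tsv)
    pd.DataFrame(result.proxy_log.substituted,
                 columns=["target", "proxy", "r2", "sign"]).to_csv(
        out / "proxy_substitutions.tsv", **tsv)

    log = {
        "config": config.to_log_dict(),
        "n_index_snps": len(result.index_snps),
        "n_proxy_substitutions": len(result.proxy_log.substituted),
        "proxy_unrecoverable": result.proxy_log.unrecoverable,
        "n_instruments": len(result.hset),
        "drop_reasons": result.hset.drop_reasons(),
        "r2_total": result.strength.r2_total,
        "f_statistic": result.strength.f_stat,
        "detectable_or_80": result.detectable_or_80,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")

    # figures + their data tables
    ivw_est = result.results.get("ivw")
    if ivw_est is not None and len(result.results.single_snp):
        plots.forest_single_snp(result.results.single_snp, ivw_est.beta,
                                (ivw_est.ci_low, ivw_est.ci_high),
                                out / "forest_single_snp.png")
    plots.scatter_methods(result.hset.pairs, result.results.estimates,
                          out / "scatter_methods.png")
    or_table = _category_or_table(result, config.run_labels)
    or_table.to_csv(out / "forest_or_data.tsv", **tsv)
    if len(or_table):
        plots.forest_odds_ratios(or_table, out / "forest_or.png")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-in, files-out entry point for the whole workflow."""
    p = config.paths
    exposure = read_summary_stats(p.exposure, dialect=config.exposure_dialect,
                                  trait_label="exposure", n_total=config.n_exposure)
    outcome = read_summary_stats(p.outcome, dialect=config.outcome_dialect,
                                 trait_label="outcome")
    if p.panel_dosages is None or p.panel_meta is None:
        raise ConfigurationError("panel_dosages and panel_meta paths are required")
    panel = LDPanel.read(p.panel_dosages, p.panel_meta)
    annotations = None
    if p.annotations is not None:
        annotations = read_annotations(p.annotations,
                                       config.sensitivity.category_vocabulary)

    result = run_study(exposure, outcome, panel, config, annotations=annotations)
    result.out_dir = Path(p.out_dir)
    _write_outputs(result, config)
    return result
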
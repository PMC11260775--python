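"""Publication-style figures: single-SNP forest, method scatter, and the
odds-ratio forest across main and exclusion analyses.

Every figure is drawn from a plain table that the pipeline also writes to
disk, so results stay regenerable and testable without image comparison.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.figure import Figure


def forest_single_snp(single_snp: pd.DataFrame, summary_beta: float,
                      summary_ci: tuple[float, float], path: str | Path) -> None:
    """Per-SNP Wald-ratio forest with the combined IVW estimate at the
    bottom and a vertical no-effect line at 0."""
    df = single_snp.sort_values("beta").reset_index(drop=True)
    n = len(df)
    fig = Figure(figsize=(6, max(3, 0.18 * n + 1.5)))
    ax = fig.add_subplot(111)
    y = np.arange(n, 0, -1)
    beta = df["beta"].to_numpy(float)
    ax.errorbar(beta, y,
                xerr=[beta - df["ci_low"].to_numpy(float),
                      df["ci_high"].to_numpy(float) - beta],
                fmt="o", ms=3, color="black", ecolor="grey", elinewidth=0.8, capsize=0)
    ax.errorbar([summary_beta], [0],
                xerr=[[summary_beta - summary_ci[0]], [summary_ci[1] - summary_beta]],
                fmt="D", ms=5, color="crimson")
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(list(y) + [0])
    ax.set_yticklabels(list(df["rsid"]) + ["All (IVW)"], fontsize=6)
    ax.set_xlabel("MR effect size (log OR per SD)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)


def scatter_methods(pairs: pd.DataFrame, estimates, path: str | Path) -> None:
    """SNP effect on exposure vs effect on outcome, with one fitted line
    per MR method (Egger drawn with its intercept, others through 0)."""
    fig = Figure(figsize=(6, 5))
    ax = fig.add_subplot(111)
    g, G = pairs["gamma"].to_numpy(float), pairs["Gamma"].to_numpy(float)
    flip = np.sign(g)
    g, G = g * flip, G * flip  # display convention: exposure effect positive
    ax.errorbar(g, G, xerr=pairs["se_x"], yerr=pairs["se_y"], fmt="o", ms=3,
                color="black", ecolor="lightgrey", elinewidth=0.7)
    xs = np.linspace(0, g.max() * 1.05, 50)
    colors = {"ivw": "tab:blue", "egger": "tab:orange",
              "weighted_median": "tab:green", "weighted_mode": "tab:red"}
    for est in estimates:
        icpt = est.extras.get("intercept", 0.0) if est.method == "egger" else 0.0
        ax.plot(xs, icpt + est.beta * xs, color=colors.get(est.method, "grey"),
                label=est.method)
    ax.set_xlabel("SNP effect on exposure (SD)")
    ax.set_ylabel("SNP effect on outcome (log OR)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)


def forest_odds_ratios(table: pd.DataFrame, path: str | Path) -> None:
    """OR forest across analyses (rows: label, or, or_ci_low, or_ci_high),
    log-scaled x axis with the no-effect line at OR = 1."""
    n = len(table)
    fig = Figure(figsize=(6, max(2.5, 0.35 * n + 1.2)))
    ax = fig.add_subplot(111)
    y = np.arange(n, 0, -1)
    odds = table["or"].to_numpy(float)
    ax.errorbar(odds, y,
                xerr=[odds - table["or_ci_low"].to_numpy(float),
                      table["or_ci_high"].to_numpy(float) - odds],
                fmt="s", ms=4, color="black", ecolor="grey")
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xscale("log")
    ax.set_yticks(y)
    ax.set_yticklabels(table["label"], fontsize=8)
    ax.set_xlabel("OR for outcome per 1 SD increase in exposure")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
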
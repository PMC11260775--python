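import numpy as np
import pandas as pd
import pytest

from ivmr.errors import UndefinedLDError
from ivmr.io import table_from_frame
from ivmr.ld import LDPanel, compute_r2, find_proxy, ld_clump
from ivmr.simulate import LDStructure, SimulationConfig, simulate_two_sample


def _panel(cols: dict, meta_rows=None):
    rsids = list(cols)
    if meta_rows is None:
        meta_rows = [{"rsid": r, "chrom": "1", "pos": (i + 1) * 1000,
                      "counted_allele": "A"} for i, r in enumerate(rsids)]
    return LDPanel.from_genotypes(pd.DataFrame(cols), pd.DataFrame(meta_rows))


def test_r2_identical_and_antiphased_dosages():
    panel = _panel({"a": [0, 1, 2, 0], "b": [0, 1, 2, 0], "c": [2, 1, 0, 2]})
    assert compute_r2(panel, "a", "b") == pytest.approx(1.0)
    # perfect negative correlation still gives r² = 1
    assert compute_r2(panel, "a", "c") == pytest.approx(1.0)
    assert panel.phase_sign("a", "c") == -1


def test_r2_hand_computed_zero():
    panel = _panel({"a": [0, 0, 1, 1], "b": [0, 1, 0, 1]})
    assert compute_r2(panel, "a", "b") == pytest.approx(0.0, abs=1e-12)


def test_r2_symmetric_and_self():
    panel = _panel({"a": [0, 1, 2, 1], "b": [2, 1, 0, 1]})
    assert compute_r2(panel, "a", "b") == pytest.approx(compute_r2(panel, "b", "a"))
    assert compute_r2(panel, "a", "a") == 1.0


def test_monomorphic_snp_is_undefined():
    panel = _panel({"a": [1, 1, 1, 1], "b": [0, 1, 2, 0]})
    with pytest.raises(UndefinedLDError, match="monomorphic"):
        compute_r2(panel, "a", "b")


def _sumtable(rows):
    df = pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "pval"])
    df["effect_allele"] = "A"
    df["other_allele"] = "G"
    df["beta"] = 0.1
    df["se"] = 0.01
    df["eaf"] = 0.3
    return table_from_frame(df)


def test_clump_rule_keeps_independent_snps():
    # A (p=1e-10) indexes; B (r²=0.5, 50 kb away) is clumped; C (r²=5e-4) kept
    table = _sumtable([("A", "1", 1_000_000, 1e-10),
                       ("B", "1", 1_050_000, 1e-9),
                       ("C", "1", 1_100_000, 1e-9)])
    records = pd.DataFrame([
        {"rsid_a": "A", "rsid_b": "B", "r2": 0.5},
        {"rsid_a": "A", "rsid_b": "C", "r2": 0.0005},
    ])
    panel = LDPanel.from_r2_records(records)
    out = ld_clump(table, panel)
    assert list(out.df["rsid"]) == ["A", "C"]


def test_clump_window_scoped_to_chromosome():
    table = _sumtable([("A", "1", 1_000_000, 1e-10),
                       ("B", "2", 1_000_000, 1e-9)])
    records = pd.DataFrame([{"rsid_a": "A", "rsid_b": "B", "r2": 0.99}])
    out = ld_clump(table, LDPanel.from_r2_records(records))
    assert set(out.df["rsid"]) == {"A", "B"}


def test_clump_beyond_window_retained():
    table = _sumtable([("A", "1", 1_000_000, 1e-10),
                       ("B", "1", 12_000_001, 1e-9)])  # > 10,000 kb apart
    records = pd.DataFrame([{"rsid_a": "A", "rsid_b": "B", "r2": 0.99}])
    out = ld_clump(table, LDPanel.from_r2_records(records))
    assert set(out.df["rsid"]) == {"A", "B"}


def _brute_force_clump(df, panel, r2_thr, window):
    """Independent re-implementation of the greedy rule for the oracle."""
    remaining = df.sort_values(["pval", "pos", "rsid"]).to_dict("records")
    kept = []
    while remaining:
        idx = remaining.pop(0)
        kept.append(idx["rsid"])
        survivors = []
        for r in remaining:
            same_window = (r["chrom"] == idx["chrom"]
                           and abs(r["pos"] - idx["pos"]) <= window)
            if same_window and panel.r2(idx["rsid"], r["rsid"]) > r2_thr:
                continue
            survivors.append(r)
        remaining = survivors
    return kept


def test_clump_matches_brute_force_oracle_on_ld_blocks():
    cfg = SimulationConfig(n_snp=20, ld=LDStructure(block_size=4, within_r2=0.8),
                           seed=11)
    study = simulate_two_sample(cfg)
    table = study.exposure
    out = ld_clump(table, study.panel, p_threshold=1.01, r2_threshold=0.1,
                   window_kb=100)
    df = table.df[table.df["pval"] < 1.01]
    expected = _brute_force_clump(df, study.panel, 0.1, 100_000)
    assert list(out.df["rsid"]) == expected


def test_clump_output_is_an_antichain():
    cfg = SimulationConfig(n_snp=30, ld=LDStructure(block_size=5, within_r2=0.9),
                           seed=3)
    study = simulate_two_sample(cfg)
    out = ld_clump(study.exposure, study.panel, p_threshold=1.01,
                   r2_threshold=0.05, window_kb=100)
    kept = out.df
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            a, b = kept.iloc[i], kept.iloc[j]
            if a["chrom"] == b["chrom"] and abs(a["pos"] - b["pos"]) <= 100_000:
                assert study.panel.r2(a["rsid"], b["rsid"]) <= 0.05


def test_clump_missing_snp_policy():
    table = _sumtable([("A", "1", 1_000_000, 1e-10),
                       ("Z", "1", 1_050_000, 1e-9)])
    panel = _panel({"A": [0, 1, 2, 0, 1]})
    out = ld_clump(table, panel, missing_policy="drop")
    assert list(out.df["rsid"]) == ["A"]
    out = ld_clump(table, panel, missing_policy="unlinked")
    assert set(out.df["rsid"]) == {"A", "Z"}


# ---------------- proxy search ----------------

def _proxy_panel():
    rng = np.random.default_rng(5)
    t = rng.integers(0, 3, 300).astype(float)

    def degrade(x, keep):
        y = x.copy()
        m = rng.random(len(x)) > keep
        y[m] = rng.integers(0, 3, m.sum())
        return y

    cols = {"target": t, "good": degrade(t, 0.97), "near": degrade(t, 0.95),
            "far": degrade(t, 0.95), "weak": degrade(t, 0.4)}
    meta = [
        {"rsid": "target", "chrom": "1", "pos": 100_000, "counted_allele": "A"},
        {"rsid": "good", "chrom": "1", "pos": 105_000, "counted_allele": "A"},
        {"rsid": "near", "chrom": "1", "pos": 110_000, "counted_allele": "A"},
        {"rsid": "far", "chrom": "1", "pos": 200_000, "counted_allele": "A"},
        {"rsid": "weak", "chrom": "1", "pos": 120_000, "counted_allele": "A"},
    ]
    return _panel(cols, meta)


def test_find_proxy_returns_best_match():
    panel = _proxy_panel()
    match = find_proxy(panel, "target", {"good", "weak"}, min_r2=0.8)
    assert match is not None and match.proxy == "good"
    assert match.r2 >= 0.8


def test_find_proxy_none_below_threshold():
    panel = _proxy_panel()
    assert find_proxy(panel, "target", {"weak"}, min_r2=0.8) is None


def test_find_proxy_tie_breaks_by_distance():
    # force an exact r² tie by duplicating one dosage column at two distances
    rng = np.random.default_rng(7)
    t = rng.integers(0, 3, 200).astype(float)
    p = t.copy()
    p[:10] = (p[:10] + 1) % 3
    cols = {"target": t, "near": p, "far": p.copy()}
    meta = [{"rsid": "target", "chrom": "1", "pos": 100_000, "counted_allele": "A"},
            {"rsid": "near", "chrom": "1", "pos": 110_000, "counted_allele": "A"},
            {"rsid": "far", "chrom": "1", "pos": 200_000, "counted_allele": "A"}]
    panel = _panel(cols, meta)
    match = find_proxy(panel, "target", {"near", "far"}, min_r2=0.5)
    assert match.proxy == "near"
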
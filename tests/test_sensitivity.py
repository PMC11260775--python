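import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ivmr.errors import MRMethodUnavailable
from ivmr.estimators import EstimatorConfig, ivw, run_all
from ivmr.harmonize import harmonize
from ivmr.sensitivity import (category_exclusion_analysis, cochran_q,
                              leave_one_out, mr_presso, sensitivity_suite)
from ivmr.simulate import (PleiotropyConfig, SimulationConfig,
                           annotate_invalid, simulate_two_sample)

from conftest import hset_from_arrays


def _null_hset(n_snp=50, seed=0, theta=0.0):
    rng = np.random.default_rng(seed)
    g = rng.uniform(0.05, 0.2, n_snp)
    se_y = rng.uniform(0.01, 0.04, n_snp)
    G = rng.normal(theta * g, se_y)
    return hset_from_arrays(g, 0.001, G, se_y)


# ---------------- Cochran's Q ----------------

def test_q_zero_when_ratios_identical():
    hset = hset_from_arrays([0.1, 0.2, 0.4], 0.001, [0.05, 0.10, 0.20], 0.1)
    res = cochran_q(hset)
    assert res.q == pytest.approx(0.0, abs=1e-20)
    assert res.pval == pytest.approx(1.0)


def test_q_two_snp_hand_value(two_snp_hset):
    res = cochran_q(two_snp_hset)
    # Q = 1*(2-1.2)^2 + 4*(1-1.2)^2 = 0.8, df = 1
    assert res.q == pytest.approx(0.8, rel=1e-12)
    assert res.df == 1
    assert res.pval == pytest.approx(stats.chi2.sf(0.8, 1), rel=1e-12)
    assert res.pval == pytest.approx(0.371, abs=5e-4)


def test_q_requires_two_snps():
    with pytest.raises(MRMethodUnavailable):
        cochran_q(hset_from_arrays([0.1], 0.01, [0.2], 0.1))


def test_q_nonnegative_and_zero_iff_equal_ratios():
    hset = _null_hset(seed=5)
    assert cochran_q(hset).q > 0


# ---------------- MR-PRESSO ----------------

def test_presso_requires_four_snps():
    with pytest.raises(MRMethodUnavailable):
        mr_presso(hset_from_arrays([0.1] * 3, 0.01, [0.2] * 3, 0.1), seed=0)


def test_presso_flags_planted_outlier():
    rng = np.random.default_rng(17)
    n = 50
    g = rng.uniform(0.05, 0.2, n)
    se_y = np.full(n, 0.02)
    G = rng.normal(0.2 * g, se_y)
    G[13] += 10 * 0.02  # residual ten times the noise scale
    hset = hset_from_arrays(g, 0.001, G, se_y)
    # the empirical outlier p-value cannot fall below J/(n_sim+1), so the
    # simulation count must out-resolve the Bonferroni-adjusted threshold
    res = mr_presso(hset, n_sim=2000, seed=1)
    assert "rs14" in res.outlier_rsids
    assert res.global_pval < 0.05


def test_presso_distortion_zero_when_removal_changes_nothing():
    # symmetric pair of mild outliers that cancel: removing them leaves the
    # IVW slope unchanged, so the distortion coefficient must be ~0
    g = np.array([0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
    G = 0.3 * g
    hset = hset_from_arrays(g, 0.001, G, 0.01)
    res = mr_presso(hset, n_sim=300, seed=2)
    assert res.outlier_rsids == set()
    assert res.distortion_coefficient == 0.0
    assert res.beta_no_outliers == pytest.approx(res.beta_all)


def test_presso_null_global_p_is_well_calibrated():
    """Specificity: under no pleiotropy the global test should rarely fire."""
    hits = 0
    n_rep = 60
    for seed in range(n_rep):
        hset = _null_hset(n_snp=50, seed=1000 + seed, theta=0.2)
        res = mr_presso(hset, n_sim=300, seed=seed)
        hits += res.global_pval <= 0.05
    assert hits / n_rep <= 0.10


# ---------------- leave-one-out ----------------

def test_loo_cardinality():
    hset = _null_hset(n_snp=3, seed=2)
    assert len(leave_one_out(hset)) == 3


def test_loo_stable_for_homogeneous_instruments():
    hset = _null_hset(n_snp=40, seed=3, theta=0.3)
    full = ivw(hset)
    loo = leave_one_out(hset)
    assert (abs(loo["beta"] - full.beta) < full.extras["se_fixed"]).all()


def test_loo_removing_outlier_moves_estimate_toward_truth():
    rng = np.random.default_rng(4)
    n = 20
    g = rng.uniform(0.05, 0.2, n)
    se_y = np.full(n, 0.02)
    G = rng.normal(0.0 * g, se_y)
    G[5] += 0.5  # single strongly pleiotropic instrument
    hset = hset_from_arrays(g, 0.001, G, se_y)
    full = ivw(hset, model="fixed")
    loo = leave_one_out(hset, model="fixed")
    removed_out = loo.loc[loo["rsid_removed"] == "rs6", "beta"].iloc[0]
    assert abs(removed_out - 0.0) < abs(full.beta - 0.0)


# ---------------- category exclusion ----------------

def _cat_inputs(seed=6):
    cfg = SimulationConfig(
        n_snp=60, theta=0.1,
        pleiotropy=PleiotropyConfig(fraction_invalid=0.3, mean=0.04, sd=0.01,
                                    balanced=False),
        palindromic_fraction=0.0, strand_flip_fraction=0.0, swap_fraction=0.0,
        seed=seed)
    study = simulate_two_sample(cfg)
    hset = harmonize(study.exposure, study.outcome)
    ann = annotate_invalid(study, "lipid")
    return hset, ann


def test_exclusion_of_unannotated_category_is_identity():
    hset, ann = _cat_inputs()
    cfg = EstimatorConfig(n_boot=50, seed=0)
    runs = category_exclusion_analysis(hset, ann, ["blood"], config=cfg)
    main = run_all(hset, cfg)
    assert runs["blood"].n_snp == len(hset)
    assert runs["blood"].results.get("ivw").beta == pytest.approx(
        main.get("ivw").beta)


def test_all_annotated_category_is_not_estimable():
    hset, _ = _cat_inputs()
    ann = {r: {"lipid"} for r in hset.rsids}
    runs = category_exclusion_analysis(hset, ann, ["lipid"],
                                       config=EstimatorConfig(n_boot=50, seed=0))
    assert runs["lipid"].not_estimable is not None


def test_excluding_confounded_category_shrinks_egger_intercept():
    from ivmr.estimators import mr_egger
    hset, ann = _cat_inputs()
    main_intercept = mr_egger(hset).extras["intercept"]
    runs = category_exclusion_analysis(hset, ann, ["lipid"],
                                       config=EstimatorConfig(n_boot=50, seed=0))
    assert abs(runs["lipid"].egger_intercept) < abs(main_intercept)


def test_keep_only_mode_restricts_to_category():
    hset, ann = _cat_inputs()
    runs = category_exclusion_analysis(hset, ann, ["lipid"], mode="keep_only",
                                       config=EstimatorConfig(n_boot=50, seed=0))
    n_tagged = sum(1 for r in hset.rsids if "lipid" in ann.get(r, set()))
    assert runs["lipid"].n_snp == n_tagged


def test_exclusion_runs_use_main_code_path():
    hset, ann = _cat_inputs()
    calls = []

    def spy_runner(h, cfg=None):
        calls.append(len(h))
        return run_all(h, cfg)

    category_exclusion_analysis(hset, ann, ["lipid", "blood"],
                                config=EstimatorConfig(n_boot=10, seed=0),
                                runner=spy_runner)
    assert len(calls) == 2  # one full-pipeline invocation per category


# ---------------- aggregate suite ----------------

def test_sensitivity_suite_bundles_everything():
    hset, ann = _cat_inputs()
    rep = sensitivity_suite(hset, annotations=ann, categories=["lipid"],
                            keep_only_categories=["lipid"], presso_n_sim=200,
                            seed=0, config=EstimatorConfig(n_boot=20, seed=0))
    assert rep.q_df == len(hset) - 1
    assert rep.presso is not None
    assert len(rep.loo) == len(hset)
    assert set(rep.category_runs) == {"lipid", "only_lipid"}
    d = rep.to_dict()
    assert d["q_stat"] >= 0
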
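import numpy as np
import pandas as pd
import pytest

from ivmr.errors import ConfigurationError, MRMethodUnavailable
from ivmr.estimators import (EstimatorConfig, ivw, mr_egger, run_all,
                             wald_ratio, weighted_median,
                             _weighted_median_point, weighted_mode,
                             _mode_point, _mode_bandwidth)
from ivmr.harmonize import harmonize
from ivmr.simulate import PleiotropyConfig, SimulationConfig, simulate_two_sample

from conftest import hset_from_arrays


def _hset_from_study(study):
    return harmonize(study.exposure, study.outcome)


# ---------------- Wald ratio ----------------

def test_wald_ratio_direct_formula():
    e = wald_ratio({"rsid": "rs1", "gamma": 0.1, "Gamma": 0.2, "se_y": 0.05})
    assert e.beta == pytest.approx(2.0)
    assert e.se == pytest.approx(0.5)


def test_wald_ratio_null_effect():
    e = wald_ratio({"rsid": "rs1", "gamma": 1.0, "Gamma": 0.0, "se_y": 0.05})
    assert e.beta == 0.0


def test_wald_ratio_zero_gamma_errors():
    with pytest.raises(ConfigurationError, match="rs9"):
        wald_ratio({"rsid": "rs9", "gamma": 0.0, "Gamma": 0.2, "se_y": 0.05})


# ---------------- IVW ----------------

def test_ivw_single_snp_reduces_to_wald():
    hset = hset_from_arrays([0.1], 0.01, [0.2], 0.05)
    e = ivw(hset)
    assert e.beta == pytest.approx(2.0)
    assert e.se == pytest.approx(0.5)


def test_ivw_two_snp_closed_form(two_snp_hset):
    e = ivw(two_snp_hset)
    assert e.beta == pytest.approx(1.2, rel=1e-12)
    assert e.extras["se_fixed"] == pytest.approx(5 ** -0.5, rel=1e-12)
    assert e.extras["q"] == pytest.approx(0.8, rel=1e-12)
    # Q/(J-1) = 0.8 < 1, so the multiplicative scaling clips at 1
    assert e.se == pytest.approx(5 ** -0.5, rel=1e-12)


def test_ivw_fixed_equals_ratio_of_weighted_sums():
    rng = np.random.default_rng(0)
    g = rng.uniform(0.05, 0.2, 20)
    G = rng.normal(0.3 * g, 0.05)
    se_y = rng.uniform(0.02, 0.08, 20)
    hset = hset_from_arrays(g, 0.01, G, se_y)
    e = ivw(hset, model="fixed")
    w = 1 / se_y**2
    oracle = np.sum(w * g * G) / np.sum(w * g**2)
    assert e.beta == pytest.approx(oracle, rel=1e-12)
    assert e.se == pytest.approx(np.sum(g**2 / se_y**2) ** -0.5, rel=1e-12)


def test_ivw_recovers_truth_with_strong_instruments():
    cfg = SimulationConfig(n_snp=50, theta=0.3, palindromic_fraction=0.0,
                           strand_flip_fraction=0.0, swap_fraction=0.0, seed=21)
    hset = _hset_from_study(simulate_two_sample(cfg))
    e = ivw(hset)
    assert abs(e.beta - 0.3) < 3 * e.se


# ---------------- MR-Egger ----------------

def test_egger_exact_fit_line():
    g = np.array([0.1, 0.2, 0.3])
    hset = hset_from_arrays(g, 0.001, 0.05 + 2 * g, 0.1)
    e = mr_egger(hset)
    assert e.beta == pytest.approx(2.0, rel=1e-9)
    assert e.extras["intercept"] == pytest.approx(0.05, rel=1e-9)
    assert e.extras["q_egger"] == pytest.approx(0.0, abs=1e-16)


def test_egger_zero_intercept_on_proportional_data():
    g = np.array([0.1, 0.25, 0.3, 0.15])
    hset = hset_from_arrays(g, 0.001, 0.7 * g, 0.05)
    e = mr_egger(hset)
    assert e.extras["intercept"] == pytest.approx(0.0, abs=1e-12)
    assert e.beta == pytest.approx(0.7, rel=1e-9)


def test_egger_orients_instruments_before_fitting():
    g = np.array([0.1, 0.2, 0.3])
    G = 0.02 + 0.5 * g
    # the same pairs with one instrument reported on the opposite allele
    sign = np.array([1.0, -1.0, 1.0])
    hset1 = hset_from_arrays(g * sign, 0.001, G * sign, 0.1)
    hset2 = hset_from_arrays(g, 0.001, G, 0.1)
    e1, e2 = mr_egger(hset1), mr_egger(hset2)
    assert e1.beta == pytest.approx(e2.beta, rel=1e-9)
    assert e1.extras["intercept"] == pytest.approx(e2.extras["intercept"], rel=1e-9)


def test_egger_recovers_directional_pleiotropy_mean():
    cfg = SimulationConfig(
        n_snp=200, theta=0.0,
        pleiotropy=PleiotropyConfig(fraction_invalid=1.0, mean=0.02, sd=0.005,
                                    balanced=False),
        palindromic_fraction=0.0, strand_flip_fraction=0.0, swap_fraction=0.0,
        seed=33)
    hset = _hset_from_study(simulate_two_sample(cfg))
    e = mr_egger(hset)
    assert abs(e.extras["intercept"] - 0.02) < 3 * e.extras["intercept_se"]


def test_egger_collinearity_warning():
    hset = hset_from_arrays([0.1, 0.1, 0.1], 0.001, [0.2, 0.21, 0.19], 0.1)
    e = mr_egger(hset)
    assert "warning" in e.extras


# ---------------- weighted median ----------------

def test_weighted_median_equal_weights_hand_value():
    assert _weighted_median_point(np.array([1.0, 2.0, 3.0]),
                                  np.ones(3)) == pytest.approx(2.0)


def test_weighted_median_unequal_weights_hand_value():
    theta = np.array([1.0, 2.0, 3.0, 10.0])
    w = np.array([3.0, 3.0, 3.0, 1.0])
    # interpolation: 2 + (0.5 - 0.45) / (0.75 - 0.45) = 2.166666...
    assert _weighted_median_point(theta, w) == pytest.approx(13 / 6, rel=1e-9)


def test_weighted_median_estimator_end_to_end():
    hset = hset_from_arrays([0.1, 0.1, 0.1, 0.1], 0.001,
                            [0.1, 0.2, 0.3, 1.0], [0.1, 0.1, 0.1, 0.1])
    e = weighted_median(hset, n_boot=200, seed=1)
    assert e.beta == pytest.approx(2.5)  # median of ratios {1,2,3,10}
    assert e.se > 0


def test_weighted_median_robust_at_40pct_invalid_weight():
    """With 40% of the weight on instruments sharing directional pleiotropy,
    IVW converges to a biased limit while the weighted median's bias is an
    order-of-the-ratio-noise effect that vanishes as the studies grow."""

    def fit(n_scale):
        cfg = SimulationConfig(
            n_snp=100, theta=0.0,
            n_exposure=114_999 * n_scale, n_case=9_358 * n_scale,
            n_control=15_482 * n_scale,
            pleiotropy=PleiotropyConfig(fraction_invalid=0.4, mean=0.05,
                                        sd=0.01, balanced=False),
            palindromic_fraction=0.0, strand_flip_fraction=0.0,
            swap_fraction=0.0, seed=8)
        hset = _hset_from_study(simulate_two_sample(cfg))
        return weighted_median(hset, n_boot=200, seed=2), ivw(hset)

    med, est_ivw = fit(1)
    med_big, ivw_big = fit(16)
    # IVW is dragged by the invalid mass at every sample size
    assert abs(est_ivw.beta) > 0.1 and abs(ivw_big.beta) > 0.1
    # the median attenuates the bias already at the base size ...
    assert abs(med.beta) < 0.6 * abs(est_ivw.beta)
    # ... and converges to the truth as the ratio noise shrinks
    assert abs(med_big.beta) < 0.5 * abs(med.beta)
    assert abs(med_big.beta) < 0.03


# ---------------- weighted mode ----------------

def test_mode_finds_majority_cluster():
    theta = np.array([1.00, 1.01, 0.99, 5.0])
    w = np.ones(4) / 4
    h = _mode_bandwidth(theta, 1.0)
    est = _mode_point(theta, w, 1.0)
    assert abs(est - 1.0) <= h


def test_mode_all_ratios_equal():
    hset = hset_from_arrays([0.1, 0.2, 0.4], 0.001,
                            [0.05, 0.10, 0.20], 0.1)  # every ratio = 0.5
    e = weighted_mode(hset, n_boot=50, seed=3)
    assert e.beta == pytest.approx(0.5)


def test_mode_recovers_largest_homogeneous_cluster():
    # 60% of weight pleiotropic but mutually heterogeneous; the largest
    # coherent cluster sits at theta = 0.2
    rng = np.random.default_rng(12)
    n_valid, n_invalid = 40, 60
    g = rng.uniform(0.08, 0.2, n_valid + n_invalid)
    se_y = np.full(n_valid + n_invalid, 0.004)
    G = 0.2 * g + rng.normal(0, se_y)
    spread = rng.uniform(-0.06, 0.06, n_invalid)  # scattered pleiotropy
    G[n_valid:] += spread
    hset = hset_from_arrays(g, 0.001, G, se_y)
    e = weighted_mode(hset, n_boot=100, seed=4)
    assert abs(e.beta - 0.2) < 3 * e.se


# ---------------- invariances ----------------

@pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
def test_scale_equivariance(two_snp_hset, c):
    scaled = hset_from_arrays(two_snp_hset.gamma, two_snp_hset.se_x,
                              c * two_snp_hset.Gamma, c * two_snp_hset.se_y)
    e0, e1 = ivw(two_snp_hset), ivw(scaled)
    assert e1.beta == pytest.approx(c * e0.beta, rel=1e-12)
    assert e1.se == pytest.approx(c * e0.se, rel=1e-12)


def test_per_snp_sign_flip_invariance():
    rng = np.random.default_rng(9)
    g = rng.uniform(0.05, 0.2, 12)
    G = 0.4 * g + rng.normal(0, 0.02, 12)
    se_y = np.full(12, 0.02)
    h1 = hset_from_arrays(g, 0.005, G, se_y)
    flip = rng.random(12) < 0.5
    sign = np.where(flip, -1.0, 1.0)
    h2 = hset_from_arrays(g * sign, 0.005, G * sign, se_y)
    assert ivw(h2).beta == pytest.approx(ivw(h1).beta, rel=1e-12)
    assert mr_egger(h2).beta == pytest.approx(mr_egger(h1).beta, rel=1e-9)
    m1 = weighted_median(h1, n_boot=50, seed=5)
    m2 = weighted_median(h2, n_boot=50, seed=5)
    assert m2.beta == pytest.approx(m1.beta, rel=1e-12)
    k1 = weighted_mode(h1, n_boot=2, seed=5)
    k2 = weighted_mode(h2, n_boot=2, seed=5)
    assert k2.beta == pytest.approx(k1.beta, rel=1e-9)


# ---------------- run_all ----------------

def test_run_all_cardinality():
    rng = np.random.default_rng(2)
    g = rng.uniform(0.05, 0.2, 42)
    hset = hset_from_arrays(g, 0.005, 0.1 * g + rng.normal(0, 0.02, 42), 0.02)
    res = run_all(hset, EstimatorConfig(n_boot=50, seed=0))
    assert {e.method for e in res.estimates} == {"ivw", "egger",
                                                 "weighted_median", "weighted_mode"}
    assert len(res.single_snp) == 42


def test_run_all_single_pair_reports_absences():
    hset = hset_from_arrays([0.1], 0.01, [0.2], 0.05)
    res = run_all(hset, EstimatorConfig(n_boot=50, seed=0))
    assert {e.method for e in res.estimates} == {"ivw"}
    assert set(res.absent) == {"egger", "weighted_median", "weighted_mode"}
    for reason in res.absent.values():
        assert "requires" in reason


def test_run_all_reproducible_with_seed():
    rng = np.random.default_rng(4)
    g = rng.uniform(0.05, 0.2, 10)
    hset = hset_from_arrays(g, 0.005, 0.2 * g + rng.normal(0, 0.02, 10), 0.02)
    r1 = run_all(hset, EstimatorConfig(n_boot=100, seed=7))
    r2 = run_all(hset, EstimatorConfig(n_boot=100, seed=7))
    for e1, e2 in zip(r1.estimates, r2.estimates):
        assert e1.se == e2.se
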
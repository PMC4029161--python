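"""Likelihood framework: ML estimation, LR tests, kappa^2, lambda bounds, bins."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from repeatdim import freqstats as fq
from repeatdim.freqstats import CountPair


# ---------------------------------------------------------------------------
# log likelihood and ML estimates

def test_loglik_empty_success_case():
    assert fq.log_likelihood(0.0, 0.0, CountPair(0, 0, 2, 2)) == 0.0


def test_loglik_direct_evaluation():
    """x_s=1, N_s=2, f_s=0.5, germline terms zeroed -> ln(0.25)."""
    val = fq.log_likelihood(0.5, 0.0, CountPair(1, 0, 2, 5))
    assert val == pytest.approx(math.log(0.25))


def test_loglik_zero_frequency_with_successes_is_neg_inf():
    assert fq.log_likelihood(0.0, 0.5, CountPair(1, 0, 2, 2)) == -math.inf


def test_loglik_maximised_at_sample_proportions():
    """Grid-search oracle: ML at f_hat = x/N in each genome."""
    counts = CountPair(3, 7, 10, 20)
    grid = np.linspace(0, 1, 101)
    best = max(((fs, fg) for fs in grid for fg in grid),
               key=lambda p: fq.log_likelihood(p[0], p[1], counts))
    assert best[0] == pytest.approx(0.3, abs=1e-9)
    assert best[1] == pytest.approx(0.35, abs=1e-9)


def test_ml_estimates_basic():
    f_s, f_g, f_0 = fq.ml_estimates(CountPair(10, 10, 1000, 1000))
    assert f_s == f_g == f_0 == 0.01


def test_zero_count_ratio_undefined():
    cmp = fq.compare_superfamily("X", CountPair(0, 5, 1000, 1000), n_sim=500)
    assert cmp.ratio is None
    assert cmp.lambda_95 is None


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 50), st.integers(0, 50), st.integers(1, 100),
       st.integers(1, 100))
def test_pooled_estimate_between_sample_proportions(xs, xg, ns_extra, ng_extra):
    counts = CountPair(xs, xg, xs + ns_extra, xg + ng_extra)
    f_s, f_g, f_0 = fq.ml_estimates(counts)
    assert min(f_s, f_g) - 1e-12 <= f_0 <= max(f_s, f_g) + 1e-12


# ---------------------------------------------------------------------------
# LR statistic

def _two_prop_lr_oracle(counts):
    """Independent two-proportion LR statistic, coded from the definition."""
    def ll(x, n, f):
        out = 0.0
        if x > 0:
            out += x * math.log(f)
        if n - x > 0:
            out += (n - x) * math.log(1 - f)
        return out
    fs, fg = counts.x_s / counts.N_s, counts.x_g / counts.N_g
    f0 = (counts.x_s + counts.x_g) / (counts.N_s + counts.N_g)
    alt = ll(counts.x_s, counts.N_s, fs) + ll(counts.x_g, counts.N_g, fg)
    null = ll(counts.x_s, counts.N_s, f0) + ll(counts.x_g, counts.N_g, f0)
    return 2 * (alt - null)


def test_equal_proportions_give_zero_statistic():
    assert fq.equality_statistic(CountPair(10, 20, 1000, 2000)) == 0.0


def test_lr_statistic_matches_independent_oracle():
    counts = CountPair(10, 30, 1000, 1000)
    assert fq.equality_statistic(counts) == pytest.approx(
        _two_prop_lr_oracle(counts), rel=1e-12)


def test_lr_statistic_symmetric_under_genome_swap():
    a = fq.equality_statistic(CountPair(10, 30, 1000, 2000))
    b = fq.equality_statistic(CountPair(30, 10, 2000, 1000))
    assert a == pytest.approx(b, rel=1e-12)


# ---------------------------------------------------------------------------
# kappa^2 simulation

def test_kappa2_joint_matches_chi2_2df():
    """For f > 1e-4 the simulated cutoff approaches chi^2(2df) 5.991."""
    k2 = fq.simulate_kappa2((1e-3, 1.5e-3), (200_000, 200_000), "joint",
                            alpha=0.05, n_sim=10_000, seed=5)
    assert abs(k2 - stats.chi2.ppf(0.95, 2)) < 0.15


def test_kappa2_alpha_one_is_minimum():
    rng = np.random.default_rng(1)
    k2 = fq.simulate_kappa2((1e-3, 1e-3), (10_000, 10_000), "joint",
                            alpha=1.0, n_sim=500, seed=1)
    xs = rng.binomial(10_000, 1e-3, 500)  # same draw count; min is >= 0 anyway
    assert k2 >= 0.0
    k2_small = fq.simulate_kappa2((1e-3, 1e-3), (10_000, 10_000), "joint",
                                  alpha=0.5, n_sim=500, seed=1)
    assert k2 <= k2_small


def test_kappa2_deterministic_given_seed():
    a = fq.simulate_kappa2((1e-3, 2e-3), (50_000, 50_000), "joint", 0.05, 2000, 9)
    b = fq.simulate_kappa2((1e-3, 2e-3), (50_000, 50_000), "joint", 0.05, 2000, 9)
    assert a == b


def test_kappa2_departs_from_chi2_for_rare_repeats():
    """Very rare repeats: discreteness pulls the cutoff off the chi^2 value."""
    k2 = fq.simulate_kappa2((2e-6, 2e-6), (100_000, 100_000), "joint",
                            alpha=0.05, n_sim=4000, seed=13)
    assert abs(k2 - stats.chi2.ppf(0.95, 2)) > 0.5


# ---------------------------------------------------------------------------
# equality test

def test_equality_test_equal_proportions_p_near_one():
    res = fq.test_equal_frequency(CountPair(50, 50, 10_000, 10_000),
                                  n_sim=2000, seed=3)
    assert res.p_value > 0.9
    assert not res.reject


def test_equality_test_zero_counts_untested():
    res = fq.test_equal_frequency(CountPair(0, 0, 1000, 1000))
    assert not res.tested
    assert math.isnan(res.p_value)


def test_equality_test_power_large_effect():
    """f_g = 2e-3 vs f_s = 1e-3 at N = 200,000 -> essentially always rejected."""
    rng = np.random.default_rng(17)
    rejections = 0
    for _ in range(30):
        cp = CountPair(int(rng.binomial(200_000, 1e-3)),
                       int(rng.binomial(200_000, 2e-3)), 200_000, 200_000)
        rejections += fq.test_equal_frequency(cp, n_sim=2000, seed=rng).reject
    assert rejections == 30


def test_equality_test_pvalues_uniform_under_null():
    """Calibration: null p-values approximately uniform(0,1)."""
    rng = np.random.default_rng(23)
    f0, Ns, Ng = 2e-3, 30_000, 10_000
    pvals = []
    for _ in range(400):
        cp = CountPair(int(rng.binomial(Ns, f0)), int(rng.binomial(Ng, f0)),
                       Ns, Ng)
        res = fq.test_equal_frequency(cp, n_sim=1000, seed=rng)
        if res.tested:
            pvals.append(res.p_value)
    d, p = stats.kstest(pvals, "uniform")
    assert p > 0.01


# ---------------------------------------------------------------------------
# joint confidence region

def test_joint_region_contains_ml_estimate():
    cp = CountPair(40, 80, 50_000, 50_000)
    ci_s, ci_g, _ = fq.joint_confidence_region(cp, n_sim=2000, seed=7)
    assert ci_s[0] <= cp.x_s / cp.N_s <= ci_s[1]
    assert ci_g[0] <= cp.x_g / cp.N_g <= ci_g[1]


def test_joint_region_shrinks_with_sample_size():
    cp1 = CountPair(40, 80, 50_000, 50_000)
    cp10 = CountPair(400, 800, 500_000, 500_000)
    ci1, _, _ = fq.joint_confidence_region(cp1, n_sim=2000, seed=7)
    ci10, _, _ = fq.joint_confidence_region(cp10, n_sim=2000, seed=7)
    assert ci10[1] - ci10[0] < ci1[1] - ci1[0]


def test_joint_region_coverage():
    """True (f_s, f_g) falls inside the region in ~95 % of datasets."""
    rng = np.random.default_rng(29)
    fs_t, fg_t, Ns, Ng = 1e-3, 2e-3, 200_000, 200_000
    n_rep, covered = 300, 0
    for _ in range(n_rep):
        cp = CountPair(int(rng.binomial(Ns, fs_t)), int(rng.binomial(Ng, fg_t)),
                       Ns, Ng)
        fs, fg, _ = fq.ml_estimates(cp)
        _, _, k2 = fq.joint_confidence_region(cp, n_sim=1500, seed=rng)
        covered += fq.lr_statistic(cp, (fs_t, fg_t), (fs, fg)) <= k2
    assert abs(covered / n_rep - 0.95) < 0.035


# ---------------------------------------------------------------------------
# lambda (ratio) thresholds

def test_lambda_ordering_germline_dominant():
    cp = CountPair(100, 400, 100_000, 200_000)  # ratio 2
    ratio = (400 / 200_000) / (100 / 100_000)
    l95 = fq.ratio_threshold(cp, 0.05)
    l99 = fq.ratio_threshold(cp, 0.01)
    assert l99 < l95 < ratio
    assert l95 > 1


def test_lambda_ordering_somatic_dominant():
    cp = CountPair(400, 100, 100_000, 200_000)
    ratio = (100 / 200_000) / (400 / 100_000)
    l95 = fq.ratio_threshold(cp, 0.05)
    l99 = fq.ratio_threshold(cp, 0.01)
    assert ratio < l95 < l99 < 1


def test_lambda_na_when_bound_crosses_one():
    """Marginally significant repeats: the 99 % bound does not exist."""
    cp = CountPair(14, 5, 100_000, 100_000)  # modest somatic excess
    stat = fq.equality_statistic(cp)
    assert fq.ratio_statistic(cp, 1.0) == pytest.approx(stat, rel=1e-9)
    if stat < stats.chi2.ppf(0.98, 1):
        assert fq.ratio_threshold(cp, 0.01) is None


def test_ratio_statistic_constrained_ml_matches_grid():
    """Profile value along the ridge agrees with a brute-force grid search."""
    cp = CountPair(30, 90, 10_000, 10_000)
    lam = 1.7
    grid = np.linspace(1e-6, 0.02, 20_000)
    ll = np.array([fq.log_likelihood(f, min(lam * f, 1.0), cp) for f in grid])
    best = ll.max()
    fs, fg, _ = fq.ml_estimates(cp)
    expected = 2 * (fq.log_likelihood(fs, fg, cp) - best)
    assert fq.ratio_statistic(cp, lam) == pytest.approx(expected, abs=1e-3)


def test_lambda_coverage_one_sided():
    """True ratio exceeds the one-sided 95 % lower bound in ~95 % of datasets."""
    rng = np.random.default_rng(31)
    fs_t, fg_t, Ns, Ng = 1e-3, 2e-3, 200_000, 200_000
    rho = fg_t / fs_t
    n_rep, covered = 400, 0
    for _ in range(n_rep):
        cp = CountPair(int(rng.binomial(Ns, fs_t)), int(rng.binomial(Ng, fg_t)),
                       Ns, Ng)
        lam = fq.ratio_threshold(cp, 0.05)
        covered += lam is None or rho > lam
    assert abs(covered / n_rep - 0.95) < 0.03


# ---------------------------------------------------------------------------
# classification (labels as reported in the study's comparison table)

@pytest.mark.parametrize("p, fs, fg, expected", [
    (0.653, 1.0e-4, 0.671e-4, fq.NEITHER),
    (1e-17, 1.0e-3, 1.888e-3, fq.GERMLINE_DOMINANT),
    (1e-17, 1.0e-3, 0.5324e-3, fq.SOMATIC_DOMINANT),
    (0.04, 2e-4, 1e-4, fq.SOMATIC_DOMINANT),
])
def test_classify_superfamily(p, fs, fg, expected):
    assert fq.classify_superfamily(p, fs, fg, alpha=0.05) == expected


# ---------------------------------------------------------------------------
# subfamily binning (Poisson approximation)

def test_subfamily_bin_equal_proportions():
    label, stat, p = fq.subfamily_bin(CountPair(20, 40, 1000, 2000))
    assert label == fq.BIN_EQUAL
    assert stat == pytest.approx(0.0, abs=1e-12)


def test_subfamily_bin_zero_counts_equal_by_convention():
    label, stat, p = fq.subfamily_bin(CountPair(0, 0, 1000, 1000))
    assert label == fq.BIN_EQUAL
    assert math.isnan(p)


def test_poisson_lr_matches_brute_force():
    """Statistic equals 2[l(alt) - l(null)] with pooled-rate Poisson null."""
    cp = CountPair(7, 19, 5000, 8000)

    def pois_ll(x, mu):
        return x * math.log(mu) - mu if x > 0 else -mu
    f0 = (cp.x_s + cp.x_g) / (cp.N_s + cp.N_g)
    alt = pois_ll(cp.x_s, cp.x_s) + pois_ll(cp.x_g, cp.x_g)
    null = pois_ll(cp.x_s, cp.N_s * f0) + pois_ll(cp.x_g, cp.N_g * f0)
    assert fq.poisson_lr_statistic(cp) == pytest.approx(2 * (alt - null), rel=1e-9)


def test_subfamily_bin_type_one_error():
    """~5 % false excision/retention calls at moderate counts under the null."""
    rng = np.random.default_rng(37)
    f0, Ns, Ng = 1e-3, 100_000, 100_000
    n_rep = 2000
    false = 0
    for _ in range(n_rep):
        cp = CountPair(int(rng.binomial(Ns, f0)), int(rng.binomial(Ng, f0)),
                       Ns, Ng)
        label, _, _ = fq.subfamily_bin(cp)
        false += label != fq.BIN_EQUAL
    assert abs(false / n_rep - 0.05) < 0.02


def test_subfamily_bin_direction():
    label, _, _ = fq.subfamily_bin(CountPair(10, 100, 100_000, 100_000))
    assert label == fq.BIN_EXCISED
    label, _, _ = fq.subfamily_bin(CountPair(100, 10, 100_000, 100_000))
    assert label == fq.BIN_RETAINED


# ---------------------------------------------------------------------------
# 2-sample z tests

def test_z_identical_samples():
    z, p = fq.two_sample_z([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert z == 0.0
    assert p == 1.0


def test_z_matches_statsmodels_oracle():
    from statsmodels.stats.weightstats import CompareMeans, DescrStatsW
    rng = np.random.default_rng(41)
    a = rng.normal(7.5, 2.0, 300)
    b = rng.normal(8.8, 2.2, 500)
    z, p = fq.two_sample_z(a, b)
    cm = CompareMeans(DescrStatsW(a), DescrStatsW(b))
    z_ref, p_ref = cm.ztest_ind(usevar="unequal")
    assert z == pytest.approx(z_ref, rel=1e-9)
    assert p == pytest.approx(p_ref, rel=1e-9)


def test_age_by_bin_z_direction(rng):
    """Younger excised bin -> significantly negative z vs the reference bin."""
    import pandas as pd
    rows = []
    for fam, mean, label in [("f1", 3.0, fq.BIN_EXCISED),
                             ("f2", 6.0, fq.BIN_EQUAL),
                             ("f3", 9.0, fq.BIN_RETAINED)]:
        for v in rng.normal(mean, 1.0, 200):
            rows.append({"family_id": fam, "jc_percent": v})
    est = pd.DataFrame(rows)
    bins = {"f1": fq.BIN_EXCISED, "f2": fq.BIN_EQUAL, "f3": fq.BIN_RETAINED}
    cdfs, ztab = fq.age_by_bin(bins, est)
    ztab = ztab.set_index("comparison")
    assert ztab.loc["excised_vs_equal", "z"] < 0
    assert ztab.loc["excised_vs_equal", "p_value"] < 1e-6
    assert ztab.loc["retained_vs_equal", "z"] > 0
    assert len(cdfs[fq.BIN_EQUAL]) == 200
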
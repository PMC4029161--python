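"""Likelihood framework for germline/soma repeat-frequency comparisons.

Each shotgun read is treated as an independent Bernoulli trial: with x_s and
x_g reads mapping to a repeat out of N_s and N_g total reads,

    ln L(f_s, f_g) = x_s ln f_s + (N_s - x_s) ln(1 - f_s)
                   + x_g ln f_g + (N_g - x_g) ln(1 - f_g).

The module provides ML estimation (sample proportions and the pooled
estimate), likelihood-ratio tests of H0: f_g = f_s with simulation-calibrated
cutoffs and percentile-ranked p-values, joint confidence regions with
one-dimensional per-genome summaries, one-sided confidence bounds (lambda
thresholds) for the ratio f_g/f_s via a profile likelihood along the ridge
f_g = lambda f_s, a Poisson-approximation chi^2(1) shortcut for binning
individual repeat (sub)families as excised / retained / equal, and 2-sample
z-tests comparing mean divergence between bins.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import xlogy

GERMLINE_DOMINANT = "Germline"
SOMATIC_DOMINANT = "Somatic"
NEITHER = "Neither"

BIN_EXCISED = "excised"     # f_g/f_s >> 1
BIN_RETAINED = "retained"   # f_g/f_s << 1
BIN_EQUAL = "equal"         # reference


@dataclass(frozen=True)
class CountPair:
    """Observed mapped-read counts and totals for one repeat in both genomes."""

    x_s: int
    x_g: int
    N_s: int
    N_g: int

    def __post_init__(self) -> None:
        if self.N_s <= 0 or self.N_g <= 0:
            raise ValueError("totals must be positive")
        if not (0 <= self.x_s <= self.N_s and 0 <= self.x_g <= self.N_g):
            raise ValueError("counts must satisfy 0 <= x <= N")


@dataclass
class FrequencyComparison:
    """Everything the per-superfamily comparison table reports."""

    superfamily: str
    counts: CountPair
    f_s: float
    f_g: float
    f_0: float
    ratio: Optional[float]
    x2: float
    x2_joint: float
    p_value: float
    dominant: str
    lambda_95: Optional[float]
    lambda_99: Optional[float]
    ci_s: Tuple[float, float]
    ci_g: Tuple[float, float]


# ---------------------------------------------------------------------------
# Likelihood primitives

def _binom_loglik(x, n, f):
    """Bernoulli-product log likelihood term; 0*log(0) == 0, f==0 with x>0 -> -inf."""
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    f = np.asarray(f, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = xlogy(x, f) + xlogy(n - x, 1.0 - f)
    return out


def log_likelihood(f_s: float, f_g: float, counts: CountPair) -> float:
    """ln L(f_s, f_g; x_s, x_g) on the log scale."""
    for f in (f_s, f_g):
        if not 0 <= f <= 1:
            raise ValueError("frequencies must be in [0, 1]")
    val = (_binom_loglik(counts.x_s, counts.N_s, f_s)
           + _binom_loglik(counts.x_g, counts.N_g, f_g))
    return float(val)


def ml_estimates(counts: CountPair) -> Tuple[float, float, float]:
    """Sample proportions and the pooled estimate under H0: f_s = f_g."""
    f_s = counts.x_s / counts.N_s
    f_g = counts.x_g / counts.N_g
    f_0 = (counts.x_s + counts.x_g) / (counts.N_s + counts.N_g)
    return f_s, f_g, f_0


def lr_statistic(counts: CountPair,
                 null: Tuple[float, float],
                 alt: Tuple[float, float]) -> float:
    """X^2 = -2 [ln L(null) - ln L(alt)]."""
    return -2.0 * (log_likelihood(*null, counts) - log_likelihood(*alt, counts))


def equality_statistic(counts: CountPair) -> float:
    """X^2 for H0: f_s = f_g (pooled null vs unconstrained ML)."""
    f_s, f_g, f_0 = ml_estimates(counts)
    return max(lr_statistic(counts, (f_0, f_0), (f_s, f_g)), 0.0)


def _equality_statistic_vec(xs, xg, N_s, N_g):
    fs, fg = xs / N_s, xg / N_g
    f0 = (xs + xg) / (N_s + N_g)
    alt = _binom_loglik(xs, N_s, fs) + _binom_loglik(xg, N_g, fg)
    null = _binom_loglik(xs, N_s, f0) + _binom_loglik(xg, N_g, f0)
    return np.maximum(2.0 * (alt - null), 0.0)


def _joint_statistic_vec(xs, xg, N_s, N_g, f_s0, f_g0):
    fs, fg = xs / N_s, xg / N_g
    alt = _binom_loglik(xs, N_s, fs) + _binom_loglik(xg, N_g, fg)
    null = _binom_loglik(xs, N_s, f_s0) + _binom_loglik(xg, N_g, f_g0)
    return np.maximum(2.0 * (alt - null), 0.0)


# ---------------------------------------------------------------------------
# Simulation-calibrated cutoffs and tests

def simulate_kappa2(f_gen: Tuple[float, float],
                    totals: Tuple[int, int],
                    recipe: str = "joint",
                    alpha: float = 0.05,
                    n_sim: int = 10_000,
                    seed: Union[int, np.random.Generator] = 0) -> float:
    """Empirical (1 - alpha) quantile of a likelihood-ratio statistic under
    binomial sampling at the given generating frequencies.

    Recipes: ``joint`` -- the 2-parameter region statistic
    -2 ln Lambda(f_gen vs per-draw ML) (approaches the chi^2 2-df quantile for
    frequencies above ~1e-4); ``equality`` -- the pooled-null equality
    statistic (1-df analogue).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f_s0, f_g0 = f_gen
    N_s, N_g = totals
    xs = rng.binomial(N_s, f_s0, size=n_sim).astype(float)
    xg = rng.binomial(N_g, f_g0, size=n_sim).astype(float)
    if recipe == "joint":
        sims = _joint_statistic_vec(xs, xg, N_s, N_g, f_s0, f_g0)
    elif recipe == "equality":
        sims = _equality_statistic_vec(xs, xg, N_s, N_g)
    else:
        raise ValueError(f"unknown recipe {recipe!r}")
    return float(np.quantile(sims, 1.0 - alpha))


@dataclass
class EqualityTest:
    x2: float
    p_value: float
    reject: bool
    tested: bool


def test_equal_frequency(counts: CountPair,
                         alpha: float = 0.05,
                         n_sim: int = 10_000,
                         seed: Union[int, np.random.Generator] = 0) -> EqualityTest:
    """Simulation-based likelihood-ratio test of H0: f_s = f_g.

    The p-value is the percentile ranking of the observed X^2 among
    statistics simulated under the pooled null, with the finite-sample
    (r + 1)/(n + 1) correction.  x_s = x_g = 0 leaves the repeat untested.
    """
    if counts.x_s == 0 and counts.x_g == 0:
        return EqualityTest(0.0, float("nan"), False, tested=False)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = equality_statistic(counts)
    _, _, f_0 = ml_estimates(counts)
    xs = rng.binomial(counts.N_s, f_0, size=n_sim).astype(float)
    xg = rng.binomial(counts.N_g, f_0, size=n_sim).astype(float)
    sims = _equality_statistic_vec(xs, xg, counts.N_s, counts.N_g)
    r = int(np.count_nonzero(sims >= obs - 1e-12))
    p = (r + 1) / (n_sim + 1)
    return EqualityTest(obs, p, p < alpha, tested=True)


# ---------------------------------------------------------------------------
# Joint confidence region and 1-D summaries

def _profile_interval(x: int, N: int, kappa2: float) -> Tuple[float, float]:
    """{f : 2 [l(f_hat) - l(f)] <= kappa2}, located by root bisection."""
    f_hat = x / N
    if kappa2 <= 0:
        return f_hat, f_hat
    lhat = float(_binom_loglik(x, N, f_hat))

    def dev(f: float) -> float:
        return 2.0 * (lhat - float(_binom_loglik(x, N, f))) - kappa2

    lo = 0.0
    if x > 0:
        if dev(1e-12) < 0:
            lo = 0.0
        else:
            lo = float(optimize.brentq(dev, 1e-12, f_hat, xtol=1e-12, rtol=1e-10))
    hi = 1.0
    if x < N:
        if dev(1.0 - 1e-12) < 0:
            hi = 1.0
        else:
            hi = float(optimize.brentq(dev, f_hat if f_hat > 0 else 1e-300,
                                       1.0 - 1e-12, xtol=1e-12, rtol=1e-10))
    return lo, hi


def joint_confidence_region(counts: CountPair,
                            alpha: float = 0.05,
                            n_sim: int = 10_000,
                            seed: Union[int, np.random.Generator] = 0,
                            kappa2: Optional[float] = None,
                            ) -> Tuple[Tuple[float, float], Tuple[float, float], float]:
    """Per-genome 1-D summaries (min/max of each coordinate) of the joint
    likelihood-ratio confidence region, plus the kappa^2 used.

    The region is {(f_s, f_g) : -2 ln Lambda((f_s, f_g) vs ML) <= kappa^2};
    because the likelihood factorises, each coordinate's extrema solve the
    per-genome profile deviance equal to kappa^2.
    """
    f_s, f_g, _ = ml_estimates(counts)
    if kappa2 is None:
        kappa2 = simulate_kappa2((f_s, f_g), (counts.N_s, counts.N_g),
                                 recipe="joint", alpha=alpha,
                                 n_sim=n_sim, seed=seed)
    ci_s = _profile_interval(counts.x_s, counts.N_s, kappa2)
    ci_g = _profile_interval(counts.x_g, counts.N_g, kappa2)
    return ci_s, ci_g, float(kappa2)


# ---------------------------------------------------------------------------
# Ratio (lambda) one-sided confidence bounds

def _constrained_ml(counts: CountPair, lam: float) -> Tuple[float, float]:
    """ML of (f_s, f_g) constrained to the ridge f_g = lam * f_s.

    The stationarity condition reduces to a quadratic in f_s; the admissible
    root lies in (0, min(1, 1/lam)).
    """
    a = counts.x_s + counts.x_g
    b = counts.N_s - counts.x_s
    c = counts.N_g - counts.x_g
    if a == 0:
        return 0.0, 0.0
    A = lam * (a + b + c)
    B = a * (1.0 + lam) + b + lam * c
    C = float(a)
    disc = B * B - 4.0 * A * C
    disc = max(disc, 0.0)
    upper = min(1.0, 1.0 / lam)
    roots = []
    if A > 0:
        sq = math.sqrt(disc)
        roots = [(B - sq) / (2 * A), (B + sq) / (2 * A)]
    else:
        roots = [C / B]
    eps = 1e-15
    for fs in sorted(roots):
        if eps < fs < upper - eps:
            return fs, lam * fs
    # boundary fallbacks (degenerate counts)
    fs = min(max(roots[0], eps), upper - eps)
    return fs, lam * fs


def ratio_statistic(counts: CountPair, lam: float) -> float:
    """Profile LR statistic for H0: f_g / f_s = lam."""
    f_s, f_g, _ = ml_estimates(counts)
    fs_c, fg_c = _constrained_ml(counts, lam)
    return max(lr_statistic(counts, (fs_c, fg_c), (f_s, f_g)), 0.0)


def ratio_threshold(counts: CountPair,
                    alpha: float = 0.05,
                    cutoff: Union[str, float] = "chisq",
                    n_sim: int = 10_000,
                    seed: Union[int, np.random.Generator] = 0,
                    rtol: float = 1e-4) -> Optional[float]:
    """One-sided confidence bound (lambda threshold) for f_g / f_s.

    For f_g_hat > f_s_hat this is the largest lambda > 1 such that
    H0: f_g/f_s <= lambda is rejected at level alpha (the endpoint of a
    one-sided (1 - alpha) CI); the construction is mirrored for
    f_g_hat < f_s_hat.  The search bisects the profile-likelihood statistic
    along the ridge f_g = lambda f_s to relative tolerance ``rtol``.

    Returns None ("NA") when no lambda on the estimate's side of 1 can be
    rejected -- including when the equality test itself would not reject.
    ``cutoff`` is either the one-sided chi^2(1) critical value ("chisq"),
    a numeric critical value, or "simulate" (calibrated at the constrained
    ML on the boundary lambda = 1).
    """
    if counts.x_s == 0 or counts.x_g == 0:
        return None
    f_s, f_g, _ = ml_estimates(counts)
    ratio = f_g / f_s
    if ratio == 1.0:
        return None
    if cutoff == "chisq":
        crit = float(stats.chi2.ppf(1.0 - 2.0 * alpha, df=1))
    elif cutoff == "simulate":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        fs_c, fg_c = _constrained_ml(counts, 1.0)
        xs = rng.binomial(counts.N_s, fs_c, size=n_sim)
        xg = rng.binomial(counts.N_g, fg_c, size=n_sim)
        sims = np.empty(n_sim)
        side = 1.0 if ratio > 1 else -1.0
        for i in range(n_sim):
            cp = CountPair(int(xs[i]), int(xg[i]), counts.N_s, counts.N_g)
            s = equality_statistic(cp)
            fs_i, fg_i, _ = ml_estimates(cp)
            sims[i] = s if side * (fg_i - fs_i) > 0 else 0.0
        crit = float(np.quantile(sims, 1.0 - alpha))
    else:
        crit = float(cutoff)

    def g(lam: float) -> float:
        return ratio_statistic(counts, lam) - crit

    if g(1.0) < 0:
        return None
    # statistic is 0 at lambda = ratio and >= crit at lambda = 1
    lo, hi = (1.0, ratio) if ratio > 1 else (ratio, 1.0)
    lam = float(optimize.brentq(g, lo, hi, xtol=1e-15, rtol=rtol))
    return lam


def classify_superfamily(p_value: float, f_s: float, f_g: float,
                         alpha: float = 0.05) -> str:
    """Dominant-genome label: Neither unless H0: f_g = f_s is rejected."""
    if not np.isfinite(p_value) or p_value >= alpha:
        return NEITHER
    return GERMLINE_DOMINANT if f_g > f_s else SOMATIC_DOMINANT


def compare_superfamily(superfamily: str,
                        counts: CountPair,
                        alpha: float = 0.05,
                        n_sim: int = 10_000,
                        seed: Union[int, np.random.Generator] = 0,
                        lambda_cutoff: Union[str, float] = "chisq",
                        ) -> FrequencyComparison:
    """Full Table-style comparison for one superfamily."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f_s, f_g, f_0 = ml_estimates(counts)
    eq = test_equal_frequency(counts, alpha, n_sim, rng)
    ratio = (f_g / f_s) if f_s > 0 and f_g > 0 else None
    dominant = classify_superfamily(eq.p_value, f_s, f_g, alpha) if eq.tested else NEITHER
    lam95 = lam99 = None
    if dominant != NEITHER and ratio is not None:
        lam95 = ratio_threshold(counts, 0.05, lambda_cutoff, n_sim, rng)
        lam99 = ratio_threshold(counts, 0.01, lambda_cutoff, n_sim, rng)
    ci_s, ci_g, _ = joint_confidence_region(counts, alpha, n_sim, rng)
    x2_joint = lr_statistic(counts, (f_0, f_0), (f_s, f_g))
    return FrequencyComparison(
        superfamily=superfamily, counts=counts,
        f_s=f_s, f_g=f_g, f_0=f_0, ratio=ratio,
        x2=eq.x2, x2_joint=x2_joint, p_value=eq.p_value,
        dominant=dominant, lambda_95=lam95, lambda_99=lam99,
        ci_s=ci_s, ci_g=ci_g,
    )


def compare_table(counts_by_superfamily: Mapping[str, CountPair],
                  alpha: float = 0.05,
                  n_sim: int = 10_000,
                  seed: int = 0,
                  lambda_cutoff: Union[str, float] = "chisq") -> pd.DataFrame:
    """Per-superfamily comparison table (one row per superfamily)."""
    rows = []
    children = np.random.SeedSequence(seed).spawn(len(counts_by_superfamily))
    for child, (sup, counts) in zip(children, sorted(counts_by_superfamily.items())):
        cmp = compare_superfamily(sup, counts, alpha, n_sim,
                                  np.random.default_rng(child), lambda_cutoff)
        rows.append({
            "superfamily": sup,
            "x_g": counts.x_g, "x_s": counts.x_s,
            "N_g": counts.N_g, "N_s": counts.N_s,
            "f_g": cmp.f_g, "f_s": cmp.f_s, "f_0": cmp.f_0,
            "p_value": cmp.p_value, "x2": cmp.x2, "x2_joint": cmp.x2_joint,
            "dominant": cmp.dominant,
            "ratio": cmp.ratio if cmp.ratio is not None else np.nan,
            "lambda_95": cmp.lambda_95 if cmp.lambda_95 is not None else np.nan,
            "lambda_99": cmp.lambda_99 if cmp.lambda_99 is not None else np.nan,
            "ci_s_lo": cmp.ci_s[0], "ci_s_hi": cmp.ci_s[1],
            "ci_g_lo": cmp.ci_g[0], "ci_g_hi": cmp.ci_g[1],
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Subfamily binning (Poisson approximation) and age-by-bin comparisons

def poisson_lr_statistic(counts: CountPair) -> float:
    """LR statistic under x ~ Poisson(N f) with pooled-rate null."""
    f_0 = (counts.x_s + counts.x_g) / (counts.N_s + counts.N_g)
    if f_0 == 0:
        return 0.0
    stat = 2.0 * (xlogy(counts.x_s, counts.x_s / (counts.N_s * f_0))
                  + xlogy(counts.x_g, counts.x_g / (counts.N_g * f_0)))
    return float(max(stat, 0.0))


def subfamily_bin(counts: CountPair, alpha: float = 0.05
                  ) -> Tuple[str, float, float]:
    """Bin one repeat as excised / retained / equal.

    Uses the Poisson approximation to the binomial with a chi^2 1-df
    p-value.  x_s = x_g = 0 bins as equal by convention (flagged upstream).
    Returns (bin label, statistic, p-value).
    """
    if counts.x_s == 0 and counts.x_g == 0:
        return BIN_EQUAL, 0.0, float("nan")
    stat = poisson_lr_statistic(counts)
    p = float(stats.chi2.sf(stat, df=1))
    if p >= alpha:
        return BIN_EQUAL, stat, p
    f_s, f_g, _ = ml_estimates(counts)
    return (BIN_EXCISED if f_g > f_s else BIN_RETAINED), stat, p


def two_sample_z(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """2-sample z statistic (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2), two-sided p."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    se = math.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    if se == 0:
        return 0.0, 1.0
    z = (a.mean() - b.mean()) / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def age_by_bin(bin_labels: Mapping[str, str],
               divergence: pd.DataFrame,
               value_col: str = "jc_percent",
               key_col: str = "family_id",
               ) -> Tuple[Dict[str, np.ndarray], pd.DataFrame]:
    """Cumulative divergence distributions per excision bin plus z-tests.

    ``bin_labels`` maps repeat identifiers to bin labels; ``divergence``
    holds per-copy divergence percentages attributable to those repeats.
    Returns the sorted per-bin value arrays (empirical CDF support) and a
    table of excised-vs-equal and retained-vs-equal z comparisons.
    """
    values: Dict[str, List[float]] = {BIN_EXCISED: [], BIN_RETAINED: [], BIN_EQUAL: []}
    for row in divergence.itertuples():
        label = bin_labels.get(getattr(row, key_col))
        val = getattr(row, value_col)
        if label in values and val is not None and np.isfinite(val):
            values[label].append(float(val))
    cdfs = {k: np.sort(np.asarray(v)) for k, v in values.items()}
    rows = []
    for name in (BIN_EXCISED, BIN_RETAINED):
        sample, ref = cdfs[name], cdfs[BIN_EQUAL]
        if sample.size < 2 or ref.size < 2:
            rows.append({"comparison": f"{name}_vs_equal", "z": np.nan,
                         "p_value": np.nan, "mean": np.nan, "mean_equal": np.nan,
                         "n": sample.size, "n_equal": ref.size})
            continue
        z, p = two_sample_z(sample, ref)
        rows.append({"comparison": f"{name}_vs_equal", "z": z, "p_value": p,
                     "mean": float(sample.mean()), "mean_equal": float(ref.mean()),
                     "n": sample.size, "n_equal": ref.size})
    return cdfs, pd.DataFrame(rows)
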
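"""Canned analyses: calibration experiments and end-to-end synthetic studies.

These functions are the computational steps behind the numbered analysis
scripts and the acceptance checks: simulation-based calibration of the
likelihood-ratio machinery (cutoffs, type-I error, coverage) and full
synthetic germline/soma analyses run through the same code paths as the
pipeline (annotation, divergence refinement, frequency tests, binning).
"""
from __future__ import annotations

from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import annotate, characterize, divergence, freqstats, seqio, simkit
from .freqstats import CountPair
from .models import GERMLINE, SOMA

#: Read totals used for calibration experiments: a 1/20 scale-down of the
#: study's germline/somatic 454 read counts (612,470 and 207,451).
CALIBRATION_N = {GERMLINE: 30_600, SOMA: 10_400}


# ---------------------------------------------------------------------------
# Statistical calibration

def kappa2_calibration(f_s: float = 1e-3, f_g: float = 1.5e-3,
                       totals: Tuple[int, int] = (200_000, 200_000),
                       alpha: float = 0.05, n_sim: int = 10_000,
                       seed: int = 0) -> float:
    """Simulated joint-region cutoff kappa^2 at non-rare frequencies.

    For frequencies above ~1e-4 this approaches the chi^2(2 df) quantile
    (5.991 at alpha = 0.05).
    """
    return freqstats.simulate_kappa2((f_s, f_g), totals, "joint", alpha,
                                     n_sim, seed)


def equality_type1_error(f0: float = 1e-3,
                         totals: Optional[Tuple[int, int]] = None,
                         n_rep: int = 1000, n_sim: int = 10_000,
                         alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical type-I error of the simulation-calibrated equality test."""
    N_s, N_g = totals if totals else (CALIBRATION_N[SOMA], CALIBRATION_N[GERMLINE])
    rng = np.random.default_rng(seed)
    rejections = tested = 0
    for _ in range(n_rep):
        cp = CountPair(int(rng.binomial(N_s, f0)), int(rng.binomial(N_g, f0)),
                       N_s, N_g)
        res = freqstats.test_equal_frequency(cp, alpha, n_sim, rng)
        if res.tested:
            tested += 1
            rejections += res.reject
    return rejections / tested


def joint_region_coverage(f_s: float = 1e-3, f_g: float = 2e-3,
                          totals: Tuple[int, int] = (200_000, 200_000),
                          n_rep: int = 500, n_sim: int = 2000,
                          alpha: float = 0.05, seed: int = 0) -> float:
    """Fraction of simulated datasets whose joint region covers the truth."""
    N_s, N_g = totals
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_rep):
        cp = CountPair(int(rng.binomial(N_s, f_s)), int(rng.binomial(N_g, f_g)),
                       N_s, N_g)
        fs_hat, fg_hat, _ = freqstats.ml_estimates(cp)
        _, _, k2 = freqstats.joint_confidence_region(cp, alpha, n_sim, rng)
        dev = freqstats.lr_statistic(cp, (f_s, f_g), (fs_hat, fg_hat))
        covered += dev <= k2
    return covered / n_rep


def lambda_coverage(f_s: float = 1e-3, f_g: float = 2e-3,
                    totals: Tuple[int, int] = (200_000, 200_000),
                    n_rep: int = 500, alpha: float = 0.05,
                    seed: int = 0) -> float:
    """Coverage of the one-sided ratio bound: true f_g/f_s beyond lambda."""
    N_s, N_g = totals
    rho = f_g / f_s
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_rep):
        cp = CountPair(int(rng.binomial(N_s, f_s)), int(rng.binomial(N_g, f_g)),
                       N_s, N_g)
        lam = freqstats.ratio_threshold(cp, alpha)
        if lam is None:
            covered += 1  # no bound claimed, truth cannot be excluded
        else:
            covered += (rho > lam) if rho > 1 else (rho < lam)
    return covered / n_rep


# ---------------------------------------------------------------------------
# Proliferation-burst landscape (recent expansion, young copies excised)

#: Families emulating a recent proliferation burst: high-frequency young
#: families with low somatic retention, a reference tier whose retention
#: matches the genome-wide average (frequency ratio ~1), and old
#: high-retention families.  Ages in the burst tier sit below 1 % divergence.
_BURST_TABLE = [
    ("yA", "DNA-hAT",   1800, 1200, 0.15, ("u", 0.000, 0.010), 3, 2.0),
    ("yB", "LINE-L1",   2000, 1000, 0.20, ("u", 0.000, 0.012), 4, 2.0),
    ("yC", "Unknown",   1500, 1400, 0.15, ("u", 0.000, 0.010), 3, 2.0),
    ("yD", "DNA-MuDR",  1600,  800, 0.18, ("u", 0.002, 0.015), 3, 2.0),
    ("mA", "LTR-BEL",   1500,  500, 0.48, ("u", 0.045, 0.075), 3, 2.0),
    ("mB", "Unknown",   1400,  600, 0.48, ("u", 0.050, 0.080), 3, 2.0),
    ("mC", "LTR-Copia", 1300,  400, 0.48, ("u", 0.045, 0.075), 2, 2.0),
    ("oA", "LTR-Gypsy", 2000,  700, 0.92, ("u", 0.090, 0.140), 4, 2.0),
    ("oB", "LINE-CR1",  1700,  500, 0.95, ("u", 0.100, 0.140), 4, 2.0),
    ("oC", "Unknown",   1400,  500, 0.90, ("u", 0.090, 0.130), 3, 2.0),
]


def burst_landscape(copy_scale: float = 1.0):
    """FamilySpecs for the proliferation-burst landscape."""
    specs = []
    for fam, sup, L, n, r, age, drift, cpg in _BURST_TABLE:
        dist = simkit.AgeDistribution.uniform(age[1], age[2])
        specs.append(simkit.FamilySpec(
            family_id=fam, superfamily=sup, consensus_length=L,
            copy_count_germline=max(int(round(n * copy_scale)), 2),
            retention_prob=r, age_distribution=dist,
            master_drift_subs=drift, cpg_rate_multiplier=cpg))
    return specs


def landscape_analysis(specs=None,
                       n_reads: Optional[Mapping[str, int]] = None,
                       seed: int = 0,
                       min_identity: float = 0.80,
                       min_overlap: int = 100,
                       alpha: float = 0.05) -> Dict:
    """Full in-memory synthetic analysis: simulate, filter, annotate, refine,
    bin, and compare, returning every headline quantity.

    Uses the default landscape when ``specs`` is None.
    """
    land = simkit.simulate_landscape(specs, n_reads=n_reads, seed=seed)

    filtered = {}
    for label, rs in land.readsets.items():
        kept, _removed = seqio.duplicate_filter(rs.reads)
        filtered[label] = simkit.ReadSet(label, kept, rs.genome_size_gb,
                                         rs.read_length_model)

    assignments, mask_fraction, fam_counts, totals = {}, {}, {}, {}
    profiles = {}
    for label, size_gb in ((GERMLINE, simkit.GERMLINE_GB), (SOMA, simkit.SOMA_GB)):
        rs = filtered[label]
        alns = annotate.annotate_readset(rs, land.library, min_identity,
                                         min_overlap)
        assignments[label] = alns
        mask = annotate.mask_summary(alns, rs)
        mask_fraction[label] = float(
            mask.loc[mask["class"] == "TOTAL", "masked_fraction"].iloc[0])
        fractions = {row["class"]: row["masked_fraction"]
                     for _, row in mask.iterrows() if row["class"] != "TOTAL"}
        profiles[label] = characterize.extrapolate_content(fractions, size_gb,
                                                           label)
        fam_counts[label] = pd.Series(
            [a.family_id for a in alns]).value_counts()
        totals[label] = len(rs)

    est = divergence.refine_all(assignments[GERMLINE] + assignments[SOMA],
                                land.library)
    dists = {}
    for label in (GERMLINE, SOMA):
        vals = est.loc[est.genome_label == label, "jc_percent"].dropna()
        dists[label] = divergence.divergence_distribution(vals, label)
    ks_d, ks_p = divergence.ks_compare(
        est.loc[est.genome_label == GERMLINE, "jc_percent"].dropna(),
        est.loc[est.genome_label == SOMA, "jc_percent"].dropna())

    bins = {}
    for fam in land.library:
        cp = CountPair(int(fam_counts[SOMA].get(fam.family_id, 0)),
                       int(fam_counts[GERMLINE].get(fam.family_id, 0)),
                       totals[SOMA], totals[GERMLINE])
        bins[fam.family_id], _, _ = freqstats.subfamily_bin(cp, alpha)
    cdfs, ztab = freqstats.age_by_bin(bins, est)

    eliminated, headline = characterize.eliminated_repeat_gb(
        profiles[GERMLINE], profiles[SOMA])
    return {
        "landscape": land,
        "estimates": est,
        "masked_fraction": mask_fraction,
        "profiles": profiles,
        "eliminated_gb": eliminated,
        "eliminated_gb_headline": headline,
        "distributions": dists,
        "ks": (ks_d, ks_p),
        "bins": bins,
        "bin_cdfs": cdfs,
        "z_tests": ztab,
    }
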
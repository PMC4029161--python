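"""Substitution cataloguing, master-lineage/CpG exclusion, JC correction, KS."""
import math

import numpy as np
import pytest

from repeatdim import divergence, simkit
from repeatdim.models import GERMLINE, SOMA, CopyAlignment
from repeatdim.simkit import AgeDistribution, FamilySpec


def _aln(read_id, cons_seg, read_seg, cons_start=0, genome=GERMLINE, fam="fam"):
    return CopyAlignment(read_id, fam, genome, cons_start,
                         cons_start + len(cons_seg.replace("-", "")),
                         0, len(read_seg.replace("-", "")),
                         cons_seg, read_seg)


# ---------------------------------------------------------------------------
# catalogue_substitutions

def test_identical_copy_yields_no_records():
    a = _aln("r1", "ACGTACGT" * 20, "ACGTACGT" * 20)
    assert divergence.catalogue_substitutions([a]) == []


def test_hand_fixture_two_substitutions():
    cons = "A" * 50 + "C" * 50
    read = list(cons)
    read[10] = "G"   # A -> G at consensus position 10
    read[42] = "T"   # A -> T at consensus position 42 (consensus there is A)
    a = _aln("r1", cons, "".join(read))
    recs = divergence.catalogue_substitutions([a])
    assert {(r.consensus_position, r.ancestral_base, r.derived_base)
            for r in recs} == {(10, "A", "G"), (42, "A", "T")}


def test_gap_columns_produce_no_records():
    cons = "ACGT-ACGT"
    read = "ACGTTAC-T"
    a = CopyAlignment("r1", "fam", GERMLINE, 0, 8, 0, 8, cons, read)
    recs = divergence.catalogue_substitutions([a])
    assert recs == []  # only gap/match columns


def test_simulated_family_records_match_truth(landscape):
    """Catalogued substitutions equal the simulator's per-copy truth exactly."""
    fam = landscape.library[0]
    rt = landscape.truth.reads
    rt = rt[(rt.family_id == fam.family_id) & (rt.genome_label == GERMLINE)]
    alns = simkit.oracle_alignments(landscape.readsets[GERMLINE], rt,
                                    landscape.pools)
    subs = landscape.truth.substitutions
    subs = subs[subs.family_id == fam.family_id]
    by_copy = {cid: {(r.pos, r.derived) for r in grp.itertuples()}
               for cid, grp in subs.groupby("copy_id")}
    read_truth = rt.set_index("read_id")
    recs = divergence.catalogue_substitutions(alns)
    by_read = {}
    for r in recs:
        by_read.setdefault(r.copy_id.split("/")[0], set()).add(
            (r.consensus_position, r.derived_base))
    for read_id, found in by_read.items():
        row = read_truth.loc[read_id]
        window = set(range(row.start, row.start + row.length))
        expected = {s for s in by_copy.get(row.copy_id, set()) if s[0] in window}
        assert found == expected


# ---------------------------------------------------------------------------
# find_shared_substitutions

def test_private_substitutions_not_excluded():
    cons = "ACGTACGT" * 20
    reads = []
    for i, pos in enumerate((3, 17, 33)):
        seg = list(cons)
        seg[pos] = "A" if seg[pos] != "A" else "C"
        reads.append(_aln(f"r{i}", cons, "".join(seg)))
    recs = divergence.catalogue_substitutions(reads)
    assert divergence.find_shared_substitutions(recs) == set()


def test_lone_shared_substitution_threshold_boundary():
    """One signature in 2 copies: excluded at min_group=1, kept at min_group=2."""
    cons = "ACGTACGT" * 20
    seg = list(cons)
    seg[50] = "A" if seg[50] != "A" else "C"
    reads = [_aln("r1", cons, "".join(seg)), _aln("r2", cons, "".join(seg))]
    recs = divergence.catalogue_substitutions(reads)
    assert divergence.find_shared_substitutions(recs, min_group=1) == {50}
    assert divergence.find_shared_substitutions(recs, min_group=2) == set()


def test_master_drift_positions_excluded():
    """Drift substitutions inherited as a block by a copy cohort are excluded.

    Copies that branched after all five drift substitutions share all five
    signatures, so the signatures group together and pass min_group=2.
    """
    spec = FamilySpec("drift", "DNA-hAT", consensus_length=1500,
                      copy_count_germline=120, master_drift_subs=5,
                      age_distribution=AgeDistribution.point(0.0))
    fam, copies, truth = simkit.evolve_family(spec, seed=31)
    full_branch = truth.copies.loc[truth.copies.branch_k == 5, "copy_id"]
    assert len(full_branch) >= 10
    alns = [CopyAlignment(cid, "drift", GERMLINE, 0, len(copies[cid]), 0,
                          len(copies[cid]), fam.consensus, copies[cid])
            for cid in full_branch]
    recs = divergence.catalogue_substitutions(alns)
    excluded = divergence.find_shared_substitutions(recs, min_copies=2, min_group=2)
    master_pos = {pos for pos, _a, _d in truth.master_subs["drift"]}
    assert master_pos == excluded


# ---------------------------------------------------------------------------
# cpg_positions

@pytest.mark.parametrize("seq, expected", [
    ("ACGT", {1, 2}),
    ("AAAA", set()),
    ("CGCG", {0, 1, 2, 3}),
    ("CCGG", {1, 2}),
])
def test_cpg_positions(seq, expected):
    assert divergence.cpg_positions(seq) == expected


# ---------------------------------------------------------------------------
# refine_divergence / Jukes-Cantor

def test_jc_closed_form():
    assert divergence.jukes_cantor(0.0) == 0.0
    assert divergence.jukes_cantor(0.10) == pytest.approx(0.107326, abs=1e-6)
    with pytest.raises(ValueError):
        divergence.jukes_cantor(0.75)


def test_refine_all_mismatches_at_excluded_positions():
    cons = "AAAATTTT" * 20
    seg = list(cons)
    for pos in (10, 20, 30):
        seg[pos] = "C"
    a = _aln("r1", cons, "".join(seg))
    est = divergence.refine_divergence(a, {10, 20, 30}, set())
    assert est.refined_p == 0.0
    assert est.jc_distance == 0.0
    assert est.raw_p == pytest.approx(3 / len(cons))
    assert est.n_sites_excluded_shared == 3


def test_refined_p_denominator_excludes_sites():
    cons = "A" * 100
    seg = list(cons)
    seg[0] = "C"          # counted mismatch
    seg[50] = "G"         # excluded mismatch
    a = _aln("r1", cons, "".join(seg))
    est = divergence.refine_divergence(a, {50}, set())
    assert est.refined_p == pytest.approx(1 / 99)


def test_refine_no_countable_columns_warns():
    cons = "ACGT" * 30
    a = _aln("r1", cons, cons)
    with pytest.warns(UserWarning):
        assert divergence.refine_divergence(a, set(range(len(cons))), set()) is None


def test_jc_distance_never_below_refined_p(oracle_alignments, landscape):
    est = divergence.refine_all(oracle_alignments, landscape.library)
    ok = est.dropna(subset=["jc_distance"])
    assert (ok.jc_distance >= ok.refined_p - 1e-12).all()


def test_exclusion_invariant_under_read_order(oracle_alignments, landscape):
    est1 = divergence.refine_all(oracle_alignments, landscape.library)
    est2 = divergence.refine_all(list(reversed(oracle_alignments)),
                                 landscape.library)
    m1 = est1.set_index("copy_id").sort_index()
    m2 = est2.set_index("copy_id").sort_index()
    assert (m1.refined_p == m2.refined_p).all()


# ---------------------------------------------------------------------------
# parameter recovery (the refinement's purpose)

def _read_scale_family(spec, n_reads, seed):
    """Shotgun-scale oracle alignments for one simulated family."""
    pools, truth = simkit.assemble_genomes([spec], seed=seed)
    rs, rt = simkit.sample_reads(pools.pool(GERMLINE), n_reads, seed=seed + 1)
    alns = simkit.oracle_alignments(rs, rt, pools)
    return pools.families[0], alns, truth


def _recovery_errors(seed):
    """(raw error, refined error) vs true mean age, one simulated family."""
    spec = FamilySpec("fam", "DNA-hAT", consensus_length=2000,
                      copy_count_germline=300, master_drift_subs=8,
                      cpg_rate_multiplier=3.0,
                      age_distribution=AgeDistribution.uniform(0.01, 0.04))
    fam, alns, truth = _read_scale_family(spec, n_reads=400, seed=seed * 100)
    est = divergence.refine_all(alns, [fam])
    true_mean = truth.copies.p_true.mean()
    raw_d = np.mean([divergence.jukes_cantor(p) for p in est.raw_p])
    ref_d = est.jc_distance.mean()
    return abs(raw_d - true_mean), abs(ref_d - true_mean)


def test_refinement_reduces_upward_bias():
    """Refined divergence closer to true age than raw in >= 95 % of seeds."""
    wins = sum(ref < raw for raw, ref in (_recovery_errors(s) for s in range(20)))
    assert wins >= 19


def test_no_drift_no_cpg_refined_close_to_raw():
    """Without drift or CpG effects, exclusion changes divergence < 2 % relative.

    At shotgun read depth, spurious shared-signature collisions are rare, so
    refined and raw mismatch proportions nearly coincide.
    """
    spec = FamilySpec("fam", "DNA-hAT", consensus_length=2000,
                      copy_count_germline=1200, master_drift_subs=0,
                      cpg_rate_multiplier=1.0,
                      age_distribution=AgeDistribution.point(0.05))
    fam, alns, _ = _read_scale_family(spec, n_reads=250, seed=4100)
    est = divergence.refine_all(alns, [fam])
    rel = abs(est.refined_p.mean() - est.raw_p.mean()) / est.raw_p.mean()
    assert rel < 0.02


# ---------------------------------------------------------------------------
# distributions and KS

def test_distribution_all_zero_first_bin():
    dist = divergence.divergence_distribution([0.0] * 10, GERMLINE)
    assert dist.proportions[0] == 1.0


def test_distribution_proportions_sum_to_one(oracle_alignments, landscape):
    est = divergence.refine_all(oracle_alignments, landscape.library)
    vals = est.loc[est.genome_label == GERMLINE, "jc_percent"].dropna()
    dist = divergence.divergence_distribution(vals, GERMLINE)
    assert dist.proportions.sum() == pytest.approx(1.0, abs=1e-9)
    assert (dist.proportions >= 0).all()


def test_young_pointmass_modal_bin_below_one_percent():
    spec = FamilySpec("young", "DNA-hAT", consensus_length=1500,
                      copy_count_germline=60, master_drift_subs=1,
                      age_distribution=AgeDistribution.point(0.005))
    fam, copies, _ = simkit.evolve_family(spec, seed=51)
    alns = [CopyAlignment(cid, "young", GERMLINE, 0, len(s), 0, len(s),
                          fam.consensus, s) for cid, s in copies.items()]
    est = divergence.refine_all(alns, [fam])
    dist = divergence.divergence_distribution(est.jc_percent.dropna(), GERMLINE)
    assert dist.proportions.argmax() == 0


def test_ks_identical_samples():
    d, p = divergence.ks_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert d == 0.0
    assert p == pytest.approx(1.0)


def test_ks_degenerate_input():
    assert divergence.ks_compare([1.0] * 5, [1.0] * 5) == (0.0, 1.0)


def test_ks_power_separated_normals(rng):
    """N(0.05) vs N(0.10), n=1000 -> rejection at alpha=0.01 in >= 99 % of seeds."""
    rejections = 0
    for _ in range(50):
        a = rng.normal(0.05, 0.01, 1000)
        b = rng.normal(0.10, 0.01, 1000)
        _, p = divergence.ks_compare(a, b)
        rejections += p < 0.01
    assert rejections == 50


def test_ks_type_one_error_calibrated(rng):
    """Identical generating distributions -> ~5 % rejections at alpha=0.05."""
    n_rep = 2000
    rej = 0
    for _ in range(n_rep):
        a = rng.normal(0.0, 1.0, 60)
        b = rng.normal(0.0, 1.0, 60)
        _, p = divergence.ks_compare(a, b)
        rej += p < 0.05
    assert abs(rej / n_rep - 0.05) < 0.015
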
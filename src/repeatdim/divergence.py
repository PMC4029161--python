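"""Master-lineage-corrected repeat divergence estimation.

A repeat copy's divergence from its family consensus overestimates its age
when the consensus actually summarises several states of a drifting master
element: substitutions that occurred on the active master lineage are
inherited by whole cohorts of copies and inflate every copy-to-consensus
comparison.  This module implements the four-step refinement: catalogue all
substitutions across a family's pairwise alignments, identify shared
(master-lineage) substitution signatures, drop CpG sites (convergence-prone),
recompute each copy's mismatch proportion over the remaining sites, and
convert it to a Jukes-Cantor distance d = -(3/4) ln(1 - (4/3) p).
"""
from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .models import CopyAlignment, RepeatFamily

_VALID = set("ACGT")


@dataclass(frozen=True)
class SubstitutionRecord:
    """One observed substitution in one repeat copy (consensus coordinates)."""

    family_id: str
    consensus_position: int
    ancestral_base: str
    derived_base: str
    copy_id: str

    def __post_init__(self) -> None:
        if self.ancestral_base == self.derived_base:
            raise ValueError("ancestral and derived base identical")
        if self.ancestral_base not in _VALID or self.derived_base not in _VALID:
            raise ValueError("bases must be in {A,C,G,T}")

    @property
    def signature(self) -> Tuple[int, str]:
        return (self.consensus_position, self.derived_base)


@dataclass
class DivergenceEstimate:
    """Raw and refined mismatch proportions plus the Jukes-Cantor distance."""

    copy_id: str
    family_id: str
    genome_label: str
    raw_p: float
    refined_p: float
    n_sites_total: int
    n_sites_excluded_shared: int
    n_sites_excluded_cpg: int
    jc_distance: Optional[float]   # None when refined_p >= 0.75

    @property
    def jc_percent(self) -> Optional[float]:
        return None if self.jc_distance is None else 100.0 * self.jc_distance


@dataclass
class DivergenceDistribution:
    """Figure-style binned divergence profile for one genome."""

    genome_label: str
    bin_edges: np.ndarray          # percent, 1 %-wide, left-closed right-open
    proportions: np.ndarray        # per-bin proportion of repeat-assigned reads
    mean_percent: float
    n: int


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4) ln(1 - (4/3) p); requires p < 0.75."""
    if p >= 0.75:
        raise ValueError("Jukes-Cantor distance undefined for p >= 0.75")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def cpg_positions(consensus: str) -> Set[int]:
    """Both positions of every CpG dinucleotide on the consensus top strand."""
    out: Set[int] = set()
    for i in range(len(consensus) - 1):
        if consensus[i] == "C" and consensus[i + 1] == "G":
            out.add(i)
            out.add(i + 1)
    return out


def catalogue_substitutions(alignments: Sequence[CopyAlignment]
                            ) -> List[SubstitutionRecord]:
    """One record per mismatching non-gap column, germline and soma pooled.

    Alignments are expected to already pass the identity/overlap filters.
    Gap columns and columns with ambiguous bases produce no records.
    """
    records: List[SubstitutionRecord] = []
    for aln in alignments:
        for cb, rb, pos in aln.columns():
            if pos is None or rb == "-":
                continue
            if cb not in _VALID or rb not in _VALID:
                continue
            if cb != rb:
                records.append(SubstitutionRecord(
                    aln.family_id, pos, cb, rb, aln.copy_id))
    return records


def find_shared_substitutions(records: Sequence[SubstitutionRecord],
                              min_copies: int = 2,
                              min_group: int = 2) -> Set[int]:
    """Consensus positions carrying likely master-lineage substitutions.

    A substitution signature (position, derived base) is *shared* when seen
    in >= ``min_copies`` distinct copies.  Shared signatures are grouped by
    the exact set of copies carrying them; a group is excluded only when it
    contains >= ``min_group`` signatures ("groups of two or more
    substitutions shared by two or more copies").  ``min_group=1`` gives the
    laxer reading in which every shared signature is excluded on its own.
    """
    carriers: Dict[Tuple[int, str], Set[str]] = defaultdict(set)
    for rec in records:
        carriers[rec.signature].add(rec.copy_id)
    groups: Dict[FrozenSet[str], List[Tuple[int, str]]] = defaultdict(list)
    for sig, copies in carriers.items():
        if len(copies) >= min_copies:
            groups[frozenset(copies)].append(sig)
    excluded: Set[int] = set()
    for sigs in groups.values():
        if len(sigs) >= min_group:
            excluded.update(pos for pos, _ in sigs)
    return excluded


def refine_divergence(alignment: CopyAlignment,
                      excluded_shared: Set[int],
                      excluded_cpg: Set[int]) -> Optional[DivergenceEstimate]:
    """Recompute divergence with excluded sites removed from numerator and
    denominator, then apply the Jukes-Cantor correction.

    Returns None (with a warning) when no countable columns remain.
    """
    total = mismatch_all = 0
    kept = mismatch_kept = 0
    n_shared = n_cpg = 0
    for cb, rb, pos in alignment.columns():
        if pos is None or rb == "-" or cb not in _VALID or rb not in _VALID:
            continue
        total += 1
        is_mm = cb != rb
        if is_mm:
            mismatch_all += 1
        if pos in excluded_shared:
            n_shared += 1
            continue
        if pos in excluded_cpg:
            n_cpg += 1
            continue
        kept += 1
        if is_mm:
            mismatch_kept += 1
    if kept == 0:
        warnings.warn(f"{alignment.copy_id}: no countable columns after exclusion")
        return None
    raw_p = mismatch_all / total
    refined_p = mismatch_kept / kept
    jc = jukes_cantor(refined_p) if refined_p < 0.75 else None
    return DivergenceEstimate(
        copy_id=alignment.copy_id, family_id=alignment.family_id,
        genome_label=alignment.genome_label,
        raw_p=raw_p, refined_p=refined_p,
        n_sites_total=total, n_sites_excluded_shared=n_shared,
        n_sites_excluded_cpg=n_cpg, jc_distance=jc,
    )


def refine_family(alignments: Sequence[CopyAlignment],
                  consensus: str,
                  min_copies: int = 2,
                  min_group: int = 2) -> List[DivergenceEstimate]:
    """Run the full refinement for one family (alignments from both genomes)."""
    records = catalogue_substitutions(alignments)
    shared = find_shared_substitutions(records, min_copies, min_group)
    cpg = cpg_positions(consensus)
    out = []
    for aln in alignments:
        est = refine_divergence(aln, shared, cpg)
        if est is not None:
            out.append(est)
    return out


def refine_all(alignments: Sequence[CopyAlignment],
               library: Sequence[RepeatFamily],
               min_copies: int = 2,
               min_group: int = 2) -> pd.DataFrame:
    """Refinement across a whole library; returns a tidy per-copy table."""
    cons = {fam.family_id: fam.consensus for fam in library}
    sup = {fam.family_id: fam.superfamily for fam in library}
    by_family: Dict[str, List[CopyAlignment]] = defaultdict(list)
    for aln in alignments:
        by_family[aln.family_id].append(aln)
    rows = []
    for fam_id, alns in by_family.items():
        for est in refine_family(alns, cons[fam_id], min_copies, min_group):
            rows.append({
                "copy_id": est.copy_id, "family_id": est.family_id,
                "superfamily": sup.get(est.family_id, "Unknown"),
                "genome_label": est.genome_label,
                "raw_p": est.raw_p, "refined_p": est.refined_p,
                "n_sites_total": est.n_sites_total,
                "n_excluded_shared": est.n_sites_excluded_shared,
                "n_excluded_cpg": est.n_sites_excluded_cpg,
                "jc_distance": est.jc_distance,
                "jc_percent": est.jc_percent,
            })
    return pd.DataFrame(rows, columns=[
        "copy_id", "family_id", "superfamily", "genome_label", "raw_p",
        "refined_p", "n_sites_total", "n_excluded_shared", "n_excluded_cpg",
        "jc_distance", "jc_percent"])


def divergence_distribution(values_percent: Iterable[float],
                            genome_label: str) -> DivergenceDistribution:
    """1 %-wide left-closed binning of divergence percentages.

    Proportions are per-bin read counts over the genome's total
    repeat-assigned reads, so they sum to 1.
    """
    vals = np.asarray([v for v in values_percent if v is not None and np.isfinite(v)])
    if vals.size == 0:
        raise ValueError("no divergence estimates to bin")
    top = max(1, int(math.floor(vals.max())) + 1)
    edges = np.arange(0, top + 1, dtype=float)
    counts, _ = np.histogram(vals, bins=edges)
    props = counts / vals.size
    return DivergenceDistribution(genome_label, edges, props,
                                  float(vals.mean()), int(vals.size))


def ks_compare(d_germline: Sequence[float], d_soma: Sequence[float]
               ) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on un-binned divergence values."""
    a = np.asarray(list(d_germline), dtype=float)
    b = np.asarray(list(d_soma), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 estimates per genome")
    if np.unique(np.concatenate([a, b])).size == 1:
        return 0.0, 1.0
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
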
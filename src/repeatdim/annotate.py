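"""Native read-to-repeat-library assignment and masking summaries.

Each read is assigned to at most one repeat family: the highest-scoring
local alignment (affine gap scoring) of the read, on either strand, against
any library consensus, subject to the study's >= 80 % identity and >= 100 bp
overlap filters.  A fast edit-distance infix prescreen (edlib) locates
candidate families and windows; the reported alignment is then computed with
affine scoring inside the located window.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np
import pandas as pd
from Bio import Align

from .models import CopyAlignment, MaskRecord, RepeatFamily, revcomp
from .seqio import merge_mask_intervals
from .simkit import ReadSet

#: Known-TE classes are reported per superfamily; these three are the
#: catch-all classes of the masking summaries.
CATCHALL_CLASSES = ("Simple", "Unknown", "rRNA")


@dataclass(frozen=True)
class Scoring:
    """Affine local-alignment scoring; defaults make the identity filter,
    not the score, the effective gate."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -1


def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _window_align(aligner: Align.PairwiseAligner, query: str, consensus: str,
                  loc: Tuple[int, int], margin: int = 32
                  ) -> Optional[Tuple[float, str, str, int, int, int, int]]:
    """Affine local alignment of query against a consensus window.

    Returns (score, aligned_cons, aligned_query, cons_start, cons_end,
    q_start, q_end) with consensus coordinates offset back to the full
    consensus, or None when no positive-scoring alignment exists.
    """
    w_start = max(0, loc[0] - margin)
    w_end = min(len(consensus), loc[1] + 1 + margin)
    window = consensus[w_start:w_end]
    try:
        alignment = aligner.align(window, query)[0]
    except (IndexError, ValueError):
        return None
    t0, t1 = int(alignment.coordinates[0][0]), int(alignment.coordinates[0][-1])
    q0, q1 = int(alignment.coordinates[1][0]), int(alignment.coordinates[1][-1])
    return (float(alignment.score), str(alignment[0]), str(alignment[1]),
            w_start + t0, w_start + t1, q0, q1)


def assign_read(read_id: str,
                seq: str,
                library: Sequence[RepeatFamily],
                genome_label: str = "germline",
                min_identity: float = 0.80,
                min_overlap: int = 100,
                scoring: Scoring = Scoring(),
                max_candidates: int = 3,
                _aligner: Optional[Align.PairwiseAligner] = None,
                ) -> Optional[CopyAlignment]:
    """Best passing alignment of one read against the library, or None.

    Ties are broken by higher score, then higher identity, then
    lexicographic family_id.  Reads shorter than ``min_overlap`` cannot pass
    the overlap filter and return None.
    """
    if not library:
        raise ValueError("empty repeat library")
    if len(seq) < min_overlap:
        return None
    aligner = _aligner if _aligner is not None else _make_aligner(scoring)
    rc = revcomp(seq)
    kmax = max(int(len(seq) * 0.35), 8)

    prescreen = []
    for fam in library:
        for strand, q in (("+", seq), ("-", rc)):
            hit = edlib.align(q, fam.consensus, mode="HW", task="locations", k=kmax)
            if hit["editDistance"] >= 0:
                prescreen.append((hit["editDistance"], fam.family_id, strand,
                                  fam, hit["locations"][0]))
    if not prescreen:
        return None
    prescreen.sort(key=lambda t: (t[0], t[1], t[2]))

    best: Optional[CopyAlignment] = None
    best_key = None
    seen = set()
    for dist, fam_id, strand, fam, loc in prescreen:
        if (fam_id, strand) in seen:
            continue
        seen.add((fam_id, strand))
        if len(seen) > max_candidates:
            break
        q = seq if strand == "+" else rc
        res = _window_align(aligner, q, fam.consensus, loc)
        if res is None:
            continue
        score, a_cons, a_read, c0, c1, q0, q1 = res
        if strand == "+":
            r0, r1 = q0, q1
        else:
            r0, r1 = len(seq) - q1, len(seq) - q0
        aln = CopyAlignment(
            read_id=read_id, family_id=fam.family_id, genome_label=genome_label,
            cons_start=c0, cons_end=c1, read_start=r0, read_end=r1,
            aligned_cons=a_cons, aligned_read=a_read,
            superfamily=fam.superfamily, strand=strand, score=score,
        )
        if aln.identity < min_identity or aln.overlap_bp < min_overlap:
            continue
        key = (aln.score, aln.identity, _NegStr(aln.family_id))
        if best is None or key > best_key:
            best, best_key = aln, key
    return best


class _NegStr(str):
    """Orders lexicographically smaller strings as larger (for max-keying)."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def annotate_readset(readset: ReadSet,
                     library: Sequence[RepeatFamily],
                     min_identity: float = 0.80,
                     min_overlap: int = 100,
                     scoring: Scoring = Scoring(),
                     ) -> List[CopyAlignment]:
    """Assign every read in a read set; unassignable reads are skipped."""
    aligner = _make_aligner(scoring)
    out = []
    for read_id, seq in readset.reads.items():
        aln = assign_read(read_id, seq, library, readset.genome_label,
                          min_identity, min_overlap, scoring, _aligner=aligner)
        if aln is not None:
            out.append(aln)
    return out


def filter_alignments(alignments: Sequence[CopyAlignment],
                      min_identity: float = 0.80,
                      min_overlap: int = 100) -> List[CopyAlignment]:
    """Apply the identity/overlap filters to externally produced alignments."""
    return [a for a in alignments
            if a.identity >= min_identity and a.overlap_bp >= min_overlap]


_ALN_COLUMNS = ["read_id", "family_id", "genome_label", "superfamily", "strand",
                "cons_start", "cons_end", "read_start", "read_end",
                "identity", "overlap_bp", "score", "aligned_cons", "aligned_read"]


def alignments_to_frame(alignments: Sequence[CopyAlignment]) -> pd.DataFrame:
    """Tidy table mirroring CopyAlignment fields (round-trips losslessly)."""
    rows = [{
        "read_id": a.read_id, "family_id": a.family_id,
        "genome_label": a.genome_label, "superfamily": a.superfamily,
        "strand": a.strand, "cons_start": a.cons_start, "cons_end": a.cons_end,
        "read_start": a.read_start, "read_end": a.read_end,
        "identity": a.identity, "overlap_bp": a.overlap_bp, "score": a.score,
        "aligned_cons": a.aligned_cons, "aligned_read": a.aligned_read,
    } for a in alignments]
    return pd.DataFrame(rows, columns=_ALN_COLUMNS)


def frame_to_alignments(frame: pd.DataFrame) -> List[CopyAlignment]:
    return [CopyAlignment(
        read_id=row.read_id, family_id=row.family_id,
        genome_label=row.genome_label, cons_start=int(row.cons_start),
        cons_end=int(row.cons_end), read_start=int(row.read_start),
        read_end=int(row.read_end), aligned_cons=row.aligned_cons,
        aligned_read=row.aligned_read, superfamily=row.superfamily,
        strand=row.strand, score=float(row.score),
    ) for row in frame.itertuples()]


def mask_summary(assignments: Sequence[CopyAlignment],
                 readset: ReadSet) -> pd.DataFrame:
    """Masked bp and masked fraction of total read bp, overall and per class.

    Known-TE assignments are reported per superfamily; ``Simple``,
    ``Unknown`` and ``rRNA`` are reported as their own classes.  Overlapping
    intervals on a read are merged before accounting.
    """
    total_bp = readset.total_bp
    records = [MaskRecord(a.read_id, a.read_start, a.read_end,
                          a.family_id, a.superfamily)
               for a in assignments if a.read_end > a.read_start]
    merged = merge_mask_intervals(records)
    per_class: Dict[str, int] = {}
    for rec in merged:
        per_class[rec.superfamily] = per_class.get(rec.superfamily, 0) + rec.masked_bp
    rows = [{"class": sup, "masked_bp": bp,
             "masked_fraction": bp / total_bp if total_bp else 0.0}
            for sup, bp in sorted(per_class.items())]
    total_masked = sum(per_class.values())
    if total_masked > total_bp:
        raise AssertionError("merged masked bp exceeds total read bp")
    rows.append({"class": "TOTAL", "masked_bp": total_masked,
                 "masked_fraction": total_masked / total_bp if total_bp else 0.0})
    return pd.DataFrame(rows, columns=["class", "masked_bp", "masked_fraction"])


def superfamily_counts(assignments: Sequence[CopyAlignment],
                       n_total_reads: int) -> Tuple[pd.Series, int]:
    """Reads per superfamily (x) and the frequency denominator N.

    Each read contributes once (its single best assignment).  N is the total
    number of reads in the genome's read set, assigned or not, so that
    x/N estimates the probability that a random shotgun read from the genome
    maps to the superfamily.
    """
    counts: Dict[str, int] = {}
    seen = set()
    for a in assignments:
        if a.read_id in seen:
            raise ValueError(f"read {a.read_id} assigned more than once")
        seen.add(a.read_id)
        counts[a.superfamily] = counts.get(a.superfamily, 0) + 1
    if len(seen) > n_total_reads:
        raise ValueError("more assignments than reads")
    return pd.Series(counts, dtype=int).sort_index(), int(n_total_reads)
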
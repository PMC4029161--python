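"""Genome-content extrapolation and ORF identification in unknown repeats.

Masked base-pair fractions from low-coverage shotgun data are extrapolated
to genomic gigabases per repeat class (masked fraction x genome size), and
unknown repeats are screened for open reading frames in all six frames
under a relaxed (no in-frame stop required) and a strict (in-frame stop
required) definition.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import RepeatFamily, revcomp

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"


@dataclass
class GenomeContentProfile:
    """Per-class extrapolated repeat content (Gb) for one genome."""

    genome_label: str
    genome_size_gb: float
    class_fractions: Dict[str, float]
    class_gb: Dict[str, float] = field(init=False)
    total_repeat_gb: float = field(init=False)

    def __post_init__(self) -> None:
        for cls, frac in self.class_fractions.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"masked fraction for {cls} outside [0, 1]")
        total_fraction = sum(self.class_fractions.values())
        if total_fraction > 1 + 1e-9:
            raise AssertionError("class masked fractions sum > 1 (merge invariant violated)")
        self.class_gb = {cls: frac * self.genome_size_gb
                         for cls, frac in self.class_fractions.items()}
        self.total_repeat_gb = sum(self.class_gb.values())

    @property
    def total_masked_fraction(self) -> float:
        return sum(self.class_fractions.values())


@dataclass(frozen=True)
class OrfCall:
    """One open reading frame on a repeat sequence.

    ``frame`` is 0-2 on the forward strand and 3-5 on the reverse strand;
    ``start``/``end`` are 0-based half-open on the repeat's forward
    coordinates.  Strict calls include the stop codon in their length.
    """

    repeat_id: str
    frame: int
    start: int
    end: int
    mode: str
    is_longest: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def extrapolate_content(class_fractions: Mapping[str, float],
                        genome_size_gb: float,
                        genome_label: str = "germline") -> GenomeContentProfile:
    """Class Gb = class masked fraction x genome size (Gb)."""
    return GenomeContentProfile(genome_label, float(genome_size_gb),
                                dict(class_fractions))


def eliminated_repeat_gb(profile_germline: GenomeContentProfile,
                         profile_soma: GenomeContentProfile,
                         ) -> Tuple[float, int]:
    """Repeat Gb lost at diminution: germline total minus soma total.

    Returns (full-precision difference, nearest-integer headline figure).
    A negative difference is reported with a warning, since under pure
    diminution the soma cannot carry more repeat sequence than the germline.
    """
    diff = profile_germline.total_repeat_gb - profile_soma.total_repeat_gb
    if diff < 0:
        warnings.warn("somatic repeat content exceeds germline; "
                      "inconsistent with pure diminution")
    return diff, int(round(diff))


# ---------------------------------------------------------------------------
# ORF finding

def _codon_ok(codon: str) -> bool:
    return "N" not in codon and len(codon) == 3


def _scan_frame(seq: str, offset: int) -> List[Tuple[int, int, bool]]:
    """Longest ORF per inter-stop segment in one frame of one strand.

    Returns (start, end, has_stop) in the scanned sequence's coordinates;
    ``end`` includes the stop codon when present, else the last complete
    codon.  Within a stop-delimited segment only the first (longest) ATG
    run is kept, collapsing overlapping same-frame ORFs.
    """
    n = len(seq)
    calls: List[Tuple[int, int, bool]] = []
    seg_atg: Optional[int] = None
    i = offset
    while i + 3 <= n:
        codon = seq[i:i + 3]
        if _codon_ok(codon) and codon in STOP_CODONS:
            if seg_atg is not None:
                calls.append((seg_atg, i + 3, True))
            seg_atg = None
        elif seg_atg is None and _codon_ok(codon) and codon == START_CODON:
            seg_atg = i
        i += 3
    if seg_atg is not None:
        calls.append((seg_atg, i, False))  # truncated at sequence end, no wrap
    return calls


def find_orfs(repeat_id: str, sequence: str, mode: str = "relaxed",
              min_len: int = 100) -> List[OrfCall]:
    """Six-frame ORF search under the relaxed or strict definition.

    Relaxed: starts with ATG, no in-frame stop within the call, length
    strictly greater than ``min_len`` nt.  Strict: additionally requires an
    in-frame stop codon, which counts toward the length.  Codons containing
    N never match ATG nor a stop.  The longest call per repeat is flagged.
    """
    if mode not in ("relaxed", "strict"):
        raise ValueError("mode must be 'relaxed' or 'strict'")
    seq = sequence.upper()
    L = len(seq)
    rc = revcomp(seq)
    calls: List[OrfCall] = []
    for strand, s in (("+", seq), ("-", rc)):
        for off in range(3):
            frame = off if strand == "+" else 3 + off
            for start, end, has_stop in _scan_frame(s, off):
                if mode == "strict":
                    if not has_stop:
                        continue
                    length = end - start
                else:
                    length = (end - 3 - start) if has_stop else (end - start)
                    end = start + length
                if length <= min_len:
                    continue
                if strand == "+":
                    f_start, f_end = start, end
                else:
                    f_start, f_end = L - end, L - start
                calls.append(OrfCall(repeat_id, frame, f_start, f_end, mode))
    if calls:
        longest = max(range(len(calls)), key=lambda i: (calls[i].length, -i))
        calls = [OrfCall(c.repeat_id, c.frame, c.start, c.end, c.mode,
                         is_longest=(i == longest))
                 for i, c in enumerate(calls)]
    return calls


def orf_census(library: Sequence[RepeatFamily], mode: str = "relaxed",
               min_len: int = 100) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Longest-ORF census over a repeat library.

    Returns a per-repeat table (longest ORF length; 0 when none) and summary
    statistics: repeats with >= 1 ORF, the raw fraction, and the percentage.
    """
    if not library:
        raise ValueError("empty library")
    rows = []
    for fam in library:
        calls = find_orfs(fam.family_id, fam.consensus, mode, min_len)
        longest = max((c.length for c in calls), default=0)
        rows.append({"repeat_id": fam.family_id, "longest_orf_nt": longest,
                     "n_orfs": len(calls), "external_hit": ""})
    table = pd.DataFrame(rows)
    n_with = int((table["longest_orf_nt"] > 0).sum())
    fraction = n_with / len(library)
    summary = {"n_repeats": float(len(library)), "n_with_orf": float(n_with),
               "fraction": fraction, "percent": 100.0 * fraction}
    return table, summary


def census_percent(n_with_orf: int, n_total: int) -> float:
    """Raw percentage n_with_orf / n_total * 100 (no rounding applied)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_with_orf / n_total
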
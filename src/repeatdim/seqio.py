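"""On-disk formats and the replicate-read filter.

FASTA readers/writers, parsers for the RepeatMasker ``.out`` and ``.align``
dialects, repeat-library IO using the ``>familyID#Superfamily`` header
convention, and the prefix-clustering replicate filter applied to
pyrosequencing shotgun reads before any downstream analysis.
"""
from __future__ import annotations

import math
import re
import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from Bio import SeqIO

from .models import CopyAlignment, MaskRecord, RepeatFamily, revcomp

PathLike = Union[str, Path]

#: Closed superfamily vocabulary (configurable per call).  Known-TE taxonomy
#: plus the three catch-all classes.
DEFAULT_SUPERFAMILIES: Tuple[str, ...] = (
    "DNA-Chapaev", "DNA-Ginger1", "DNA-Harbinger", "DNA-hAT", "DNA-Kolobok",
    "DNA-MuDR", "DNA-Polinton", "DNA-Sola", "DNA-Tc1",
    "LINE-CR1", "LINE-L1", "LINE-MINIME_DN", "LINE-Penelope", "LINE-RTE",
    "LTR-BEL", "LTR-Copia", "LTR-DIRS", "LTR-ERV1", "LTR-ERV3", "LTR-Gypsy",
    "LTR-Pao", "SINE-tRNA",
    "Simple", "rRNA", "Unknown",
)

#: Non-TE RepeatMasker class strings and their catch-all mapping.
_BASE_CLASS_MAP = {
    "Simple_repeat": "Simple",
    "Low_complexity": "Simple",
    "Satellite": "Simple",
    "rRNA": "rRNA",
    "Unknown": "Unknown",
    "Unspecified": "Unknown",
}


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: PathLike) -> Dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    IDs are the first whitespace token of each header; sequences are
    normalised to uppercase.  Duplicate IDs are kept but warned about and
    suffix-disambiguated (``id.2``, ``id.3``, ...).
    """
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in seqs:
            k = 2
            while f"{name}.{k}" in seqs:
                k += 1
            warnings.warn(f"duplicate FASTA id {name!r}; storing as {name}.{k}")
            name = f"{name}.{k}"
        seqs[name] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return seqs


def write_fasta(seqs: Union[Mapping[str, str], Iterable[Tuple[str, str]]],
                path: PathLike, width: int = 60) -> None:
    """Write sequences as wrapped FASTA, preserving input order."""
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_library(path: PathLike,
                 vocabulary: Sequence[str] = DEFAULT_SUPERFAMILIES,
                 class_map: Optional[Mapping[str, str]] = None) -> List[RepeatFamily]:
    """Read a repeat library FASTA using ``>familyID#Superfamily`` headers.

    Headers without a ``#`` classification are assigned ``Unknown``.  The
    classification token is mapped into the superfamily vocabulary (both the
    native ``DNA-hAT`` style and the RepeatMasker ``DNA/hAT`` style are
    accepted).
    """
    families = []
    for name, seq in read_fasta(path).items():
        if "#" in name:
            fam_id, label = name.split("#", 1)
            superfamily = map_repeat_class(label, vocabulary, class_map)
        else:
            fam_id, superfamily = name, "Unknown"
        families.append(RepeatFamily(fam_id, superfamily, seq))
    return families


def write_library(families: Iterable[RepeatFamily], path: PathLike) -> None:
    write_fasta(
        ((f"{fam.family_id}#{fam.superfamily}", fam.consensus) for fam in families),
        path,
    )


# ---------------------------------------------------------------------------
# RepeatMasker class mapping

def map_repeat_class(label: str,
                     vocabulary: Sequence[str] = DEFAULT_SUPERFAMILIES,
                     class_map: Optional[Mapping[str, str]] = None) -> str:
    """Map a RepeatMasker class/family string into the superfamily vocabulary.

    ``LINE/L1`` -> ``LINE-L1``; suffixed families fall back to their
    superfamily (``DNA/hAT-Charlie`` -> ``DNA-hAT``); non-TE classes map to
    ``Simple``/``rRNA``; anything unmapped -> ``Unknown``.
    """
    label = label.strip()
    if class_map and label in class_map:
        return class_map[label]
    if label in vocabulary:
        return label
    base = label.split("/")[0].split("-")[0]
    if label in _BASE_CLASS_MAP:
        return _BASE_CLASS_MAP[label]
    if base in _BASE_CLASS_MAP:
        return _BASE_CLASS_MAP[base]
    candidate = label.replace("/", "-")
    while candidate:
        if candidate in vocabulary:
            return candidate
        if "-" not in candidate:
            break
        candidate = candidate.rsplit("-", 1)[0]
    return "Unknown"


# ---------------------------------------------------------------------------
# RepeatMasker .out

def parse_repeatmasker_out(path: PathLike,
                           vocabulary: Sequence[str] = DEFAULT_SUPERFAMILIES,
                           class_map: Optional[Mapping[str, str]] = None,
                           ) -> List[MaskRecord]:
    """Parse a RepeatMasker ``.out`` annotation table into MaskRecords.

    Query coordinates are converted from the file's 1-based inclusive
    convention to 0-based half-open.  An empty annotation section yields an
    empty list.
    """
    records: List[MaskRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if not fields[0].lstrip("-").isdigit():
                continue  # header lines ("SW", "score", ...)
            if len(fields) < 14:
                raise ValueError(f"{path}:{lineno}: expected >=14 columns, got {len(fields)}")
            try:
                qbegin, qend = int(fields[5]), int(fields[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable query coordinates") from exc
            records.append(MaskRecord(
                read_id=fields[4],
                start=qbegin - 1,
                end=qend,
                family_id=fields[9],
                superfamily=map_repeat_class(fields[10], vocabulary, class_map),
            ))
    return records


# ---------------------------------------------------------------------------
# RepeatMasker .align

_ALIGN_HEADER = re.compile(
    r"^\s*(\d+)\s+([\d.]+)\s+([\d.]+)\s+([\d.]+)\s+(\S+)\s+(\d+)\s+(\d+)\s+\(\d+\)\s+(.*)$"
)
_ALIGN_SEQLINE = re.compile(
    r"^(C\s+)?\s*(\S+)\s+(\d+)\s+([A-Za-z-]+)\s+(\d+)\s*$"
)


def parse_repeatmasker_align(path: PathLike,
                             genome_label: str = "unknown",
                             vocabulary: Sequence[str] = DEFAULT_SUPERFAMILIES,
                             class_map: Optional[Mapping[str, str]] = None,
                             ) -> List[CopyAlignment]:
    """Parse a RepeatMasker ``.align`` file (interleaved pairwise blocks).

    Each block contributes one :class:`CopyAlignment`.  Complement ('C') hits
    are reverse-complemented into consensus-forward orientation, so recorded
    consensus coordinates always ascend and substitution bases are reported
    on the consensus strand.
    """
    alignments: List[CopyAlignment] = []
    state: Optional[dict] = None

    def finalize(st: dict) -> None:
        q = "".join(st["qparts"])
        c = "".join(st["cparts"])
        if len(q) != len(c):
            raise ValueError(
                f"{path}: block for {st['read_id']} has query/consensus "
                f"length mismatch ({len(q)} vs {len(c)})"
            )
        strand = "-" if st["complement"] else "+"
        if st["complement"]:
            q, c = revcomp(q), revcomp(c)
        rep = st["rep_label"]
        if "#" in rep:
            fam_id, label = rep.split("#", 1)
            superfamily = map_repeat_class(label, vocabulary, class_map)
        else:
            fam_id, superfamily = rep, "Unknown"
        clo, chi = min(st["cpos"]), max(st["cpos"])
        alignments.append(CopyAlignment(
            read_id=st["read_id"],
            family_id=fam_id,
            genome_label=genome_label,
            cons_start=clo - 1,
            cons_end=chi,
            read_start=st["qbegin"] - 1,
            read_end=st["qend"],
            aligned_cons=c.upper(),
            aligned_read=q.upper(),
            superfamily=superfamily,
            strand=strand,
            score=float(st["score"]),
        ))

    with open(path) as fh:
        for line in fh:
            header = _ALIGN_HEADER.match(line)
            if header:
                if state is not None:
                    finalize(state)
                rest = header.group(8).split()
                complement = rest and rest[0] == "C"
                if complement:
                    rest = rest[1:]
                state = {
                    "score": header.group(1),
                    "read_id": header.group(5),
                    "qbegin": int(header.group(6)),
                    "qend": int(header.group(7)),
                    "rep_label": rest[0] if rest else "Unknown",
                    "complement": complement,
                    "qparts": [], "cparts": [], "cpos": [],
                }
                continue
            if state is None:
                continue
            if line.startswith(("Matrix", "Transitions", "Gap_init")):
                finalize(state)
                state = None
                continue
            m = _ALIGN_SEQLINE.match(line)
            if not m:
                continue  # annotation mid-lines, blanks
            if m.group(2) == state["read_id"] and not m.group(1):
                state["qparts"].append(m.group(4))
            else:
                state["cparts"].append(m.group(4))
                state["cpos"].extend((int(m.group(3)), int(m.group(5))))
    if state is not None:
        finalize(state)
    return alignments


# ---------------------------------------------------------------------------
# Replicate filter

def _prefix_identity(longer: np.ndarray, shorter: np.ndarray) -> float:
    """Identity of ``shorter`` against the equal-length prefix of ``longer``."""
    n = shorter.size
    return float(np.count_nonzero(longer[:n] == shorter)) / n


def duplicate_filter(reads: Mapping[str, str],
                     identity_cutoff: float = 0.99,
                     length_requirement: float = 1.0,
                     initial_match: int = 3,
                     ) -> Tuple[Dict[str, str], int]:
    """Remove artifactual replicate reads from a pyrosequencing read set.

    Reads are grouped by their first ``initial_match`` bases (reads with
    different prefixes never cluster).  Within a group, reads are considered
    longest-first; a read is a replicate of an earlier representative if it
    aligns end-to-start against the representative's prefix with identity
    >= ``identity_cutoff`` over at least ``length_requirement`` times its own
    length.  One representative (the longest; ties by first appearance) is
    kept per replicate cluster.

    Returns the kept reads (original input order) and the removed count.
    """
    if not 0 < identity_cutoff <= 1:
        raise ValueError("identity_cutoff must be in (0, 1]")
    if initial_match < 0:
        raise ValueError("initial_match must be >= 0")

    order = list(reads.items())
    groups: Dict[str, List[int]] = {}
    for idx, (_, seq) in enumerate(order):
        groups.setdefault(seq[:initial_match], []).append(idx)

    removed: set = set()
    for members in groups.values():
        members = sorted(members, key=lambda i: (-len(order[i][1]), i))
        reps: List[np.ndarray] = []
        for idx in members:
            seq = order[idx][1]
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            required = math.ceil(length_requirement * arr.size)
            is_replicate = False
            for rep in reps:
                if rep.size < arr.size or arr.size < required:
                    continue
                if _prefix_identity(rep, arr) >= identity_cutoff:
                    is_replicate = True
                    break
            if is_replicate:
                removed.add(idx)
            else:
                reps.append(arr)

    kept = {name: seq for idx, (name, seq) in enumerate(order) if idx not in removed}
    return kept, len(removed)


# ---------------------------------------------------------------------------
# Mask-interval merging (shared bp accounting)

def merge_mask_intervals(records: Sequence[MaskRecord]) -> List[MaskRecord]:
    """Merge overlapping mask intervals on each read.

    Overlapping intervals are merged before bp accounting so a read can never
    be >100 % masked; the merged interval keeps the class attribution of the
    longer contributing record (ties: earlier record).
    """
    by_read: Dict[str, List[MaskRecord]] = {}
    for rec in records:
        by_read.setdefault(rec.read_id, []).append(rec)
    merged: List[MaskRecord] = []
    for read_id, recs in by_read.items():
        recs = sorted(recs, key=lambda r: (r.start, r.end))
        cur_start, cur_end = recs[0].start, recs[0].end
        cur_attr = recs[0]
        for rec in recs[1:]:
            if rec.start < cur_end:  # overlap
                cur_end = max(cur_end, rec.end)
                if rec.masked_bp > cur_attr.masked_bp:
                    cur_attr = rec
            else:
                merged.append(MaskRecord(read_id, cur_start, cur_end,
                                         cur_attr.family_id, cur_attr.superfamily))
                cur_start, cur_end, cur_attr = rec.start, rec.end, rec
        merged.append(MaskRecord(read_id, cur_start, cur_end,
                                 cur_attr.family_id, cur_attr.superfamily))
    return merged
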
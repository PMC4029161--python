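"""Core record types shared across pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterator, Optional, Tuple

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

GERMLINE = "germline"
SOMA = "soma"


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatFamily:
    """A repeat family: consensus (master/ancestral) sequence plus classification.

    ``superfamily`` is a label from the closed taxonomy used throughout the
    package (e.g. ``DNA-hAT``, ``LINE-L1``, ``LTR-Gypsy``) or one of the
    catch-all classes ``Unknown``, ``Simple``, ``rRNA``.
    """

    family_id: str
    superfamily: str
    consensus: str

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class MaskRecord:
    """One masked interval on a shotgun read (0-based half-open)."""

    read_id: str
    start: int
    end: int
    family_id: str
    superfamily: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def masked_bp(self) -> int:
        return self.end - self.start


@dataclass
class CopyAlignment:
    """One read segment aligned to one family consensus.

    Aligned strings are stored in consensus-forward orientation; for a
    complement ('-') hit ``aligned_read`` is the reverse complement of the
    read segment.  Coordinates are 0-based half-open: ``cons_start/cons_end``
    on the consensus, ``read_start/read_end`` on the original (input-strand)
    read.
    """

    read_id: str
    family_id: str
    genome_label: str
    cons_start: int
    cons_end: int
    read_start: int
    read_end: int
    aligned_cons: str
    aligned_read: str
    superfamily: str = "Unknown"
    strand: str = "+"
    score: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.aligned_cons) != len(self.aligned_read):
            raise ValueError(
                f"{self.read_id}: aligned block length mismatch "
                f"({len(self.aligned_cons)} vs {len(self.aligned_read)})"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def copy_id(self) -> str:
        """Identifier of the repeat copy this read samples."""
        return f"{self.read_id}/{self.genome_label}"

    def columns(self) -> Iterator[Tuple[str, str, Optional[int]]]:
        """Yield (consensus base, read base, consensus position) per column.

        The consensus position is ``None`` for columns where the consensus
        carries a gap.
        """
        pos = self.cons_start
        for cb, rb in zip(self.aligned_cons, self.aligned_read):
            if cb == "-":
                yield cb, rb, None
            else:
                yield cb, rb, pos
                pos += 1

    @cached_property
    def overlap_bp(self) -> int:
        """Aligned non-gap columns."""
        return sum(
            1 for cb, rb in zip(self.aligned_cons, self.aligned_read)
            if cb != "-" and rb != "-"
        )

    @cached_property
    def n_mismatch(self) -> int:
        return sum(
            1 for cb, rb in zip(self.aligned_cons, self.aligned_read)
            if cb != "-" and rb != "-" and cb != rb
        )

    @property
    def identity(self) -> float:
        """Matching columns / aligned non-gap columns."""
        if self.overlap_bp == 0:
            return 0.0
        return 1.0 - self.n_mismatch / self.overlap_bp
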
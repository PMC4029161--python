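"""Seeded synthetic repeat-landscape generator.

Emulates the statistical structure the downstream analysis assumes: repeat
families descending from drifting master lineages, per-copy age (expected
divergence) distributions, CpG hypermutability, chromatin diminution as
per-copy Bernoulli survival into the soma, and shotgun sampling of
fixed-length-distribution reads from each genome.  Every stochastic choice
is recorded in ground-truth tables so downstream estimators can be tested
for parameter recovery.

Substitutions only by default; a small-indel mode exists but defaults off so
the substitution-based divergence oracle stays exact.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .models import GERMLINE, SOMA, CopyAlignment, RepeatFamily, revcomp

PathLike = Union[str, Path]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_OTHER = {b: _BASES[_BASES != b] for b in _BASES}

#: (mean, sd, min) read-length models matching the 454 shotgun scale of the
#: study system (germline / somatic average read lengths 183 and 216 bp).
GERMLINE_READ_MODEL = (183.0, 40.0, 50)
SOMA_READ_MODEL = (216.0, 45.0, 50)

#: Haploid-equivalent genome sizes (Gb) of the study system.
GERMLINE_GB = 15.0
SOMA_GB = 3.0


# ---------------------------------------------------------------------------
# Age distributions

@dataclass(frozen=True)
class AgeDistribution:
    """Distribution of per-copy expected divergence p_true, support in [0, 0.20].

    Kinds: ``point`` (point mass at ``a``), ``uniform`` (uniform on [a, b]),
    ``mixture`` (two-component mixture of other distributions).
    """

    kind: str
    a: float = 0.0
    b: float = 0.0
    components: Tuple[Tuple[float, "AgeDistribution"], ...] = ()

    MAX_P = 0.20

    @classmethod
    def point(cls, p: float) -> "AgeDistribution":
        return cls("point", a=p)

    @classmethod
    def uniform(cls, lo: float, hi: float) -> "AgeDistribution":
        return cls("uniform", a=lo, b=hi)

    @classmethod
    def mixture(cls, w1: float, d1: "AgeDistribution",
                d2: "AgeDistribution") -> "AgeDistribution":
        return cls("mixture", components=((w1, d1), (1.0 - w1, d2)))

    def __post_init__(self) -> None:
        lo, hi = self.support()
        if lo < 0 or hi > self.MAX_P:
            raise ValueError(f"age distribution support [{lo}, {hi}] outside [0, {self.MAX_P}]")

    def support(self) -> Tuple[float, float]:
        if self.kind == "point":
            return self.a, self.a
        if self.kind == "uniform":
            return self.a, self.b
        if self.kind == "mixture":
            los, his = zip(*(c.support() for _, c in self.components))
            return min(los), max(his)
        raise ValueError(f"unknown age distribution kind {self.kind!r}")

    def mean(self) -> float:
        if self.kind == "point":
            return self.a
        if self.kind == "uniform":
            return 0.5 * (self.a + self.b)
        return sum(w * c.mean() for w, c in self.components)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "point":
            return np.full(n, self.a)
        if self.kind == "uniform":
            return rng.uniform(self.a, self.b, size=n)
        weights = np.array([w for w, _ in self.components])
        choice = rng.choice(len(self.components), size=n, p=weights / weights.sum())
        out = np.empty(n)
        for i, (_, comp) in enumerate(self.components):
            mask = choice == i
            out[mask] = comp.sample(rng, int(mask.sum()))
        return out


# ---------------------------------------------------------------------------
# Family specification

@dataclass(frozen=True)
class FamilySpec:
    """Generative parameters for one repeat family."""

    family_id: str
    superfamily: str = "Unknown"
    consensus_length: int = 1000
    copy_count_germline: int = 50
    retention_prob: float = 1.0
    age_distribution: AgeDistribution = field(
        default_factory=lambda: AgeDistribution.point(0.05))
    master_drift_subs: int = 0
    cpg_rate_multiplier: float = 1.0
    indel_rate: float = 0.0           # off by default (substitution-only model)
    indel_mean_len: float = 2.0       # geometric mean length when enabled

    def __post_init__(self) -> None:
        if not 0 <= self.retention_prob <= 1:
            raise ValueError("retention_prob must be in [0, 1]")
        if self.consensus_length < 200:
            raise ValueError("consensus_length must be >= 200 (100 bp overlap filter)")
        if self.copy_count_germline < 1:
            raise ValueError("copy_count_germline must be >= 1")
        if self.cpg_rate_multiplier < 1:
            raise ValueError("cpg_rate_multiplier must be >= 1")
        if self.master_drift_subs < 0 or self.master_drift_subs > self.consensus_length:
            raise ValueError("master_drift_subs out of range")
        _, hi = self.age_distribution.support()
        if hi * self.cpg_rate_multiplier > 0.75:
            raise ValueError(
                "per-site substitution probability p_true * cpg_rate_multiplier "
                "may exceed 0.75; must stay a probability safely below saturation"
            )


# ---------------------------------------------------------------------------
# Truth bookkeeping

@dataclass
class SimTruth:
    """Ground truth emitted by the generator.

    copies:         one row per copy (family_id, copy_id, germline, soma,
                    p_true, branch_k, n_subs).
    substitutions:  one row per realised difference from consensus
                    (family_id, copy_id, pos, ancestral, derived, origin).
    families:       per-family true frequencies as copy-bp fractions of each
                    pool, retention probability and true ratio.
    master_subs:    family_id -> ordered [(pos, ancestral, derived), ...] on
                    the master lineage.
    reads:          appended by :func:`sample_reads`; one row per read
                    (read_id, genome_label, family_id, copy_id, start,
                    length, strand, background).
    """

    copies: pd.DataFrame
    substitutions: pd.DataFrame
    families: pd.DataFrame
    master_subs: Dict[str, List[Tuple[int, str, str]]]
    reads: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class GenomePools:
    """Copy pools for both genomes; the soma pool is a subset of the germline."""

    families: List[RepeatFamily]
    copies: Dict[str, str]                 # copy_id -> sequence
    germline_ids: List[str]
    soma_ids: List[str]

    def pool(self, genome_label: str) -> List[Tuple[str, str, str]]:
        """(family_id, copy_id, sequence) triples for one genome."""
        ids = self.germline_ids if genome_label == GERMLINE else self.soma_ids
        return [(cid.split(":")[0], cid, self.copies[cid]) for cid in ids]


@dataclass
class ReadSet:
    """Shotgun reads sampled from one genome."""

    genome_label: str
    reads: Dict[str, str]
    genome_size_gb: Optional[float] = None
    read_length_model: Tuple[float, float, int] = GERMLINE_READ_MODEL

    @property
    def total_bp(self) -> int:
        return sum(len(s) for s in self.reads.values())

    def __len__(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# Core operations

def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(_BASES, size=length)

def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()

def _cpg_site_mask(cons: np.ndarray) -> np.ndarray:
    """Both positions of every consensus top-strand CpG dinucleotide."""
    mask = np.zeros(cons.size, dtype=bool)
    is_cg = (cons[:-1] == ord("C")) & (cons[1:] == ord("G"))
    mask[:-1] |= is_cg
    mask[1:] |= is_cg
    return mask


def evolve_family(spec: FamilySpec, seed: Union[int, np.random.Generator]
                  ) -> Tuple[RepeatFamily, Dict[str, str], SimTruth]:
    """Generate a consensus, a drifting master lineage, and descendant copies.

    The master lineage accumulates ``master_drift_subs`` substitutions in a
    fixed order; each copy branches off after a uniform-random prefix of that
    order and then accumulates private substitutions at per-site probability
    ``p_true`` (times ``cpg_rate_multiplier`` at consensus CpG positions).
    Returns the family, ``{copy_id: sequence}``, and a SimTruth fragment.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L, n = spec.consensus_length, spec.copy_count_germline
    cons = _random_seq(rng, L)

    # ordered master-lineage substitutions
    master: List[Tuple[int, str, str]] = []
    master_state = cons.copy()
    if spec.master_drift_subs:
        positions = rng.choice(L, size=spec.master_drift_subs, replace=False)
        for pos in positions:
            old = master_state[pos]
            new = rng.choice(_OTHER[old])
            master.append((int(pos), chr(old), chr(new)))
            master_state[pos] = new

    cpg = _cpg_site_mask(cons)
    p_true = spec.age_distribution.sample(rng, n)
    site_mult = np.where(cpg, spec.cpg_rate_multiplier, 1.0)

    copies: Dict[str, str] = {}
    copy_rows = []
    sub_pos: List[np.ndarray] = []
    sub_anc: List[np.ndarray] = []
    sub_der: List[np.ndarray] = []
    sub_copy_idx: List[np.ndarray] = []
    sub_master: List[np.ndarray] = []
    copy_ids: List[str] = []
    for i in range(n):
        copy_id = f"{spec.family_id}:c{i:04d}"
        copy_ids.append(copy_id)
        k = int(rng.integers(0, len(master) + 1))
        seq = cons.copy()
        for pos, _anc, der in master[:k]:
            seq[pos] = ord(der)
        p_site = p_true[i] * site_mult
        if p_site.max() > 0.75:
            raise ValueError("per-site substitution probability exceeds 0.75")
        hits = np.nonzero(rng.random(L) < p_site)[0]
        for pos in hits:
            seq[pos] = rng.choice(_OTHER[seq[pos]])
        if spec.indel_rate > 0:
            seq = _apply_indels(rng, seq, spec.indel_rate, spec.indel_mean_len)
        copies[copy_id] = _to_str(seq)

        if spec.indel_rate == 0:
            diff = np.nonzero(seq != cons)[0]
            inherited = {(pos, ord(der)) for pos, _a, der in master[:k]}
            sub_pos.append(diff.astype(np.int32))
            sub_anc.append(cons[diff])
            sub_der.append(seq[diff])
            sub_copy_idx.append(np.full(diff.size, i, dtype=np.int32))
            sub_master.append(np.fromiter(
                ((int(p), int(seq[p])) in inherited for p in diff),
                dtype=bool, count=diff.size))
            n_subs = diff.size
        else:
            n_subs = -1
        copy_rows.append({
            "family_id": spec.family_id, "copy_id": copy_id,
            "germline": True, "soma": True,
            "p_true": float(p_true[i]), "branch_k": k, "n_subs": int(n_subs),
        })

    family = RepeatFamily(spec.family_id, spec.superfamily, _to_str(cons))
    if sub_pos:
        pos_all = np.concatenate(sub_pos)
        idx_all = np.concatenate(sub_copy_idx)
        code = np.zeros(256, dtype=np.int8)
        for j, b in enumerate(b"ACGT"):
            code[b] = j
        subs = pd.DataFrame({
            "family_id": pd.Categorical([spec.family_id] * pos_all.size),
            "copy_id": pd.Categorical.from_codes(idx_all, categories=copy_ids),
            "pos": pos_all,
            "ancestral": pd.Categorical.from_codes(
                code[np.concatenate(sub_anc)], categories=list("ACGT")),
            "derived": pd.Categorical.from_codes(
                code[np.concatenate(sub_der)], categories=list("ACGT")),
            "origin": pd.Categorical.from_codes(
                np.concatenate(sub_master).astype(np.int8),
                categories=["private", "master"]),
        })
    else:
        subs = pd.DataFrame(columns=["family_id", "copy_id", "pos",
                                     "ancestral", "derived", "origin"])
    truth = SimTruth(
        copies=pd.DataFrame(copy_rows),
        substitutions=subs,
        families=pd.DataFrame(),
        master_subs={spec.family_id: master},
    )
    return family, copies, truth


def _apply_indels(rng: np.random.Generator, seq: np.ndarray,
                  rate: float, mean_len: float) -> np.ndarray:
    """Optional small-indel mode (geometric lengths); off by default."""
    out: List[np.ndarray] = []
    i = 0
    p_len = 1.0 / max(mean_len, 1.0)
    while i < seq.size:
        r = rng.random()
        if r < rate / 2:                       # deletion
            i += int(rng.geometric(p_len))
        elif r < rate:                         # insertion
            out.append(_random_seq(rng, int(rng.geometric(p_len))))
            out.append(seq[i:i + 1]); i += 1
        else:
            out.append(seq[i:i + 1]); i += 1
    return np.concatenate(out) if out else seq[:0]


def assemble_genomes(specs: Sequence[FamilySpec], seed: int
                     ) -> Tuple[GenomePools, SimTruth]:
    """Evolve every family and apply diminution (Bernoulli retention) per copy.

    The soma pool is always a subset of the germline pool.  True per-family
    frequencies are recorded as copy-bp fractions of each pool.
    """
    if not specs:
        raise ValueError("need at least one FamilySpec")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(specs) + 1)
    retention_rng = np.random.default_rng(child_seeds[-1])

    families, copies = [], {}
    copy_frames, sub_frames, master_subs = [], [], {}
    germline_ids, soma_ids = [], []
    for spec, child in zip(specs, child_seeds):
        fam, fam_copies, truth = evolve_family(spec, np.random.default_rng(child))
        families.append(fam)
        copies.update(fam_copies)
        master_subs.update(truth.master_subs)
        ctab = truth.copies
        keep = retention_rng.random(len(ctab)) < spec.retention_prob
        ctab = ctab.assign(soma=keep)
        copy_frames.append(ctab)
        sub_frames.append(truth.substitutions)
        germline_ids.extend(ctab["copy_id"])
        soma_ids.extend(ctab.loc[keep, "copy_id"])

    copy_table = pd.concat(copy_frames, ignore_index=True)
    sub_table = pd.concat(sub_frames, ignore_index=True)

    lengths = copy_table["copy_id"].map(lambda c: len(copies[c]))
    copy_table = copy_table.assign(length=lengths)
    g_bp = copy_table["length"].sum()
    s_bp = copy_table.loc[copy_table["soma"], "length"].sum()
    fam_rows = []
    for spec in specs:
        sub = copy_table[copy_table["family_id"] == spec.family_id]
        fg = sub["length"].sum() / g_bp
        fs = sub.loc[sub["soma"], "length"].sum() / s_bp if s_bp else 0.0
        fam_rows.append({
            "family_id": spec.family_id, "superfamily": spec.superfamily,
            "retention_prob": spec.retention_prob,
            "true_freq_germline": fg, "true_freq_soma": fs,
            "true_ratio": fg / fs if fs > 0 else np.nan,
            "mean_p_true": spec.age_distribution.mean(),
        })

    pools = GenomePools(families, copies, germline_ids, soma_ids)
    truth = SimTruth(copy_table, sub_table, pd.DataFrame(fam_rows), master_subs)
    return pools, truth


def sample_reads(pool: Sequence[Tuple[str, str, str]],
                 n_reads: int,
                 read_length_model: Tuple[float, float, int] = GERMLINE_READ_MODEL,
                 background_fraction: float = 0.0,
                 seed: Union[int, np.random.Generator] = 0,
                 genome_label: str = GERMLINE,
                 genome_size_gb: Optional[float] = None,
                 ) -> Tuple[ReadSet, pd.DataFrame]:
    """Sample shotgun reads from a copy pool.

    Reads are uniform-random substrings of pool members (chosen with
    probability proportional to copy length) or, with probability
    ``background_fraction``, random non-repetitive background sequence.
    Reads are emitted on a uniform-random strand.  Start positions, source
    copies and strands are recorded in the returned truth table for oracle
    alignment.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not 0 <= background_fraction < 1:
        raise ValueError("background_fraction must be in [0, 1)")
    if not pool:
        raise ValueError("empty copy pool")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean, sd, min_len = read_length_model

    lengths = np.array([len(seq) for _, _, seq in pool], dtype=float)
    weights = lengths / lengths.sum()

    raw = rng.normal(mean, sd, size=n_reads)
    read_lens = np.maximum(np.rint(raw).astype(int), int(min_len))
    is_bg = rng.random(n_reads) < background_fraction
    src = rng.choice(len(pool), size=n_reads, p=weights)
    strands = np.where(rng.random(n_reads) < 0.5, "+", "-")

    reads: Dict[str, str] = {}
    rows = []
    for i in range(n_reads):
        read_id = f"{genome_label}_{i:06d}"
        rl = int(read_lens[i])
        if is_bg[i]:
            seq = _to_str(_random_seq(rng, rl))
            rows.append({"read_id": read_id, "genome_label": genome_label,
                         "family_id": "", "copy_id": "", "start": -1,
                         "length": rl, "strand": "+", "background": True})
        else:
            fam_id, copy_id, copy_seq = pool[src[i]]
            rl = min(rl, len(copy_seq))
            start = int(rng.integers(0, len(copy_seq) - rl + 1))
            seq = copy_seq[start:start + rl]
            if strands[i] == "-":
                seq = revcomp(seq)
            rows.append({"read_id": read_id, "genome_label": genome_label,
                         "family_id": fam_id, "copy_id": copy_id,
                         "start": start, "length": rl,
                         "strand": str(strands[i]), "background": False})
        reads[read_id] = seq

    readset = ReadSet(genome_label, reads, genome_size_gb, read_length_model)
    return readset, pd.DataFrame(rows)


def subsample_genome(sequences: Mapping[str, str],
                     fraction: float,
                     read_length_model: Tuple[float, float, int] = GERMLINE_READ_MODEL,
                     n_replicates: int = 1,
                     seed: int = 0) -> List[ReadSet]:
    """Randomly subsample a genome into read-length chunks, ``n_replicates`` times.

    Each replicate partitions every input sequence into consecutive chunks
    with lengths drawn from the read-length model, shuffles the chunks, and
    keeps chunks until the target of ``fraction`` x input bp is reached
    (trimming the final chunk so each replicate's total bp matches the target
    exactly).  ``fraction=1`` therefore returns the input itself partitioned.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    total_bp = sum(len(s) for s in sequences.values())
    target = int(round(fraction * total_bp))
    mean, sd, min_len = read_length_model
    out: List[ReadSet] = []
    for rep, child in enumerate(np.random.SeedSequence(seed).spawn(n_replicates)):
        rng = np.random.default_rng(child)
        chunks: List[str] = []
        for name, seq in sequences.items():
            i = 0
            while i < len(seq):
                rl = max(int(round(rng.normal(mean, sd))), int(min_len))
                chunks.append(seq[i:i + rl])
                i += rl
        order = rng.permutation(len(chunks))
        picked: List[str] = []
        acc = 0
        for j in order:
            if acc >= target:
                break
            chunk = chunks[j]
            if acc + len(chunk) > target:
                chunk = chunk[: target - acc]
            picked.append(chunk)
            acc += len(chunk)
        reads = {f"sub{rep}_{k:06d}": chunk for k, chunk in enumerate(picked)}
        out.append(ReadSet(f"subsample{rep}", reads,
                           read_length_model=read_length_model))
    return out


# ---------------------------------------------------------------------------
# Oracle alignments

def oracle_alignments(readset: ReadSet, read_truth: pd.DataFrame,
                      pools: GenomePools) -> List[CopyAlignment]:
    """Build exact read-to-consensus alignments from the simulator's truth.

    In the substitution-only model each copy is colinear with its consensus,
    so the recorded start position gives a gapless alignment.  Background
    reads yield no alignment.
    """
    cons = {fam.family_id: fam.consensus for fam in pools.families}
    out: List[CopyAlignment] = []
    for row in read_truth.itertuples():
        if row.background:
            continue
        read = readset.reads[row.read_id]
        aligned_read = revcomp(read) if row.strand == "-" else read
        c = cons[row.family_id][row.start:row.start + row.length]
        out.append(CopyAlignment(
            read_id=row.read_id, family_id=row.family_id,
            genome_label=readset.genome_label,
            cons_start=int(row.start), cons_end=int(row.start + row.length),
            read_start=0, read_end=int(row.length),
            aligned_cons=c, aligned_read=aligned_read,
            superfamily=next(f.superfamily for f in pools.families
                             if f.family_id == row.family_id),
            strand=row.strand,
        ))
    return out


# ---------------------------------------------------------------------------
# Default landscape (the study conditions)

#: family_id, superfamily, consensus bp, germline copies, retention prob,
#: age distribution, master drift subs, CpG rate multiplier
_DEFAULT_TABLE = [
    ("hAT-1",       "DNA-hAT",       1800, 1100, 0.15, ("u", 0.005, 0.030), 6, 2.0),
    ("hAT-2",       "DNA-hAT",       1200,  600, 0.20, ("u", 0.010, 0.040), 4, 2.0),
    ("MuDR-1",      "DNA-MuDR",      2000,  800, 0.12, ("u", 0.005, 0.035), 5, 2.0),
    ("L1-1",        "LINE-L1",       2500, 1000, 0.18, ("u", 0.010, 0.050), 8, 2.0),
    ("L1-2",        "LINE-L1",       1600,  500, 0.25, ("u", 0.020, 0.060), 3, 2.0),
    ("Gypsy-1",     "LTR-Gypsy",     2200,  900, 0.90, ("u", 0.080, 0.130), 5, 2.0),
    ("Gypsy-2",     "LTR-Gypsy",     1400,  450, 0.85, ("u", 0.090, 0.140), 4, 2.0),
    ("CR1-1",       "LINE-CR1",      1800,  550, 0.95, ("u", 0.100, 0.140), 6, 2.0),
    ("ERV1-1",      "LTR-ERV1",      1500,  400, 0.92, ("u", 0.090, 0.140), 3, 2.0),
    ("DIRS-1",      "LTR-DIRS",      1300,  250, 0.88, ("u", 0.100, 0.140), 2, 2.0),
    ("BEL-1",       "LTR-BEL",       1500,  350, 0.45, ("u", 0.050, 0.090), 4, 2.0),
    ("Copia-1",     "LTR-Copia",     1300,  300, 0.40, ("u", 0.050, 0.090), 3, 2.0),
    ("Chapaev-1",   "DNA-Chapaev",   1100,  200, 0.42, ("u", 0.040, 0.080), 2, 2.0),
    ("Pao-1",       "LTR-Pao",       1400,  325, 0.40, ("u", 0.050, 0.090), 3, 2.0),
    ("Harbinger-1", "DNA-Harbinger", 1200,  225, 0.80, ("u", 0.080, 0.130), 3, 2.0),
    ("Unk-1",       "Unknown",       1500, 1300, 0.15, ("u", 0.005, 0.030), 5, 2.0),
    ("Unk-2",       "Unknown",       1200, 1000, 0.20, ("u", 0.010, 0.050), 4, 2.0),
    ("Unk-3",       "Unknown",       1800,  750, 0.45, ("u", 0.040, 0.090), 6, 2.0),
    ("Unk-4",       "Unknown",       1000,  600, 0.50, ("u", 0.050, 0.090), 2, 2.0),
    ("Unk-5",       "Unknown",       1400,  450, 0.90, ("u", 0.090, 0.140), 4, 2.0),
    ("Unk-6",       "Unknown",        900,  400, 0.85, ("u", 0.100, 0.140), 3, 2.0),
    ("Simple-1",    "Simple",         600,  300, 0.40, ("u", 0.020, 0.060), 0, 1.0),
    ("rRNA-1",      "rRNA",          2000,  150, 0.95, ("p", 0.020, 0.0),   0, 1.0),
]

#: Default read counts per genome: a desk-scale reduction of the study's 454
#: runs (612,470 germline and 207,451 somatic reads), sized so that per-copy
#: sampling depth stays well below 1x, as in the real low-coverage survey.
DEFAULT_N_READS = {GERMLINE: 10_000, SOMA: 5_000}

#: Default background (non-repetitive) read fractions: one minus the study's
#: masked base-pair fractions (87.6 % germline, 71.7 % soma).
DEFAULT_BACKGROUND = {GERMLINE: 0.124, SOMA: 0.283}


def default_landscape(copy_scale: float = 1.0) -> List[FamilySpec]:
    """The default synthetic landscape: young high-frequency DNA/LINE families
    with low somatic retention, old LTR/LINE-CR1 families with high retention,
    and a large complement of unknown repeats.  ``copy_scale`` scales all copy
    counts (for quick demos)."""
    specs = []
    for fam, sup, L, n, r, age, drift, cpg in _DEFAULT_TABLE:
        dist = (AgeDistribution.point(age[1]) if age[0] == "p"
                else AgeDistribution.uniform(age[1], age[2]))
        specs.append(FamilySpec(
            family_id=fam, superfamily=sup, consensus_length=L,
            copy_count_germline=max(int(round(n * copy_scale)), 2),
            retention_prob=r, age_distribution=dist,
            master_drift_subs=drift, cpg_rate_multiplier=cpg,
        ))
    return specs


@dataclass
class Landscape:
    """A fully simulated paired germline/soma landscape."""

    pools: GenomePools
    truth: SimTruth
    readsets: Dict[str, ReadSet]

    @property
    def library(self) -> List[RepeatFamily]:
        return self.pools.families


def simulate_landscape(specs: Optional[Sequence[FamilySpec]] = None,
                       n_reads: Optional[Mapping[str, int]] = None,
                       background: Optional[Mapping[str, float]] = None,
                       read_models: Optional[Mapping[str, Tuple[float, float, int]]] = None,
                       seed: int = 0) -> Landscape:
    """Simulate both genomes and paired shotgun read sets in one call."""
    specs = list(specs) if specs is not None else default_landscape()
    n_reads = dict(DEFAULT_N_READS if n_reads is None else n_reads)
    background = dict(DEFAULT_BACKGROUND if background is None else background)
    read_models = dict(read_models or {GERMLINE: GERMLINE_READ_MODEL,
                                       SOMA: SOMA_READ_MODEL})
    ss = np.random.SeedSequence(seed)
    genome_seed, g_seed, s_seed = ss.spawn(3)
    pools, truth = assemble_genomes(specs, seed)

    read_frames = []
    readsets = {}
    for label, child, size_gb in ((GERMLINE, g_seed, GERMLINE_GB),
                                  (SOMA, s_seed, SOMA_GB)):
        rs, rt = sample_reads(
            pools.pool(label), n_reads[label], read_models[label],
            background.get(label, 0.0), np.random.default_rng(child),
            genome_label=label, genome_size_gb=size_gb)
        readsets[label] = rs
        read_frames.append(rt)
    truth.reads = pd.concat(read_frames, ignore_index=True)
    return Landscape(pools, truth, readsets)


def expected_read_ratio(truth: SimTruth, superfamily: str,
                        background: Mapping[str, float]) -> float:
    """Expected germline/soma read-frequency ratio for a superfamily.

    Read frequencies scale the pool bp shares by (1 - background fraction)
    of each genome's reads.
    """
    fam = truth.families
    sub = fam[fam["superfamily"] == superfamily]
    fg = sub["true_freq_germline"].sum() * (1 - background[GERMLINE])
    fs = sub["true_freq_soma"].sum() * (1 - background[SOMA])
    return fg / fs if fs > 0 else math.inf


# ---------------------------------------------------------------------------
# Output writers

def write_landscape(landscape: Landscape, outdir: PathLike = ".") -> Dict[str, Path]:
    """Write reads (FASTA per genome), the library, and truth tables (TSV)."""
    from . import seqio  # local import; seqio does not depend on simkit

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for label, rs in landscape.readsets.items():
        p = outdir / f"reads_{label}.fasta"
        seqio.write_fasta(rs.reads, p)
        paths[f"reads_{label}"] = p
    p = outdir / "library.fasta"
    seqio.write_library(landscape.library, p)
    paths["library"] = p
    for name in ("copies", "substitutions", "families", "reads"):
        tab: pd.DataFrame = getattr(landscape.truth, name)
        p = outdir / f"truth_{name}.tsv"
        tab.to_csv(p, sep="\t", index=False)
        paths[f"truth_{name}"] = p
    return paths
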
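"""End-to-end orchestration of the synthetic germline/soma repeat analysis.

Chains simulate -> replicate filter -> annotate -> divergence -> frequency
tests -> genome content -> ORF census, writing every stage's outputs and a
machine-readable summary into a run directory.  Stages communicate only
through documented files/tables; any stage failure aborts with the stage
name attached.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import annotate, characterize, divergence, freqstats, seqio, simkit
from .models import GERMLINE, SOMA

log = logging.getLogger("repeatdim")

PathLike = Union[str, Path]


@dataclass
class RunConfig:
    """Flat configuration for a full synthetic run."""

    seed: int = 0
    copy_scale: float = 1.0
    n_reads_germline: int = simkit.DEFAULT_N_READS[GERMLINE]
    n_reads_soma: int = simkit.DEFAULT_N_READS[SOMA]
    background_germline: float = simkit.DEFAULT_BACKGROUND[GERMLINE]
    background_soma: float = simkit.DEFAULT_BACKGROUND[SOMA]
    genome_size_germline_gb: float = simkit.GERMLINE_GB
    genome_size_soma_gb: float = simkit.SOMA_GB
    min_identity: float = 0.80
    min_overlap: int = 100
    dup_identity_cutoff: float = 0.99
    dup_length_requirement: float = 1.0
    dup_initial_match: int = 3
    min_copies: int = 2            # shared-substitution copy threshold
    min_group: int = 2             # shared-substitution group threshold
    bin_corrected: bool = True     # bin JC-corrected (vs raw) divergence
    freq_denominator: str = "all"  # "all" reads or "assigned" reads as N
    alpha: float = 0.05
    n_sim: int = 10_000
    lambda_cutoff: str = "chisq"   # or "simulate"
    orf_min_len: int = 100

    def __post_init__(self) -> None:
        if self.freq_denominator not in ("all", "assigned"):
            raise ValueError("freq_denominator must be 'all' or 'assigned'")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity out of range")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha out of range")

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def run_pipeline(config: RunConfig, outdir: PathLike) -> Dict:
    """Run every stage in dependency order; returns the summary dict.

    Outputs land in ``outdir``; ``summary.json`` reproduces the shapes of the
    per-superfamily comparison table, the genome-content profile, the
    divergence distributions, and the age-by-excision-bin tests.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    summary: Dict = {"seed": config.seed, "stages": {}}
    written: Dict[str, Path] = {}

    def record(stage: str, **paths: Path) -> None:
        summary["stages"][stage] = {
            name: {"path": p.name, "sha256": _sha256(p)}
            for name, p in paths.items()
        }
        written.update(paths)

    # --- simulate -----------------------------------------------------------
    try:
        landscape = simkit.simulate_landscape(
            simkit.default_landscape(config.copy_scale),
            n_reads={GERMLINE: config.n_reads_germline, SOMA: config.n_reads_soma},
            background={GERMLINE: config.background_germline,
                        SOMA: config.background_soma},
            seed=config.seed)
        paths = simkit.write_landscape(landscape, outdir)
        record("simulate", **{k: Path(v) for k, v in paths.items()})
        log.info("simulate: %d families, %d + %d reads",
                 len(landscape.library),
                 len(landscape.readsets[GERMLINE]), len(landscape.readsets[SOMA]))
    except Exception as exc:
        raise StageError("simulate", exc) from exc

    # --- replicate filter ---------------------------------------------------
    try:
        filtered = {}
        for label, rs in landscape.readsets.items():
            kept, removed = seqio.duplicate_filter(
                rs.reads, config.dup_identity_cutoff,
                config.dup_length_requirement, config.dup_initial_match)
            filtered[label] = simkit.ReadSet(label, kept, rs.genome_size_gb,
                                             rs.read_length_model)
            summary.setdefault("replicate_filter", {})[label] = {
                "removed": removed, "removed_fraction": removed / len(rs.reads)}
            p = outdir / f"reads_{label}.filtered.fasta"
            seqio.write_fasta(kept, p)
            record(f"filter_{label}", reads=p)
    except Exception as exc:
        raise StageError("filter-dups", exc) from exc

    # --- annotate -----------------------------------------------------------
    try:
        assignments = {}
        counts = {}
        mask_tables = {}
        for label, rs in filtered.items():
            alns = annotate.annotate_readset(rs, landscape.library,
                                             config.min_identity, config.min_overlap)
            assignments[label] = alns
            frame = annotate.alignments_to_frame(alns)
            p = outdir / f"alignments_{label}.tsv"
            frame.to_csv(p, sep="\t", index=False)
            mask = annotate.mask_summary(alns, rs)
            pm = outdir / f"mask_summary_{label}.tsv"
            mask.to_csv(pm, sep="\t", index=False)
            mask_tables[label] = mask
            n_total = len(rs) if config.freq_denominator == "all" else len(alns)
            counts[label] = annotate.superfamily_counts(alns, n_total)
            record(f"annotate_{label}", alignments=p, mask_summary=pm)
            total_frac = float(mask.loc[mask["class"] == "TOTAL", "masked_fraction"].iloc[0])
            summary.setdefault("masked_fraction", {})[label] = total_frac
    except Exception as exc:
        raise StageError("annotate", exc) from exc

    # --- divergence ---------------------------------------------------------
    try:
        all_alns = assignments[GERMLINE] + assignments[SOMA]
        est = divergence.refine_all(all_alns, landscape.library,
                                    config.min_copies, config.min_group)
        p = outdir / "divergence_estimates.tsv"
        est.to_csv(p, sep="\t", index=False)
        value_col = "jc_percent" if config.bin_corrected else "refined_p"
        dist_frames = []
        for label in (GERMLINE, SOMA):
            sub = est[est["genome_label"] == label]
            vals = (sub[value_col] if config.bin_corrected
                    else 100.0 * sub[value_col]).dropna()
            dist = divergence.divergence_distribution(vals, label)
            dist_frames.append(pd.DataFrame({
                "genome_label": label,
                "bin_lo": dist.bin_edges[:-1], "bin_hi": dist.bin_edges[1:],
                "proportion": dist.proportions}))
            summary.setdefault("divergence", {})[label] = {
                "mean_percent": dist.mean_percent, "n": dist.n}
        pd_path = outdir / "divergence_distributions.tsv"
        pd.concat(dist_frames, ignore_index=True).to_csv(pd_path, sep="\t", index=False)
        d_g = est.loc[est["genome_label"] == GERMLINE, "jc_percent"].dropna()
        d_s = est.loc[est["genome_label"] == SOMA, "jc_percent"].dropna()
        ks_d, ks_p = divergence.ks_compare(d_g, d_s)
        summary["divergence"]["ks"] = {"D": ks_d, "p_value": ks_p}
        record("divergence", estimates=p, distributions=pd_path)
    except Exception as exc:
        raise StageError("divergence", exc) from exc

    # --- superfamily frequency tests ---------------------------------------
    try:
        (xg, n_g), (xs, n_s) = counts[GERMLINE], counts[SOMA]
        known = sorted((set(xg.index) | set(xs.index))
                       - set(annotate.CATCHALL_CLASSES))
        pairs = {sup: freqstats.CountPair(int(xs.get(sup, 0)), int(xg.get(sup, 0)),
                                          n_s, n_g)
                 for sup in known}
        table2 = freqstats.compare_table(pairs, config.alpha, config.n_sim,
                                         config.seed, config.lambda_cutoff)
        p = outdir / "superfamily_comparisons.tsv"
        table2.to_csv(p, sep="\t", index=False)
        summary["superfamily_comparisons"] = {
            row["superfamily"]: {"dominant": row["dominant"],
                                 "ratio": None if pd.isna(row["ratio"]) else row["ratio"],
                                 "p_value": row["p_value"]}
            for _, row in table2.iterrows()}
        record("compare-freqs", table=p)
    except Exception as exc:
        raise StageError("compare-freqs", exc) from exc

    # --- subfamily binning and age-by-bin -----------------------------------
    try:
        fam_counts_g = pd.Series(
            [a.family_id for a in assignments[GERMLINE]]).value_counts()
        fam_counts_s = pd.Series(
            [a.family_id for a in assignments[SOMA]]).value_counts()
        bins = {}
        bin_rows = []
        for fam in landscape.library:
            cp = freqstats.CountPair(int(fam_counts_s.get(fam.family_id, 0)),
                                     int(fam_counts_g.get(fam.family_id, 0)),
                                     n_s, n_g)
            label, stat, pval = freqstats.subfamily_bin(cp, config.alpha)
            bins[fam.family_id] = label
            bin_rows.append({"family_id": fam.family_id,
                             "superfamily": fam.superfamily, "bin": label,
                             "x_g": cp.x_g, "x_s": cp.x_s,
                             "statistic": stat, "p_value": pval})
        bins_path = outdir / "subfamily_bins.tsv"
        pd.DataFrame(bin_rows).to_csv(bins_path, sep="\t", index=False)
        cdfs, ztab = freqstats.age_by_bin(bins, est)
        z_path = outdir / "age_by_bin.tsv"
        ztab.to_csv(z_path, sep="\t", index=False)
        summary["age_by_bin"] = {
            row["comparison"]: {"z": None if pd.isna(row["z"]) else row["z"],
                                "mean": None if pd.isna(row["mean"]) else row["mean"],
                                "mean_equal": (None if pd.isna(row["mean_equal"])
                                               else row["mean_equal"])}
            for _, row in ztab.iterrows()}
        record("age-by-bin", bins=bins_path, ztests=z_path)
    except Exception as exc:
        raise StageError("age-by-bin", exc) from exc

    # --- genome content ------------------------------------------------------
    try:
        profiles = {}
        for label, size in ((GERMLINE, config.genome_size_germline_gb),
                            (SOMA, config.genome_size_soma_gb)):
            mask = mask_tables[label]
            fractions = {row["class"]: row["masked_fraction"]
                         for _, row in mask.iterrows() if row["class"] != "TOTAL"}
            profiles[label] = characterize.extrapolate_content(fractions, size, label)
        diff, headline = characterize.eliminated_repeat_gb(
            profiles[GERMLINE], profiles[SOMA])
        content_rows = []
        for label, prof in profiles.items():
            for cls, gb in sorted(prof.class_gb.items()):
                content_rows.append({"genome_label": label, "class": cls,
                                     "fraction": prof.class_fractions[cls],
                                     "gb": gb})
            content_rows.append({"genome_label": label, "class": "TOTAL",
                                 "fraction": prof.total_masked_fraction,
                                 "gb": prof.total_repeat_gb})
        p = outdir / "genome_content.tsv"
        pd.DataFrame(content_rows).to_csv(p, sep="\t", index=False)
        summary["genome_content"] = {
            "germline_repeat_gb": profiles[GERMLINE].total_repeat_gb,
            "somatic_repeat_gb": profiles[SOMA].total_repeat_gb,
            "eliminated_repeat_gb": diff,
            "eliminated_repeat_gb_headline": headline}
        record("genome-content", table=p)
    except Exception as exc:
        raise StageError("genome-content", exc) from exc

    # --- ORF census on unknown repeats --------------------------------------
    try:
        unknown = [f for f in landscape.library if f.superfamily == "Unknown"]
        orf_summary = {}
        if unknown:
            for mode in ("relaxed", "strict"):
                tab, stats_ = characterize.orf_census(unknown, mode,
                                                      config.orf_min_len)
                p = outdir / f"orfs_{mode}.tsv"
                tab.to_csv(p, sep="\t", index=False)
                orf_summary[mode] = stats_
                record(f"orfs_{mode}", table=p)
        summary["orf_census"] = orf_summary
    except Exception as exc:
        raise StageError("orfs", exc) from exc

    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
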